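"""Upstream-regulator over-representation on hub gene lists.

A generic hypergeometric test against a user-supplied regulator-to-targets
annotation (GMT format) stands in for proprietary pathway software, and the
random-gene-list control guards against enrichment driven purely by the
a-priori bias of the profiling panels: k random lists of the same size are
drawn from the same universe, and a regulator survives only if it is
BH-significant on the real list and strictly more significant than its best
p-value across the random lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .blocks import ValidationError
from .differential import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class RegulatorAnnotation:
    """Regulator id -> target gene-symbol set, restricted to a universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValidationError("empty gene universe")
        trimmed = {}
        for reg, targets in self.sets.items():
            t = set(targets) & self.universe
            if t:
                trimmed[reg] = t
            else:
                log.info("regulator %s has no targets inside the universe; dropped", reg)
        if not trimmed:
            raise ValidationError("no regulator has targets inside the universe")
        self.sets = trimmed


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: one set per line, tab-separated name, description,
    then member gene symbols."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


@dataclass
class EnrichmentResult:
    regulator: str
    overlap: int
    set_size: int
    list_size: int
    universe_size: int
    p_value: float
    q_value: float = float("nan")
    random_min_p: float = float("nan")
    significant_after_control: bool = False


def hypergeom_enrich(gene_list, annotation: RegulatorAnnotation
                     ) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric p per regulator: P[X >= overlap] with X ~
    Hypergeometric(universe, set size, list size); BH q across regulators."""
    genes = set(gene_list)
    if not genes:
        raise ValidationError("empty gene list")
    outside = genes - annotation.universe
    if outside:
        log.warning("%d gene(s) outside the universe dropped: %s",
                    len(outside), sorted(outside)[:5])
        genes -= outside
    if not genes:
        raise ValidationError("no query gene inside the universe")
    m = len(annotation.universe)
    results = []
    for reg in sorted(annotation.sets):
        targets = annotation.sets[reg]
        overlap = len(genes & targets)
        p = float(hypergeom.sf(overlap - 1, m, len(targets), len(genes)))
        results.append(EnrichmentResult(reg, overlap, len(targets), len(genes),
                                        m, min(p, 1.0)))
    q = bh_adjust([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def random_control_filter(
    real_results: list[EnrichmentResult],
    annotation: RegulatorAnnotation,
    list_size: int,
    k_random: int = 3,
    seed: int = 0,
    q_threshold: float = 0.05,
    require_dominance: bool = True,
) -> list[EnrichmentResult]:
    """Mark regulators significant only if BH-significant on the real list
    and (by default) strictly below every random list's p for that regulator.

    ``require_dominance=False`` relaxes to BH significance alone.
    """
    universe = sorted(annotation.universe)
    if list_size > len(universe):
        raise ValidationError("list_size exceeds the universe")
    rng = np.random.default_rng(seed)
    random_min: dict[str, float] = {r.regulator: np.inf for r in real_results}
    for _ in range(k_random):
        draw = rng.choice(len(universe), size=list_size, replace=False)
        random_list = [universe[i] for i in draw]
        for res in hypergeom_enrich(random_list, annotation):
            if res.regulator in random_min:
                random_min[res.regulator] = min(random_min[res.regulator], res.p_value)
    for res in real_results:
        res.random_min_p = float(random_min[res.regulator])
        ok = res.q_value < q_threshold
        if require_dominance:
            ok = ok and res.p_value < res.random_min_p
        res.significant_after_control = bool(ok)
    return real_results
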