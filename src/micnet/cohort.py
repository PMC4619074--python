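"""Seeded synthetic multi-platform cohort generator.

Emulates the data structure of a germ-cell-tumor cohort profiled on four
platforms — GoldenGate-style CpG methylation (beta values with per-probe
detection p-values and X-chromosome annotations), NanoString-style miRNA
counts with positive/negative control probes, an embryonic-stem-cell qPCR
panel (Ct values with housekeeping genes), and diploid genotype calls at four
SNPs — plus sample phenotypes (age, sex, tumor location, histology).

Cross-platform dependence is planted through hub-and-spoke latent factors:
each :class:`HubSpec` introduces one latent variable per sample (optionally
driven by histology severity) and loads a designated hub feature plus >= 4
spoke features on it, through a linear, quadratic or sinusoidal link. All
other features are mutually independent. The planted structure is recorded in
a truth record so downstream network recovery is testable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import OmicsBlock, ValidationError

HISTOLOGIES = ("normal_adjacent", "teratoma", "dysgerminoma", "yst", "mixed")
#: ordinal severity used for the histology-driven latent (lowest to highest)
HISTOLOGY_SEVERITY = {h: float(i) for i, h in enumerate(HISTOLOGIES)}

RELATIONSHIPS = ("linear", "quadratic", "sinusoid")

_SNPS = {
    "SPRY4_rs4324715": ("c", "t"),
    "BAK1_rs210138": ("a", "g"),
    "DMRT1_rs755383": ("c", "t"),
    "KITLG_rs4474514": ("a", "g"),
}

# NanoString-style positive-control ladder (target counts before lane scaling)
_POS_LADDER = (8000.0, 2000.0, 500.0, 125.0, 31.25, 8.0)


@dataclass(frozen=True)
class HubSpec:
    """One planted hub-and-spoke latent factor.

    ``hub_feature`` and each spoke are ``(platform, feature_id)`` pairs; the
    hub feature loads on the latent with a quarter of the cohort noise (it is
    the driver proxy), spokes with the full ``noise_sd``.
    """

    hub_feature: tuple[str, str]
    spoke_features: tuple[tuple[str, str], ...]
    relationship: str = "linear"
    effect_size: float = 1.5
    driven_by: str = "histology_latent"

    def __post_init__(self) -> None:
        if len(self.spoke_features) < 4:
            raise ValidationError("a hub needs at least 4 spokes")
        if self.relationship not in RELATIONSHIPS:
            raise ValidationError(f"unknown relationship {self.relationship!r}")
        if self.driven_by not in ("histology_latent", "independent_latent"):
            raise ValidationError(f"unknown latent driver {self.driven_by!r}")
        if len({p for p, _ in self.spoke_features}) < 2:
            raise ValidationError("spokes must span at least 2 platforms")

    def link(self, z: np.ndarray) -> np.ndarray:
        if self.relationship == "linear":
            return z
        if self.relationship == "quadratic":
            return z * z - 1.0  # centered so Pearson with z is ~0
        return np.sin(math.pi * z)


def _default_histology_counts() -> dict[str, int]:
    return {"yst": 9, "teratoma": 18, "dysgerminoma": 8, "mixed": 4, "normal_adjacent": 7}


def _default_hubs() -> tuple[HubSpec, ...]:
    return (
        HubSpec(
            hub_feature=("stemcell", "SC01"),
            spoke_features=(
                ("methylation", "cg00001"),
                ("methylation", "cg00002"),
                ("methylation", "cg00003"),
                ("mirna", "mir0001"),
                ("mirna", "mir0002"),
                ("mirna", "mir0003"),
            ),
            relationship="linear",
            effect_size=1.5,
            driven_by="histology_latent",
        ),
    )


@dataclass
class CohortSpec:
    """Generator parameters; the defaults mirror the study-scale cohort.

    46 samples (9 YST, 18 teratoma, 8 dysgerminoma, 4 mixed, 7 normal
    adjacent), 1505 CpG loci of which 16 fail detection and 84 are X-linked
    (disjoint sets, so 1405 survive QC), 800 miRNAs with 6 positive and 8
    negative control probes, 84 stem-cell genes plus 5 housekeeping genes,
    and per-platform missingness masks whose union leaves 40 complete-data
    samples (8 YST, hence 32 non-YST).
    """

    histology_counts: dict[str, int] = field(default_factory=_default_histology_counts)
    n_cpg: int = 1505
    n_x_linked: int = 84
    n_detection_fail: int = 16
    n_mirna: int = 800
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    n_genes: int = 84
    n_housekeeping: int = 5
    hub_specs: tuple[HubSpec, ...] = field(default_factory=_default_hubs)
    noise_sd: float = 0.5
    allele_freq: float = 0.3
    seed: int = 0
    missing_samples: dict[str, list[str]] | None = None
    allow_overlapping_flags: bool = False

    def __post_init__(self) -> None:
        counts = dict(self.histology_counts)
        unknown = set(counts) - set(HISTOLOGIES)
        if unknown:
            raise ValidationError(f"unknown histologies: {sorted(unknown)}")
        if any(c < 0 for c in counts.values()) or sum(counts.values()) <= 0:
            raise ValidationError("histology counts must be nonnegative and sum > 0")
        for name in ("n_cpg", "n_mirna", "n_genes", "n_housekeeping",
                     "n_pos_controls", "n_neg_controls"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_x_linked < 0 or self.n_detection_fail < 0:
            raise ValidationError("flag counts must be nonnegative")
        if (not self.allow_overlapping_flags
                and self.n_x_linked + self.n_detection_fail > self.n_cpg):
            raise ValidationError(
                "n_x_linked + n_detection_fail exceeds n_cpg (disjoint flags infeasible)"
            )
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not 0 < self.allele_freq < 1:
            raise ValidationError("allele_freq must lie in (0, 1)")

    @property
    def n_samples(self) -> int:
        return sum(self.histology_counts.values())

    def sample_ids(self) -> list[str]:
        prefix = {"yst": "YST", "teratoma": "TER", "dysgerminoma": "DYS",
                  "mixed": "MIX", "normal_adjacent": "NRM"}
        ids: list[str] = []
        for hist in HISTOLOGIES:
            n = self.histology_counts.get(hist, 0)
            ids.extend(f"{prefix[hist]}{i:02d}" for i in range(1, n + 1))
        return ids

    def default_missing(self) -> dict[str, list[str]]:
        """Per-platform incomplete samples: 3 for miRNA (1 YST, 1 mixed,
        1 normal), 4 for stem cell (1 YST, 1 teratoma, 2 normal); the union
        removes 6 samples from the complete-data set."""
        ids = set(self.sample_ids())
        mirna = [s for s in ("YST01", "MIX01", "NRM01") if s in ids]
        stem = [s for s in ("YST01", "TER01", "NRM02", "NRM03") if s in ids]
        return {"mirna": mirna, "stemcell": stem}


def reduced_spec(seed: int = 0, hubs: tuple[HubSpec, ...] | None = None) -> CohortSpec:
    """A structurally faithful cohort at unit scale (~80 fused features).

    Keeps the 46-sample / 40-complete design and the default planted hub but
    shrinks the feature panels so that all-pairs MIC analysis runs in well
    under a second per cohort.
    """
    return CohortSpec(
        n_cpg=30, n_x_linked=4, n_detection_fail=2,
        n_mirna=30, n_genes=15, n_housekeeping=5,
        hub_specs=_default_hubs() if hubs is None else hubs,
        seed=seed,
    )


@dataclass
class SyntheticCohort:
    """Generated multi-platform data plus the planted-truth record."""

    methylation: OmicsBlock
    detection_p: pd.DataFrame
    mirna: OmicsBlock
    stemcell: OmicsBlock
    genotypes: pd.DataFrame  # SNP-by-sample strings like "a/g"
    annotations: pd.DataFrame  # indexed by sample_id
    truth: dict

    def blocks(self) -> dict[str, OmicsBlock]:
        return {"methylation": self.methylation, "mirna": self.mirna,
                "stemcell": self.stemcell}


def _feature_ids(spec: CohortSpec) -> dict[str, list[str]]:
    return {
        "methylation": [f"cg{i:05d}" for i in range(1, spec.n_cpg + 1)],
        "mirna": [f"mir{i:04d}" for i in range(1, spec.n_mirna + 1)],
        "stemcell": [f"SC{i:02d}" for i in range(1, spec.n_genes + 1)],
    }


def _hub_effects(spec: CohortSpec, samples: list[str], codes: np.ndarray,
                 rng: np.random.Generator) -> tuple[dict[tuple[str, str], np.ndarray],
                                                    set[tuple[str, str]]]:
    """Per-feature latent contribution effect*f(z) for every hub/spoke feature."""
    effects: dict[tuple[str, str], np.ndarray] = {}
    hubs: set[tuple[str, str]] = set()
    n = len(samples)
    for hub in spec.hub_specs:
        if hub.driven_by == "histology_latent":
            std = codes.std()
            base = (codes - codes.mean()) / (std if std > 0 else 1.0)
            z = base + rng.normal(0.0, 0.3, size=n)
        else:
            z = rng.normal(0.0, 1.0, size=n)
        contrib = hub.effect_size * hub.link(z)
        hubs.add(hub.hub_feature)
        for feat in (hub.hub_feature, *hub.spoke_features):
            effects[feat] = effects.get(feat, 0.0) + contrib
    return effects, hubs


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort deterministically from ``spec`` (including its seed)."""
    if spec.n_samples == 0:
        raise ValidationError("cohort must contain at least one sample")
    rng = np.random.default_rng(spec.seed)
    samples = spec.sample_ids()
    n = len(samples)
    ids = _feature_ids(spec)
    known = {(p, f) for p, feats in ids.items() for f in feats}
    for hub in spec.hub_specs:
        for feat in (hub.hub_feature, *hub.spoke_features):
            if feat not in known:
                raise ValidationError(f"hub references unknown feature {feat}")

    annotations = _generate_annotations(spec, samples, rng)
    codes = annotations["histology"].map(HISTOLOGY_SEVERITY).to_numpy(dtype=float)
    effects, hub_feats = _hub_effects(spec, samples, codes, rng)

    def noise_for(feat: tuple[str, str]) -> float:
        return spec.noise_sd / 4.0 if feat in hub_feats else spec.noise_sd

    # --- methylation: logit-normal betas, detection p-values, X/fail flags ---
    meth_ids = ids["methylation"]
    mu = rng.normal(0.0, 1.5, size=spec.n_cpg)
    logit = np.empty((spec.n_cpg, n))
    for i, fid in enumerate(meth_ids):
        feat = ("methylation", fid)
        eps = rng.normal(0.0, noise_for(feat), size=n)
        shift = effects.get(feat, 0.0)
        base = 0.0 if feat in effects else mu[i]  # planted loci centered at beta=0.5
        logit[i] = base + shift + eps
    beta = 1.0 / (1.0 + np.exp(-logit))

    # flagged locus sets: fail loci at the end, X-linked just before (disjoint
    # by construction unless overlap is explicitly allowed)
    fail_idx = np.arange(spec.n_cpg - spec.n_detection_fail, spec.n_cpg)
    if spec.allow_overlapping_flags:
        x_idx = rng.choice(spec.n_cpg, size=spec.n_x_linked, replace=False)
    else:
        x_stop = spec.n_cpg - spec.n_detection_fail
        x_idx = np.arange(x_stop - spec.n_x_linked, x_stop)

    det_p = rng.uniform(0.0, 0.04, size=(spec.n_cpg, n))
    lo = math.ceil(0.25 * n)
    hi = max(lo, math.floor(0.5 * n))
    for i in fail_idx:
        k = int(rng.integers(lo, hi + 1))
        cols = rng.choice(n, size=k, replace=False)
        det_p[i, cols] = rng.uniform(0.051, 1.0, size=k)

    n_mgenes = max(1, min(807, (spec.n_cpg + 1) // 2))
    meth_meta = pd.DataFrame(index=pd.Index(meth_ids, name="feature_id"))
    meth_meta["gene_symbol"] = [f"MGENE{(i % n_mgenes) + 1:03d}" for i in range(spec.n_cpg)]
    meth_meta["chr_x"] = False
    meth_meta.iloc[x_idx, meth_meta.columns.get_loc("chr_x")] = True
    methylation = OmicsBlock(
        "methylation", pd.DataFrame(beta, index=meth_ids, columns=samples), meth_meta
    )
    detection_p = pd.DataFrame(det_p, index=meth_ids, columns=samples)

    # --- miRNA: NB counts with lane factors and control probes ---
    mir_ids = ids["mirna"]
    base_mean = 10.0 ** rng.uniform(1.3, 3.3, size=spec.n_mirna)
    dispersion = 10.0 ** rng.uniform(np.log10(0.05), np.log10(0.5), size=spec.n_mirna)
    lane = np.exp(rng.normal(0.0, 0.3, size=n))
    counts = np.empty((spec.n_mirna, n), dtype=np.int64)
    for i, fid in enumerate(mir_ids):
        feat = ("mirna", fid)
        mult = np.ones(n)
        if feat in effects:
            # linear-in-latent mean shift, floored at 2 % of base expression
            mult = np.maximum(0.02, 1.0 + 0.3 * effects[feat])
            disp = 0.05
            m = max(base_mean[i], 500.0)  # planted features kept well expressed
        else:
            disp = dispersion[i]
            m = base_mean[i]
        mean = m * mult * lane
        size = 1.0 / disp
        counts[i] = rng.negative_binomial(size, size / (size + mean))
    pos_ids = [f"POS_{chr(65 + i)}" for i in range(spec.n_pos_controls)]
    neg_ids = [f"NEG_{chr(65 + i)}" for i in range(spec.n_neg_controls)]
    ladder = np.array([_POS_LADDER[i % len(_POS_LADDER)] for i in range(spec.n_pos_controls)])
    pos_counts = rng.poisson(ladder[:, None] * lane[None, :]).astype(np.int64)
    pos_counts = np.maximum(pos_counts, 1)  # positive controls must be nonzero
    neg_counts = rng.poisson(2.0, size=(spec.n_neg_controls, n)).astype(np.int64)
    mir_values = pd.DataFrame(
        np.vstack([counts, pos_counts, neg_counts]),
        index=mir_ids + pos_ids + neg_ids, columns=samples,
    )
    mir_meta = pd.DataFrame(index=pd.Index(mir_values.index, name="feature_id"))
    mir_meta["gene_symbol"] = [f"MIR{i + 1:04d}" for i in range(spec.n_mirna)] + \
        [""] * (spec.n_pos_controls + spec.n_neg_controls)
    mir_meta["control_role"] = ["none"] * spec.n_mirna + \
        ["positive"] * spec.n_pos_controls + ["negative"] * spec.n_neg_controls
    mirna = OmicsBlock("mirna", mir_values.astype(float), mir_meta)

    # --- stem-cell qPCR: Ct with a per-sample plate shift ---
    sc_ids = ids["stemcell"]
    hk_ids = [f"HK{i:02d}" for i in range(1, spec.n_housekeeping + 1)]
    plate = rng.normal(0.0, 0.8, size=n)
    gene_base = rng.normal(25.0, 2.0, size=spec.n_genes)
    ct = np.empty((spec.n_genes, n))
    for i, fid in enumerate(sc_ids):
        feat = ("stemcell", fid)
        eps = rng.normal(0.0, noise_for(feat), size=n)
        # higher latent expression -> lower Ct
        ct[i] = gene_base[i] + plate - effects.get(feat, 0.0) + eps
    hk_base = rng.normal(16.0, 1.0, size=spec.n_housekeeping)
    hk_ct = hk_base[:, None] + plate[None, :] + rng.normal(0.0, 0.15,
                                                           size=(spec.n_housekeeping, n))
    sc_values = pd.DataFrame(np.vstack([ct, hk_ct]), index=sc_ids + hk_ids, columns=samples)
    sc_meta = pd.DataFrame(index=pd.Index(sc_values.index, name="feature_id"))
    sc_meta["gene_symbol"] = [f"STEM{i + 1:02d}" for i in range(spec.n_genes)] + \
        [f"HKG{i + 1}" for i in range(spec.n_housekeeping)]
    sc_meta["control_role"] = ["none"] * spec.n_genes + \
        ["housekeeping"] * spec.n_housekeeping
    stemcell = OmicsBlock("stemcell", sc_values, sc_meta)

    # --- genotypes: Hardy-Weinberg draws per SNP ---
    geno = {}
    for snp, (ref, alt) in _SNPS.items():
        draws = rng.random((2, n)) < spec.allele_freq
        calls = []
        for s in range(n):
            pair = sorted(alt if d else ref for d in draws[:, s])
            calls.append("/".join(pair))
        geno[snp] = calls
    genotypes = pd.DataFrame(geno, index=samples).T
    genotypes.index.name = "snp_id"

    # --- missingness masks ---
    missing = spec.missing_samples if spec.missing_samples is not None \
        else spec.default_missing()
    for platform, gone in missing.items():
        block = {"methylation": methylation, "mirna": mirna, "stemcell": stemcell}[platform]
        block.values.loc[:, [s for s in gone if s in block.values.columns]] = np.nan

    truth = {
        "planted_edges": [
            [list(h.hub_feature), list(s), h.relationship]
            for h in spec.hub_specs for s in h.spoke_features
        ],
        "planted_hubs": [list(h.hub_feature) for h in spec.hub_specs],
        "seed": spec.seed,
    }
    return SyntheticCohort(methylation, detection_p, mirna, stemcell,
                           genotypes, annotations, truth)


def _generate_annotations(spec: CohortSpec, samples: list[str],
                          rng: np.random.Generator) -> pd.DataFrame:
    age_range = {"yst": (0.0, 4.0), "dysgerminoma": (7.0, 16.0), "teratoma": (0.0, 21.0),
                 "mixed": (0.0, 14.0), "normal_adjacent": (1.0, 19.0)}
    p_male = {"yst": 0.55, "dysgerminoma": 0.0, "teratoma": 0.17,
              "mixed": 0.75, "normal_adjacent": 0.3}
    p_location = {  # ovary, testis, extragonadal
        "yst": (0.25, 0.25, 0.5), "dysgerminoma": (1.0, 0.0, 0.0),
        "teratoma": (0.5, 0.06, 0.44), "mixed": (0.25, 0.5, 0.25),
        "normal_adjacent": (0.15, 0.15, 0.7),
    }
    rows = []
    for sid in samples:
        hist = {"YST": "yst", "TER": "teratoma", "DYS": "dysgerminoma",
                "MIX": "mixed", "NRM": "normal_adjacent"}[sid[:3]]
        lo, hi = age_range[hist]
        age = round(float(rng.uniform(lo, hi)), 1)
        sex = "male" if rng.random() < p_male[hist] else "female"
        loc = ("ovary", "testis", "extragonadal")[
            int(rng.choice(3, p=p_location[hist]))]
        rows.append({"sample_id": sid, "age_years": age, "sex": sex,
                     "location": loc, "histology": hist,
                     "age_group": "<10" if age < 10 else ">=10"})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# disk round trip

def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> list[Path]:
    """Write one TSV per platform block (meta columns inline), the detection
    p-value matrix, annotations, genotypes, and the truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if len(cohort.annotations) == 0:
        raise ValidationError("cannot write a cohort with zero samples")
    written: list[Path] = []

    def _write_block(name: str, block: OmicsBlock) -> None:
        meta_cols = [c for c in ("gene_symbol", "chr_x", "control_role")
                     if c in block.feature_meta]
        df = pd.concat([block.feature_meta[meta_cols], block.values], axis=1)
        df.index.name = "feature_id"
        path = directory / f"{name}.tsv"
        df.to_csv(path, sep="\t", float_format="%.17g")
        written.append(path)

    _write_block("methylation", cohort.methylation)
    p = directory / "methylation_detection_p.tsv"
    dp = cohort.detection_p.copy()
    dp.index.name = "feature_id"
    dp.to_csv(p, sep="\t", float_format="%.17g")
    written.append(p)
    _write_block("mirna", cohort.mirna)
    _write_block("stemcell", cohort.stemcell)
    p = directory / "annotations.tsv"
    cohort.annotations.to_csv(p, sep="\t")
    written.append(p)
    p = directory / "genotypes.tsv"
    cohort.genotypes.to_csv(p, sep="\t")
    written.append(p)
    p = directory / "truth.json"
    p.write_text(json.dumps(cohort.truth, indent=1, sort_keys=True))
    written.append(p)
    return written


def read_cohort(directory: str | Path) -> SyntheticCohort:
    directory = Path(directory)

    def _read_block(name: str, platform: str) -> OmicsBlock:
        df = pd.read_csv(directory / f"{name}.tsv", sep="\t", index_col=0)
        df.index = df.index.astype(str)
        meta_cols = [c for c in ("gene_symbol", "chr_x", "control_role") if c in df]
        meta = df[meta_cols].copy()
        if "gene_symbol" in meta:
            meta["gene_symbol"] = meta["gene_symbol"].fillna("")
        values = df.drop(columns=meta_cols).astype(float)
        return OmicsBlock(platform, values, meta)

    methylation = _read_block("methylation", "methylation")
    detection_p = pd.read_csv(directory / "methylation_detection_p.tsv",
                              sep="\t", index_col=0)
    detection_p.index = detection_p.index.astype(str)
    mirna = _read_block("mirna", "mirna")
    stemcell = _read_block("stemcell", "stemcell")
    annotations = pd.read_csv(directory / "annotations.tsv", sep="\t",
                              index_col="sample_id")
    genotypes = pd.read_csv(directory / "genotypes.tsv", sep="\t", index_col=0)
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return SyntheticCohort(methylation, detection_p, mirna, stemcell,
                           genotypes, annotations, truth)
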