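"""Fusion of molecular platforms with encoded phenotypes and genotypes into
one row-stacked matrix for all-pairs correlation.

Categorical phenotypes are mapped to ordered numeric codes (low to high
severity for histology); diploid genotype calls are encoded on a
transition/transversion-grouped numeric scale (transitions, being more
likely, sit near the homozygote they connect; transversions get small
magnitudes). Fusion restricts samples to the complete-data intersection
across platforms and drops control/housekeeping rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import FusedMatrix, OmicsBlock, ValidationError

log = logging.getLogger(__name__)

#: transition/transversion-grouped codes for diploid calls (normalized pairs)
DEFAULT_GENOTYPE_TABLE: dict[str, float] = {
    "t/t": -4.0, "c/t": -3.0, "c/c": -2.0, "g/t": -0.5, "c/g": -0.2,
    "a/t": 0.2, "a/c": 0.5, "a/a": 2.0, "a/g": 3.0, "g/g": 4.0,
}

#: ordered low-severity-to-high phenotype codes; an explicit assumption — the
#: ordering follows the listing normal adjacent, teratoma, dysgerminoma, YST,
#: mixed, and is fully overridable via EncodingConfig
DEFAULT_HISTOLOGY_CODES = {"normal_adjacent": 0.0, "teratoma": 1.0,
                           "dysgerminoma": 2.0, "yst": 3.0, "mixed": 4.0}
DEFAULT_LOCATION_CODES = {"ovary": 0.0, "testis": 1.0, "extragonadal": 2.0}
DEFAULT_SEX_CODES = {"male": 0.0, "female": 1.0}


def normalize_call(call: str) -> str:
    """Lowercase, strip, and order-normalize a diploid call ('G/a ' -> 'a/g')."""
    alleles = sorted(a.strip().lower() for a in str(call).split("/"))
    if len(alleles) != 2 or any(a not in "acgt" or len(a) != 1 for a in alleles):
        raise ValidationError(f"malformed diploid call {call!r}")
    return "/".join(alleles)


@dataclass
class EncodingConfig:
    histology_codes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HISTOLOGY_CODES))
    location_codes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOCATION_CODES))
    sex_codes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_CODES))
    genotype_table: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_TABLE))

    def __post_init__(self) -> None:
        for name in ("histology_codes", "location_codes", "sex_codes", "genotype_table"):
            codes = getattr(self, name)
            if len(set(codes.values())) != len(codes):
                raise ValidationError(f"{name} codes must be injective")


def encode_genotype(call: str, table: dict[str, float] | None = None,
                    snp_id: str = "?", sample_id: str = "?") -> float:
    """Numeric code for a diploid call; order-insensitive (g/a == a/g)."""
    table = DEFAULT_GENOTYPE_TABLE if table is None else table
    key = normalize_call(call)
    if key not in table:
        raise ValidationError(
            f"genotype {key!r} (SNP {snp_id}, sample {sample_id}) not in encoding table")
    return float(table[key])


def encode_genotype_block(genotypes: pd.DataFrame,
                          config: EncodingConfig | None = None) -> OmicsBlock:
    """Encode a SNP-by-sample frame of diploid calls into a numeric block."""
    config = config or EncodingConfig()
    coded = pd.DataFrame(index=genotypes.index, columns=genotypes.columns, dtype=float)
    for snp in genotypes.index:
        for sample in genotypes.columns:
            call = genotypes.loc[snp, sample]
            if pd.isna(call):
                coded.loc[snp, sample] = np.nan
            else:
                coded.loc[snp, sample] = encode_genotype(
                    call, config.genotype_table, snp_id=snp, sample_id=sample)
    meta = pd.DataFrame(index=coded.index)
    meta["gene_symbol"] = [str(s).split("_")[0] for s in coded.index]
    return OmicsBlock("genotype", coded, meta)


def encode_phenotypes(annotations: pd.DataFrame,
                      config: EncodingConfig | None = None) -> OmicsBlock:
    """One numeric row per phenotype variable: age passthrough plus coded
    sex, location and histology."""
    config = config or EncodingConfig()
    rows = {}
    rows["age_years"] = annotations["age_years"].astype(float)
    for col, codes in (("sex", config.sex_codes), ("location", config.location_codes),
                       ("histology", config.histology_codes)):
        vals = annotations[col]
        missing = set(vals.dropna()) - set(codes)
        if missing:
            raise ValidationError(f"no code for {col} level(s) {sorted(missing)}")
        rows[col] = vals.map(codes).astype(float)
    values = pd.DataFrame(rows).T
    values.columns = annotations.index
    return OmicsBlock("phenotype", values)


def build_fused_matrix(blocks: list[OmicsBlock], require_complete: bool = True
                       ) -> FusedMatrix:
    """Row-stack >= 2 platform blocks, tag rows with their platform, restrict
    samples to the complete-data intersection, and drop control rows."""
    if len(blocks) < 2:
        raise ValidationError("fusion needs at least 2 platform blocks")
    cleaned = [b.noncontrol() for b in blocks]
    if require_complete:
        common: set[str] | None = None
        for b in cleaned:
            cs = b.complete_samples()
            common = cs if common is None else common & cs
        all_samples = set().union(*(set(b.sample_ids) for b in cleaned))
        dropped = sorted(all_samples - (common or set()))
        if dropped:
            log.info("fusion: %d samples excluded for incomplete data: %s",
                     len(dropped), dropped)
    else:
        common = set().union(*(set(b.sample_ids) for b in cleaned))
    if not common:
        raise ValidationError("no sample is complete across all platforms")
    # preserve the sample order of the first block, then any extras
    order = [s for s in cleaned[0].sample_ids if s in common]
    order += sorted(common - set(order))
    parts, tags, symbols = [], [], []
    for b in cleaned:
        vals = b.values.reindex(columns=order)
        parts.append(vals)
        tags.extend([b.platform] * len(vals))
        symbols.extend(b.feature_meta["gene_symbol"].tolist())
    values = pd.concat(parts, axis=0)
    if values.index.has_duplicates:
        raise ValidationError("feature ids collide across platforms")
    return FusedMatrix(values,
                       pd.Series(tags, index=values.index, name="platform"),
                       pd.Series(symbols, index=values.index, name="gene_symbol"))


def subset_samples(fused: FusedMatrix, exclude_histology: str,
                   annotations: pd.DataFrame | None = None,
                   config: EncodingConfig | None = None) -> FusedMatrix:
    """Drop all samples of one histology (e.g. the YSTs) from the fused
    matrix, keeping every feature row."""
    if annotations is not None:
        hist = annotations["histology"].reindex(fused.sample_ids)
        drop = set(hist.index[hist == exclude_histology])
    else:
        if "histology" not in fused.values.index:
            raise ValidationError("no histology row or annotations available")
        config = config or EncodingConfig()
        code = config.histology_codes.get(exclude_histology)
        if code is None:
            raise ValidationError(f"no code for histology {exclude_histology!r}")
        row = fused.values.loc["histology"]
        drop = set(row.index[row == code])
    keep = [s for s in fused.sample_ids if s not in drop]
    if not keep:
        raise ValidationError("exclusion would empty the fused matrix")
    return FusedMatrix(fused.values[keep].copy(), fused.platforms.copy(),
                       fused.gene_symbols.copy())
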