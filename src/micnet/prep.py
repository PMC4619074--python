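"""Per-platform QC and normalization.

Methylation: beta computation and locus filtering (detection-failure and
X-linked removal). miRNA counts: positive-control normalization (per-sample
geometric-mean factor) and negative-control background flooring at an upper
quantile. Stem-cell qPCR: delta-Ct against the housekeeping-gene mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .blocks import OmicsBlock, ValidationError

log = logging.getLogger(__name__)


def compute_beta(methylated_signal: float, unmethylated_signal: float,
                 offset: float = 0.0) -> float:
    """Methylation fraction beta = M / (M + U + offset).

    The default keeps the plain two-term ratio; ``offset`` restores the
    platform's customary +100 stabilizer if wanted. Both signals zero yields
    NaN (missing), logged.
    """
    if methylated_signal < 0 or unmethylated_signal < 0:
        raise ValidationError("fluorescence signals must be nonnegative")
    total = methylated_signal + unmethylated_signal
    if total == 0:
        log.warning("beta undefined: both signals zero")
        return float("nan")
    return methylated_signal / (total + offset)


@dataclass
class MethylationQCReport:
    n_input_loci: int
    n_detection_removed: int
    n_x_removed: int
    n_retained: int
    removed_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"n_input_loci": self.n_input_loci,
                "n_detection_removed": self.n_detection_removed,
                "n_x_removed": self.n_x_removed,
                "n_retained": self.n_retained,
                "removed_ids": list(self.removed_ids)}


def filter_methylation_loci(
    block: OmicsBlock,
    detection_p: pd.DataFrame,
    fail_fraction: float = 0.25,
    detection_alpha: float = 0.05,
    drop_x: bool = True,
) -> tuple[OmicsBlock, MethylationQCReport]:
    """Remove loci failing detection in >= ``fail_fraction`` of samples
    (detection p > ``detection_alpha``), and X-linked loci when ``drop_x``.

    The fraction boundary is inclusive: a locus failing in exactly 25 % of
    samples is removed.
    """
    if not 0 < fail_fraction <= 1:
        raise ValidationError("fail_fraction must lie in (0, 1]")
    if (list(detection_p.index) != block.feature_ids
            or list(detection_p.columns) != block.sample_ids):
        raise ValidationError("detection p-value matrix not aligned with block")
    frac_fail = (detection_p.to_numpy(dtype=float) > detection_alpha).mean(axis=1)
    det_removed = frac_fail >= fail_fraction
    x_removed = block.feature_meta["chr_x"].to_numpy(dtype=bool) if drop_x \
        else np.zeros(len(block.values), dtype=bool)
    removed = det_removed | x_removed
    kept = block.values.index[~removed]
    out = OmicsBlock("methylation", block.values.loc[kept].copy(),
                     block.feature_meta.loc[kept].copy())
    report = MethylationQCReport(
        n_input_loci=len(block.values),
        n_detection_removed=int(det_removed.sum()),
        n_x_removed=int(x_removed.sum()),
        n_retained=len(kept),
        removed_ids=list(block.values.index[removed]),
    )
    log.info("methylation QC: %d in, %d detection-fail, %d X-linked, %d retained",
             report.n_input_loci, report.n_detection_removed,
             report.n_x_removed, report.n_retained)
    return out, report


def _positive_controls(block: OmicsBlock) -> pd.DataFrame:
    mask = block.feature_meta["control_role"] == "positive"
    pos = block.values.loc[mask]
    if pos.empty:
        raise ValidationError("no positive-control rows present")
    return pos


def normalize_mirna_positive(block: OmicsBlock) -> OmicsBlock:
    """Scale each sample so positive-control geometric means are equal.

    Factor f_s = (cohort mean of per-sample positive-control geomeans) /
    (sample s geomean); all non-control rows are multiplied by f_s.
    Samples that are entirely missing are passed through untouched.
    """
    pos = _positive_controls(block)
    values = block.values.copy()
    present = [s for s in values.columns if values[s].notna().any()]
    zero = [s for s in present if (pos[s] <= 0).any() or pos[s].isna().any()]
    if zero:
        raise ValidationError(
            f"nonpositive or missing positive-control count in sample(s) {zero}"
        )
    geo = gmean(pos[present].to_numpy(dtype=float), axis=0)
    factors = pd.Series(geo.mean() / geo, index=present)
    scale_rows = block.feature_meta["control_role"] == "none"
    values.loc[scale_rows, present] = values.loc[scale_rows, present] * factors
    return OmicsBlock(block.platform, values, block.feature_meta.copy())


def apply_negative_background(block: OmicsBlock, quantile: float = 0.75
                              ) -> tuple[OmicsBlock, pd.DataFrame]:
    """Floor non-control counts at the per-sample upper quantile of the
    negative controls (linear-interpolation quantile).

    Returns the floored block and a boolean below-background flag frame for
    the non-control rows.
    """
    mask = block.feature_meta["control_role"] == "negative"
    neg = block.values.loc[mask]
    if neg.empty:
        raise ValidationError("no negative-control rows present")
    values = block.values.copy()
    present = [s for s in values.columns if values[s].notna().any()]
    background = neg[present].quantile(quantile, interpolation="linear")
    target = block.feature_meta["control_role"] == "none"
    sub = values.loc[target, present]
    flags = sub.lt(background, axis=1)
    values.loc[target, present] = sub.clip(lower=background, axis=1)
    flag_frame = pd.DataFrame(False, index=values.index[target], columns=values.columns)
    flag_frame.loc[:, present] = flags
    return OmicsBlock(block.platform, values, block.feature_meta.copy()), flag_frame


def normalize_delta_ct(block: OmicsBlock) -> OmicsBlock:
    """Delta-Ct: subtract each sample's housekeeping-gene mean Ct from every
    target gene; housekeeping rows are dropped from the output.

    A sample with any missing housekeeping Ct gets all-missing delta-Ct
    (logged) rather than a silently biased reference.
    """
    hk = block.feature_meta["control_role"] == "housekeeping"
    if not hk.any():
        raise ValidationError("no housekeeping rows present")
    hk_ct = block.values.loc[hk]
    targets = block.values.loc[~hk].copy()
    ref = hk_ct.mean(axis=0)
    incomplete = hk_ct.isna().any(axis=0) & block.values.notna().any(axis=0)
    for s in block.values.columns[incomplete]:
        log.warning("sample %s missing housekeeping Ct; delta-Ct set missing", s)
        ref[s] = np.nan
    dct = targets.sub(ref, axis=1)
    return OmicsBlock(block.platform, dct, block.feature_meta.loc[~hk].copy())
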