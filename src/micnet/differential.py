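"""Differential analysis: exact negative-binomial count test with BH
correction, delta-delta-Ct fold changes, Welch tests on delta-Ct, and
city-block / average-linkage hierarchical clustering.

The count test follows the exact conditional scheme for two-group NB data:
per feature the pooled mean and a method-of-moments dispersion are estimated,
each group's count sum is modeled as NB, and the two-sided p-value is the
total probability of all count splits (a, b) with a + b equal to the observed
total whose probability does not exceed that of the observed split.

With two or three replicates per group a raw per-feature moment estimate of
the dispersion is so noisy that the test becomes markedly anticonservative,
so, as in the classic count-based DE methods, the per-feature variance is
combined with a mean-variance trend fitted across features (lowess), taking
the larger of the two (``dispersion_mode="max"``; ``"per_feature"`` and
``"fit"`` are available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import nbinom, ttest_ind
from statsmodels.stats.multitest import multipletests

from .blocks import OmicsBlock, ValidationError

log = logging.getLogger(__name__)

_DISPERSION_FLOOR = 1e-8
_LOG2_3FOLD = 1.58  # |log2 fold| beyond this marks a >= 3-fold change


@dataclass
class DEResult:
    feature_id: str
    mean_a: float
    mean_b: float
    dispersion: float
    p_value: float
    q_value: float = float("nan")


def _nb_exact_p(counts_a: np.ndarray, counts_b: np.ndarray, disp: float) -> float:
    """Exact NB p-value for one feature at a given dispersion."""
    na, nb_ = len(counts_a), len(counts_b)
    m = np.concatenate([counts_a, counts_b]).mean()
    ka, kb = int(counts_a.sum()), int(counts_b.sum())
    ks = ka + kb
    if ks == 0:
        return 1.0
    # group sums ~ NB(mean n_g * m, size n_g / disp)
    a = np.arange(ks + 1)
    ra, rb = na / disp, nb_ / disp
    mu_a, mu_b = na * m, nb_ * m
    logp = (nbinom.logpmf(a, ra, ra / (ra + mu_a))
            + nbinom.logpmf(ks - a, rb, rb / (rb + mu_b)))
    logp -= logp.max()
    probs = np.exp(logp)
    p_obs = probs[ka]
    p = probs[probs <= p_obs * (1 + 1e-7)].sum() / probs.sum()
    return min(max(p, np.finfo(float).tiny), 1.0)


def _dispersions(mat: np.ndarray, na: int, mode: str) -> np.ndarray:
    """Per-feature NB dispersion: moment estimate from the pooled
    within-group variance, optionally combined with a cross-feature
    mean-variance lowess trend."""
    ca, cb = mat[:, :na].astype(float), mat[:, na:].astype(float)
    m = mat.mean(axis=1)
    ssq = ((ca - ca.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((cb - cb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    v = ssq / max(mat.shape[1] - 2, 1)
    if mode != "per_feature" and len(m) >= 10:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        fitted = np.maximum(lowess(v, m, frac=0.7, return_sorted=False), 0.0)
        v = fitted if mode == "fit" else np.maximum(v, fitted)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, 0.0)
    return np.maximum(d, _DISPERSION_FLOOR)


def nb_test(counts: pd.DataFrame, groups: pd.Series,
            round_counts: bool = True, dispersion_mode: str = "max") -> pd.DataFrame:
    """Two-sided exact NB test per feature between the two levels of ``groups``.

    ``counts`` is feature-by-sample; ``groups`` maps sample id to one of two
    levels, each with >= 2 samples. Normalized (real-valued) counts are
    rounded to the nearest integer first (``round_counts``), since the test
    is defined on counts. Returns a frame with means, dispersion, p and BH q.
    """
    if dispersion_mode not in ("max", "fit", "per_feature"):
        raise ValidationError(f"unknown dispersion_mode {dispersion_mode!r}")
    groups = groups.reindex(counts.columns).dropna()
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValidationError(f"need exactly two group levels, got {levels}")
    sa = groups.index[groups == levels[0]]
    sb = groups.index[groups == levels[1]]
    if len(sa) < 2 or len(sb) < 2:
        raise ValidationError("each group needs at least 2 samples")
    mat = counts[list(sa) + list(sb)].to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValidationError("missing counts; restrict to complete samples first")
    if round_counts:
        mat = np.rint(mat)
    elif not np.allclose(mat, np.rint(mat)):
        raise ValidationError("non-integer counts: pass round_counts=True to round")
    mat = mat.astype(np.int64)
    disp = _dispersions(mat, len(sa), dispersion_mode)
    rows = []
    for i, fid in enumerate(counts.index):
        ca, cb = mat[i, :len(sa)].astype(float), mat[i, len(sa):].astype(float)
        p = _nb_exact_p(ca, cb, disp[i])
        rows.append((fid, ca.mean(), cb.mean(), disp[i], p))
    out = pd.DataFrame(rows, columns=["feature_id", f"mean_{levels[0]}",
                                      f"mean_{levels[1]}", "dispersion", "p_value"])
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out.set_index("feature_id")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class FoldChangeResult:
    gene_id: str
    delta_delta_ct: float
    fold_change: float
    log2_fold: float
    passes_3fold: bool
    missing: bool = False


def fold_change_ddct(dct: OmicsBlock | pd.DataFrame, group_a, group_b,
                     log2_threshold: float = _LOG2_3FOLD) -> list[FoldChangeResult]:
    """Relative expression of group_a vs group_b by the 2^(-ddCt) method.

    ddCt = mean dCt(a) - mean dCt(b); fold = 2**(-ddCt); the 3-fold flag
    fires when |log2 fold| > ``log2_threshold`` (1.58 by default, i.e. a
    >= 3-fold change in either direction).
    """
    values = dct.values if isinstance(dct, OmicsBlock) else dct
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b or set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint and nonempty")
    results = []
    for gene in values.index:
        a = values.loc[gene, group_a].astype(float)
        b = values.loc[gene, group_b].astype(float)
        if a.isna().all() or b.isna().all():
            results.append(FoldChangeResult(gene, float("nan"), float("nan"),
                                            float("nan"), False, missing=True))
            continue
        ddct = a.mean() - b.mean()
        log2_fold = -ddct
        results.append(FoldChangeResult(
            gene, float(ddct), float(2.0 ** (-ddct)), float(log2_fold),
            bool(abs(log2_fold) > log2_threshold)))
    return results


def welch_test_dct(dct: OmicsBlock | pd.DataFrame, group_a, group_b) -> pd.Series:
    """Two-sided Welch t-test on delta-Ct per gene; degenerate zero-variance
    equal-mean genes get p = 1."""
    values = dct.values if isinstance(dct, OmicsBlock) else dct
    a = values[list(group_a)].to_numpy(dtype=float)
    b = values[list(group_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("each group needs at least 2 samples")
    res = ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p) & np.isclose(np.nanmean(a, axis=1), np.nanmean(b, axis=1))
    p[degenerate] = 1.0
    return pd.Series(p, index=values.index, name="p_value")


@dataclass
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus the clustered labels."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def _pairwise_cityblock(mat: np.ndarray) -> np.ndarray:
    """Condensed city-block distances over columns, pairwise-complete with
    count rescaling (missing coordinates dropped, sum rescaled to full
    dimensionality)."""
    n_feat, n = mat.shape
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(mat[:, i]) & ~np.isnan(mat[:, j])
            k = int(both.sum())
            if k == 0:
                raise ValidationError("no shared observations between two samples")
            d = np.abs(mat[both, i] - mat[both, j]).sum() * (n_feat / k)
            out.append(d)
    return np.asarray(out)


def hcluster(matrix: pd.DataFrame, metric: str = "cityblock",
             linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of sample columns over feature rows.

    City-block metric and average linkage by default; samples with no
    observed values are excluded (logged).
    """
    if metric != "cityblock":
        raise ValidationError("only the city-block metric is supported")
    keep = [c for c in matrix.columns if matrix[c].notna().any()]
    dropped = set(matrix.columns) - set(keep)
    if dropped:
        log.warning("excluding all-missing samples from clustering: %s", sorted(dropped))
    if len(keep) < 2:
        raise ValidationError("need at least 2 samples to cluster")
    dist = _pairwise_cityblock(matrix[keep].to_numpy(dtype=float))
    Z = hierarchy.linkage(dist, method=linkage)
    return Dendrogram(Z, list(keep))
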