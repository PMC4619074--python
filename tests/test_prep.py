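"""Platform preprocessing: beta computation, locus filtering, count
normalization and delta-Ct."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micnet import (OmicsBlock, ValidationError, apply_negative_background,
                    compute_beta, filter_methylation_loci, normalize_delta_ct,
                    normalize_mirna_positive)


@pytest.mark.parametrize("m, u, expected", [
    (500.0, 0.0, 1.0),
    (300.0, 300.0, 0.5),
    (100.0, 300.0, 0.25),
    (0.0, 120.0, 0.0),
])
def test_compute_beta_values(m, u, expected):
    assert compute_beta(m, u) == pytest.approx(expected)


def test_compute_beta_degenerate_and_invalid():
    assert math.isnan(compute_beta(0.0, 0.0))
    with pytest.raises(ValidationError):
        compute_beta(-1.0, 5.0)


@given(m=st.floats(0, 1e6), u=st.floats(0, 1e6))
@settings(max_examples=50, derandomize=True)
def test_compute_beta_bounded(m, u):
    b = compute_beta(m, u)
    assert math.isnan(b) or 0.0 <= b <= 1.0


def _meth_block(beta, chr_x=None):
    beta = pd.DataFrame(beta)
    beta.index = [f"cg{i}" for i in range(len(beta))]
    beta.columns = [f"s{i}" for i in range(beta.shape[1])]
    meta = pd.DataFrame(index=beta.index)
    meta["chr_x"] = chr_x if chr_x is not None else False
    return OmicsBlock("methylation", beta, meta)


def test_filter_boundary_is_inclusive():
    """A locus failing detection in exactly 25 % of samples is removed."""
    block = _meth_block(np.full((2, 4), 0.5))
    detp = pd.DataFrame(0.01, index=block.values.index, columns=block.values.columns)
    detp.iloc[0, 0] = 0.2  # 1 of 4 samples = exactly 25 %
    out, report = filter_methylation_loci(block, detp)
    assert report.n_detection_removed == 1
    assert list(out.values.index) == ["cg1"]


def test_filter_noop_and_x_removal():
    block = _meth_block(np.full((3, 4), 0.5), chr_x=[False, False, True])
    detp = pd.DataFrame(0.01, index=block.values.index, columns=block.values.columns)
    out, report = filter_methylation_loci(block, detp, drop_x=False)
    assert report.n_retained == 3
    out, report = filter_methylation_loci(block, detp, drop_x=True)
    assert report.n_retained == 2 and report.n_x_removed == 1
    assert report.removed_ids == ["cg2"]


def test_filter_idempotent(full_cohort):
    out1, r1 = filter_methylation_loci(full_cohort.methylation, full_cohort.detection_p)
    detp = full_cohort.detection_p.loc[out1.values.index]
    out2, r2 = filter_methylation_loci(out1, detp)
    assert r2.n_detection_removed == 0 and r2.n_x_removed == 0
    assert list(out2.values.index) == list(out1.values.index)


def test_filter_misaligned_rejected(full_cohort):
    with pytest.raises(ValidationError):
        filter_methylation_loci(full_cohort.methylation,
                                full_cohort.detection_p.iloc[:-1])


def test_positive_normalization_hand_case():
    """Two samples with positive-control geomeans 100 and 400: the cohort
    mean geomean is 250, so factors are 2.5 and 0.625."""
    values = pd.DataFrame({"s1": [100.0, 100.0, 8.0], "s2": [400.0, 400.0, 8.0]},
                          index=["p1", "p2", "t1"])
    meta = pd.DataFrame({"control_role": ["positive", "positive", "none"]},
                        index=values.index)
    out = normalize_mirna_positive(OmicsBlock("mirna", values, meta))
    assert out.values.loc["t1", "s1"] == pytest.approx(8.0 * 2.5)
    assert out.values.loc["t1", "s2"] == pytest.approx(8.0 * 0.625)


def test_positive_normalization_equalizes_geomeans(count_block):
    out = normalize_mirna_positive(count_block)
    # factor applied to target rows equalizes the implied control geomeans
    factors = (out.values.loc["t1"] / count_block.values.loc["t1"])
    pos_geomeans = np.exp(np.log(count_block.values.loc[["p1", "p2"]]).mean(axis=0))
    scaled = pos_geomeans * factors
    assert np.allclose(scaled, scaled.iloc[0], rtol=1e-9)
    # scale invariance: doubling one sample's counts halves its factor, so
    # its normalized counts keep the same relation to every other sample
    # (the cohort-mean numerator rescales all samples by a common constant)
    doubled = count_block.values.copy()
    doubled["s1"] = doubled["s1"] * 2
    out2 = normalize_mirna_positive(
        OmicsBlock("mirna", doubled, count_block.feature_meta))
    ratio_before = out.values.loc["t1", "s1"] / out.values.loc["t1", "s2"]
    ratio_after = out2.values.loc["t1", "s1"] / out2.values.loc["t1", "s2"]
    assert ratio_after == pytest.approx(ratio_before, rel=1e-12)


def test_positive_normalization_preserves_rank(count_block):
    out = normalize_mirna_positive(count_block)
    for s in out.sample_ids:
        raw = count_block.values.loc[["t1", "t2"], s].rank()
        new = out.values.loc[["t1", "t2"], s].rank()
        assert (raw == new).all()


def test_positive_normalization_zero_control_rejected(count_block):
    bad = count_block.values.copy()
    bad.loc["p1", "s1"] = 0.0
    with pytest.raises(ValidationError, match="s1"):
        normalize_mirna_positive(OmicsBlock("mirna", bad, count_block.feature_meta))


def test_negative_background_quantile_floor(count_block):
    """Negative controls {1,2,3,4} give a 0.75-quantile background of 3.25
    under linear interpolation; lower counts are floored and flagged."""
    out, flags = apply_negative_background(count_block)
    assert out.values.loc["t2", "s1"] == pytest.approx(3.25)
    assert bool(flags.loc["t2", "s1"])
    assert out.values.loc["t1", "s1"] == pytest.approx(10.0)
    assert not bool(flags.loc["t1", "s1"])
    assert out.values.loc["t2", "s2"] == pytest.approx(20.0)
    assert not bool(flags.loc["t2", "s2"])


def test_negative_background_zero_controls_no_floor():
    values = pd.DataFrame({"s1": [0.0, 0.0, 5.0]}, index=["n1", "n2", "t1"])
    meta = pd.DataFrame({"control_role": ["negative", "negative", "none"]},
                        index=values.index)
    out, flags = apply_negative_background(OmicsBlock("mirna", values, meta))
    assert out.values.loc["t1", "s1"] == 5.0
    assert not flags.to_numpy().any()


def test_negative_background_boundary_unflagged():
    values = pd.DataFrame({"s1": [2.0, 2.0, 2.0]}, index=["n1", "n2", "t1"])
    meta = pd.DataFrame({"control_role": ["negative", "negative", "none"]},
                        index=values.index)
    out, flags = apply_negative_background(OmicsBlock("mirna", values, meta))
    assert out.values.loc["t1", "s1"] == 2.0
    assert not bool(flags.loc["t1", "s1"])


def _ct_block(ct_rows, hk_rows):
    idx = [f"g{i}" for i in range(len(ct_rows))] + [f"hk{i}" for i in range(len(hk_rows))]
    values = pd.DataFrame(np.vstack([ct_rows, hk_rows]), index=idx)
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame({"control_role": ["none"] * len(ct_rows)
                         + ["housekeeping"] * len(hk_rows)}, index=idx)
    return OmicsBlock("stemcell", values, meta)


def test_delta_ct_hand_case():
    """Housekeeping Cts {18..22} average 20; a gene at Ct 24 has dCt 4."""
    block = _ct_block([[24.0]], [[18.0], [19.0], [20.0], [21.0], [22.0]])
    out = normalize_delta_ct(block)
    assert out.values.loc["g0", "s0"] == pytest.approx(4.0)
    assert "hk0" not in out.values.index


def test_delta_ct_plate_shift_invariance():
    rng = np.random.default_rng(0)
    ct = rng.normal(25, 2, size=(4, 3))
    hk = rng.normal(18, 1, size=(5, 3))
    base = normalize_delta_ct(_ct_block(ct, hk))
    shifted = normalize_delta_ct(_ct_block(ct + 1.7, hk + 1.7))
    pd.testing.assert_frame_equal(base.values, shifted.values, atol=1e-9, rtol=0)


def test_delta_ct_missing_housekeeping_sets_sample_missing():
    block = _ct_block([[24.0, 25.0]], [[20.0, np.nan], [20.0, 20.0]])
    out = normalize_delta_ct(block)
    assert out.values.loc["g0", "s0"] == pytest.approx(4.0)
    assert np.isnan(out.values.loc["g0", "s1"])
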