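"""Encoding and fusion: genotype codes, phenotype rows, complete-case
sample intersection and histology subsetting."""

import numpy as np
import pandas as pd
import pytest

from micnet import (EncodingConfig, OmicsBlock, ValidationError,
                    build_fused_matrix, encode_genotype, encode_genotype_block,
                    encode_phenotypes, subset_samples)
from micnet.fusion import DEFAULT_GENOTYPE_TABLE
from micnet.pipeline import fuse_cohort


ALL_CODES = {"t/t": -4.0, "c/t": -3.0, "c/c": -2.0, "g/t": -0.5, "c/g": -0.2,
             "a/t": 0.2, "a/c": 0.5, "a/a": 2.0, "a/g": 3.0, "g/g": 4.0}


@pytest.mark.parametrize("call, code", sorted(ALL_CODES.items()))
def test_genotype_codes(call, code):
    assert encode_genotype(call) == code


def test_genotype_order_and_case_insensitive():
    assert encode_genotype("g/a") == 3.0
    assert encode_genotype("G/A") == 3.0
    assert encode_genotype("T/C") == encode_genotype("c/t") == -3.0


def test_genotype_table_covers_all_unordered_pairs():
    from itertools import combinations_with_replacement
    pairs = {"/".join(sorted(p)) for p in combinations_with_replacement("acgt", 2)}
    assert pairs == set(DEFAULT_GENOTYPE_TABLE)
    assert len(set(DEFAULT_GENOTYPE_TABLE.values())) == 10  # injective


def test_genotype_unknown_pair_names_snp_and_sample():
    with pytest.raises(ValidationError, match="rs1.*sampleX"):
        encode_genotype("a/a", table={"c/t": -3.0}, snp_id="rs1", sample_id="sampleX")
    with pytest.raises(ValidationError):
        encode_genotype("a/n")


def test_encode_genotype_block(reduced_cohort):
    block = encode_genotype_block(reduced_cohort.genotypes)
    assert block.platform == "genotype"
    codes = set(block.values.to_numpy().ravel())
    assert codes <= set(ALL_CODES.values())


def test_phenotype_encoding_rows():
    ann = pd.DataFrame({
        "age_years": [13.5, 2.0],
        "sex": ["female", "male"],
        "location": ["ovary", "testis"],
        "histology": ["normal_adjacent", "yst"],
    }, index=["s1", "s2"])
    block = encode_phenotypes(ann)
    assert block.values.loc["age_years", "s1"] == 13.5  # passthrough
    assert block.values.loc["histology", "s1"] == 0.0  # lowest severity anchor
    assert block.values.loc["histology", "s2"] == 3.0
    # two samples differing only in sex differ only in the sex row
    ann2 = ann.copy()
    ann2.loc["s2"] = ann.loc["s1"]
    ann2.loc["s2", "sex"] = "male"
    b2 = encode_phenotypes(ann2)
    diff = (b2.values["s1"] != b2.values["s2"])
    assert diff.sum() == 1 and diff["sex"]


def test_phenotype_uncovered_level_rejected():
    ann = pd.DataFrame({"age_years": [1.0], "sex": ["female"],
                        "location": ["ovary"], "histology": ["embryonal"]},
                       index=["s1"])
    with pytest.raises(ValidationError):
        encode_phenotypes(ann)


def test_encoding_config_requires_injective_codes():
    with pytest.raises(ValidationError):
        EncodingConfig(sex_codes={"male": 1.0, "female": 1.0})


def _block(platform, rows, samples, roles=None):
    values = pd.DataFrame(rows, columns=samples)
    values.index = [f"{platform[:2]}{i}" for i in range(len(values))]
    meta = pd.DataFrame(index=values.index)
    if roles:
        meta["control_role"] = roles
    return OmicsBlock(platform, values, meta)


def test_fusion_intersects_complete_samples():
    a = _block("mirna", [[1.0, 2.0, 3.0]], ["s1", "s2", "s3"])
    b = _block("stemcell", [[4.0, 5.0, np.nan]], ["s1", "s2", "s3"])
    fused = build_fused_matrix([a, b])
    assert fused.sample_ids == ["s1", "s2"]
    assert fused.n_features == 2
    assert set(fused.platforms) == {"mirna", "stemcell"}


def test_fusion_identical_samples_unchanged():
    a = _block("mirna", [[1.0, 2.0]], ["s1", "s2"])
    b = _block("stemcell", [[3.0, 4.0]], ["s1", "s2"])
    assert build_fused_matrix([a, b]).sample_ids == ["s1", "s2"]


def test_fusion_drops_control_rows():
    a = _block("mirna", [[1.0], [2.0], [3.0]], ["s1"],
               roles=["none", "positive", "negative"])
    b = _block("stemcell", [[4.0], [5.0]], ["s1"], roles=["none", "housekeeping"])
    fused = build_fused_matrix([a, b])
    assert fused.n_features == 2


def test_fusion_single_block_rejected():
    a = _block("mirna", [[1.0]], ["s1"])
    with pytest.raises(ValidationError):
        build_fused_matrix([a])


def test_fusion_empty_intersection_rejected():
    a = _block("mirna", [[1.0, np.nan]], ["s1", "s2"])
    b = _block("stemcell", [[np.nan, 2.0]], ["s1", "s2"])
    with pytest.raises(ValidationError):
        build_fused_matrix([a, b])


def test_complete_cohort_is_forty_samples_with_eight_yst(full_cohort):
    """Per-platform missingness leaves 40 complete samples including 8 YST;
    excluding YST leaves 32."""
    fused, _ = fuse_cohort(full_cohort)
    assert len(fused.sample_ids) == 40
    hist = full_cohort.annotations.loc[fused.sample_ids, "histology"]
    assert (hist == "yst").sum() == 8
    sub = subset_samples(fused, "yst", annotations=full_cohort.annotations)
    assert len(sub.sample_ids) == 32
    assert sub.n_features == fused.n_features


def test_subset_via_histology_row(fused_reduced):
    sub = subset_samples(fused_reduced, "yst")
    hist_row = fused_reduced.values.loc["histology"]
    assert len(sub.sample_ids) == (hist_row != 3.0).sum()


def test_subset_absent_histology_is_identity(fused_reduced):
    """Excluding a histology absent from the cohort changes nothing, and
    re-excluding is idempotent."""
    once = subset_samples(fused_reduced, "yst")
    twice = subset_samples(once, "yst")
    assert twice.sample_ids == once.sample_ids


def test_fused_row_count_excludes_controls(reduced_cohort):
    fused, qc = fuse_cohort(reduced_cohort)
    spec_rows = (qc.n_retained  # methylation after QC
                 + 30           # miRNA targets (controls dropped)
                 + 15           # stem-cell genes (housekeeping dropped)
                 + 4            # SNPs
                 + 4)           # phenotype rows
    assert fused.n_features == spec_rows
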