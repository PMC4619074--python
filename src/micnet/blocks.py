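"""Core data containers shared by every pipeline stage.

An :class:`OmicsBlock` holds one platform's feature-by-sample matrix plus
per-feature metadata; a :class:`FusedMatrix` is the row-stacked multi-platform
matrix used for all-pairs correlation, with a platform tag on every row.
Values are stored as pandas DataFrames (features as rows, samples as columns)
so the standard TSV round trip is just ``DataFrame.to_csv`` / ``read_csv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PLATFORMS = ("methylation", "mirna", "stemcell", "genotype", "phenotype")

#: roles a feature row can play; everything except "none" is excluded from fusion
CONTROL_ROLES = ("none", "positive", "negative", "housekeeping")


class ValidationError(ValueError):
    """Raised when a container or operation precondition is violated."""


@dataclass
class OmicsBlock:
    """One platform's feature-by-sample numeric matrix with feature metadata.

    Parameters
    ----------
    platform : str
        One of ``PLATFORMS``.
    values : pandas.DataFrame
        Features as rows (index = feature ids), samples as columns.
    feature_meta : pandas.DataFrame, optional
        Indexed like ``values``; recognised columns are ``gene_symbol``,
        ``chr_x`` (bool) and ``control_role`` (one of ``CONTROL_ROLES``).
        Missing columns are filled with defaults.
    """

    platform: str
    values: pd.DataFrame
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(f"unknown platform {self.platform!r}")
        self.values.index.name = "feature_id"
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dupes[:5]}")
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(index=self.values.index)
        meta = self.feature_meta.reindex(self.values.index)
        if "gene_symbol" not in meta:
            meta["gene_symbol"] = ""
        meta["gene_symbol"] = meta["gene_symbol"].fillna("")
        if "chr_x" not in meta:
            meta["chr_x"] = False
        meta["chr_x"] = meta["chr_x"].fillna(False).astype(bool)
        if "control_role" not in meta:
            meta["control_role"] = "none"
        meta["control_role"] = meta["control_role"].fillna("none")
        bad = set(meta["control_role"]) - set(CONTROL_ROLES)
        if bad:
            raise ValidationError(f"unknown control roles: {sorted(bad)}")
        self.feature_meta = meta
        if self.platform == "methylation":
            v = self.values.to_numpy(dtype=float)
            finite = v[np.isfinite(v)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValidationError("methylation beta values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def noncontrol(self) -> "OmicsBlock":
        """Return a copy restricted to rows with control_role == 'none'."""
        keep = self.feature_meta["control_role"] == "none"
        return OmicsBlock(
            self.platform, self.values.loc[keep].copy(), self.feature_meta.loc[keep].copy()
        )

    def complete_samples(self) -> set[str]:
        """Samples with at least one non-missing value and no all-missing column."""
        v = self.values
        return set(v.columns[v.notna().any(axis=0)])

    def write_tsv(self, path: str | Path) -> None:
        df = self.values.copy()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t")

    def write_meta_tsv(self, path: str | Path) -> None:
        meta = self.feature_meta.copy()
        meta.index.name = "feature_id"
        meta.to_csv(path, sep="\t")


def read_block_tsv(
    path: str | Path, platform: str, meta_path: str | Path | None = None
) -> OmicsBlock:
    """Read a feature-by-sample TSV (first column feature id, header of sample ids)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
    return OmicsBlock(platform, values, meta)


@dataclass
class FusedMatrix:
    """Row-stacked multi-platform matrix with a platform tag per row.

    ``values`` rows use globally unique feature ids; ``platforms`` is a Series
    aligned to the row index; ``gene_symbols`` carries the per-row symbol used
    later for hub gene lists (empty string where none applies).
    """

    values: pd.DataFrame
    platforms: pd.Series
    gene_symbols: pd.Series

    def __post_init__(self) -> None:
        if not self.platforms.index.equals(self.values.index):
            raise ValidationError("platform tags misaligned with fused rows")
        if not self.gene_symbols.index.equals(self.values.index):
            raise ValidationError("gene symbols misaligned with fused rows")
        bad = set(self.platforms) - set(PLATFORMS)
        if bad:
            raise ValidationError(f"unknown platforms in fused matrix: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-form frame with a leading ``platform`` column (the TSV layout)."""
        out = self.values.copy()
        out.insert(0, "gene_symbol", self.gene_symbols)
        out.insert(0, "platform", self.platforms)
        out.index.name = "feature_id"
        return out

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def read_fused_tsv(path: str | Path) -> FusedMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    platforms = df.pop("platform")
    symbols = df.pop("gene_symbol").fillna("")
    return FusedMatrix(df, platforms, symbols)
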