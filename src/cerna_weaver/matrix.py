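"""Count and expression matrix containers with TSV round-trip I/O.

A :class:`CountMatrix` holds raw integer counts (features x samples) for one
RNA class together with per-sample library sizes (total mapped reads, which
may exceed the class-assigned column sums) and, for the mRNA class, feature
lengths in bp. An :class:`ExpressionMatrix` is the normalized counterpart and
records the unit it was computed in so downstream consumers never mix scales.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_UNITS = ("SRPBM", "TPM", "FPKM")


class MatrixError(ValueError):
    """Raised for malformed count/expression matrices."""


@dataclass
class CountMatrix:
    """Integer feature x sample counts for one RNA class.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, features on rows, samples on columns.
    library_size
        Per-sample total mapped reads. Defaults to the column sums of
        ``counts`` (self-contained synthetic runs); must dominate them when
        supplied externally.
    feature_length_bp
        Per-feature exon-model length in bp; required only for FPKM.
    """

    counts: pd.DataFrame
    library_size: pd.Series = None  # type: ignore[assignment]
    feature_length_bp: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts.index.name = "feature_id"
        if self.counts.index.has_duplicates:
            raise MatrixError("duplicate feature ids")
        if self.counts.columns.has_duplicates:
            raise MatrixError("duplicate sample ids")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise MatrixError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise MatrixError("negative counts")
        colsum = self.counts.sum(axis=0)
        if self.library_size is None:
            self.library_size = colsum.astype(np.int64)
        else:
            self.library_size = self.library_size.reindex(self.counts.columns)
            if self.library_size.isna().any():
                raise MatrixError("library_size missing for some samples")
            self.library_size = self.library_size.astype(np.int64)
            if (self.library_size <= 0).any():
                raise MatrixError("library sizes must be positive")
            if (self.library_size < colsum).any():
                raise MatrixError("library_size smaller than class column sum")
        if self.feature_length_bp is not None:
            self.feature_length_bp = self.feature_length_bp.reindex(self.counts.index)
            if self.feature_length_bp.isna().any():
                raise MatrixError("feature length missing for some features")
            if (self.feature_length_bp <= 0).any():
                raise MatrixError("feature lengths must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[samples].copy(),
            library_size=self.library_size[samples].copy(),
            feature_length_bp=None
            if self.feature_length_bp is None
            else self.feature_length_bp.copy(),
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        library_size: pd.Series | None = None,
        feature_length_bp: pd.Series | None = None,
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, library_size=library_size, feature_length_bp=feature_length_bp)


@dataclass
class ExpressionMatrix:
    """Normalized expression values with their unit recorded."""

    values: pd.DataFrame
    unit: str = field(default="TPM")

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise MatrixError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise MatrixError("expression values must be finite")
        if (self.values.to_numpy() < 0).any():
            raise MatrixError("expression values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# unit={self.unit}\n")
            df = self.values.copy()
            df.index.name = "feature_id"
            df.to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# unit="):
                raise MatrixError("missing '# unit=' header")
            unit = first.strip().split("=", 1)[1]
            df = pd.read_csv(io.StringIO(fh.read()), sep="\t", index_col=0)
        return cls(df, unit=unit)


def read_length_table(path: str | Path) -> pd.Series:
    """Read a two-column ``feature_id<TAB>length_bp`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "length_bp"])
    return df.set_index("feature_id")["length_bp"].astype(np.int64)
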