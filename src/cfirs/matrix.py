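"""Expression-matrix container shared by all pipeline stages.

A matrix holds non-negative cfRNA expression values, features in rows and
samples in columns, together with stable feature/sample identifiers. The
on-disk format is plain TSV: first column ``feature_id``, remaining columns
one per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "StructuralError"]


class StructuralError(ValueError):
    """Raised when two pipeline objects disagree on feature/sample structure."""


@dataclass
class ExpressionMatrix:
    """Features x samples table of non-negative expression values.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_features, n_samples)``, all finite and >= 0.
    feature_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    """

    values: np.ndarray
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise StructuralError("values must be 2-D (features x samples)")
        n_feat, n_samp = self.values.shape
        if len(self.feature_ids) != n_feat:
            raise StructuralError(
                f"{len(self.feature_ids)} feature ids for {n_feat} rows"
            )
        if len(self.sample_ids) != n_samp:
            raise StructuralError(
                f"{len(self.sample_ids)} sample ids for {n_samp} columns"
            )
        if len(set(self.feature_ids)) != n_feat:
            raise StructuralError("feature ids must be unique")
        if len(set(self.sample_ids)) != n_samp:
            raise StructuralError("sample ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise StructuralError("expression values must be finite (no NaN/inf)")
        if np.any(self.values < 0):
            raise StructuralError("expression values must be non-negative")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.feature_ids, name="feature_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df)

    def check_same_features(self, other: "ExpressionMatrix") -> None:
        if self.feature_ids != other.feature_ids:
            raise StructuralError("matrices do not share an identical feature index")
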