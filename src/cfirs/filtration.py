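"""Indicator cfRNA selection by four-step two-group filtration.

Candidate features are reduced to a set of risk indicators by applying, in
order:

1. drop features with zero expression in every sample of both groups;
2. drop features whose NP and PE min-max ranges coincide exactly
   (range-overlap coefficient of 1);
3. drop features whose ranges overlap heavily *and* whose standardized mean
   deviation is small (high overlap alone is not disqualifying when the
   means are well separated);
4. keep features whose between-group difference is significant under a
   two-sided Mann-Whitney U test after Benjamini-Hochberg adjustment across
   the features surviving steps 1-3.

The overlap coefficient is intersection-over-union of the per-group
[min, max] ranges; the standardized mean deviation is the absolute mean
difference over the pooled standard deviation. Both are exposed as free
functions and reported per selected feature for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ParameterError
from .matrix import ExpressionMatrix, StructuralError

__all__ = [
    "FilterParams",
    "IndicatorSet",
    "NoIndicatorsError",
    "drop_zero_features",
    "overlap_coefficient",
    "standardized_mean_deviation",
    "group_difference_test",
    "select_indicators",
]

#: diagnostic / group-statistic columns of an IndicatorSet table, in order
INDICATOR_COLUMNS = [
    "overlap",
    "smd",
    "p_raw",
    "p_adj",
    "direction",
    "min_sp",
    "max_sp",
    "mean_sp",
    "min_sn",
    "max_sn",
    "mean_sn",
    "lo",
    "hi",
]


class NoIndicatorsError(RuntimeError):
    """No feature survived filtration; loosen alpha/max_overlap/min_smd."""


@dataclass
class FilterParams:
    """Thresholds for the four filtration steps.

    max_overlap and min_smd act jointly (step 3): a feature is excluded only
    when its overlap exceeds ``max_overlap`` AND its standardized mean
    deviation falls below ``min_smd``. ``adjust`` is ``"bh"`` for
    Benjamini-Hochberg or ``"none"`` for raw p-values.
    """

    max_overlap: float = 0.8
    min_smd: float = 0.5
    alpha: float = 0.05
    adjust: str = "bh"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_overlap <= 1.0:
            raise ParameterError(f"max_overlap must lie in [0, 1], got {self.max_overlap!r}")
        if self.min_smd < 0:
            raise ParameterError(f"min_smd must be >= 0, got {self.min_smd!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if self.adjust not in ("bh", "none"):
            raise ParameterError(f"adjust must be 'bh' or 'none', got {self.adjust!r}")


@dataclass
class IndicatorSet:
    """Selected indicator features with group statistics and diagnostics.

    ``table`` is indexed by feature_id, ordered by ascending adjusted p then
    feature_id, with columns ``overlap, smd, p_raw, p_adj, direction,
    min/max/mean per group, lo, hi`` where ``[lo, hi]`` is the pooled
    min-max range used for risk-score normalization downstream.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in INDICATOR_COLUMNS if c not in self.table.columns]
        if missing:
            raise StructuralError(f"indicator table missing columns {missing}")
        if len(self.table) < 1:
            raise NoIndicatorsError("indicator set is empty")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def directions(self) -> np.ndarray:
        """+1 where the PE mean exceeds the NP mean, else -1 (one per feature)."""
        return self.table["direction"].to_numpy(dtype=int)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Pooled per-feature (lo, hi) = (min over both groups, max over both)."""
        return (
            self.table["lo"].to_numpy(dtype=float),
            self.table["hi"].to_numpy(dtype=float),
        )

    def write_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("feature_id").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "IndicatorSet":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        df.index = df.index.astype(str)
        return cls(df)


def drop_zero_features(np_m: ExpressionMatrix, pe_m: ExpressionMatrix) -> np.ndarray:
    """Boolean keep-mask excluding features that are all-zero in both groups."""
    np_m.check_same_features(pe_m)
    all_zero = (np_m.values == 0).all(axis=1) & (pe_m.values == 0).all(axis=1)
    return ~all_zero


def overlap_coefficient(sp: np.ndarray, sn: np.ndarray) -> float:
    """Intersection-over-union of the two [min, max] expression ranges.

    1.0 means the ranges coincide; 0.0 means they are disjoint. Degenerate
    point ranges yield 1.0 only when both collapse to the same point.
    """
    sp = np.asarray(sp, dtype=float)
    sn = np.asarray(sn, dtype=float)
    if sp.size == 0 or sn.size == 0:
        raise ParameterError("overlap_coefficient: value sets must be non-empty")
    lo_p, hi_p = sp.min(), sp.max()
    lo_n, hi_n = sn.min(), sn.max()
    union = max(hi_p, hi_n) - min(lo_p, lo_n)
    if union == 0.0:  # both ranges a single identical point
        return 1.0
    inter = min(hi_p, hi_n) - max(lo_p, lo_n)
    return max(inter, 0.0) / union


def standardized_mean_deviation(sp: np.ndarray, sn: np.ndarray) -> float:
    """|mean(sp) - mean(sn)| over the pooled standard deviation.

    Zero pooled spread returns 0.0 for equal means and +inf otherwise
    (perfectly separated point masses).
    """
    sp = np.asarray(sp, dtype=float)
    sn = np.asarray(sn, dtype=float)
    if sp.size == 0 or sn.size == 0:
        raise ParameterError("standardized_mean_deviation: value sets must be non-empty")
    diff = abs(sp.mean() - sn.mean())
    n1, n2 = sp.size, sn.size
    dof = n1 + n2 - 2
    if dof <= 0:
        pooled_var = 0.0
    else:
        pooled_var = ((n1 - 1) * sp.var(ddof=1) + (n2 - 1) * sn.var(ddof=1)) / dof
    if pooled_var == 0.0:
        return 0.0 if diff == 0.0 else float("inf")
    return float(diff / np.sqrt(pooled_var))


def group_difference_test(sp: np.ndarray, sn: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value for a between-group location shift.

    Exact for tie-free samples up to 25 per group, normal approximation
    with tie correction otherwise.
    """
    sp = np.asarray(sp, dtype=float)
    sn = np.asarray(sn, dtype=float)
    if sp.size < 3 or sn.size < 3:
        raise ParameterError("group_difference_test: each group needs >= 3 values")
    no_ties = np.unique(np.concatenate([sp, sn])).size == sp.size + sn.size
    method = "exact" if (no_ties and max(sp.size, sn.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(sp, sn, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def select_indicators(
    np_m: ExpressionMatrix,
    pe_m: ExpressionMatrix,
    params: FilterParams | None = None,
) -> IndicatorSet:
    """Run the four filtration steps and return the selected indicator set.

    Deterministic given the inputs and invariant to sample order within each
    group (every statistic used is symmetric in the samples).
    """
    if params is None:
        params = FilterParams()
    np_m.check_same_features(pe_m)
    if np_m.n_samples < 3 or pe_m.n_samples < 3:
        raise ParameterError("select_indicators: need >= 3 samples per group")

    keep = drop_zero_features(np_m, pe_m)
    ids = np.array(np_m.feature_ids, dtype=object)

    records: list[dict] = []
    for i in np.flatnonzero(keep):
        sn = np_m.values[i]
        sp = pe_m.values[i]
        ov = overlap_coefficient(sp, sn)
        if ov == 1.0:
            continue
        smd = standardized_mean_deviation(sp, sn)
        if ov > params.max_overlap and smd < params.min_smd:
            continue
        mean_sp, mean_sn = sp.mean(), sn.mean()
        if mean_sp == mean_sn:
            continue  # risk direction undefined
        records.append(
            {
                "feature_id": str(ids[i]),
                "overlap": ov,
                "smd": smd,
                "p_raw": group_difference_test(sp, sn),
                "direction": 1 if mean_sp > mean_sn else -1,
                "min_sp": sp.min(),
                "max_sp": sp.max(),
                "mean_sp": mean_sp,
                "min_sn": sn.min(),
                "max_sn": sn.max(),
                "mean_sn": mean_sn,
            }
        )

    if not records:
        raise NoIndicatorsError(
            "no features survived range/deviation filtration; "
            "loosen max_overlap/min_smd or check the input cohort"
        )

    df = pd.DataFrame.from_records(records).set_index("feature_id")
    if params.adjust == "bh":
        df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_adj"] = df["p_raw"]

    df = df[df["p_adj"] < params.alpha]
    if df.empty:
        raise NoIndicatorsError(
            f"no features significant at alpha={params.alpha} after "
            f"'{params.adjust}' adjustment; loosen alpha or check effect sizes"
        )

    df["lo"] = df[["min_sp", "min_sn"]].min(axis=1)
    df["hi"] = df[["max_sp", "max_sn"]].max(axis=1)
    df = df.sort_values(["p_adj", "feature_id"], kind="mergesort")
    return IndicatorSet(df[INDICATOR_COLUMNS])
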