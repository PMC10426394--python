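"""Synthetic two-group cfRNA cohort generator.

Emulates the structure of a plasma cell-free RNA case/control study — a
normal-pregnancy (NP) group and a preeclampsia (PE) group profiled over the
same feature set — with known ground truth, so that indicator filtration,
risk-score labeling and the regression network can all be exercised without
any external download.

Per-feature baseline abundance is log-normal (strictly non-negative,
right-skewed, as cfRNA counts are). A chosen fraction of features carries a
planted between-group shift of ``effect_size`` on the log scale, with the
shifted group's mean multiplied by ``exp(+-effect_size)``; the sign is drawn
per feature and recorded in the ground truth. A further fraction of features
is all-zero in both groups, mimicking undetected transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = ["CohortParams", "CohortTruth", "generate_cohort", "ParameterError"]


class ParameterError(ValueError):
    """Invalid generator or filter parameter; message names the field."""


@dataclass
class CohortParams:
    """Study-design knobs for one synthetic cohort.

    Defaults are a desk-scale stand-in for a ~7000-feature cfRNA study with
    tens of samples per arm: 2000 features, 30 + 30 samples, 5% of features
    informative with a 2.5 log-unit shift, 5% undetected.
    """

    n_np: int = 30
    n_pe: int = 30
    n_features: int = 2000
    frac_informative: float = 0.05
    effect_size: float = 2.5
    frac_zero: float = 0.05
    lognormal_mu: float = 1.0
    lognormal_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_np", "n_pe", "n_features"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ParameterError(f"{name} must be a positive integer, got {v!r}")
        if self.n_np < 2 or self.n_pe < 2:
            raise ParameterError("n_np and n_pe must each be >= 2")
        for name in ("frac_informative", "frac_zero"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v!r}")
        if self.frac_informative + self.frac_zero > 1.0 + 1e-12:
            raise ParameterError("frac_informative + frac_zero must be <= 1")
        if self.lognormal_sigma <= 0:
            raise ParameterError("lognormal_sigma must be > 0")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")


@dataclass
class CohortTruth:
    """Planted ground truth: which features carry a shift and its direction."""

    informative_ids: list[str] = field(default_factory=list)
    #: per informative feature: +1 if the PE mean is raised, -1 if lowered
    direction: dict[str, int] = field(default_factory=dict)

    def write_tsv(self, path: str | Path, all_feature_ids: list[str]) -> None:
        informative = set(self.informative_ids)
        df = pd.DataFrame(
            {
                "feature_id": all_feature_ids,
                "informative": [int(f in informative) for f in all_feature_ids],
                "direction": [self.direction.get(f, 0) for f in all_feature_ids],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CohortTruth":
        df = pd.read_csv(path, sep="\t")
        inf = df[df["informative"] == 1]
        return cls(
            informative_ids=list(inf["feature_id"].astype(str)),
            direction=dict(
                zip(inf["feature_id"].astype(str), inf["direction"].astype(int))
            ),
        )


def _feature_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"cfRNA_{i:0{width}d}" for i in range(n)]


def generate_cohort(
    params: CohortParams,
) -> tuple[ExpressionMatrix, ExpressionMatrix, CohortTruth]:
    """Draw one NP matrix, one PE matrix and the planted truth.

    Both matrices share an identical ordered feature index. Exactly
    ``round(frac_zero * n_features)`` features are zero in every sample of
    both groups, and ``round(frac_informative * n_features)`` features carry
    the planted log-scale shift. Identical params (including seed) yield
    bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_features
    ids = _feature_ids(n)

    n_zero = int(round(params.frac_zero * n))
    n_inf = int(round(params.frac_informative * n))

    perm = rng.permutation(n)
    zero_idx = perm[:n_zero]
    inf_idx = np.sort(perm[n_zero : n_zero + n_inf])
    signs = rng.choice([-1, 1], size=n_inf)

    # log-scale means per feature/group; PE means shifted for informative features
    mu_np = np.full(n, params.lognormal_mu)
    mu_pe = mu_np.copy()
    mu_pe[inf_idx] += signs * params.effect_size

    sig = params.lognormal_sigma
    x_np = rng.lognormal(mean=mu_np[:, None], sigma=sig, size=(n, params.n_np))
    x_pe = rng.lognormal(mean=mu_pe[:, None], sigma=sig, size=(n, params.n_pe))
    x_np[zero_idx, :] = 0.0
    x_pe[zero_idx, :] = 0.0

    np_ids = [f"NP_{j:03d}" for j in range(params.n_np)]
    pe_ids = [f"PE_{j:03d}" for j in range(params.n_pe)]
    truth = CohortTruth(
        informative_ids=[ids[i] for i in inf_idx],
        direction={ids[i]: int(s) for i, s in zip(inf_idx, signs)},
    )
    return (
        ExpressionMatrix(x_np, ids, np_ids),
        ExpressionMatrix(x_pe, ids, pe_ids),
        truth,
    )


def write_cohort(
    outdir: str | Path,
    np_m: ExpressionMatrix,
    pe_m: ExpressionMatrix,
    truth: CohortTruth,
) -> dict[str, Path]:
    """Write the cohort as TSVs: two matrices, a sample->group map, the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "np_matrix": outdir / "np_matrix.tsv",
        "pe_matrix": outdir / "pe_matrix.tsv",
        "groups": outdir / "sample_groups.tsv",
        "truth": outdir / "truth.tsv",
    }
    np_m.write_tsv(paths["np_matrix"])
    pe_m.write_tsv(paths["pe_matrix"])
    groups = pd.DataFrame(
        {
            "sample_id": np_m.sample_ids + pe_m.sample_ids,
            "group": ["NP"] * np_m.n_samples + ["PE"] * pe_m.n_samples,
        }
    )
    groups.to_csv(paths["groups"], sep="\t", index=False)
    truth.write_tsv(paths["truth"], np_m.feature_ids)
    return paths
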