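"""Synthetic training/validation profile generation.

Profiles are drawn feature-wise from a Gaussian over each indicator's pooled
two-group range [lo_i, hi_i]: mean at the midpoint, standard deviation
(hi_i - lo_i) / 6 so that the bounds sit at three sigma, with out-of-bound
draws resampled until every value lies inside its range. Labels are then
computed analytically by the risk labeler, giving an arbitrarily large
labeled dataset whose ground truth is exact by construction. A uniform
sampler over the same bounds is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .cohort import ParameterError
from .filtration import IndicatorSet
from .labeling import DegenerateRangeError, label_profiles

__all__ = ["SyntheticDataset", "pooled_bounds", "sample_profiles", "build_dataset"]


def pooled_bounds(indicators: IndicatorSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (lo, hi) pooled over both groups; requires hi > lo."""
    lo, hi = indicators.bounds
    if np.any(hi <= lo):
        bad = np.asarray(indicators.feature_ids)[hi <= lo]
        raise DegenerateRangeError(
            f"degenerate pooled range (hi <= lo) for features: {list(bad[:5])}"
        )
    return lo, hi


def sample_profiles(
    lo: np.ndarray,
    hi: np.ndarray,
    count: int,
    seed: int | np.random.Generator,
    method: str = "gaussian",
) -> np.ndarray:
    """Draw ``count`` profiles within per-feature bounds, shape (count, N).

    ``method="gaussian"`` draws from N(midpoint, range/6) truncated to
    [lo, hi] by resampling; ``method="uniform"`` draws uniformly.
    Seeded calls are bit-reproducible.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if count < 1:
        raise ParameterError(f"count must be >= 1, got {count}")
    if np.any(hi <= lo):
        raise DegenerateRangeError("sample_profiles requires hi > lo per feature")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if method == "uniform":
        return rng.uniform(lo, hi, size=(count, lo.size))
    if method != "gaussian":
        raise ParameterError(f"method must be 'gaussian' or 'uniform', got {method!r}")

    mid = (lo + hi) / 2.0
    sd = (hi - lo) / 6.0
    x = rng.normal(mid, sd, size=(count, lo.size))
    out = (x < lo) | (x > hi)
    while out.any():  # ~0.27% of draws fall outside +-3 sigma
        x[out] = rng.normal(np.broadcast_to(mid, x.shape)[out],
                            np.broadcast_to(sd, x.shape)[out])
        out = (x < lo) | (x > hi)
    return x


@dataclass
class SyntheticDataset:
    """Labeled synthetic profile sets for network training and validation.

    ``x_train`` (M x N) / ``x_test`` (Q x N) hold expression profiles within
    the pooled bounds; ``y_train`` / ``y_test`` their analytic contribution
    vectors in [0, 1]. Regeneration from (indicators, M, Q, seed) is
    bit-identical.
    """

    x_train: np.ndarray
    y_train: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    seed: int

    @property
    def n_features(self) -> int:
        return self.x_train.shape[1]

    def save(self, outdir: str | Path) -> None:
        """Write four TSVs plus a YAML manifest; round-trips losslessly."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("x_train", "y_train", "x_test", "y_test"):
            np.savetxt(outdir / f"{name}.tsv", getattr(self, name),
                       delimiter="\t", fmt="%.17g")
        manifest = {
            "seed": int(self.seed),
            "m": int(self.x_train.shape[0]),
            "q": int(self.x_test.shape[0]),
            "n_features": int(self.n_features),
            "lo": [float(v) for v in self.lo],
            "hi": [float(v) for v in self.hi],
        }
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))

    @classmethod
    def load(cls, outdir: str | Path) -> "SyntheticDataset":
        outdir = Path(outdir)
        manifest = yaml.safe_load((outdir / "manifest.yaml").read_text())
        arrays = {
            name: np.loadtxt(outdir / f"{name}.tsv", delimiter="\t", ndmin=2)
            for name in ("x_train", "y_train", "x_test", "y_test")
        }
        return cls(
            **arrays,
            lo=np.array(manifest["lo"], dtype=float),
            hi=np.array(manifest["hi"], dtype=float),
            seed=int(manifest["seed"]),
        )


def build_dataset(
    indicators: IndicatorSet,
    m: int = 7913,
    q: int = 1000,
    seed: int = 0,
    method: str = "gaussian",
) -> SyntheticDataset:
    """Generate M training and Q validation profiles with analytic labels.

    Train and test streams use independent child streams spawned from the
    seed, so changing M does not perturb the test profiles.
    """
    if m < 1 or q < 1:
        raise ParameterError("m and q must be >= 1")
    lo, hi = pooled_bounds(indicators)
    ss_train, ss_test = np.random.SeedSequence(seed).spawn(2)
    x_train = sample_profiles(lo, hi, m, np.random.default_rng(ss_train), method)
    x_test = sample_profiles(lo, hi, q, np.random.default_rng(ss_test), method)
    y_train, _ = label_profiles(x_train, indicators, bound_source="pooled")
    y_test, _ = label_profiles(x_test, indicators, bound_source="pooled")
    return SyntheticDataset(x_train, y_train, x_test, y_test, lo, hi, seed)
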