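"""Direction-corrected min-max risk labeling.

Each indicator cfRNA contributes a value in [0, 1]: expression is min-max
normalized over the pooled two-group range and, for indicators whose mean is
*lower* in the disease group, the normalization is flipped so that 1 always
means "maximally disease-like". The scalar Individual Risk Score (IRS) of a
profile is the arithmetic mean of its per-indicator contributions, so a
profile at every risk-direction extreme scores exactly 1 and a profile at
every opposite extreme scores exactly 0.

Bounds default to the pooled per-feature [lo, hi] carried by the indicator
set (consistent labels across batches, analytic extremes); a per-batch mode
re-derives bounds from the profile batch itself. Inputs outside the bounds
are clipped before normalizing, preserving the [0, 1] contract.
"""

from __future__ import annotations

import numpy as np

from .cohort import ParameterError
from .filtration import IndicatorSet
from .matrix import StructuralError

__all__ = [
    "feature_contribution",
    "irs_from_contributions",
    "label_profiles",
    "DegenerateRangeError",
]


class DegenerateRangeError(ValueError):
    """A normalization range has hi == lo; such features must be filtered out."""


def feature_contribution(x, lo, hi, direction):
    """Per-feature contribution in [0, 1] (vectorized over broadcastable args).

    direction +1: (clip(x) - lo) / (hi - lo); direction -1: flipped.
    """
    x = np.asarray(x, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    direction = np.asarray(direction)
    if np.any(hi <= lo):
        raise DegenerateRangeError("feature_contribution requires hi > lo per feature")
    up = (np.clip(x, lo, hi) - lo) / (hi - lo)
    return np.where(direction == 1, up, 1.0 - up)


def irs_from_contributions(y) -> float:
    """Scalar IRS: arithmetic mean of a contribution vector."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ParameterError("irs_from_contributions: contribution vector is empty")
    return float(y.mean())


def label_profiles(
    x: np.ndarray,
    indicators: IndicatorSet,
    bound_source: str = "pooled",
) -> tuple[np.ndarray, np.ndarray]:
    """Label a batch of profiles: contribution matrix and IRS per profile.

    Parameters
    ----------
    x
        Array of shape ``(n_profiles, n_indicators)``; columns must follow
        the indicator-set order.
    bound_source
        ``"pooled"`` (default) uses the pooled two-group bounds stored on the
        indicator set; ``"per-batch"`` uses the min/max of each column of
        ``x`` itself.

    Returns
    -------
    (y, irs)
        ``y`` with the same shape as ``x``, values in [0, 1]; ``irs`` of
        length ``n_profiles``, the row means of ``y``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != len(indicators):
        raise StructuralError(
            f"profiles have {x.shape[1]} columns but the indicator set has "
            f"{len(indicators)} features"
        )
    if bound_source == "pooled":
        lo, hi = indicators.bounds
    elif bound_source == "per-batch":
        lo, hi = x.min(axis=0), x.max(axis=0)
    else:
        raise ParameterError(f"bound_source must be 'pooled' or 'per-batch', got {bound_source!r}")
    y = feature_contribution(x, lo, hi, indicators.directions)
    return y, y.mean(axis=1)
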