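"""Error and separation metrics for predicted versus calculated risk scores.

Error amplitude is summarized three ways on the signed per-profile errors
e_k = predicted - truth: the mean absolute error, the maximum absolute
error, and the peak-to-valley (PV) error max(e) - min(e), the full signed
range. Group separation is the per-group mean IRS (NP vs PE) and a
threshold classification accuracy; per-sample prediction latency is
reported informationally.
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ParameterError
from .matrix import StructuralError

__all__ = [
    "EvalReport",
    "error_stats",
    "group_mean_irs",
    "classify",
    "best_threshold",
    "latency_probe",
]


@dataclass
class EvalReport:
    """Flat metric bundle; serializes to YAML and a one-row TSV."""

    mae: float
    max_abs_error: float
    pv_error: float
    group_mean_irs: dict[str, float]
    irs_difference: float
    threshold: float
    accuracy: float
    per_sample_latency_s: float | None = None
    hardware: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def to_tsv(self, path: str | Path) -> None:
        flat = asdict(self)
        means = flat.pop("group_mean_irs")
        flat["mean_irs_np"] = means.get("NP")
        flat["mean_irs_pe"] = means.get("PE")
        pd.DataFrame([flat]).to_csv(path, sep="\t", index=False)


def error_stats(pred, truth) -> dict[str, float]:
    """MAE, max absolute error and peak-to-valley error of pred - truth."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise StructuralError(
            f"prediction/truth length mismatch: {pred.shape} vs {truth.shape}"
        )
    if pred.size == 0:
        raise StructuralError("error_stats requires at least one value")
    e = pred - truth
    return {
        "mae": float(np.abs(e).mean()),
        "max_abs_error": float(np.abs(e).max()),
        "pv_error": float(e.max() - e.min()),
    }


def group_mean_irs(irs, labels) -> dict[str, float]:
    """Mean IRS per group and the PE - NP difference.

    ``labels`` must contain only "NP" and "PE", each at least once.
    """
    irs = np.asarray(irs, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if irs.shape != labels.shape:
        raise StructuralError("irs and labels must have equal length")
    unknown = set(labels) - {"NP", "PE"}
    if unknown:
        raise ParameterError(f"unknown group labels: {sorted(unknown)}")
    out: dict[str, float] = {}
    for g in ("NP", "PE"):
        mask = labels == g
        if not mask.any():
            raise ParameterError(f"group {g} is empty")
        out[g] = float(irs[mask].mean())
    out["difference"] = out["PE"] - out["NP"]
    return out


def classify(irs, threshold: float, truth_labels=None):
    """Label PE iff IRS >= threshold; optionally score against true labels.

    Returns ``(predicted_labels, accuracy)``; accuracy is None without
    truth labels.
    """
    if not 0.0 < threshold < 1.0:
        raise ParameterError(f"threshold must lie in (0, 1), got {threshold!r}")
    irs = np.asarray(irs, dtype=float)
    pred = np.where(irs >= threshold, "PE", "NP")
    if truth_labels is None:
        return pred, None
    truth_labels = np.asarray(truth_labels, dtype=object)
    if truth_labels.shape != irs.shape:
        raise StructuralError("irs and truth_labels must have equal length")
    return pred, float((pred == truth_labels).mean())


def best_threshold(irs, truth_labels, step: float = 0.01) -> tuple[float, float]:
    """Exhaustive grid sweep; returns (threshold, accuracy) maximizing accuracy."""
    grid = np.arange(step, 1.0, step)
    accs = [classify(irs, t, truth_labels)[1] for t in grid]
    k = int(np.argmax(accs))
    return float(grid[k]), float(accs[k])


def latency_probe(results, profiles, repeats: int = 15) -> dict:
    """Wall-clock per-sample prediction latency, averaged over repeats.

    Measures both one-at-a-time and whole-batch prediction; informational
    only (hardware-dependent).
    """
    if repeats < 1:
        raise ParameterError("repeats must be >= 1")
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    one = profiles[:1]

    t0 = time.perf_counter()
    for _ in range(repeats):
        results.predict_irs(one)
    single = (time.perf_counter() - t0) / repeats

    t0 = time.perf_counter()
    for _ in range(repeats):
        results.predict_irs(profiles)
    batched = (time.perf_counter() - t0) / (repeats * len(profiles))

    return {
        "single_sample_s": single,
        "batched_per_sample_s": batched,
        "hardware": platform.processor() or platform.machine(),
    }
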