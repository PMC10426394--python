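"""End-to-end run orchestration: simulate -> filter -> label -> generate ->
train -> predict -> evaluate, with a hashed manifest for reproducibility.

Every stage writes its artifacts into the run directory; the manifest
records package/numpy versions, the global seed, and a sha256 per output
file so that two runs with the same config can be compared byte-for-byte
(all pre-training artifacts are bit-reproducible under a fixed seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortParams, ParameterError, generate_cohort, write_cohort
from .evaluation import EvalReport, error_stats, group_mean_irs, classify, latency_probe
from .filtration import FilterParams, select_indicators
from .labeling import label_profiles
from .model import FCDNModel
from .nn import FCDNConfig
from .sampling import build_dataset

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("cfirs")


def _filtered_kwargs(cls, d: dict, stage: str) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ParameterError(f"unknown {stage} config keys: {sorted(unknown)}")
    return d


@dataclass
class RunConfig:
    """Per-stage parameters plus global seed and output directory.

    Round-trips losslessly through YAML; unknown keys are rejected.
    """

    cohort: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    dataset: dict = field(default_factory=dict)  # m, q, method
    fcdn: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)  # threshold
    seed: int = 0
    outdir: str = "cfirs_run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # validate stage keys eagerly so config errors surface before any work
        _filtered_kwargs(CohortParams, {**self.cohort, "seed": 0}, "cohort")
        _filtered_kwargs(FilterParams, self.filter, "filter")
        unknown = set(self.dataset) - {"m", "q", "method"}
        if unknown:
            raise ParameterError(f"unknown dataset config keys: {sorted(unknown)}")
        _filtered_kwargs(FCDNConfig, {**self.fcdn, "seed": 0}, "fcdn")
        unknown = set(self.evaluation) - {"threshold", "latency_repeats"}
        if unknown:
            raise ParameterError(f"unknown evaluation config keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stage failures propagate with the stage name prefixed; artifacts written
    before the failure are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=config.log_level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    config.to_yaml(outdir / "config.yaml")
    artifacts: list[Path] = [outdir / "config.yaml"]

    def stage(name):
        def deco(fn):
            def wrapped(*a, **kw):
                log.info("stage %s", name)
                try:
                    return fn(*a, **kw)
                except Exception as exc:
                    raise type(exc)(f"[stage {name}] {exc}") from exc
            return wrapped
        return deco

    # simulate ----------------------------------------------------------
    @stage("simulate")
    def _simulate():
        params = CohortParams(**{**config.cohort, "seed": seeds[0]})
        np_m, pe_m, truth = generate_cohort(params)
        paths = write_cohort(outdir / "cohort", np_m, pe_m, truth)
        artifacts.extend(paths.values())
        return np_m, pe_m, truth

    np_m, pe_m, truth = _simulate()

    # filter ------------------------------------------------------------
    @stage("filter")
    def _filter():
        indicators = select_indicators(np_m, pe_m, FilterParams(**config.filter))
        indicators.write_tsv(outdir / "indicators.tsv")
        artifacts.append(outdir / "indicators.tsv")
        return indicators

    indicators = _filter()
    log.info("selected %d indicator cfRNAs", len(indicators))

    # label the cohort samples (calculated IRS ground truth per sample) --
    @stage("label")
    def _label():
        rows = []
        for matrix, group in ((np_m, "NP"), (pe_m, "PE")):
            sub = matrix.to_frame().loc[indicators.feature_ids].to_numpy().T
            _, irs = label_profiles(sub, indicators)
            rows.append(pd.DataFrame(
                {"sample_id": matrix.sample_ids, "group": group, "irs": irs}
            ))
        cohort_irs = pd.concat(rows, ignore_index=True)
        cohort_irs.to_csv(outdir / "cohort_irs.tsv", sep="\t", index=False)
        artifacts.append(outdir / "cohort_irs.tsv")
        return cohort_irs

    cohort_irs = _label()

    # generate ----------------------------------------------------------
    @stage("generate")
    def _generate():
        ds = build_dataset(
            indicators,
            m=int(config.dataset.get("m", 7913)),
            q=int(config.dataset.get("q", 1000)),
            seed=seeds[1],
            method=config.dataset.get("method", "gaussian"),
        )
        ds.save(outdir / "dataset")
        artifacts.extend(sorted((outdir / "dataset").iterdir()))
        return ds

    dataset = _generate()

    # train -------------------------------------------------------------
    @stage("train")
    def _train():
        cfg = FCDNConfig(**{**config.fcdn, "seed": seeds[2]})
        results = FCDNModel(dataset, indicators, cfg).fit()
        results.save(outdir / "model")
        return results

    results = _train()
    log.info("best validation MAE %.5f at epoch %d",
             results.best_val_mae, results.best_epoch)

    # predict + evaluate -------------------------------------------------
    @stage("evaluate")
    def _evaluate():
        pred_irs = results.predict_irs(dataset.x_test)
        _, truth_irs = label_profiles(dataset.x_test, indicators)
        stats = error_stats(pred_irs, truth_irs)

        cohort_profiles = pd.concat(
            [np_m.to_frame().loc[indicators.feature_ids].T,
             pe_m.to_frame().loc[indicators.feature_ids].T]
        ).to_numpy()
        cohort_pred = results.predict_irs(cohort_profiles)
        labels = cohort_irs["group"].to_numpy()
        means = group_mean_irs(cohort_pred, labels)
        thr = float(config.evaluation.get("threshold", 0.5))
        _, acc = classify(cohort_pred, thr, labels)
        lat = latency_probe(
            results, dataset.x_test[:32],
            repeats=int(config.evaluation.get("latency_repeats", 15)),
        )
        report = EvalReport(
            mae=stats["mae"],
            max_abs_error=stats["max_abs_error"],
            pv_error=stats["pv_error"],
            group_mean_irs={"NP": means["NP"], "PE": means["PE"]},
            irs_difference=means["difference"],
            threshold=thr,
            accuracy=acc,
            per_sample_latency_s=lat["batched_per_sample_s"],
            hardware=lat["hardware"],
        )
        report.to_yaml(outdir / "eval_report.yaml")
        report.to_tsv(outdir / "eval_report.tsv")
        artifacts.extend([outdir / "eval_report.yaml", outdir / "eval_report.tsv"])
        pd.DataFrame(
            {"sample_id": cohort_irs["sample_id"], "group": labels,
             "calculated_irs": cohort_irs["irs"], "predicted_irs": cohort_pred}
        ).to_csv(outdir / "cohort_predictions.tsv", sep="\t", index=False)
        artifacts.append(outdir / "cohort_predictions.tsv")
        return report

    report = _evaluate()
    log.info("held-out IRS MAE %.5f, cohort accuracy %.3f", report.mae, report.accuracy)

    manifest = {
        "cfirs_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stage_seeds": {"simulate": seeds[0], "generate": seeds[1], "train": seeds[2]},
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return outdir
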