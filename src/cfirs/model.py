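"""FCDN regression model with a statsmodels-style Model/Results split.

``FCDNModel`` binds a labeled synthetic dataset and an indicator set to a
network configuration; ``fit()`` trains with mean-absolute-error loss and
Adam, early-stopping on an internal validation split of the training
stream, and returns an ``FCDNResults`` carrying the best weights, the
per-epoch history, diagnostics and prediction methods.

Inputs are internally rescaled by the stored pooled bounds to [-1, 1]
before entering the network, so convolution weights see a homogeneous scale
across indicators regardless of their raw expression ranges; the stored
bounds make this part of the fitted model, and profiles outside the bounds
are handled by the logistic output squash rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.linear_model import LinearRegression

from .filtration import IndicatorSet
from .matrix import StructuralError
from .nn import Adam, FCDNConfig, FCDNNetwork
from .sampling import SyntheticDataset

__all__ = [
    "FCDNModel",
    "FCDNResults",
    "TrainingDivergenceError",
    "linear_baseline_mae",
]


class TrainingDivergenceError(RuntimeError):
    """Loss became non-finite during training; message carries the epoch."""


def _mae(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.abs(pred - truth).mean())


class FCDNModel:
    """Contribution-vector regression network bound to its training data.

    Parameters
    ----------
    dataset
        Synthetic profile sets with analytic contribution labels.
    indicators
        The indicator set the dataset was generated from; its ordering and
        pooled bounds travel with the fitted model.
    config
        Architecture and optimization hyperparameters.
    """

    def __init__(
        self,
        dataset: SyntheticDataset,
        indicators: IndicatorSet,
        config: FCDNConfig | None = None,
    ):
        if dataset.n_features != len(indicators):
            raise StructuralError(
                f"dataset has {dataset.n_features} features but the indicator "
                f"set has {len(indicators)}"
            )
        self.dataset = dataset
        self.indicators = indicators
        self.config = config or FCDNConfig()
        self.network = FCDNNetwork(self.config, dataset.n_features)

    @classmethod
    def from_indicators(
        cls,
        indicators: IndicatorSet,
        m: int = 7913,
        q: int = 1000,
        seed: int = 0,
        config: FCDNConfig | None = None,
    ) -> "FCDNModel":
        """Build the model by generating its synthetic dataset on the fly."""
        from .sampling import build_dataset

        return cls(build_dataset(indicators, m=m, q=q, seed=seed), indicators, config)

    # ------------------------------------------------------------------

    def _scale(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.dataset.lo, self.dataset.hi
        return 2.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo) - 1.0

    def fit(self, disp: bool = False) -> "FCDNResults":
        """Train to minimize MAE; return results at the best validation MAE.

        The learning rate is halved (``lr_decay_factor``) whenever the
        validation MAE has not improved for ``lr_decay_patience`` epochs —
        with an L1 objective the reachable loss floor is proportional to
        the step size, so plateau decay is what lets the fit converge —
        and training stops early after ``early_stop_patience`` epochs
        without a ``min_delta`` improvement.
        """
        from .nn.layers import DTYPE

        cfg = self.config
        net = self.network
        x_all = self._scale(self.dataset.x_train).astype(DTYPE)
        y_all = self.dataset.y_train.astype(DTYPE)
        n = x_all.shape[0]

        split_rng = np.random.default_rng([cfg.seed, 101])
        order = split_rng.permutation(n)
        n_val = max(1, int(round(cfg.val_fraction * n)))
        val_idx, train_idx = order[:n_val], order[n_val:]
        x_tr, y_tr = x_all[train_idx], y_all[train_idx]
        x_val, y_val = x_all[val_idx], y_all[val_idx]

        opt = Adam(net, lr=cfg.lr)
        shuffle_rng = np.random.default_rng([cfg.seed, 202])
        best_val = np.inf
        best_weights = net.get_weights()
        best_epoch = 0
        history: list[dict] = []
        since_best = 0
        since_decay_best = 0

        for epoch in range(1, cfg.epochs + 1):
            perm = shuffle_rng.permutation(len(x_tr))
            losses = []
            for start in range(0, len(x_tr), cfg.batch):
                idx = perm[start : start + cfg.batch]
                xb, yb = x_tr[idx], y_tr[idx]
                pred = net.forward(xb, training=True)
                err = pred - yb
                loss = np.abs(err).mean()
                if not np.isfinite(loss):
                    raise TrainingDivergenceError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                losses.append(loss)
                net.backward(np.sign(err, dtype=DTYPE) / DTYPE(err.size))
                opt.step()

            val_pred = net.forward(x_val, training=False)
            val_mae = _mae(val_pred, y_val)
            history.append(
                {"epoch": epoch, "train_mae": float(np.mean(losses)),
                 "val_mae": val_mae, "lr": opt.lr}
            )
            if disp:
                print(f"epoch {epoch:3d}  train MAE {np.mean(losses):.5f}  "
                      f"val MAE {val_mae:.5f}  lr {opt.lr:.2e}")

            if val_mae < best_val - cfg.min_delta:
                since_best = 0
            else:
                since_best += 1
            if val_mae < best_val:
                best_val = val_mae
                best_weights = net.get_weights()
                best_epoch = epoch
                since_decay_best = 0
            else:
                since_decay_best += 1
            if since_best >= cfg.early_stop_patience:
                break
            if since_decay_best >= cfg.lr_decay_patience and opt.lr > cfg.min_lr:
                opt.lr = max(opt.lr * cfg.lr_decay_factor, cfg.min_lr)
                since_decay_best = 0

        if cfg.restore_best:
            net.set_weights(best_weights)
        else:
            best_val = history[-1]["val_mae"]
            best_epoch = len(history)
        # align BN inference statistics with the full training distribution
        net.recalibrate_bn(x_tr)
        return FCDNResults(
            model=self,
            history=pd.DataFrame(history),
            best_val_mae=float(best_val),
            best_epoch=best_epoch,
        )


@dataclass
class FCDNResults:
    """Fitted-model container: best weights live on ``model.network``."""

    model: FCDNModel
    history: pd.DataFrame
    best_val_mae: float
    best_epoch: int
    _param_count: int = field(init=False)

    def __post_init__(self) -> None:
        self._param_count = self.model.network.parameter_count()

    # -- prediction ------------------------------------------------------

    def _check_profiles(self, profiles) -> np.ndarray:
        if isinstance(profiles, pd.DataFrame):
            expected = self.model.indicators.feature_ids
            if list(profiles.columns) != expected:
                raise StructuralError(
                    "profile columns do not match the model's indicator order"
                )
            profiles = profiles.to_numpy(dtype=float)
        x = np.atleast_2d(np.asarray(profiles, dtype=float))
        if x.shape[1] != self.model.dataset.n_features:
            raise StructuralError(
                f"profiles have {x.shape[1]} features; model expects "
                f"{self.model.dataset.n_features}"
            )
        return x

    def predict_contributions(self, profiles, batch: int = 512) -> np.ndarray:
        """Predicted per-indicator contribution vectors, values in [0, 1]."""
        x = self.model._scale(self._check_profiles(profiles))
        out = [
            self.model.network.forward(x[i : i + batch], training=False)
            for i in range(0, x.shape[0], batch)
        ]
        return np.vstack(out)

    def predict_irs(self, profiles) -> np.ndarray:
        """Predicted IRS per profile: mean of the predicted contributions."""
        return self.predict_contributions(profiles).mean(axis=1)

    def mae(self, profiles, y_true) -> float:
        return _mae(self.predict_contributions(profiles), np.asarray(y_true))

    @property
    def test_mae(self) -> float:
        """Contribution MAE on the held-out test stream of the dataset."""
        return self.mae(self.model.dataset.x_test, self.model.dataset.y_test)

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        ds = self.model.dataset
        rows = [
            ("Indicators (N)", ds.n_features),
            ("Training profiles (M)", ds.x_train.shape[0]),
            ("Held-out profiles (Q)", ds.x_test.shape[0]),
            ("Residual blocks", cfg.n_blocks),
            ("Filters / kernel", f"{cfg.filters} / {cfg.kernel}"),
            ("Parameters", self._param_count),
            ("Epochs run", len(self.history)),
            ("Best epoch", self.best_epoch),
            ("Best val MAE", f"{self.best_val_mae:.5f}"),
            ("Held-out MAE", f"{self.test_mae:.5f}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["FCDN contribution regression", "=" * 40]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Train/validation MAE learning curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_mae"], label="train")
        ax.plot(self.history["epoch"], self.history["val_mae"], label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MAE")
        ax.legend()
        return ax

    # -- persistence -----------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        """Persist config (YAML), weights (npz), indicator table and history."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.model.config.to_dict(),
            "best_val_mae": self.best_val_mae,
            "best_epoch": self.best_epoch,
            "n_features": self.model.dataset.n_features,
            "optimizer": "adam",
            "nonlinearity": "relu",
            "output": "logistic",
            "lo": [float(v) for v in self.model.dataset.lo],
            "hi": [float(v) for v in self.model.dataset.hi],
        }
        (outdir / "model.yaml").write_text(yaml.safe_dump(meta))
        weights = {f"w{i:04d}": w
                   for i, w in enumerate(self.model.network.get_weights())}
        np.savez(outdir / "weights.npz", **weights)
        self.model.indicators.write_tsv(outdir / "indicators.tsv")
        self.history.to_csv(outdir / "history.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, outdir: str | Path, dataset: SyntheticDataset | None = None) -> "FCDNResults":
        """Rebuild a fitted results object from ``save()`` output.

        If no dataset is given, a minimal stand-in carrying only the stored
        bounds is constructed (sufficient for prediction).
        """
        outdir = Path(outdir)
        meta = yaml.safe_load((outdir / "model.yaml").read_text())
        indicators = IndicatorSet.read_tsv(outdir / "indicators.tsv")
        if dataset is None:
            lo = np.array(meta["lo"], dtype=float)
            hi = np.array(meta["hi"], dtype=float)
            stub = np.zeros((1, int(meta["n_features"])))
            dataset = SyntheticDataset(stub, stub, stub, stub, lo, hi, seed=0)
        model = FCDNModel(dataset, indicators, FCDNConfig(**meta["config"]))
        with np.load(outdir / "weights.npz") as z:
            model.network.set_weights([z[k] for k in sorted(z.files)])
        history = pd.read_csv(outdir / "history.tsv", sep="\t")
        return cls(
            model=model,
            history=history,
            best_val_mae=float(meta["best_val_mae"]),
            best_epoch=int(meta["best_epoch"]),
        )


def linear_baseline_mae(dataset: SyntheticDataset) -> float:
    """Held-out MAE of an ordinary-least-squares baseline.

    The contribution target is affine in the profile, so this baseline
    solves the task essentially exactly; it serves as a floor the network
    must stay close to (a guard against silent architecture bugs), not as a
    competitor it could beat.
    """
    reg = LinearRegression().fit(dataset.x_train, dataset.y_train)
    pred = np.clip(reg.predict(dataset.x_test), 0.0, 1.0)
    return _mae(pred, dataset.y_test)
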