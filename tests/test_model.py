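"""Model/Results interface: learning sanity, aggregation identity, persistence."""

import numpy as np
import pytest

from cfirs import FCDNConfig, FCDNModel, build_dataset, linear_baseline_mae
from cfirs.matrix import StructuralError
from cfirs.model import FCDNResults

from conftest import make_indicators


@pytest.fixture(scope="module")
def ten_feature_indicators():
    rng = np.random.default_rng(0)
    lo = rng.uniform(0, 5, size=10)
    return make_indicators(
        lo=lo, hi=lo + rng.uniform(1, 10, size=10),
        direction=rng.choice([-1, 1], size=10),
    )


@pytest.fixture(scope="module")
def fitted_small(ten_feature_indicators):
    ds = build_dataset(ten_feature_indicators, m=200, q=50, seed=1)
    cfg = FCDNConfig(n_blocks=2, filters=8, epochs=50, batch=32, seed=1)
    return FCDNModel(ds, ten_feature_indicators, cfg).fit()


def test_validation_mae_improves_over_training(fitted_small):
    h = fitted_small.history
    assert h["val_mae"].iloc[-1] < h["val_mae"].iloc[0]
    assert fitted_small.best_val_mae <= h["val_mae"].min() + 1e-12


def test_overfits_a_tiny_memorization_set(ten_feature_indicators):
    """With enough epochs on 32 fixed profiles the network memorizes them."""
    ds = build_dataset(ten_feature_indicators, m=36, q=4, seed=2)
    # final-epoch weights and a slow decay schedule: the 4-profile validation
    # split is far too noisy for model selection on a memorization run
    cfg = FCDNConfig(n_blocks=2, filters=16, dropout=0.0, epochs=1200, batch=8,
                     lr=1e-2, lr_decay_factor=0.5, lr_decay_patience=60,
                     min_lr=1e-5, val_fraction=0.11, early_stop_patience=1200,
                     min_delta=0.0, restore_best=False, seed=2)
    res = FCDNModel(ds, ten_feature_indicators, cfg).fit()
    train_mae = res.mae(ds.x_train, ds.y_train)
    assert train_mae < 0.01


def test_predict_irs_equals_mean_of_contributions(fitted_small):
    x = fitted_small.model.dataset.x_test
    contrib = fitted_small.predict_contributions(x)
    np.testing.assert_allclose(
        fitted_small.predict_irs(x), contrib.mean(axis=1), atol=1e-12
    )


def test_predictions_in_unit_interval_even_out_of_bounds(fitted_small):
    lo = fitted_small.model.dataset.lo
    x = np.vstack([lo - 50.0, lo + 1e3])
    y = fitted_small.predict_contributions(x)
    assert np.all((y >= 0.0) & (y <= 1.0))


def test_identical_profiles_identical_predictions(fitted_small):
    x = fitted_small.model.dataset.x_test[:1]
    two = np.vstack([x, x])
    pred = fitted_small.predict_contributions(two)
    np.testing.assert_array_equal(pred[0], pred[1])


def test_profile_feature_mismatch_rejected(fitted_small):
    with pytest.raises(StructuralError):
        fitted_small.predict_contributions(np.zeros((2, 7)))


def test_dataframe_column_order_enforced(fitted_small):
    import pandas as pd

    ids = fitted_small.model.indicators.feature_ids
    x = fitted_small.model.dataset.x_test[:2]
    ok = pd.DataFrame(x, columns=ids)
    pred = fitted_small.predict_contributions(ok)
    assert pred.shape == (2, len(ids))
    bad = ok[list(reversed(ids))]
    with pytest.raises(StructuralError):
        fitted_small.predict_contributions(bad)


def test_seeded_fit_reproducible(ten_feature_indicators):
    ds = build_dataset(ten_feature_indicators, m=60, q=10, seed=5)
    cfg = FCDNConfig(n_blocks=1, filters=4, epochs=3, seed=7)
    r1 = FCDNModel(ds, ten_feature_indicators, cfg).fit()
    r2 = FCDNModel(ds, ten_feature_indicators, cfg).fit()
    np.testing.assert_array_equal(
        r1.history["val_mae"].to_numpy(), r2.history["val_mae"].to_numpy()
    )


def test_save_load_roundtrip(tmp_path, fitted_small):
    fitted_small.save(tmp_path / "model")
    back = FCDNResults.load(tmp_path / "model")
    x = fitted_small.model.dataset.x_test[:5]
    np.testing.assert_allclose(
        back.predict_contributions(x),
        fitted_small.predict_contributions(x),
        atol=1e-6,
    )
    assert back.best_epoch == fitted_small.best_epoch


def test_linear_baseline_is_essentially_exact(ten_feature_indicators):
    """The contribution target is affine in the profile, so OLS solves it."""
    ds = build_dataset(ten_feature_indicators, m=100, q=30, seed=9)
    assert linear_baseline_mae(ds) < 1e-8


def test_summary_mentions_key_quantities(fitted_small):
    s = fitted_small.summary()
    assert "val MAE" in s and "Parameters" in s
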