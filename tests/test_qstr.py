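"""Nano-QSTR models: prediction, fitting, statistics, split and domain."""

import numpy as np
import pandas as pd
import pytest

from mitotox.errors import SingularDesignError
from mitotox.qstr import (
    QstrDataset,
    QstrModel,
    applicability_domain,
    cooh_model,
    fit_ols,
    load_published_dataset,
    pristine_model,
    report_for_subset,
    report_from_predictions,
    split_dataset,
)
from mitotox.synthetic import SyntheticConfig, make_qstr_dataset


# --- prediction -----------------------------------------------------------

@pytest.mark.parametrize("model, desc, expected", [
    (pristine_model(), {"GNar": 0.0, "MAXDP": 0.0}, -2.87142),
    (pristine_model(), {"GNar": 1.0, "MAXDP": 1.0}, -8.24425 + 0.614121 - 2.87142),
    (cooh_model(), {"GNar": 0.0, "PW5": 0.0, "LOC": 0.0}, -2326.4),
    (cooh_model(), {"GNar": 1.0, "PW5": 1.0, "LOC": 1.0},
     -1005.47 - 1401.69 - 139.55 - 2326.4),
])
def test_predict_matches_hand_arithmetic(model, desc, expected):
    assert model.predict(desc) == pytest.approx(expected, abs=1e-12)


def test_predict_missing_descriptor_raises():
    with pytest.raises(KeyError, match="MAXDP"):
        pristine_model().predict({"GNar": 1.0})


def test_model_validates_dimensions():
    with pytest.raises(ValueError):
        QstrModel(("a", "b"), (1.0,), 0.0)
    with pytest.raises(ValueError):
        QstrModel(("a",), (np.nan,), 0.0)


# --- published-table reproduction -----------------------------------------

def test_published_residual_column_identity():
    for which in ("pristine", "carboxyl"):
        t = load_published_dataset(which).table
        gap = np.max(np.abs(t.observed - t.predicted - t.residual))
        assert gap < 1e-4


def test_published_split_sizes():
    for which in ("pristine", "carboxyl"):
        t = load_published_dataset(which).table
        assert len(t) == 45
        assert (t.split == "training").sum() == 34
        assert (t.split == "validation").sum() == 11


def test_perfect_predictions_give_unit_r2():
    obs = np.array([1.0, 2.0, 4.0, 3.0, 5.0, 0.5])
    rep = report_from_predictions(obs, obs, 2)
    assert rep.r_squared == pytest.approx(1.0) and rep.ss_residual == 0.0


def test_constant_response_flagged_degenerate():
    with pytest.raises(ValueError, match="constant"):
        report_from_predictions([2.0, 2.0, 2.0, 2.0, 2.0], [2.0, 1.0, 2.0, 3.0, 2.0], 1)


def test_report_invariants_on_published_tables():
    """R² = SSmod/(SSmod+SSres) and F = MSEmod/MSEres hold for every block."""
    for which, p in (("pristine", 2), ("carboxyl", 3)):
        ds = load_published_dataset(which)
        for subset in ("training", "validation", "all"):
            rep = report_for_subset(ds, subset, p)
            assert rep.f_statistic == pytest.approx(rep.mse_model / rep.mse_residual)
            n = rep.df_model + rep.df_residual + 1
            assert n == rep.n_rows
            assert rep.adjusted_r_squared == pytest.approx(
                1 - (1 - rep.r_squared) * (n - 1) / rep.df_residual)


# --- OLS fitting ----------------------------------------------------------

def test_noiseless_fit_recovers_coefficients_exactly():
    cfg = SyntheticConfig(seed=11, qstr_sigma=0.0)
    ds = make_qstr_dataset(cfg)
    names = list(cfg.qstr_coefficients)
    model, report, _ = fit_ols(ds, names, use_split=False)
    for name, coef in zip(model.descriptor_names, model.coefficients):
        assert coef == pytest.approx(cfg.qstr_coefficients[name], rel=1e-8)
    assert model.intercept == pytest.approx(cfg.qstr_intercept, rel=1e-8)
    assert report.r_squared == pytest.approx(1.0, abs=1e-12)


def test_ols_sum_of_squares_decomposition():
    """With an intercept, SS_model + SS_residual equals the total SS."""
    ds = make_qstr_dataset(SyntheticConfig(seed=5, qstr_sigma=2.0))
    _, rep, _ = fit_ols(ds, ["GNar", "MAXDP"], use_split=False)
    y = ds.table["observed"].to_numpy()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    assert rep.ss_model + rep.ss_residual == pytest.approx(ss_tot, rel=1e-8)


def test_r2_improves_as_noise_vanishes():
    r2 = [fit_ols(make_qstr_dataset(SyntheticConfig(seed=4, qstr_sigma=s)),
                  ["GNar", "MAXDP", "PW5", "LOC"], use_split=False)[1].r_squared
          for s in (8.0, 2.0, 0.5, 0.0)]
    assert r2 == sorted(r2)
    assert r2[-1] == pytest.approx(1.0, abs=1e-12)


def test_singular_design_raises():
    table = pd.DataFrame({
        "label": [f"r{i}" for i in range(12)],
        "a": np.arange(12.0),
        "b": 2.0 * np.arange(12.0),  # collinear with a
        "observed": np.arange(12.0) + 1.0,
    })
    with pytest.raises(SingularDesignError):
        fit_ols(QstrDataset(table), ["a", "b"], use_split=False)


# --- splitting ------------------------------------------------------------

def test_split_rounds_half_up():
    ds = make_qstr_dataset(SyntheticConfig(seed=1, qstr_n=45))
    out = split_dataset(ds, 0.7, seed=2)
    assert (out.table.split == "training").sum() == 32  # round(31.5) -> 32


def test_split_deterministic_under_seed():
    ds = make_qstr_dataset(SyntheticConfig(seed=1))
    a = split_dataset(ds, 0.7, seed=9).table.split.tolist()
    b = split_dataset(ds, 0.7, seed=9).table.split.tolist()
    assert a == b


def test_split_explicit_assignment():
    ds = make_qstr_dataset(SyntheticConfig(seed=1, qstr_n=45))
    labels = ["training"] * 34 + ["validation"] * 11
    out = split_dataset(ds, assignment=labels)
    assert out.table.split.tolist() == labels


def test_split_rejects_empty_partition():
    ds = make_qstr_dataset(SyntheticConfig(seed=1, qstr_n=10))
    with pytest.raises(ValueError):
        split_dataset(ds, 0.01, seed=0)


# --- applicability domain -------------------------------------------------

def test_leverages_sum_to_parameter_count():
    """Hat-matrix trace identity: training leverages sum to p + 1."""
    ds = make_qstr_dataset(SyntheticConfig(seed=8))
    ds = split_dataset(ds, 0.7, seed=8)
    model, _, _ = fit_ols(ds, ["GNar", "MAXDP"])
    ad = applicability_domain(model, ds)
    train_mask = (ds.table.split == "training").to_numpy()
    assert ad.leverage[train_mask].sum() == pytest.approx(3.0, rel=1e-9)


def test_h_star_formula():
    ds = load_published_dataset("pristine")
    model = QstrModel(("n", "m"), (0.0, 0.0), 0.0)
    ad = applicability_domain(model, ds, predicted="predicted")
    assert ad.h_star == pytest.approx(9 / 34)


def test_centroid_row_has_minimal_leverage():
    ds = make_qstr_dataset(SyntheticConfig(seed=13, qstr_n=20))
    model, _, _ = fit_ols(ds, ["GNar", "MAXDP"], use_split=False)
    train = ds.table
    centroid = {
        "label": "centroid",
        "GNar": train.GNar.mean(),
        "MAXDP": train.MAXDP.mean(),
        "PW5": 0.0, "LOC": 0.0,
        "observed": train.observed.mean(),
    }
    augmented = QstrDataset(pd.concat(
        [train, pd.DataFrame([centroid])], ignore_index=True))
    split = ["training"] * len(train) + ["validation"]
    augmented = split_dataset(augmented, assignment=split)
    ad = applicability_domain(model, augmented)
    assert ad.leverage[-1] == pytest.approx(1 / len(train), rel=1e-9)
    assert ad.leverage[-1] == pytest.approx(ad.leverage.min(), rel=1e-9)


def test_domain_flags_extreme_rows():
    ds = make_qstr_dataset(SyntheticConfig(seed=21, qstr_n=30, qstr_sigma=0.1))
    table = ds.table.copy()
    table.loc[0, "GNar"] = 50.0  # far outside the sampled descriptor range
    ds = QstrDataset(table)
    model, _, _ = fit_ols(ds, ["GNar", "MAXDP"], use_split=False)
    ad = applicability_domain(model, ds)
    assert bool(ad.outside[0])
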