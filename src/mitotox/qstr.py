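"""Nano-QSTR linear toxicity models with validation and applicability domain.

Two published linear models map topological descriptors of a nanotube to a
docking-derived toxicity response f(FEB):

* pristine tubes:  f(FEB_1) = −8.24425·GNar + 0.614121·MAXDP − 2.87142
* carboxyl tubes:  f(FEB_2) = −1005.47·GNar − 1401.69·PW5 − 139.55·LOC − 2326.4

This module evaluates those models, refits ordinary least squares on
descriptor tables, rebuilds the published statistics blocks from
observed/predicted columns, performs the 70/30 train/validation split, and
delimits a leverage-based applicability domain (Williams construction:
hat-matrix leverages against standardized residuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import SingularDesignError

#: printed model coefficients, usable directly with ``predict``
PRISTINE_MODEL_COEFFS = {"GNar": -8.24425, "MAXDP": 0.614121}
PRISTINE_MODEL_INTERCEPT = -2.87142
COOH_MODEL_COEFFS = {"GNar": -1005.47, "PW5": -1401.69, "LOC": -139.55}
COOH_MODEL_INTERCEPT = -2326.4


@dataclass(frozen=True)
class QstrModel:
    """A linear toxicity model: response = intercept + Σ coef·descriptor."""

    descriptor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    response_name: str = "f(FEB)"

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.descriptor_names):
            raise ValueError("one coefficient per descriptor required")
        values = (*self.coefficients, self.intercept)
        if not all(np.isfinite(values)):
            raise ValueError("model parameters must be finite")

    @classmethod
    def from_mapping(cls, coeffs: dict[str, float], intercept: float,
                     response_name: str = "f(FEB)") -> "QstrModel":
        names = tuple(coeffs)
        return cls(names, tuple(coeffs[k] for k in names), intercept, response_name)

    def predict(self, descriptors) -> float:
        """Evaluate the model on one descriptor mapping (dict-like or
        DescriptorVector)."""
        if hasattr(descriptors, "as_dict"):
            descriptors = descriptors.as_dict()
        try:
            return float(self.intercept + sum(
                c * float(descriptors[name])
                for name, c in zip(self.descriptor_names, self.coefficients)))
        except KeyError as exc:
            raise KeyError(f"descriptor {exc.args[0]!r} missing from input") from exc

    def predict_frame(self, table: pd.DataFrame) -> np.ndarray:
        x = table[list(self.descriptor_names)].to_numpy(dtype=float)
        return x @ np.asarray(self.coefficients) + self.intercept


def pristine_model() -> QstrModel:
    return QstrModel.from_mapping(PRISTINE_MODEL_COEFFS, PRISTINE_MODEL_INTERCEPT, "f(FEB_1)")


def cooh_model() -> QstrModel:
    return QstrModel.from_mapping(COOH_MODEL_COEFFS, COOH_MODEL_INTERCEPT, "f(FEB_2)")


@dataclass(frozen=True)
class RegressionReport:
    """The statistics block printed alongside a fitted model."""

    multiple_r: float
    r_squared: float
    adjusted_r_squared: float
    ss_model: float
    ss_residual: float
    df_model: int
    df_residual: int
    mse_model: float
    mse_residual: float
    f_statistic: float
    p_value: float
    n_rows: int

    def as_dict(self) -> dict[str, float]:
        return {
            "multiple_r": self.multiple_r,
            "r_squared": self.r_squared,
            "adjusted_r_squared": self.adjusted_r_squared,
            "ss_model": self.ss_model,
            "ss_residual": self.ss_residual,
            "df_model": self.df_model,
            "df_residual": self.df_residual,
            "mse_model": self.mse_model,
            "mse_residual": self.mse_residual,
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "n_rows": self.n_rows,
        }


@dataclass
class QstrDataset:
    """Labelled descriptor/response rows with a train/validation split.

    ``table`` must carry at least ``label``, ``observed`` and (optionally)
    ``predicted`` and ``split`` columns; descriptor columns are free-form.
    """

    table: pd.DataFrame
    true_coefficients: dict[str, float] | None = field(default=None)
    true_intercept: float | None = field(default=None)

    def __post_init__(self) -> None:
        if "label" in self.table.columns and self.table["label"].duplicated().any():
            raise ValueError("row labels must be unique")

    def subset(self, which: str) -> pd.DataFrame:
        if which == "all":
            return self.table
        if "split" not in self.table.columns:
            raise ValueError("dataset has no split assignment")
        out = self.table[self.table["split"] == which]
        if out.empty:
            raise ValueError(f"subset {which!r} is empty")
        return out


def report_from_predictions(observed, predicted, n_descriptors: int) -> RegressionReport:
    """Rebuild the printed statistics block from observed/predicted columns.

    SS_model is taken about the mean of the *observed* response; degrees of
    freedom follow the supplied model dimension p: df_model = p,
    df_residual = n − p − 1.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0:
        raise ValueError("empty subset")
    if obs.size != pred.size:
        raise ValueError("observed and predicted lengths differ")
    n = obs.size
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant response: R² undefined")
    ss_mod = float(np.sum((pred - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    df_model = n_descriptors
    df_residual = n - n_descriptors - 1
    if df_residual <= 0:
        raise ValueError(f"need more than p+1 rows, got n={n}, p={n_descriptors}")
    mse_mod = ss_mod / df_model
    mse_res = ss_res / df_residual
    f_stat = mse_mod / mse_res if mse_res > 0 else float("inf")
    return RegressionReport(
        multiple_r=float(np.sqrt(max(0.0, r2))),
        r_squared=r2,
        adjusted_r_squared=1.0 - (1.0 - r2) * (n - 1) / df_residual,
        ss_model=ss_mod,
        ss_residual=ss_res,
        df_model=df_model,
        df_residual=df_residual,
        mse_model=mse_mod,
        mse_residual=mse_res,
        f_statistic=f_stat,
        p_value=float(stats.f.sf(f_stat, df_model, df_residual)),
        n_rows=n,
    )


def report_for_subset(dataset: QstrDataset, subset: str, n_descriptors: int) -> RegressionReport:
    """Statistics block for one split subset of a dataset that already has
    observed and predicted columns (e.g. the published tables)."""
    part = dataset.subset(subset)
    return report_from_predictions(part["observed"], part["predicted"], n_descriptors)


def fit_ols(dataset: QstrDataset, descriptor_names: list[str], response: str = "observed",
            use_split: bool = True) -> tuple[QstrModel, RegressionReport, sm.regression.linear_model.RegressionResultsWrapper]:
    """Ordinary least squares with intercept on the training rows.

    Returns the fitted model, its statistics block, and the underlying
    statsmodels results (standard errors, confidence intervals...).
    """
    rows = dataset.subset("training") if use_split and "split" in dataset.table.columns else dataset.table
    y = rows[response].to_numpy(dtype=float)
    x = rows[list(descriptor_names)].to_numpy(dtype=float)
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    res = sm.OLS(y, design).fit()
    model = QstrModel(tuple(descriptor_names), tuple(res.params[1:]), float(res.params[0]))
    pred = res.fittedvalues
    report = report_from_predictions(y, pred, len(descriptor_names))
    return model, report, res


def split_dataset(dataset: QstrDataset, train_fraction: float = 0.7,
                  seed: int | None = None, assignment=None) -> QstrDataset:
    """Assign rows to training/validation.

    Either reproducibly at random under ``seed`` (training count rounded
    half up), or via an explicit per-row ``assignment`` vector such as the
    published table labels.
    """
    table = dataset.table.copy()
    n = len(table)
    if assignment is not None:
        assignment = list(assignment)
        if len(assignment) != n:
            raise ValueError("assignment length mismatch")
        if not set(assignment) <= {"training", "validation"}:
            raise ValueError("assignment entries must be 'training' or 'validation'")
        table["split"] = assignment
    else:
        if not 0.0 < train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        # round half up in exact rational arithmetic (0.7 is not a binary
        # float, so 45*0.7 + 0.5 would floor to 31 instead of 32)
        frac = Fraction(train_fraction).limit_denominator(10**6)
        n_train = int(n * frac + Fraction(1, 2))
        if n_train == 0 or n_train == n:
            raise ValueError("split leaves an empty partition")
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        split = np.full(n, "validation", dtype=object)
        split[order[:n_train]] = "training"
        table["split"] = split
    return QstrDataset(table, dataset.true_coefficients, dataset.true_intercept)


@dataclass(frozen=True)
class ApplicabilityDomain:
    """Williams-plot applicability domain of a fitted model.

    Leverages h_i come from the hat matrix of the training design;
    h* = 3(p+1)/n_train.  A row is outside the domain if h_i > h* or its
    standardized residual exceeds 3 in magnitude.
    """

    leverage: np.ndarray
    h_star: float
    std_residual: np.ndarray
    outside: np.ndarray
    labels: tuple[str, ...]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.labels,
            "leverage": self.leverage,
            "std_residual": self.std_residual,
            "outside": self.outside,
        })


def applicability_domain(model: QstrModel, dataset: QstrDataset,
                         response: str = "observed",
                         predicted: str | None = None) -> ApplicabilityDomain:
    """Leverage/standardized-residual domain for every row of the dataset,
    with the hat matrix built from the training rows.

    Predictions come from the model unless ``predicted`` names a column of
    already-computed predictions (e.g. the published tables, whose
    descriptor values are not recoverable)."""
    table = dataset.table
    train = dataset.subset("training") if "split" in table.columns else table
    x_train = sm.add_constant(train[list(model.descriptor_names)].to_numpy(dtype=float),
                              has_constant="add")
    xtx = x_train.T @ x_train
    if np.linalg.matrix_rank(x_train) < x_train.shape[1]:
        raise SingularDesignError("training design matrix is rank deficient")
    xtx_inv = np.linalg.inv(xtx)
    x_all = sm.add_constant(table[list(model.descriptor_names)].to_numpy(dtype=float),
                            has_constant="add")
    leverage = np.einsum("ij,jk,ik->i", x_all, xtx_inv, x_all)
    p = len(model.descriptor_names)
    n_train = len(train)
    h_star = 3.0 * (p + 1) / n_train

    if predicted is not None:
        pred_train = train[predicted].to_numpy(dtype=float)
        pred_all = table[predicted].to_numpy(dtype=float)
    else:
        pred_train = model.predict_frame(train)
        pred_all = model.predict_frame(table)
    resid_train = train[response].to_numpy(dtype=float) - pred_train
    sd = float(np.std(resid_train, ddof=p + 1))
    resid_all = table[response].to_numpy(dtype=float) - pred_all
    std_resid = resid_all / sd
    outside = (leverage > h_star) | (np.abs(std_resid) > 3.0)
    labels = tuple(table["label"]) if "label" in table.columns else tuple(map(str, table.index))
    return ApplicabilityDomain(leverage, h_star, std_resid, outside, labels)


def load_published_dataset(which: str) -> QstrDataset:
    """The published observed/predicted table for one tube family
    ('pristine' or 'carboxyl'), with its printed train/validation split."""
    from .nanotube import load_table

    rows = load_table(which)
    table = pd.DataFrame(rows)
    for col in ("n", "m"):
        table[col] = table[col].astype(int)
    for col in ("observed", "predicted", "residual"):
        table[col] = table[col].astype(float)
    return QstrDataset(table)
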