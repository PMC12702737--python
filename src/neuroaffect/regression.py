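"""Response-surface regression of affect change on EEG and PANAS predictors.

The model for either outcome (Delta_Positive or Delta_Negative) is

    dE = b0 + b1*dTheta + b2*dGamma + b3*AS + b4*(dTheta*AS)
         + b5*dGamma^2 + b6*AS^2 + eps

fitted by ordinary least squares.  Raw predictors span ~1e-12 (gamma power)
to ~1e1 (PANAS points), putting squared columns near 1e-23; the design is
therefore standardized column-wise inside the solver and the coefficients
are mapped back to the original scale exactly.  The stored features remain
unstandardized -- standardization is solver-internal only.  Ridge or other
regularization is deliberately not used, to keep coefficients directly
interpretable.

Uncertainty comes from a percentile bootstrap over participant rows
(1,000 resamples by default), each resample refitted end-to-end with the
design rebuilt from the resampled raw rows.

Usage follows the Model/Results convention::

    model = AffectRegressionModel.from_dataframe(cohort_df, outcome="delta_negative")
    res = model.fit()
    res.params["affective_shift"]
    table = res.bootstrap_ci(n_resamples=1000, seed=42)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from sklearn.model_selection import KFold

from .exceptions import EstimationError, InputError
from .synthetic import COEFFICIENT_NAMES, Cohort

__all__ = [
    "PREDICTORS",
    "DesignMatrix",
    "AffectRegressionModel",
    "AffectRegressionResults",
    "MediationResult",
    "ModelComparison",
    "build_design_matrix",
    "fit_model",
    "bootstrap_coefficients",
    "mediation_indirect",
    "compare_models",
]

PREDICTORS = ("theta_change", "gamma_change", "affective_shift")

#: Term subsets for the multimodal vs unimodal comparison.  Each unimodal
#: model keeps the nonlinear terms built from its own predictors.
MODEL_TERMS: Dict[str, Tuple[str, ...]] = {
    "multimodal": COEFFICIENT_NAMES,
    "eeg_only": ("intercept", "theta_change", "gamma_change", "gamma_sq"),
    "panas_only": ("intercept", "affective_shift", "shift_sq"),
}


def _as_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, Cohort):
        return cohort.to_frame()
    if isinstance(cohort, pd.DataFrame):
        return cohort
    raise InputError(f"expected Cohort or DataFrame, got {type(cohort).__name__}")


@dataclass
class DesignMatrix:
    """Fixed-order design: intercept, dTheta, dGamma, AS, dTheta*AS, dGamma^2, AS^2.

    ``centers``/``scales`` are the per-column standardization parameters the
    solver uses internally; the stored columns are on the raw scale.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        if list(self.frame.columns) != list(COEFFICIENT_NAMES):
            raise InputError("design columns out of order")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def centers(self) -> pd.Series:
        c = self.frame.mean()
        c["intercept"] = 0.0
        return c

    @property
    def scales(self) -> pd.Series:
        s = self.frame.std(ddof=0)
        s["intercept"] = 1.0
        return s


def build_design_matrix(cohort) -> DesignMatrix:
    """Build the 7-column design from the three raw predictors.

    Interaction and quadratic columns are exact products/squares of the raw
    (unstandardized) predictors.
    """
    frame = _as_frame(cohort)
    missing = [c for c in PREDICTORS if c not in frame.columns]
    if missing:
        raise InputError(f"cohort is missing predictor columns: {missing}")
    if frame[list(PREDICTORS)].isna().any().any():
        raise InputError("predictors contain missing values")
    th = frame["theta_change"].to_numpy(dtype=float)
    ga = frame["gamma_change"].to_numpy(dtype=float)
    sh = frame["affective_shift"].to_numpy(dtype=float)
    design = pd.DataFrame({
        "intercept": np.ones_like(th),
        "theta_change": th,
        "gamma_change": ga,
        "affective_shift": sh,
        "theta_x_shift": th * sh,
        "gamma_sq": ga ** 2,
        "shift_sq": sh ** 2,
    })
    return DesignMatrix(frame=design)


def _standardized_ols(X: np.ndarray, y: np.ndarray, columns: Sequence[str]):
    """OLS on column-standardized design; returns original-scale params.

    Returns (beta_original, fitted statsmodels results on the standardized
    design, centers, scales).
    """
    n, p = X.shape
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    centers[0], scales[0] = 0.0, 1.0  # intercept untouched
    degenerate = [columns[j] for j in range(1, p) if scales[j] == 0.0]
    if degenerate:
        raise EstimationError(
            f"rank-deficient design: constant column(s) {degenerate}")
    Z = (X - centers) / scales
    Z[:, 0] = 1.0
    rank = np.linalg.matrix_rank(Z)
    if rank < p:
        _, R, piv = scipy.linalg.qr(Z, mode="economic", pivoting=True)
        d = np.abs(np.diag(R))
        bad = [columns[piv[j]] for j in range(p) if d[j] < d.max() * 1e-10]
        raise EstimationError(f"rank-deficient design; offending column(s): {bad}")
    sres = sm.OLS(y, Z).fit()
    b = sres.params
    beta = b / scales
    beta[0] = b[0] - np.sum(b[1:] * centers[1:] / scales[1:])
    return beta, sres, centers, scales


@dataclass
class AffectRegressionResults:
    """Fitted coefficients on the original predictor scale, plus diagnostics."""

    outcome: str
    params: pd.Series
    resid_sd: float
    rsquared: float
    cond_number: float
    nobs: int
    model: "AffectRegressionModel"
    _std_params: np.ndarray = field(repr=False, default=None)
    _centers: np.ndarray = field(repr=False, default=None)
    _scales: np.ndarray = field(repr=False, default=None)

    def predict(self, design: Optional[DesignMatrix] = None) -> np.ndarray:
        """Predict the outcome from original-scale coefficients."""
        X = (design or self.model.design).values
        return X @ self.params.to_numpy()

    def predict_standardized(self, design: Optional[DesignMatrix] = None) -> np.ndarray:
        """Predict through the internal standardized parameterization."""
        X = (design or self.model.design).values
        Z = (X - self._centers) / self._scales
        Z[:, 0] = 1.0
        return Z @ self._std_params

    def bootstrap_ci(self, n_resamples: int = 1000, level: float = 0.95,
                     seed: int = 0) -> pd.DataFrame:
        """Percentile bootstrap CIs per coefficient (case resampling).

        Each resample rebuilds the design from the resampled raw rows and
        refits end-to-end.  Returns a table indexed by term with columns
        estimate / ci_low / ci_high, plus bookkeeping.
        """
        frame = self.model.data
        n = len(frame)
        rng = np.random.default_rng(seed)
        draws = np.empty((n_resamples, len(COEFFICIENT_NAMES)))
        failures = 0
        for r in range(n_resamples):
            idx = rng.integers(0, n, size=n)
            sub = frame.iloc[idx].reset_index(drop=True)
            try:
                res = AffectRegressionModel.from_dataframe(sub, self.outcome).fit()
                draws[r] = res.params.to_numpy()
            except Exception:
                draws[r] = np.nan
                failures += 1
        if failures > 0.01 * n_resamples:
            raise EstimationError(
                f"refit failed on {failures}/{n_resamples} resamples (> 1%)")
        alpha = 1.0 - level
        lo, hi = np.nanquantile(draws, [alpha / 2, 1 - alpha / 2], axis=0)
        out = pd.DataFrame({
            "estimate": self.params,
            "ci_low": pd.Series(lo, index=COEFFICIENT_NAMES),
            "ci_high": pd.Series(hi, index=COEFFICIENT_NAMES),
        })
        out.attrs.update(level=level, n_resamples=n_resamples, seed=seed,
                         n_failures=failures, method="percentile")
        return out

    def summary(self) -> str:
        lines = [
            f"Affect response-surface regression: outcome = {self.outcome}",
            f"n = {self.nobs}, R^2 = {self.rsquared:.4f}, "
            f"resid sd = {self.resid_sd:.4g}, cond = {self.cond_number:.3g}",
            "-" * 58,
            f"{'term':<18}{'coef (original scale)':>24}",
        ]
        for name, value in self.params.items():
            lines.append(f"{name:<18}{value:>24.6g}")
        return "\n".join(lines)


class AffectRegressionModel:
    """OLS response-surface model of one affect-change outcome.

    Parameters
    ----------
    data : cohort DataFrame (or Cohort) with the three predictor columns
        and the outcome column.
    outcome : "delta_positive" or "delta_negative".
    """

    def __init__(self, data, outcome: str = "delta_negative"):
        frame = _as_frame(data)
        if outcome not in ("delta_positive", "delta_negative"):
            raise InputError(f"unknown outcome {outcome!r}")
        if outcome not in frame.columns:
            raise InputError(f"cohort is missing outcome column {outcome!r}")
        self.data = frame.reset_index(drop=True)
        self.outcome = outcome
        self.design = build_design_matrix(self.data)
        self.endog = self.data[outcome].to_numpy(dtype=float)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       outcome: str = "delta_negative") -> "AffectRegressionModel":
        return cls(frame, outcome=outcome)

    def fit(self) -> AffectRegressionResults:
        X = self.design.values
        y = self.endog
        n, p = X.shape
        if n < p + 1:
            raise InputError(f"need at least {p + 1} rows to fit {p} terms, got {n}")
        if not np.all(np.isfinite(y)):
            raise InputError("outcome contains non-finite values")
        beta, sres, centers, scales = _standardized_ols(
            X, y, list(COEFFICIENT_NAMES))
        resid = y - X @ beta
        dof = max(n - p, 1)
        sst = float(np.sum((y - y.mean()) ** 2))
        ssr = float(resid @ resid)
        rsq = 1.0 - ssr / sst if sst > 0 else (1.0 if ssr < 1e-20 else 0.0)
        return AffectRegressionResults(
            outcome=self.outcome,
            params=pd.Series(beta, index=COEFFICIENT_NAMES),
            resid_sd=float(np.sqrt(ssr / dof)),
            rsquared=float(rsq),
            cond_number=float(sres.condition_number),
            nobs=n,
            model=self,
            _std_params=np.asarray(sres.params),
            _centers=centers,
            _scales=scales,
        )


def fit_model(design: DesignMatrix, outcome: np.ndarray,
              outcome_name: str = "delta_negative") -> AffectRegressionResults:
    """Functional fit interface: a prebuilt design plus an outcome vector."""
    frame = design.frame[list(PREDICTORS)].copy()
    frame[outcome_name] = np.asarray(outcome, dtype=float)
    return AffectRegressionModel(frame, outcome=outcome_name).fit()


def bootstrap_coefficients(cohort, outcome: str, n_resamples: int = 1000,
                           level: float = 0.95, seed: int = 0) -> pd.DataFrame:
    """Fit and bootstrap in one call; see Results.bootstrap_ci."""
    res = AffectRegressionModel(_as_frame(cohort), outcome=outcome).fit()
    return res.bootstrap_ci(n_resamples=n_resamples, level=level, seed=seed)


@dataclass(frozen=True)
class MediationResult:
    """Product-of-coefficients mediation with percentile bootstrap CI."""

    predictor: str
    mediator: str
    outcome: str
    path_a: float
    path_b: float
    direct: float
    indirect: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int


def _simple_paths(frame: pd.DataFrame, predictor: str, mediator: str,
                  outcome: str) -> Tuple[float, float, float]:
    x = frame[predictor].to_numpy(dtype=float)
    m = frame[mediator].to_numpy(dtype=float)
    y = frame[outcome].to_numpy(dtype=float)
    if np.std(m) == 0:
        raise EstimationError(f"mediator {mediator!r} has zero variance")
    if np.std(x) == 0:
        raise EstimationError(f"predictor {predictor!r} has zero variance")
    # path a: m ~ x
    a = np.cov(x, m, ddof=0)[0, 1] / np.var(x)
    # paths b (mediator) and c' (direct): y ~ m + x, standardized solve
    X = np.column_stack([np.ones_like(x), m, x])
    beta, _, _, _ = _standardized_ols(X, y, ["intercept", mediator, predictor])
    return float(a), float(beta[1]), float(beta[2])


def mediation_indirect(cohort, predictor: str, outcome: str,
                       mediator: str = "affective_shift", n_boot: int = 1000,
                       level: float = 0.95, seed: int = 0) -> MediationResult:
    """Exploratory mediation: indirect effect a*b with bootstrap CI.

    path a regresses the mediator on the predictor; path b is the mediator
    coefficient in the outcome-on-(mediator + predictor) regression; the
    indirect effect is a*b, with a percentile CI over case resamples.
    """
    frame = _as_frame(cohort)
    for col in (predictor, mediator, outcome):
        if col not in frame.columns:
            raise InputError(f"cohort is missing column {col!r}")
    a, b, direct = _simple_paths(frame, predictor, mediator, outcome)
    rng = np.random.default_rng(seed)
    n = len(frame)
    draws = np.empty(n_boot)
    failures = 0
    for r in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            ar, br, _ = _simple_paths(frame.iloc[idx], predictor, mediator, outcome)
            draws[r] = ar * br
        except Exception:
            draws[r] = np.nan
            failures += 1
    if failures > 0.01 * n_boot:
        raise EstimationError(
            f"mediation refit failed on {failures}/{n_boot} resamples (> 1%)")
    alpha = 1.0 - level
    lo, hi = np.nanquantile(draws, [alpha / 2, 1 - alpha / 2])
    return MediationResult(predictor=predictor, mediator=mediator,
                           outcome=outcome, path_a=a, path_b=b, direct=direct,
                           indirect=a * b, ci_low=float(lo), ci_high=float(hi),
                           n_resamples=n_boot, seed=seed)


@dataclass(frozen=True)
class ModelComparison:
    """Repeated k-fold CV comparison of multimodal vs unimodal predictors."""

    outcome: str
    rmse_mean: Dict[str, float]
    r2_mean: Dict[str, float]
    in_sample_r2: Dict[str, float]
    delta_r2: float
    folds: int
    repeats: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rmse_mean": pd.Series(self.rmse_mean),
            "r2_mean": pd.Series(self.r2_mean),
            "in_sample_r2": pd.Series(self.in_sample_r2),
        })


def _fit_predict_terms(design: np.ndarray, cols: Sequence[int], y: np.ndarray,
                       train: np.ndarray, test: np.ndarray,
                       names: Sequence[str]) -> np.ndarray:
    Xtr, Xte = design[np.ix_(train, cols)], design[np.ix_(test, cols)]
    beta, _, _, _ = _standardized_ols(Xtr, y[train], [names[c] for c in cols])
    return Xte @ beta


def compare_models(cohort, outcome: str = "delta_positive", folds: int = 5,
                   repeats: int = 20, seed: int = 0) -> ModelComparison:
    """Mean out-of-fold RMSE and R^2 for multimodal / eeg_only / panas_only.

    Fold assignments are shared across the three models within each repeat;
    out-of-fold predictions are pooled per repeat and RMSE/R^2 averaged over
    repeats.
    """
    frame = _as_frame(cohort)
    n = len(frame)
    if n < folds:
        raise InputError(f"n = {n} smaller than folds = {folds}")
    design = build_design_matrix(frame).values
    y = frame[outcome].to_numpy(dtype=float)
    names = list(COEFFICIENT_NAMES)
    col_idx = {m: [names.index(t) for t in terms]
               for m, terms in MODEL_TERMS.items()}

    rmse = {m: [] for m in MODEL_TERMS}
    r2 = {m: [] for m in MODEL_TERMS}
    for rep in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=(seed + 7919 * rep) % (2 ** 31))
        pred = {m: np.empty(n) for m in MODEL_TERMS}
        for train, test in kf.split(np.arange(n)):
            for m, cols in col_idx.items():
                pred[m][test] = _fit_predict_terms(design, cols, y, train,
                                                   test, names)
        sst = np.sum((y - y.mean()) ** 2)
        for m in MODEL_TERMS:
            err = y - pred[m]
            rmse[m].append(float(np.sqrt(np.mean(err ** 2))))
            r2[m].append(float(1.0 - np.sum(err ** 2) / sst))

    in_sample = {}
    for m, cols in col_idx.items():
        full = np.arange(n)
        yhat = _fit_predict_terms(design, cols, y, full, full, names)
        sst = np.sum((y - y.mean()) ** 2)
        in_sample[m] = float(1.0 - np.sum((y - yhat) ** 2) / sst)

    r2_mean = {m: float(np.mean(v)) for m, v in r2.items()}
    return ModelComparison(
        outcome=outcome,
        rmse_mean={m: float(np.mean(v)) for m, v in rmse.items()},
        r2_mean=r2_mean,
        in_sample_r2=in_sample,
        delta_r2=r2_mean["multimodal"] - r2_mean["panas_only"],
        folds=folds, repeats=repeats, seed=seed,
    )
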