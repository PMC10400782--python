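"""Standardized linear models with exhaustive subset selection and LOO.

Features and target are standardized (zero mean, unit standard deviation;
population convention, configurable) so the model is ``y = sum_j w_j X_j``
with no intercept and unit-less, directly comparable weights.  Model quality
is the coefficient of determination

    R^2 = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar)^2,

and generalization is assessed by leave-one-out cross-validation: each row
is held out in turn, the standardization and fit are redone on the remaining
rows (no leakage), and the held-out row is predicted on the original scale.
MSE_LOO is the mean of the per-row squared errors and R^2_LOO applies the
R^2 formula to the LOO predictions.  Subset selection enumerates every
non-empty feature combination; the default winner minimizes MSE_LOO (in-
sample R^2 is monotone in subset size, so it cannot select).  A leave-k-out
diagnostic checks that prediction errors scale like 1/sqrt(N) as rows are
withheld.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VOID_FEATURES = ["V", "S", "L", "nbr", "dmin", "dmax", "dave", "dtotal"]
CHEM_FEATURES = ["MM", "vdW", "#C", "#Polar", "#Pos", "#Neg",
                 "#5-ring", "#6-ring"]


class DegenerateColumnError(ValueError):
    """A column to standardize has zero standard deviation."""


class RankDeficiencyError(ValueError):
    """The design matrix has collinear columns."""


@dataclass
class StandardScale:
    """Per-column mean and standard deviation of a standardization."""

    mean: pd.Series
    sd: pd.Series
    ddof: int = 0

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return (df[self.mean.index] - self.mean) / self.sd

    def inverse(self, df_std: pd.DataFrame) -> pd.DataFrame:
        return df_std * self.sd + self.mean


@dataclass
class RegressionResult:
    """Winner of a subset search with its fit and LOO diagnostics."""

    features: list[str]
    weights: np.ndarray  # standardized scale
    intercept: float  # identically 0 after standardization
    r2: float
    r2_loo: float
    mse_loo: float
    loo_predictions: np.ndarray  # original scale, one per row
    target: str = ""
    leave_k_ratios: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "features": list(self.features),
            "weights": np.asarray(self.weights).tolist(),
            "intercept": self.intercept,
            "r2": self.r2,
            "r2_loo": self.r2_loo,
            "mse_loo": self.mse_loo,
            "loo_predictions": np.asarray(self.loo_predictions).tolist(),
            "leave_k_ratios": {str(k): v for k, v in
                               self.leave_k_ratios.items()},
        }


def standardize(df: pd.DataFrame, columns: list[str] | None = None,
                ddof: int = 0) -> tuple[pd.DataFrame, StandardScale]:
    """Shift columns to zero mean and scale to unit standard deviation.

    ``ddof=0`` (population) by default.  A constant column cannot be
    standardized and raises :class:`DegenerateColumnError` naming it.
    """
    if columns is None:
        columns = [c for c in df.columns
                   if pd.api.types.is_numeric_dtype(df[c])]
    sub = df[columns].astype(float)
    sd = sub.std(ddof=ddof)
    bad = sd.index[sd <= 0].tolist()
    if bad:
        raise DegenerateColumnError(f"constant column(s): {bad}")
    mean = sub.mean()
    scale = StandardScale(mean=mean, sd=sd, ddof=ddof)
    return scale.transform(sub), scale


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a minimal culprit set via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        dropped = [names[p] for p in piv[diag <= tol]] or \
            [names[p] for p in piv[rank:]]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]}; "
            f"collinear column(s): {dropped}")


def fit_linear(X, y, feature_names: list[str] | None = None
               ) -> tuple[np.ndarray, float]:
    """Least-squares weights of ``y = X w`` (standardized, no intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows than features: n={n}, p={p}")
    names = feature_names or [f"x{j}" for j in range(p)]
    _check_rank(X, names)
    w, *_ = np.linalg.lstsq(X, y, rcond=None)
    return w, r_squared(y, X @ w)


def r_squared(y, y_hat) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (may be negative)."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if len(y) != len(y_hat) or len(y) < 2:
        raise ValueError("y and y_hat must share a length of at least 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y is constant; R^2 undefined")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def loo_cv(X, y, ddof: int = 0, refit_standardization: bool = True
           ) -> tuple[float, float, np.ndarray]:
    """Leave-one-out CV on raw (unstandardized) features and target.

    Per fold the standardization is recomputed on the training rows and the
    held-out row is predicted on the original scale.  Returns
    ``(MSE_LOO, R^2_LOO, predictions)``.  ``refit_standardization=False``
    standardizes once globally (leaky; for comparison only).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < p + 3:
        raise ValueError(f"need n >= p + 3 for LOO, got n={n}, p={p}")
    preds = np.empty(n)
    if not refit_standardization:
        xm, xs = X.mean(0), X.std(0, ddof=ddof)
        ym, ys = y.mean(), y.std(ddof=ddof)
    for k in range(n):
        tr = np.ones(n, dtype=bool)
        tr[k] = False
        Xtr, ytr = X[tr], y[tr]
        if refit_standardization:
            xm, xs = Xtr.mean(0), Xtr.std(0, ddof=ddof)
            ym, ys = ytr.mean(), ytr.std(ddof=ddof)
        if np.any(xs <= 0) or ys <= 0:
            raise RankDeficiencyError(f"fold {k}: constant column in training rows")
        Xs = (Xtr - xm) / xs
        ys_tr = (ytr - ym) / ys
        if np.linalg.matrix_rank(Xs) < p:
            raise RankDeficiencyError(f"fold {k}: rank-deficient training design")
        w, *_ = np.linalg.lstsq(Xs, ys_tr, rcond=None)
        preds[k] = ym + ys * (((X[k] - xm) / xs) @ w)
    mse = float(np.mean((y - preds) ** 2))
    return mse, r_squared(y, preds), preds


def _fit_full(X, y, ddof: int = 0):
    """Standardize, fit, and return (weights, R^2) on the full data."""
    xm, xs = X.mean(0), X.std(0, ddof=ddof)
    ym, ys = y.mean(), y.std(ddof=ddof)
    if np.any(xs <= 0):
        raise DegenerateColumnError("constant feature column")
    if ys <= 0:
        raise DegenerateColumnError("constant target")
    Xs = (X - xm) / xs
    ysd = (y - ym) / ys
    w, *_ = np.linalg.lstsq(Xs, ysd, rcond=None)
    return w, r_squared(ysd, Xs @ w)


def best_subset(
    table: pd.DataFrame,
    features: list[str],
    target: str,
    criterion: str = "loo_mse",
    ddof: int = 0,
    max_features: int = 12,
) -> RegressionResult:
    """Exhaustive search over all non-empty feature subsets.

    ``criterion`` is ``"loo_mse"`` (default; minimize MSE_LOO) or ``"r2"``
    (maximize in-sample R^2 — monotone in subset size, so the full set
    always wins; a warning says so).  Deterministic tie-break: fewer
    features, then lexicographic feature order.
    """
    if criterion not in ("loo_mse", "r2"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if len(features) > max_features:
        raise ValueError(
            f"{len(features)} candidate features exceed the exhaustive "
            f"search bound {max_features}")
    if criterion == "r2":
        warnings.warn("in-sample R^2 never decreases when a feature is "
                      "added; the full feature set always wins",
                      stacklevel=2)
    y = table[target].to_numpy(dtype=float)
    best_key = None
    best: tuple | None = None
    for size in range(1, len(features) + 1):
        for combo in itertools.combinations(sorted(features), size):
            X = table[list(combo)].to_numpy(dtype=float)
            try:
                mse, r2l, preds = loo_cv(X, y, ddof=ddof)
            except RankDeficiencyError:
                continue
            w, r2 = _fit_full(X, y, ddof=ddof)
            score = mse if criterion == "loo_mse" else -r2
            key = (score, size, combo)
            if best_key is None or key < best_key:
                best_key = key
                best = (combo, w, r2, r2l, mse, preds)
    if best is None:
        raise RankDeficiencyError("every candidate subset was rank-deficient")
    combo, w, r2, r2l, mse, preds = best
    return RegressionResult(
        features=list(combo), weights=w, intercept=0.0, r2=r2,
        r2_loo=r2l, mse_loo=mse, loo_predictions=preds, target=target,
    )


def leave_k_out_ratio(
    X,
    y,
    k: int,
    n_repeats: int = 200,
    seed: int = 0,
    ddof: int = 0,
) -> dict[int, float]:
    """Error-scaling diagnostic for leave-i-out, i = 1..k.

    ``Error_i`` is the root-mean-squared prediction error over all (or, past
    ``n_repeats``, a seeded sample of) leave-i-out folds.  Returns the ratio
    ``(Error_i * sqrt(N - i)) / (Error_1 * sqrt(N - 1))`` for each i; if the
    fit is exact (Error_1 = 0) the ratio is 1 by convention.  Values near 1
    confirm the expected 1/sqrt(N) error growth.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if k < 1 or k > 3:
        raise ValueError("k must be 1, 2 or 3")
    if n <= p + k + 1:
        raise ValueError(f"need n > p + k + 1, got n={n}, p={p}, k={k}")
    rng = np.random.default_rng(seed)

    def error_i(i: int) -> float:
        from math import comb

        if comb(n, i) <= n_repeats:
            folds = list(itertools.combinations(range(n), i))
        else:
            folds = [tuple(sorted(rng.choice(n, size=i, replace=False)))
                     for _ in range(n_repeats)]
        sq = []
        for held in folds:
            tr = np.ones(n, dtype=bool)
            tr[list(held)] = False
            Xtr, ytr = X[tr], y[tr]
            xm, xs = Xtr.mean(0), Xtr.std(0, ddof=ddof)
            ym, ys = ytr.mean(), ytr.std(ddof=ddof)
            if np.any(xs <= 0) or ys <= 0:
                continue
            w, *_ = np.linalg.lstsq((Xtr - xm) / xs, (ytr - ym) / ys,
                                    rcond=None)
            for h in held:
                pred = ym + ys * (((X[h] - xm) / xs) @ w)
                sq.append((y[h] - pred) ** 2)
        return float(np.sqrt(np.mean(sq)))

    e1 = error_i(1)
    exact = e1 <= 1e-8 * max(float(np.std(y)), 1e-30)
    out = {1: 1.0}
    for i in range(2, k + 1):
        if exact:
            out[i] = 1.0  # exact fit: 0/0 guarded by convention
        else:
            out[i] = error_i(i) * np.sqrt(n - i) / (e1 * np.sqrt(n - 1))
    return out


def fit_chemistry_to_void(
    chem: pd.DataFrame,
    void_vars: pd.DataFrame,
    chem_features: list[str] | None = None,
    void_columns: list[str] | None = None,
    criterion: str = "loo_mse",
    ddof: int = 0,
) -> dict[str, RegressionResult]:
    """Best-subset models predicting each void descriptor from chemistry.

    Both tables must be indexed by the same entities (e.g. amino-acid
    names).  Returns one :class:`RegressionResult` per void variable.
    """
    chem_features = chem_features or [c for c in CHEM_FEATURES
                                      if c in chem.columns]
    void_columns = void_columns or [c for c in VOID_FEATURES
                                    if c in void_vars.columns]
    missing = set(chem.index).symmetric_difference(void_vars.index)
    if missing:
        raise ValueError(f"row mismatch between tables: {sorted(missing)}")
    merged = chem.join(void_vars, how="inner")
    out = {}
    for target in void_columns:
        out[target] = best_subset(merged, chem_features, target,
                                  criterion=criterion, ddof=ddof)
    return out


def coefficients_table(results: dict[str, RegressionResult],
                       features: list[str] | None = None) -> pd.DataFrame:
    """Tidy table of standardized coefficients, one row per target."""
    feats = features or sorted({f for r in results.values()
                                for f in r.features})
    rows = {}
    for target, res in results.items():
        row = dict.fromkeys(feats, 0.0)
        row.update(dict(zip(res.features, res.weights)))
        row["r2"] = res.r2
        row["r2_loo"] = res.r2_loo
        rows[target] = row
    df = pd.DataFrame(rows).T
    df.index.name = "target"
    return df
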