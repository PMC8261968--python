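"""Partial least squares regression with multivariate-pattern inference.

PLS decomposes the predictors into latent components that maximize covariance
with the response, which makes it the standard tool for outcome regression on
the highly collinear intensity-spectrum variables. On top of the fit this
module provides:

* Monte-Carlo cross-validation (repeated random holdout) of the explained
  variance Q² = 1 − PRESS/TSS, with standardization re-estimated inside each
  training split;
* backwards complexity selection with a half-SD rule on shared splits;
* permutation tests of model significance;
* target projection — collapsing the components onto the single predictive
  direction w ∝ b — and the selectivity ratio, the per-predictor signed
  explained variance of the response;
* percentile-bootstrap confidence intervals for the selectivity ratio.

The deterministic fitting algorithm is SIMPLS; it satisfies the usual PLS1
oracle properties (equals univariate correlation at p = 1, equals ordinary
least squares at full rank).

The module is organised statsmodels-style: build a :class:`PLS` model from
data, call :meth:`PLS.fit`, and work with the returned :class:`PLSResults`.
The underlying operations (:func:`fit_pls`, :func:`cv_r2`,
:func:`select_components`, :func:`permutation_test`, :func:`target_projection`,
:func:`selectivity_ratio`, :func:`bootstrap_sr`) are plain functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PLS",
    "PLSResults",
    "PLSModel",
    "CVResult",
    "PermutationResult",
    "SRProfile",
    "fit_pls",
    "cv_r2",
    "select_components",
    "permutation_test",
    "target_projection",
    "selectivity_ratio",
    "bootstrap_sr",
]

_RANK_TOL = 1e-12


class RankError(np.linalg.LinAlgError):
    def __init__(self, requested: int, achieved: int):
        self.requested, self.achieved = requested, achieved
        super().__init__(
            f"requested {requested} components but predictor rank supports "
            f"only {achieved}"
        )


# ---------------------------------------------------------------------------
# core SIMPLS

def _simpls(X: np.ndarray, y: np.ndarray, a_max: int, strict: bool = True):
    """SIMPLS for a single response on centered data.

    Returns (W, T, P, q, achieved). Scores T have orthonormal columns;
    the regression vector truncated to ``a`` components is ``W[:, :a] @ q[:a]``.
    With ``strict`` a rank shortfall raises :class:`RankError`; otherwise the
    achieved number of components is returned.
    """
    n, p = X.shape
    W = np.zeros((p, a_max))
    T = np.zeros((n, a_max))
    P = np.zeros((p, a_max))
    q = np.zeros(a_max)
    V = np.zeros((p, a_max))  # orthonormal basis of x-loadings, for deflation
    s = X.T @ y
    scale = max(float(np.linalg.norm(X, ord="fro")), 1.0)
    achieved = 0
    for a in range(a_max):
        w = s.copy()
        t = X @ w
        normt = np.linalg.norm(t)
        if normt <= _RANK_TOL * scale * max(np.linalg.norm(w), _RANK_TOL):
            break
        t /= normt
        w /= normt
        pa = X.T @ t
        qa = float(y @ t)
        v = pa - V[:, :a] @ (V[:, :a].T @ pa)
        nv = np.linalg.norm(v)
        if nv <= _RANK_TOL * scale:
            break
        v /= nv
        s = s - v * (v @ s)
        W[:, a], T[:, a], P[:, a], q[a], V[:, a] = w, t, pa, qa, v
        achieved = a + 1
    if achieved < a_max and strict:
        raise RankError(a_max, achieved)
    return W[:, :achieved], T[:, :achieved], P[:, :achieved], q[:achieved], achieved


def _simpls_coef(X: np.ndarray, y: np.ndarray, a: int) -> np.ndarray:
    W, _, _, q, ach = _simpls(X, y, a, strict=False)
    return W[:, :ach] @ q[:ach]


@dataclass
class PLSModel:
    """Fitted PLS decomposition on standardized data."""

    n_components: int
    weights: np.ndarray      # p x A, T = X @ W
    scores: np.ndarray       # n x A, orthonormal columns
    x_loadings: np.ndarray   # p x A
    y_loadings: np.ndarray   # A
    coef: np.ndarray         # p, regression vector b
    training_r2: float
    cv_r2: float | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.coef


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a PLS1 model on standardized inputs.

    ``X`` columns and ``y`` are expected centered (and typically scaled);
    components maximize covariance with ``y`` under orthogonal scores.
    Raises :class:`RankError` (naming the achievable rank) if ``n_components``
    exceeds the predictor rank.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y must have matching rows")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    W, T, P, q, _ = _simpls(X, y, n_components, strict=True)
    b = W @ q
    yhat = X @ b
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / tss if tss > 0 else np.nan
    return PLSModel(n_components, W, T, P, q, b, r2)


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation

def _draw_split(rng, n: int, holdout_fraction: float, X: np.ndarray,
                max_retry: int = 20):
    """Random holdout split with in-split predictor standardization.

    Splits whose training block has a zero-variance predictor are redrawn.
    """
    n_te = max(1, int(round(holdout_fraction * n)))
    if n_te >= n - 1:
        raise ValueError("holdout leaves too few training rows")
    for _ in range(max_retry):
        perm = rng.permutation(n)
        te, tr = perm[:n_te], perm[n_te:]
        Xtr = X[tr]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            logger.debug("degenerate split (zero-variance predictor) redrawn")
            continue
        Xtr_z = (Xtr - mu) / sd
        Xte_z = (X[te] - mu) / sd
        return tr, te, Xtr_z, Xte_z
    raise RuntimeError("could not draw a non-degenerate split")


def _prepare_splits(X: np.ndarray, n_reps: int, holdout_fraction: float, rng):
    n = X.shape[0]
    return [_draw_split(rng, n, holdout_fraction, X) for _ in range(n_reps)]


def _press_tss(splits, y: np.ndarray, a_grid: np.ndarray):
    """Pooled PRESS/TSS and per-repetition holdout MSE for each grid value.

    A single SIMPLS pass at max(a_grid) per split yields predictions for every
    truncation, so all candidate complexities share the same Monte-Carlo
    splits (paired comparisons for the half-SD rule).
    """
    a_max = int(a_grid.max())
    press = np.zeros(a_grid.size)
    tss = 0.0
    mse = np.zeros((len(splits), a_grid.size))
    for r, (tr, te, Xtr_z, Xte_z) in enumerate(splits):
        ytr = y[tr]
        my = ytr.mean()
        sy = ytr.std(ddof=1)
        if sy <= 0:
            mse[r] = np.nan
            continue
        yz = (ytr - my) / sy
        W, _, _, q, ach = _simpls(Xtr_z, yz, a_max, strict=False)
        # cumulative regression vectors: b_a = W[:, :a] @ q[:a]
        B = np.cumsum(W * q[np.newaxis, :], axis=1) if ach else np.zeros((Xtr_z.shape[1], 1))
        pred_z = Xte_z @ B  # n_te x ach
        resid0 = y[te] - my
        tss += float(resid0 @ resid0)
        for k, a in enumerate(a_grid):
            col = min(int(a), ach) - 1
            pred = my + sy * pred_z[:, col] if col >= 0 else np.full(te.size, my)
            e = y[te] - pred
            sq = float(e @ e)
            press[k] += sq
            mse[r, k] = sq / te.size
    return press, tss, mse


def cv_r2(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_reps: int = 1000,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    splits=None,
) -> float:
    """Monte-Carlo cross-validated explained variance Q² = 1 − PRESS/TSS.

    Per repetition a random ``holdout_fraction`` of subjects is held out, the
    model (including predictor/response standardization) is estimated on the
    remainder, and squared prediction errors are pooled over repetitions.
    TSS is taken against the training-mean prediction, so Q² ≤ 0 means no
    better than the mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 20:
        raise ValueError("need n >= 20 for Monte-Carlo cross-validation")
    if splits is None:
        splits = _prepare_splits(X, n_reps, holdout_fraction, np.random.default_rng(seed))
    press, tss, _ = _press_tss(splits, y, np.asarray([n_components]))
    return 1.0 - press[0] / tss


@dataclass
class CVResult:
    """Cross-validation curve over candidate complexities."""

    a_grid: np.ndarray
    mean_error: np.ndarray   # mean holdout MSE per candidate A
    sd_error: np.ndarray     # SD of holdout MSE across repetitions
    q2: np.ndarray           # pooled cross-validated R^2 per candidate A
    selected_a: int
    n_reps: int

    @property
    def selected_q2(self) -> float:
        return float(self.q2[np.flatnonzero(self.a_grid == self.selected_a)[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_components": self.a_grid,
            "mean_holdout_mse": self.mean_error,
            "sd_holdout_mse": self.sd_error,
            "cv_r2": self.q2,
        })


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    a_max: int = 10,
    n_reps: int = 1000,
    cutoff_sd: float = 0.5,
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> CVResult:
    """Choose model complexity by Monte-Carlo CV with a half-SD backwards rule.

    All candidate complexities 1..a_max are evaluated on the same random
    splits. Starting from the complexity with minimum mean holdout error, the
    procedure steps backwards while the simpler model's mean error stays
    within ``cutoff_sd`` across-repetition SDs of the best, and returns the
    smallest such complexity — i.e. extra components must improve prediction
    by a meaningful margin to be kept.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if a_max < 1:
        raise ValueError("a_max must be >= 1")
    a_max = min(a_max, X.shape[1], X.shape[0] - max(2, int(round(holdout_fraction * X.shape[0]))) - 1)
    a_max = max(a_max, 1)
    rng = np.random.default_rng(seed)
    splits = _prepare_splits(X, n_reps, holdout_fraction, rng)
    a_grid = np.arange(1, a_max + 1)
    press, tss, mse = _press_tss(splits, y, a_grid)
    mean_err = np.nanmean(mse, axis=0)
    sd_err = np.nanstd(mse, axis=0, ddof=1)
    q2 = 1.0 - press / tss

    best = int(np.argmin(mean_err))
    threshold = mean_err[best] + cutoff_sd * sd_err[best]
    a_sel = best
    while a_sel > 0 and mean_err[a_sel - 1] <= threshold:
        a_sel -= 1
    return CVResult(a_grid, mean_err, sd_err, q2, int(a_grid[a_sel]), n_reps)


# ---------------------------------------------------------------------------
# permutation test

@dataclass
class PermutationResult:
    p_value: float
    observed: float
    null_values: np.ndarray
    n_perm: int

    def summary(self) -> str:
        q = np.quantile(self.null_values, [0.5, 0.95])
        return (
            f"observed Q2 = {self.observed:.4f}; permutation null median "
            f"{q[0]:.4f}, 95th pct {q[1]:.4f}; p = {self.p_value:.4g} "
            f"({self.n_perm} permutations)"
        )


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_perm: int = 10_000,
    seed: int = 0,
    n_reps: int = 100,
    holdout_fraction: float = 0.2,
) -> PermutationResult:
    """Permutation test of model significance on the cross-validated R².

    The response is permuted, the cross-validated explained variance is
    recomputed per permutation (with ``n_reps`` Monte-Carlo repetitions,
    shared splits), and ``p = (1 + #{null ≥ observed}) / (1 + n_perm)``.
    Model complexity stays fixed at the value selected on the unpermuted
    data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    splits = _prepare_splits(X, n_reps, holdout_fraction, rng)
    a = np.asarray([n_components])
    press, tss, _ = _press_tss(splits, y, a)
    observed = 1.0 - press[0] / tss
    null = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        press, tss, _ = _press_tss(splits, yp, a)
        null[b] = 1.0 - press[0] / tss
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
    return PermutationResult(p, observed, null, n_perm)


# ---------------------------------------------------------------------------
# target projection and selectivity ratio

def target_projection(model: PLSModel, X: np.ndarray):
    """Collapse a fitted model onto its single predictive direction.

    ``w_TP = b/‖b‖``; scores ``t_TP = X·w_TP``; loadings
    ``p_TP = Xᵀ·t_TP / (t_TPᵀ·t_TP)``. The rank-1 matrix t_TP·p_TPᵀ is the
    part of X predictive of the response.
    """
    b = model.coef
    nb = np.linalg.norm(b)
    if nb <= 0:
        raise ValueError("regression vector is zero; target projection undefined")
    w_tp = b / nb
    t_tp = np.asarray(X) @ w_tp
    tt = float(t_tp @ t_tp)
    if tt <= 0:
        raise ValueError("degenerate target-projected scores")
    p_tp = np.asarray(X).T @ t_tp / tt
    return t_tp, p_tp


@dataclass
class SRProfile:
    """Signed per-predictor explained variance of the response (% scale optional).

    ``sr[j]`` is the share of the predictor's variance captured by the
    target-projected component, scaled by the model's overall explained
    variance and signed by the regression coefficient — i.e. the predictor's
    specific explained variance of the response.
    """

    names: list
    sr: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    overall_r2: float = np.nan

    @property
    def peak_index(self) -> int:
        return int(np.nanargmax(np.abs(self.sr)))

    @property
    def peak_value(self) -> float:
        return float(self.sr[self.peak_index])

    def to_frame(self) -> pd.DataFrame:
        d = {"predictor": self.names, "sr": self.sr}
        if self.ci_low is not None:
            d["ci_low"] = self.ci_low
            d["ci_high"] = self.ci_high
        return pd.DataFrame(d)


def selectivity_ratio(
    model: PLSModel,
    X: np.ndarray,
    overall_r2: float,
    names=None,
) -> SRProfile:
    """Per-predictor signed explained variance from the target projection.

    For predictor j, the explained variance is ``v_j = (t_TPᵀt_TP)·p_TP,j²``
    and the total is ``s_j = ‖x_j‖²``; the ratio is scaled by the model's
    overall explained variance and signed by ``b_j``. ``|sr_j|`` can never
    exceed ``overall_r2``.
    """
    X = np.asarray(X, dtype=float)
    t_tp, p_tp = target_projection(model, X)
    tt = float(t_tp @ t_tp)
    total = np.sum(X**2, axis=0)
    ok = total > 0
    ratio = np.full(X.shape[1], np.nan)
    ratio[ok] = tt * p_tp[ok] ** 2 / total[ok]
    if np.any(~ok):
        logger.warning("zero-variance predictors flagged: %s",
                       list(np.flatnonzero(~ok)))
    sr = np.sign(model.coef) * ratio * overall_r2
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return SRProfile(list(names), sr, overall_r2=overall_r2)


def bootstrap_sr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    overall_r2: float,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
    names=None,
) -> SRProfile:
    """Percentile-bootstrap confidence intervals for the selectivity ratio.

    Subjects are resampled with replacement; the PLS model is refitted at
    fixed complexity on each resample (re-standardized) and the selectivity
    ratio recomputed. The overall explained variance enters as the fixed
    point-estimate scale — the bootstrap propagates uncertainty of the
    per-predictor variance ratios and coefficient signs.

    Resamples with a zero-variance predictor are redrawn (logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(seed)
    model = fit_pls(_z(X), _z(y), n_components)
    point = selectivity_ratio(model, _z(X), overall_r2, names=names)
    boot = np.empty((n_boot, p))
    b = 0
    redraws = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        Xb, yb = X[idx], y[idx]
        if np.any(Xb.std(axis=0) <= 0) or yb.std() <= 0:
            redraws += 1
            if redraws > 10 * n_boot:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        Xz, yz = _z(Xb), _z(yb)
        Wb, _, _, qb, ach = _simpls(Xz, yz, n_components, strict=False)
        coef = Wb[:, :ach] @ qb[:ach]
        m = PLSModel(ach, Wb, None, None, qb, coef, np.nan)
        try:
            boot[b] = selectivity_ratio(m, Xz, overall_r2).sr
        except ValueError:
            redraws += 1
            continue
        b += 1
    if redraws:
        logger.info("bootstrap_sr: %d degenerate resamples redrawn", redraws)
    alpha = (1.0 - ci_level) / 2.0
    lo = np.quantile(boot, alpha, axis=0)
    hi = np.quantile(boot, 1.0 - alpha, axis=0)
    return SRProfile(point.names, point.sr, lo, hi, overall_r2)


def _z(a: np.ndarray, ddof: int = 1) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    sd = a.std(axis=0, ddof=ddof)
    return (a - a.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# model / results facade

class PLS:
    """PLS1 regression model, statsmodels-style.

    Parameters
    ----------
    endog : (n,) response
    exog : (n, p) predictors (a DataFrame keeps column names)
    standardize : z-score predictors and response before fitting (the final
        fit; cross-validation always re-standardizes inside training splits).
    """

    def __init__(self, endog, exog, exog_names=None, standardize: bool = True):
        if isinstance(exog, pd.DataFrame):
            exog_names = exog_names or list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        exog = np.asarray(exog, dtype=float)
        endog = np.asarray(endog, dtype=float).ravel()
        if exog.ndim != 2 or exog.shape[0] != endog.shape[0]:
            raise ValueError("endog/exog shape mismatch")
        if np.isnan(exog).any() or np.isnan(endog).any():
            raise ValueError("missing values must be handled before modelling")
        self.endog = endog
        self.exog = exog
        self.exog_names = exog_names or [f"x{j}" for j in range(exog.shape[1])]
        self.standardize = standardize
        if standardize:
            self._X = _z(exog)
            self._y = _z(endog)
        else:
            self._X = exog - exog.mean(axis=0)
            self._y = endog - endog.mean()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, predictors=None,
                       **kwargs) -> "PLS":
        predictors = predictors or [c for c in data.columns if c != response]
        sub = data[[response, *predictors]].dropna()
        return cls(sub[response], sub[predictors], **kwargs)

    def fit(
        self,
        n_components: int | None = None,
        a_max: int = 10,
        cv_reps: int = 1000,
        holdout_fraction: float = 0.2,
        cutoff_sd: float = 0.5,
        seed: int = 0,
    ) -> "PLSResults":
        """Fit, selecting complexity by Monte-Carlo CV unless given."""
        cv = None
        if n_components is None:
            cv = select_components(self.exog, self.endog, a_max=a_max,
                                   n_reps=cv_reps, cutoff_sd=cutoff_sd,
                                   holdout_fraction=holdout_fraction, seed=seed)
            n_components = cv.selected_a
            q2 = cv.selected_q2
        else:
            q2 = cv_r2(self.exog, self.endog, n_components, n_reps=cv_reps,
                       holdout_fraction=holdout_fraction, seed=seed)
        model = fit_pls(self._X, self._y, n_components)
        model.cv_r2 = q2
        return PLSResults(self, model, cv)


class PLSResults:
    """Results of a PLS fit: estimates, CV diagnostics, inference helpers."""

    def __init__(self, model: PLS, fitted: PLSModel, cv: CVResult | None):
        self.model = model
        self.fitted = fitted
        self.cv_result = cv
        self.n_components = fitted.n_components
        self.params = pd.Series(fitted.coef, index=model.exog_names, name="b")
        self.training_r2 = fitted.training_r2
        self.cv_r2 = fitted.cv_r2

    @property
    def nobs(self) -> int:
        return self.model.endog.shape[0]

    def predict(self, exog=None) -> np.ndarray:
        """Predict the response (original units) for new predictors."""
        X = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        mu = self.model.exog.mean(axis=0)
        sd = self.model.exog.std(axis=0, ddof=1) if self.model.standardize else 1.0
        y = self.model.endog
        ysd = y.std(ddof=1) if self.model.standardize else 1.0
        return y.mean() + ysd * ((X - mu) / sd) @ self.fitted.coef

    def permutation_test(self, n_perm: int = 10_000, seed: int = 0,
                         n_reps: int = 100, holdout_fraction: float = 0.2
                         ) -> PermutationResult:
        return permutation_test(self.model.exog, self.model.endog,
                                self.n_components, n_perm=n_perm, seed=seed,
                                n_reps=n_reps, holdout_fraction=holdout_fraction)

    def _overall_r2(self, overall: str) -> float:
        if overall == "cv":
            if self.cv_r2 is None:
                raise ValueError("cross-validated R^2 not available")
            return max(float(self.cv_r2), 0.0)
        if overall == "training":
            return float(self.training_r2)
        raise ValueError("overall must be 'cv' or 'training'")

    def selectivity_ratio(self, overall: str = "cv") -> SRProfile:
        return selectivity_ratio(self.fitted, self.model._X,
                                 self._overall_r2(overall),
                                 names=self.model.exog_names)

    def bootstrap_sr(self, n_boot: int = 10_000, seed: int = 0,
                     ci_level: float = 0.95, overall: str = "cv") -> SRProfile:
        return bootstrap_sr(self.model.exog, self.model.endog,
                            self.n_components, self._overall_r2(overall),
                            n_boot=n_boot, seed=seed, ci_level=ci_level,
                            names=self.model.exog_names)

    def summary(self) -> str:
        lines = [
            "PLS regression results",
            "======================",
            f"n obs                {self.nobs}",
            f"n predictors         {len(self.params)}",
            f"n components (A)     {self.n_components}",
            f"training R^2         {self.training_r2:.4f}",
        ]
        if self.cv_r2 is not None:
            lines.append(f"cross-validated R^2  {self.cv_r2:.4f}")
        if self.cv_result is not None:
            lines.append(f"CV repetitions       {self.cv_result.n_reps}")
        top = self.params.abs().sort_values(ascending=False).head(5).index
        lines.append("largest |coefficients| (standardized):")
        for name in top:
            lines.append(f"  {name:<20s} {self.params[name]:+.4f}")
        return "\n".join(lines)
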