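"""Allometric scaling models for petal and corolla area.

Three models, all fitted by ordinary least squares after log
transformation (natural logarithms; the log stabilises the multiplicative
variance of area measurements):

ME (Montgomery equation), per petal
    A = k * L * W          ->   ln A = a + ln(LW),  a = ln k.
    An intercept-only regression with the slope fixed at 1:
    a_hat = mean(ln A - ln LW).

MKSE (Montgomery-Koyama-Smith equation), per flower
    A_T = k_KS * L_KS * W_KS   ->  ln A_T = c + ln(L_KS W_KS).
    Same intercept-only structure on the flower-level quantities.

PLE (power-law equation), per flower
    A_T = beta * (L_KS W_KS)^alpha  ->  ln A_T = gamma + alpha ln(L_KS W_KS).
    Free slope; alpha = 1 recovers the MKSE structure, so the PLE nests
    the MKSE and its RMSE can never be larger on the same data.

Goodness of fit is the log-scale RMSE with divisor n (not n - p).  Model
complexity is traded off with AIC = 2p - 2 lnL, where p counts the
regression parameters plus one for the error variance and lnL is the
Gaussian maximum likelihood with variance rss/n.  The percent error
PE = (RMSE_simple - RMSE_complex)/RMSE_simple * 100 decides whether the
extra PLE parameter pays for itself: PE > 5% selects the PLE, otherwise
the simpler MKSE is kept.

Confidence intervals are nonparametric: case resampling of the
observation pairs with replacement, refitting, and percentile 2.5/97.5%
bounds (3000 replicates by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .aggregate import FlowerSummary
from .geometry import PetalRecord

__all__ = [
    "ModelFit",
    "ModelComparison",
    "fit_montgomery",
    "fit_total_area_model",
    "predict_area",
    "predict_total_area",
    "compute_rmse",
    "compute_aic",
    "percent_error",
    "select_model",
    "bootstrap_ci",
]

#: default number of bootstrap replicates for confidence intervals
DEFAULT_BOOTSTRAP = 3000


@dataclass
class ModelFit:
    """A fitted scaling model on the log scale.

    ``intercept`` is the log-scale intercept (ln k for ME/MKSE, ln beta
    for PLE, in the fitting log base); ``slope`` is fixed at 1 for ME and
    MKSE and free for PLE; ``k_hat`` is the back-transformed
    proportionality coefficient (beta for PLE).  ``rmse`` is always in
    natural-log units.  ``aic`` is NaN for an exact (zero-residual) fit,
    where the Gaussian likelihood degenerates.
    """

    model: str                      # "ME", "MKSE" or "PLE"
    n: int
    intercept: float
    slope: float
    k_hat: float
    rmse: float
    aic: float
    r: float
    log_base: float = math.e
    ci_intercept: tuple[float, float] | None = None
    ci_slope: tuple[float, float] | None = None
    ci_k: tuple[float, float] | None = None
    B: int | None = None
    seed: int | None = None
    rss: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        if self.model not in ("ME", "MKSE", "PLE"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.rmse < 0:
            raise ValueError("rmse must be nonnegative")
        for ci in (self.ci_intercept, self.ci_slope, self.ci_k):
            if ci is not None and ci[0] > ci[1] + 1e-12:
                raise ValueError("confidence bounds out of order")

    @property
    def n_params(self) -> int:
        """Regression parameters (excluding the error variance)."""
        return 2 if self.model == "PLE" else 1


@dataclass
class ModelComparison:
    """Outcome of comparing a simple model against one that nests it."""

    rmse_1: float        # simpler model (MKSE)
    rmse_2: float        # complex model (PLE)
    pe: float            # percent error, %
    aic_1: float
    aic_2: float
    preferred: str
    rule_trace: str


def _me_arrays(petals: Sequence[PetalRecord]) -> tuple[np.ndarray, np.ndarray]:
    A = np.array([p.A for p in petals], dtype=float)
    L = np.array([p.L for p in petals], dtype=float)
    W = np.array([p.W for p in petals], dtype=float)
    if np.any(A <= 0) or np.any(L <= 0) or np.any(W <= 0):
        raise ValueError("all A, L, W must be positive before log transform")
    return np.log(L * W), np.log(A)


def _ks_arrays(flowers: Sequence[FlowerSummary]) -> tuple[np.ndarray, np.ndarray]:
    AT = np.array([f.A_T for f in flowers], dtype=float)
    LKS = np.array([f.L_KS for f in flowers], dtype=float)
    WKS = np.array([f.W_KS for f in flowers], dtype=float)
    if np.any(AT <= 0) or np.any(LKS <= 0) or np.any(WKS <= 0):
        raise ValueError("all A_T, L_KS, W_KS must be positive")
    return np.log(LKS * WKS), np.log(AT)


def compute_rmse(obs_log: np.ndarray, pred_log: np.ndarray) -> float:
    """Root-mean-square error of log-scale predictions, divisor n."""
    obs = np.asarray(obs_log, dtype=float)
    pred = np.asarray(pred_log, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted vectors must be equal-length "
                         "and nonempty")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def compute_aic(n: int, rss: float, n_params: int) -> float:
    """AIC = 2p - 2 lnL with the Gaussian ML variance rss/n.

    ``p = n_params + 1`` (the error variance counts as a parameter), and
    lnL = -(n/2) (ln 2pi + ln(rss/n) + 1).

    Raises
    ------
    ValueError
        If rss is zero: an exact fit has an unbounded Gaussian likelihood
        and no finite AIC ("degenerate likelihood").
    """
    if n < 1 or n_params < 1 or rss < 0:
        raise ValueError("need n >= 1, n_params >= 1, rss >= 0")
    if rss == 0:
        raise ValueError("degenerate likelihood: rss = 0 (exact fit has no "
                         "finite AIC)")
    p = n_params + 1
    loglik = -(n / 2.0) * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)
    return 2.0 * p - 2.0 * loglik


def _finish_fit(model: str, x: np.ndarray, y: np.ndarray,
                intercept_nat: float, slope: float,
                log_base: float) -> ModelFit:
    """Assemble a ModelFit from natural-log arrays and coefficients."""
    n = x.size
    resid = y - (intercept_nat + slope * x)  # natural-log residuals
    rss = float(resid @ resid)
    rmse = math.sqrt(rss / n)
    n_params = 2 if model == "PLE" else 1
    # an (effectively) exact fit has a degenerate Gaussian likelihood;
    # below float-noise residuals the AIC is reported as NaN
    exact = rmse <= 1e-12
    aic = compute_aic(n, rss, n_params) if not exact else math.nan
    r = float(stats.pearsonr(x, y).statistic) if n > 2 else (
        1.0 if n == 2 and x[0] != x[1] else math.nan)
    lb = math.log(log_base)
    return ModelFit(
        model=model, n=n,
        intercept=intercept_nat / lb,   # reported in the requested base
        slope=slope,
        k_hat=math.exp(intercept_nat),  # back-transform is base-free
        rmse=rmse, aic=aic, r=r, log_base=log_base, rss=rss,
    )


def fit_montgomery(
    petals: Sequence[PetalRecord],
    log_base: float = math.e,
    B: int = 0,
    seed: int | None = None,
) -> ModelFit:
    """Fit the Montgomery equation A = k * LW to petal records.

    Intercept-only OLS of ln A on the offset ln(LW):
    a_hat = mean(ln A - ln LW), k_hat = exp(a_hat).  The slope is 1 by
    construction.  Pass ``B > 0`` (with a seed) for bootstrap CIs.
    """
    if len(petals) < 2:
        raise ValueError("need at least 2 petals to fit the ME")
    x, y = _me_arrays(petals)
    a = float(np.mean(y - x))
    fit = _finish_fit("ME", x, y, a, 1.0, log_base)
    if B > 0:
        fit = _attach_ci(fit, x, y, B, seed)
    return fit


def fit_total_area_model(
    flowers: Sequence[FlowerSummary],
    model: str = "MKSE",
    log_base: float = math.e,
    B: int = 0,
    seed: int | None = None,
) -> ModelFit:
    """Fit the MKSE or PLE to flower summaries.

    MKSE: intercept-only OLS of ln A_T on the offset ln(L_KS W_KS).
    PLE: simple linear OLS of ln A_T on ln(L_KS W_KS) (free slope alpha).
    """
    model = model.upper()
    if model not in ("MKSE", "PLE"):
        raise ValueError(f"model must be 'MKSE' or 'PLE', got {model!r}")
    if len(flowers) < 3:
        raise ValueError("need at least 3 flowers "
                         "(slope underdetermined below that for the PLE)")
    x, y = _ks_arrays(flowers)
    if model == "MKSE":
        inter, slope = float(np.mean(y - x)), 1.0
    else:
        slope, inter = _ols_line(x, y)
    fit = _finish_fit(model, x, y, inter, slope, log_base)
    if B > 0:
        fit = _attach_ci(fit, x, y, B, seed)
    return fit


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple linear OLS: returns (slope, intercept)."""
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    denom = float(dx @ dx)
    if denom == 0:
        raise ValueError("all predictor values identical; slope undefined")
    slope = float(dx @ (y - ym)) / denom
    return slope, float(ym - slope * xm)


def predict_area(fit: ModelFit, L, W):
    """Montgomery prediction A_hat = k_hat * L * W (ME fits only)."""
    if fit.model != "ME":
        raise ValueError(f"predict_area needs an ME fit, got {fit.model}")
    return fit.k_hat * np.asarray(L, dtype=float) * np.asarray(W, dtype=float)


def predict_total_area(fit: ModelFit, L_KS, W_KS):
    """Corolla-area prediction from an MKSE or PLE fit."""
    prod = np.asarray(L_KS, dtype=float) * np.asarray(W_KS, dtype=float)
    if fit.model == "MKSE":
        return fit.k_hat * prod
    if fit.model == "PLE":
        return fit.k_hat * prod ** fit.slope
    raise ValueError(f"predict_total_area needs MKSE or PLE, got {fit.model}")


def percent_error(rmse_1: float, rmse_2: float) -> float:
    """PE = (RMSE_1 - RMSE_2) / RMSE_1 * 100, in percent.

    Subscript 1 is the simpler model.  May be negative when the
    "complex" model fits worse (only possible for non-nested pairs).
    """
    if rmse_1 <= 0:
        raise ValueError("rmse_1 must be positive")
    return (rmse_1 - rmse_2) / rmse_1 * 100.0


def select_model(
    fit_mkse: ModelFit,
    fit_ple: ModelFit,
    threshold: float = 5.0,
) -> ModelComparison:
    """Choose between the MKSE and the PLE on the same flowers.

    The PLE is preferred iff the percent error exceeds ``threshold``
    (default 5%); at or below the threshold the simpler MKSE wins.
    The rule trace records PE, the threshold, both AICs, and (when the
    PLE carries a bootstrap interval) whether its slope CI contains 1.
    """
    if fit_mkse.n != fit_ple.n:
        raise ValueError("fits are not on the same data (different n)")
    pe = percent_error(fit_mkse.rmse, fit_ple.rmse)
    preferred = "PLE" if pe > threshold else "MKSE"
    trace = (f"PE = {pe:.4f}% vs threshold {threshold:g}% -> {preferred}; "
             f"AIC(MKSE) = {fit_mkse.aic:.4f}, AIC(PLE) = {fit_ple.aic:.4f}")
    if pe < 0:
        trace += "; warning: complex model fits worse (PE < 0)"
    if fit_ple.ci_slope is not None:
        lo, hi = fit_ple.ci_slope
        inside = lo <= 1.0 <= hi
        trace += (f"; PLE slope 95% CI [{lo:.4f}, {hi:.4f}] "
                  f"{'contains' if inside else 'excludes'} 1")
    return ModelComparison(
        rmse_1=fit_mkse.rmse, rmse_2=fit_ple.rmse, pe=pe,
        aic_1=fit_mkse.aic, aic_2=fit_ple.aic,
        preferred=preferred, rule_trace=trace,
    )


def bootstrap_ci(
    data: Sequence[PetalRecord] | Sequence[FlowerSummary],
    model: str,
    B: int = DEFAULT_BOOTSTRAP,
    seed: int | None = None,
    log_base: float = math.e,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap intervals for intercept, slope and k.

    Observation pairs (cases) are resampled with replacement B times and
    the model refitted on each resample; the 2.5% and 97.5% percentiles
    of each coefficient form the 95% interval.  Reproducible given a
    seed (which is required).
    """
    model = model.upper()
    if B < 1:
        raise ValueError("B must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducible bootstrap CIs")
    if model == "ME":
        x, y = _me_arrays(data)  # type: ignore[arg-type]
    else:
        x, y = _ks_arrays(data)  # type: ignore[arg-type]
    return _bootstrap_arrays(x, y, model, B, seed, log_base)


def _bootstrap_arrays(x, y, model, B, seed, log_base=math.e):
    rng = np.random.default_rng(seed)
    n = x.size
    idx = rng.integers(0, n, size=(B, n))
    xb, yb = x[idx], y[idx]
    if model in ("ME", "MKSE"):
        inter = (yb - xb).mean(axis=1)
        slope = np.ones(B)
    elif model == "PLE":
        xm = xb.mean(axis=1, keepdims=True)
        ym = yb.mean(axis=1, keepdims=True)
        dx = xb - xm
        denom = (dx ** 2).sum(axis=1)
        if np.any(denom == 0):
            # a degenerate resample (all same predictor); retry those rows
            bad = np.flatnonzero(denom == 0)
            for b in bad:
                while True:
                    row = rng.integers(0, n, size=n)
                    if np.ptp(x[row]) > 0:
                        break
                xb[b], yb[b] = x[row], y[row]
            xm = xb.mean(axis=1, keepdims=True)
            ym = yb.mean(axis=1, keepdims=True)
            dx = xb - xm
            denom = (dx ** 2).sum(axis=1)
        slope = (dx * (yb - ym)).sum(axis=1) / denom
        inter = (ym - slope[:, None] * xm).ravel()
    else:
        raise ValueError(f"unknown model {model!r}")
    lb = math.log(log_base)
    pct = lambda v: tuple(np.percentile(v, [2.5, 97.5]))  # noqa: E731
    return {
        "intercept": pct(inter / lb),
        "slope": (1.0, 1.0) if model != "PLE" else pct(slope),
        "k": pct(np.exp(inter)),
    }


def _attach_ci(fit: ModelFit, x, y, B: int, seed: int | None) -> ModelFit:
    if seed is None:
        raise ValueError("a seed is required for reproducible bootstrap CIs")
    ci = _bootstrap_arrays(x, y, fit.model, B, seed, fit.log_base)
    return replace(fit, ci_intercept=ci["intercept"], ci_slope=ci["slope"],
                   ci_k=ci["k"], B=B, seed=seed)
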