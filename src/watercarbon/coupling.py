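"""Climate-CGR coupling statistics.

Quantifies the interannual coupling between the atmospheric CO2 growth
rate (CGR) and tropical climate drivers — water storage, lagged
precipitation, temperature — and how that coupling changes between
periods:

* Pearson and temperature-controlled partial correlations;
* case (year) bootstrap with percentile confidence intervals, used both
  for uncertainty and for the significance of a change between periods;
* interannual sensitivities: univariate OLS slope, and a bivariate ridge
  regression whose regularization is chosen by repeated random
  train/validation splits (ridge stabilizes the water and temperature
  coefficients, which are collinear because both respond to ENSO);
* fixed two-window and 25-year moving-window analyses with per-window
  re-detrending.
"""

from __future__ import annotations

import warnings
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    AnnualSeries,
    BootstrapResult,
    DegenerateInputError,
    SensitivityEstimate,
    align_series,
)
from .preprocess import detrend_linear

__all__ = [
    "pearson_corr",
    "partial_corr",
    "bootstrap_stat",
    "change_significance",
    "ols_sensitivity",
    "ridge_sensitivity",
    "window_analysis",
    "window_corr_bootstrap",
    "moving_window",
]


# ---------------------------------------------------------------------------
# array-level kernels (operate on plain aligned arrays)

def _pearson_arr(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    den = np.sqrt((xd @ xd) * (yd @ yd))
    if den == 0.0:
        return np.nan
    return float(np.clip(xd @ yd / den, -1.0, 1.0))


def _partial_arr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    rxy = _pearson_arr(x, y)
    rxz = _pearson_arr(x, z)
    ryz = _pearson_arr(y, z)
    if np.isnan(rxy) or np.isnan(rxz) or np.isnan(ryz):
        return np.nan
    den = (1.0 - rxz ** 2) * (1.0 - ryz ** 2)
    if den <= 0.0:
        return np.nan
    return float((rxy - rxz * ryz) / np.sqrt(den))


def _slope_arr(y: np.ndarray, x: np.ndarray) -> float:
    xd = x - x.mean()
    den = xd @ xd
    if den == 0.0:
        return np.nan
    return float(xd @ (y - y.mean()) / den)


def _corr_pvalue(r: float, n: int, n_controls: int = 0) -> float:
    """Two-sided p-value via the t approximation, df = n - 2 - #controls."""
    df = n - 2 - n_controls
    if df <= 0 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 else np.nan
    t = r * np.sqrt(df / (1.0 - r ** 2))
    return float(2.0 * sps.t.sf(abs(t), df))


# ---------------------------------------------------------------------------
# public statistics on AnnualSeries

def pearson_corr(x: AnnualSeries, y: AnnualSeries) -> tuple[float, float]:
    """Product-moment correlation over jointly valid years, with p-value."""
    _, (xv, yv) = align_series(x, y)
    if xv.size < 3:
        raise DegenerateInputError("need >=3 jointly valid years")
    r = _pearson_arr(xv, yv)
    if np.isnan(r):
        raise DegenerateInputError("zero variance in an input series")
    return r, _corr_pvalue(r, xv.size)


def partial_corr(x: AnnualSeries, y: AnnualSeries, z: AnnualSeries) -> tuple[float, float]:
    """Correlation of x and y after linearly removing z from both.

    Equals the correlation of the OLS residuals of x|z and y|z; computed
    here from the first-order recursion
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    """
    _, (xv, yv, zv) = align_series(x, y, z)
    if xv.size < 4:
        raise DegenerateInputError("need >=4 jointly valid years")
    rxz = _pearson_arr(xv, zv)
    ryz = _pearson_arr(yv, zv)
    if np.isnan(rxz) or np.isnan(ryz) or abs(rxz) >= 1.0 or abs(ryz) >= 1.0:
        raise DegenerateInputError("control variable collinear with an input")
    r = _partial_arr(xv, yv, zv)
    if np.isnan(r):
        raise DegenerateInputError("zero variance in an input series")
    return r, _corr_pvalue(r, xv.size, n_controls=1)


def bootstrap_stat(
    stat: Callable[..., float],
    data: Sequence[AnnualSeries],
    n_reps: int = 5000,
    seed: int = 0,
    level: float = 0.95,
    statistic_name: str | None = None,
) -> BootstrapResult:
    """Case bootstrap of a statistic over jointly valid years.

    Years are resampled with replacement jointly across all series, so the
    cross-variable dependence structure is preserved.  Replicates on which
    the statistic is degenerate (NaN) are redrawn, up to ten times the
    requested replicate count in total draws.

    ``stat`` receives one aligned numpy array per input series.
    """
    _, arrays = align_series(*data)
    n = arrays[0].size
    if n < 3:
        raise DegenerateInputError("need >=3 jointly valid years")
    point = float(stat(*arrays))

    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    filled = 0
    draws = 0
    cap = 10 * n_reps
    while filled < n_reps:
        if draws >= cap:
            raise DegenerateInputError(
                "bootstrap redraw cap exceeded (statistic degenerate on most resamples)"
            )
        idx = rng.integers(0, n, size=n)
        draws += 1
        val = stat(*(a[idx] for a in arrays))
        if np.isfinite(val):
            reps[filled] = val
            filled += 1
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return BootstrapResult(
        statistic_name=statistic_name or getattr(stat, "__name__", "stat"),
        replicates=reps,
        point_estimate=point,
        ci=(float(lo), float(hi)),
        n_reps=n_reps,
        seed=seed,
        level=level,
    )


def change_significance(a: BootstrapResult, b: BootstrapResult) -> tuple[float, float]:
    """Change of a statistic between two periods, with a bootstrap p-value.

    ``delta`` is the point estimate of period b minus period a.  The
    two-sided p-value is computed from the paired differences of the two
    independent replicate sets: p = min(1, 2 min(Pr(D >= 0), Pr(D <= 0))).
    """
    if a.statistic_name != b.statistic_name:
        raise ValueError(
            f"cannot compare {a.statistic_name!r} with {b.statistic_name!r}"
        )
    if a.n_reps != b.n_reps:
        raise ValueError("bootstrap results must have equal replicate counts")
    delta = b.point_estimate - a.point_estimate
    diffs = b.replicates - a.replicates
    p = 2.0 * min(float(np.mean(diffs >= 0.0)), float(np.mean(diffs <= 0.0)))
    return delta, min(1.0, p)


def ols_sensitivity(
    y: AnnualSeries,
    x: AnnualSeries,
    n_reps: int = 5000,
    seed: int = 0,
) -> SensitivityEstimate:
    """Univariate interannual sensitivity: the OLS slope of y on x.

    Both series are expected to be detrended upstream; the slope carries
    the units of y per unit of x (e.g. PgC yr-1 per Tt H2O).
    """
    _, (yv, xv) = align_series(y, x)
    if xv.size < 3:
        raise DegenerateInputError("need >=3 jointly valid years")
    gamma = _slope_arr(yv, xv)
    if np.isnan(gamma):
        raise DegenerateInputError("zero predictor variance")
    boot = bootstrap_stat(
        lambda yy, xx: _slope_arr(yy, xx), [y, x],
        n_reps=n_reps, seed=seed, statistic_name="ols_slope",
    )
    return SensitivityEstimate(
        gamma=gamma, model_kind="univariate_ols", regularization=0.0,
        bootstrap=boot, predictor=x.name,
    )


def _ridge_coefs(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Ridge coefficients on a centred design: (X'X + lam I)^-1 X'y."""
    k = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(k), X.T @ y)


def _select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    n_splits: int,
    val_frac: float,
    rng: np.random.Generator,
) -> float:
    """Pick the regularization by repeated random train/validation splits.

    For each split the best of the candidate values by validation mean
    squared error is recorded; the final value is the mean of the winners.
    """
    n = X.shape[0]
    n_val = max(1, int(round(val_frac * n)))
    winners = np.empty(n_splits)
    for s in range(n_splits):
        perm = rng.permutation(n)
        val, train = perm[:n_val], perm[n_val:]
        Xt, yt = X[train], y[train]
        mses = np.empty(grid.size)
        for j, lam in enumerate(grid):
            beta = _ridge_coefs(Xt, yt, lam)
            resid = y[val] - X[val] @ beta
            mses[j] = resid @ resid
        winners[s] = grid[int(np.argmin(mses))]
    return float(winners.mean())


def ridge_sensitivity(
    y: AnnualSeries,
    x1: AnnualSeries,
    x2: AnnualSeries,
    n_reps: int = 5000,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
    n_splits: int = 25,
    val_frac: float = 0.25,
    mode: Literal["ridge", "ols"] = "ridge",
    forced_lambda: float | None = None,
) -> tuple[SensitivityEstimate, SensitivityEstimate]:
    """Bivariate interannual sensitivities of y to x1 and x2.

    Predictors are standardized; the ridge penalty is selected by
    ``n_splits`` random train/validation splits over a log-spaced grid
    (default 100 values in [1e-4, 1e2]), taking per split the value with
    the lowest validation mean squared error and averaging the winners.
    Coefficients are rescaled to original units, and uncertainty comes
    from a case bootstrap at the selected penalty.  ``mode="ols"`` gives
    the penalty-free bivariate fit used as a cross-check.
    """
    _, (yv, x1v, x2v) = align_series(y, x1, x2)
    n = yv.size
    if n < 6:
        raise DegenerateInputError("need >=6 jointly valid years")
    if lambda_grid is None:
        lambda_grid = np.logspace(-4, 2, 100)

    sds = np.array([x1v.std(ddof=1), x2v.std(ddof=1)])
    if np.any(sds == 0.0):
        raise DegenerateInputError("zero predictor variance")
    r12 = _pearson_arr(x1v, x2v)
    if abs(r12) >= 1.0 - 1e-12:
        if mode == "ols":
            raise DegenerateInputError("predictors perfectly collinear")
        warnings.warn("predictors perfectly collinear; ridge splits the effect")

    def design(x1a: np.ndarray, x2a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.column_stack([x1a, x2a])
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
        sd = np.where(sd == 0.0, np.nan, sd)
        return (X - mu) / sd, sd

    X, sd0 = design(x1v, x2v)
    yc = yv - yv.mean()

    if mode == "ols":
        lam = 0.0
    elif forced_lambda is not None:
        lam = float(forced_lambda)
    else:
        lam = _select_lambda(
            X, yc, lambda_grid, n_splits, val_frac, np.random.default_rng(seed)
        )

    beta = _ridge_coefs(X, yc, lam)
    gammas = beta / sd0

    def stat_factory(which: int) -> Callable[..., float]:
        def stat(yy: np.ndarray, a1: np.ndarray, a2: np.ndarray) -> float:
            Xb, sdb = design(a1, a2)
            if np.any(np.isnan(sdb)):
                return np.nan
            bb = _ridge_coefs(Xb, yy - yy.mean(), lam)
            return float(bb[which] / sdb[which])
        return stat

    kind = "bivariate_ols" if mode == "ols" else "bivariate_ridge"
    out = []
    for which, xs in enumerate((x1, x2)):
        boot = bootstrap_stat(
            stat_factory(which), [y, x1, x2], n_reps=n_reps, seed=seed + which,
            statistic_name=f"ridge_gamma_{xs.name or which}",
        )
        out.append(
            SensitivityEstimate(
                gamma=float(gammas[which]), model_kind=kind,
                regularization=lam, bootstrap=boot, predictor=xs.name,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# windowed analyses

def _window_series(
    s: AnnualSeries, window: tuple[int, int], redetrend: bool
) -> AnnualSeries:
    sub = s.subset(*window)
    return detrend_linear(sub) if redetrend else sub


def window_corr_bootstrap(
    x: AnnualSeries,
    y: AnnualSeries,
    window: tuple[int, int],
    control: AnnualSeries | None = None,
    n_reps: int = 5000,
    seed: int = 0,
    redetrend: bool = True,
) -> BootstrapResult:
    """Bootstrap of the (partial) correlation of x and y within a window.

    Series are re-detrended within the window by default, so each window's
    statistic reflects interannual variability relative to its own trend.
    """
    xs = _window_series(x, window, redetrend)
    ys = _window_series(y, window, redetrend)
    if control is None:
        return bootstrap_stat(
            _pearson_arr, [xs, ys], n_reps=n_reps, seed=seed,
            statistic_name="pearson",
        )
    zs = _window_series(control, window, redetrend)
    return bootstrap_stat(
        _partial_arr, [xs, ys, zs], n_reps=n_reps, seed=seed,
        statistic_name="partial",
    )


def window_analysis(
    bundle: dict[str, AnnualSeries],
    windows: Sequence[tuple[int, int]],
    n_reps: int = 5000,
    seed: int = 0,
    redetrend: bool = True,
) -> pd.DataFrame:
    """Recompute the coupling statistics within each fixed window.

    ``bundle`` must contain ``"cgr"``, ``"water"`` and ``"temp"``; each
    window gets the water-CGR and temperature-CGR correlations, their
    mutually controlled partial correlations, and the univariate OLS water
    sensitivity, each with a bootstrap percentile CI.  Shared boundary
    years may appear in more than one window.
    """
    for key in ("cgr", "water", "temp"):
        if key not in bundle:
            raise ValueError(f"bundle is missing {key!r}")
    rows = []
    for w in windows:
        cgr = _window_series(bundle["cgr"], w, redetrend)
        wat = _window_series(bundle["water"], w, redetrend)
        tmp = _window_series(bundle["temp"], w, redetrend)
        if min(cgr.valid.sum(), wat.valid.sum(), tmp.valid.sum()) < 10:
            raise ValueError(f"window {w} has fewer than 10 valid years")

        entries: list[tuple[str, Callable, list[AnnualSeries]]] = [
            ("R_water_cgr", _pearson_arr, [wat, cgr]),
            ("R_temp_cgr", _pearson_arr, [tmp, cgr]),
            ("R_water_cgr|temp", _partial_arr, [wat, cgr, tmp]),
            ("R_temp_cgr|water", _partial_arr, [tmp, cgr, wat]),
            ("gamma_water", lambda a, b: _slope_arr(b, a), [wat, cgr]),
        ]
        for i, (stat_name, fn, data) in enumerate(entries):
            boot = bootstrap_stat(
                fn, data, n_reps=n_reps, seed=seed + i,
                statistic_name=stat_name,
            )
            rows.append(
                {
                    "window_start": w[0],
                    "window_end": w[1],
                    "statistic": stat_name,
                    "estimate": boot.point_estimate,
                    "ci_lo": boot.ci[0],
                    "ci_hi": boot.ci[1],
                    "n_years": int(cgr.valid.sum()),
                }
            )
    return pd.DataFrame(rows)


def moving_window(
    x: AnnualSeries,
    y: AnnualSeries,
    width: int = 25,
    control: AnnualSeries | None = None,
    redetrend: bool = True,
) -> AnnualSeries:
    """Statistic of x vs y in a sliding window, indexed by centre year.

    Computes the Pearson correlation (or the partial correlation given
    ``control``) within each ``width``-year window after re-detrending,
    stepping one year at a time.
    """
    if width < 5:
        raise ValueError("window width must be >= 5 years")
    years = np.intersect1d(x.years, y.years)
    span = int(years.max() - years.min() + 1)
    if width > span:
        raise ValueError("window width exceeds the data span")
    centres, vals, valid = [], [], []
    for start in range(int(years.min()), int(years.max()) - width + 2):
        w = (start, start + width - 1)
        centre = start + width // 2
        try:
            if control is None:
                r, _ = pearson_corr(
                    _window_series(x, w, redetrend), _window_series(y, w, redetrend)
                )
            else:
                r, _ = partial_corr(
                    _window_series(x, w, redetrend),
                    _window_series(y, w, redetrend),
                    _window_series(control, w, redetrend),
                )
            vals.append(r)
            valid.append(True)
        except DegenerateInputError:
            vals.append(np.nan)
            valid.append(False)
        centres.append(centre)
    return AnnualSeries(
        np.array(centres), np.array(vals), np.array(valid),
        units="", name=f"moving_{'partial' if control is not None else 'pearson'}",
    )
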