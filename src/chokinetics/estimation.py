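"""Parameter estimation: growth rates, threshold-Monod, yields, Luedeking-Piret.

The estimation pipeline mirrors classical batch-kinetics practice:

1. ``select_exponential_window`` / ``estimate_mu_loglinear`` — the specific
   growth rate mu at each initial glucose level S0 is the slope of
   ln X vs t over the (initial part of the) exponential phase.
2. ``estimate_threshold`` — a growth/no-growth screen over low S0 levels
   brackets the threshold glucose concentration S_t.
3. ``fit_monod_lineweaver_burk`` — with S_t fixed, the (S0, mu) pairs are
   linearized as 1/mu vs 1/(S0 - S_t); mu_max and K_s follow from the
   intercept and slope.  Linear fits are flagged valid only when r^2 > 0.97.
4. ``estimate_yield`` — the cell/substrate yield Y_xs is the through-origin
   slope of r_x against the consumption rate -r_s.
5. ``fit_lp_direct`` / ``fit_lp_integral`` — the Luedeking-Piret constants
   alpha (growth-associated, ug/cell) and beta (non-growth-associated,
   ug/cell/h) by direct rate regression or by matching the Euler-integrated
   product profile to observations.
6. ``recalibrate_at_temperature`` — refit (mu_max, Y_xs, beta) against a
   culture at a new temperature while holding S_t and alpha (and K_s) at
   their base values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import linregress

from .core_model import (
    R2_VALID_FLOOR,
    CultureTimeSeries,
    FitResult,
    KineticParameters,
    euler_integrate_product,
)
from .simulate import simulate_batch

__all__ = [
    "GrowthScreen",
    "select_exponential_window",
    "estimate_mu_loglinear",
    "fit_monod_lineweaver_burk",
    "fit_monod_nonlinear",
    "estimate_threshold",
    "estimate_yield",
    "fit_lp_direct",
    "fit_lp_integral",
    "recalibrate_at_temperature",
]


@dataclass(frozen=True)
class GrowthScreen:
    """Outcome of a growth/no-growth screen over initial glucose levels.

    ``entries`` maps S0 (g/L) to (grew, mu_estimate_or_None).
    """

    entries: tuple[tuple[float, bool, float | None], ...]

    def __post_init__(self) -> None:
        s0s = [e[0] for e in self.entries]
        if len(set(s0s)) != len(s0s):
            raise ValueError("S0 levels must be distinct")
        if any(s <= 0 for s in s0s):
            raise ValueError("S0 levels must be positive")


def _loglinear(t: np.ndarray, X: np.ndarray):
    res = linregress(t, np.log(X))
    return res.slope, res.intercept, res.rvalue**2


def select_exponential_window(
    series: CultureTimeSeries,
    min_points: int = 3,
    r2_floor: float = 0.98,
) -> tuple[float, float]:
    """Pick the exponential-growth window by exhaustive log-linear screening.

    Among all contiguous runs of at least ``min_points`` samples with X > 0,
    returns the longest whose ln X vs t regression reaches ``r2_floor``;
    ties go to the earliest start.  Returns (t_start, t_end).
    """
    ok = np.isfinite(series.X) & (series.X > 0)
    t, X = series.time[ok], series.X[ok]
    n = t.size
    if n < min_points:
        raise ValueError(
            f"only {n} positive samples; need at least min_points={min_points}"
        )
    best: tuple[int, int] | None = None  # (length, start) with -start for ties
    for i in range(n):
        for j in range(i + min_points, n + 1):
            _, _, r2 = _loglinear(t[i:j], X[i:j])
            if r2 >= r2_floor:
                length = j - i
                if best is None or (length, -i) > best[:2]:
                    best = (length, -i, j)
    if best is None:
        raise ValueError(
            f"no contiguous window of >= {min_points} points reaches "
            f"r^2 >= {r2_floor}; consider lowering the floor"
        )
    _, neg_i, j = best
    i = -neg_i
    return float(t[i]), float(t[j - 1])


def estimate_mu_loglinear(
    series: CultureTimeSeries, window: tuple[float, float] | None = None
) -> FitResult:
    """Specific growth rate as the slope of ln X vs t over a window (1/h)."""
    if window is None:
        window = (float(series.time[0]), float(series.time[-1]))
    mask = series.window_mask(*window) & np.isfinite(series.X)
    t, X = series.time[mask], series.X[mask]
    if t.size < 2:
        raise ValueError("window must contain at least 2 samples")
    if np.any(X <= 0):
        raise ValueError("all X must be > 0 in the log-linear window")
    slope, intercept, r2 = _loglinear(t, X)
    resid = np.log(X) - (slope * t + intercept)
    return FitResult(
        estimates={"mu": slope, "ln_X0": intercept},
        r_squared=r2 if t.size > 2 else 1.0,
        n_points=int(t.size),
        valid=True,  # the study gates only the Lineweaver-Burk linearization
        residuals=resid,
    )


def fit_monod_lineweaver_burk(
    mu_by_S0: list[tuple[float, float]], S_t: float
) -> FitResult:
    """Threshold-Monod fit by Lineweaver-Burk linearization.

    Regresses 1/mu on 1/(S0 - S_t); mu_max = 1/intercept,
    K_s = slope/intercept.  Points at or below the threshold are excluded
    with a warning.  The fit is flagged valid only if r^2 > 0.97.
    A non-positive intercept (no finite mu_max) is an error.
    """
    usable = [(s0, mu) for s0, mu in mu_by_S0 if s0 > S_t and mu > 0]
    dropped = len(mu_by_S0) - len(usable)
    if dropped:
        warnings.warn(
            f"excluded {dropped} point(s) with S0 <= S_t={S_t} or mu <= 0 "
            "from Lineweaver-Burk fit",
            stacklevel=2,
        )
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 usable (S0 > S_t, mu > 0) points, have {len(usable)}"
        )
    s0 = np.array([u[0] for u in usable])
    mu = np.array([u[1] for u in usable])
    inv_s = 1.0 / (s0 - S_t)
    inv_mu = 1.0 / mu
    if np.allclose(mu, mu[0], rtol=1e-12, atol=0.0):
        # saturated limit: flat mu, zero slope
        return FitResult(
            estimates={"mu_max": float(mu[0]), "K_s": 0.0},
            r_squared=1.0, n_points=len(usable), valid=True,
            residuals=np.zeros(len(usable)),
        )
    res = linregress(inv_s, inv_mu)
    if res.intercept <= 0:
        raise ValueError(
            f"Lineweaver-Burk intercept {res.intercept:.3g} <= 0: "
            "no finite mu_max; fit rejected"
        )
    mu_max = 1.0 / res.intercept
    K_s = res.slope / res.intercept
    r2 = res.rvalue**2
    resid = inv_mu - (res.slope * inv_s + res.intercept)
    return FitResult(
        estimates={"mu_max": mu_max, "K_s": K_s},
        r_squared=r2,
        n_points=len(usable),
        valid=bool(r2 > R2_VALID_FLOOR),
        residuals=resid,
    )


def fit_monod_nonlinear(
    mu_by_S0: list[tuple[float, float]], S_t: float
) -> FitResult:
    """Direct nonlinear threshold-Monod fit (diagnostic cross-check only).

    Least squares on the mu scale via scipy; the default estimator remains
    the Lineweaver-Burk linearization.
    """
    from scipy.optimize import curve_fit

    usable = [(s0, mu) for s0, mu in mu_by_S0 if s0 > S_t and mu > 0]
    if len(usable) < 3:
        raise ValueError("need >= 3 usable points")
    s0 = np.array([u[0] for u in usable])
    mu = np.array([u[1] for u in usable])

    def model(s, mu_max, K_s):
        return mu_max * (s - S_t) / (K_s + (s - S_t))

    p0 = (float(mu.max()) * 1.2, float(np.median(s0 - S_t)))
    popt, _ = curve_fit(model, s0, mu, p0=p0, maxfev=10000)
    resid = mu - model(s0, *popt)
    ss_tot = float(np.sum((mu - mu.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return FitResult(
        estimates={"mu_max": float(popt[0]), "K_s": float(popt[1])},
        r_squared=r2, n_points=len(usable), valid=True, residuals=resid,
    )


def estimate_growth_parameters(
    dataset: list[CultureTimeSeries],
    S_t: float,
    *,
    window: tuple[float, float] | None = (0.0, 48.0),
    min_points: int = 3,
    r2_floor: float = 0.98,
    substrate: str = "window_mean",
) -> FitResult:
    """Trajectories -> (mu_max, K_s): the full growth-estimation pipeline.

    For each culture, mu is the log-linear slope over ``window`` (or the
    auto-selected exponential window when ``window`` is None); replicates
    sharing a condition label are averaged.  Each condition's mu is paired
    with its substrate coordinate: by default the window-mean glucose
    concentration, which corrects the downward drift of S over the fitting
    window (``substrate="initial"`` uses the t=0 glucose instead, the
    classical mu-vs-S0 plot).  The pairs then go through the
    Lineweaver-Burk fit with the supplied threshold.
    """
    if substrate not in ("window_mean", "initial"):
        raise ValueError("substrate must be 'window_mean' or 'initial'")
    by_condition: dict[str, list[tuple[float, float]]] = {}
    for s in dataset:
        w = window if window is not None else select_exponential_window(
            s, min_points, r2_floor
        )
        mu = estimate_mu_loglinear(s, w)["mu"]
        mask = s.window_mask(*w) & np.isfinite(s.S)
        s_coord = (
            float(np.mean(s.S[mask])) if substrate == "window_mean"
            else float(s.S[s.time == s.time[0]][0])
        )
        by_condition.setdefault(s.condition, []).append((s_coord, mu))
    pairs = [
        (float(np.mean([p[0] for p in v])), float(np.mean([p[1] for p in v])))
        for v in by_condition.values()
    ]
    return fit_monod_lineweaver_burk(pairs, S_t=S_t)


def estimate_threshold(screen: GrowthScreen) -> tuple[float, tuple[float, float]]:
    """Bracket the growth threshold S_t from a growth/no-growth screen.

    Returns (midpoint estimate, (max no-grow S0, min grew S0)).
    """
    no_grow = [s0 for s0, grew, _ in screen.entries if not grew]
    grew = [s0 for s0, grew, _ in screen.entries if grew]
    if not no_grow or not grew:
        raise ValueError(
            "screen must contain at least one grew and one no-grow level "
            f"(grew at {sorted(grew)}, no growth at {sorted(no_grow)})"
        )
    lo, hi = max(no_grow), min(grew)
    if lo >= hi:
        raise ValueError(
            f"inconsistent screen: no-growth at {lo} g/L above growth at {hi} g/L"
        )
    return 0.5 * (lo + hi), (lo, hi)


def estimate_yield(
    r_x: np.ndarray, r_s: np.ndarray, *, free_intercept: bool = False
) -> FitResult:
    """Cell/substrate yield Y_xs as the through-origin slope of r_x vs -r_s.

    The substrate balance r_s = -r_x / Y_xs has no intercept, so the
    default regression is through the origin; ``free_intercept=True`` adds
    an intercept for diagnostics only (the slope is still reported as Y_xs).
    Units: cells/mg, given r_x in cells/mL/h and r_s in g/L/h (signed).
    """
    r_x = np.asarray(r_x, dtype=float)
    r_s = np.asarray(r_s, dtype=float)
    if r_x.size != r_s.size or r_x.size < 3:
        raise ValueError("need >= 3 paired rate points")
    if not np.any(r_s < 0):
        raise ValueError("no substrate consumption in window (all r_s >= 0)")
    cons = -r_s  # positive consumption rate, mg/mL/h == g/L/h
    if free_intercept:
        A = np.column_stack([cons, np.ones_like(cons)])
    else:
        A = cons[:, None]
    coef, _, _, _ = np.linalg.lstsq(A, r_x, rcond=None)
    fitted = A @ coef
    resid = r_x - fitted
    ss_tot = float(np.sum((r_x - r_x.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    est = {"Y_xs": float(coef[0])}
    if free_intercept:
        est["intercept"] = float(coef[1])
    return FitResult(
        estimates=est, r_squared=r2, n_points=int(r_x.size),
        valid=True, residuals=resid,
    )


_COLLINEARITY_TOL = 1e-8


def fit_lp_direct(r_p: np.ndarray, r_x: np.ndarray, X: np.ndarray) -> FitResult:
    """Luedeking-Piret constants by direct rate regression.

    Two-parameter linear least squares of r_p (mg/L/h) on the columns
    (r_x, X) with no intercept: alpha in ug/cell, beta in ug/cell/h.
    A pure exponential X profile makes r_x proportional to X and the
    problem singular; that case raises and points to the integral fit.
    """
    r_p = np.asarray(r_p, dtype=float)
    r_x = np.asarray(r_x, dtype=float)
    X = np.asarray(X, dtype=float)
    if not (r_p.size == r_x.size == X.size) or r_p.size < 3:
        raise ValueError("need >= 3 aligned (r_p, r_x, X) points")
    A = np.column_stack([r_x, X])
    # scale columns before the rank check so cells/mL vs cells/mL/h scales
    # do not mask collinearity
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        norms = np.where(norms == 0, 1.0, norms)
    sv = np.linalg.svd(A / norms, compute_uv=False)
    if sv[-1] / sv[0] < _COLLINEARITY_TOL:
        raise ValueError(
            "r_x and X are (numerically) collinear — X is exponential, so the "
            "direct regression cannot separate alpha from beta; use "
            "fit_lp_integral instead"
        )
    coef, _, _, _ = np.linalg.lstsq(A, r_p, rcond=None)
    resid = r_p - A @ coef
    ss_tot = float(np.sum((r_p - r_p.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return FitResult(
        estimates={"alpha": float(coef[0]), "beta": float(coef[1])},
        r_squared=r2, n_points=int(r_p.size), valid=True, residuals=resid,
    )


def fit_lp_integral(
    time: np.ndarray,
    P_obs: np.ndarray,
    X: np.ndarray,
    r_x: np.ndarray | None = None,
    *,
    dt: float | None = None,
    initial_guess: tuple[float, float] = (1e-7, 1e-8),
    rtol: float = 1e-10,
    max_iter: int = 200,
) -> FitResult:
    """Luedeking-Piret constants by matching the Euler-integrated profile.

    Minimizes the sum of squared differences between the forward-Euler
    product profile and the observed P over (alpha, beta) >= 0 with a
    deterministic derivative-free search (Powell, bounded at zero),
    converging when the relative objective change falls below ``rtol``.

    With ``dt=None`` the Euler steps run on the observation grid itself,
    using the supplied ``r_x`` (finite differences of X when omitted).
    With a positive ``dt`` the X profile is first refined to a fine grid by
    a cubic spline and the product balance is stepped at ``dt``, which
    removes the coarse-grid quadrature error when the observations are
    sparse (e.g. daily samples of a smooth culture).
    """
    time = np.asarray(time, dtype=float)
    P_obs = np.asarray(P_obs, dtype=float)
    X = np.asarray(X, dtype=float)
    if P_obs.size < 4:
        raise ValueError("need >= 4 product observations")
    P0 = float(P_obs[0])

    if dt is None:
        t_grid = time
        X_grid = X
        r_grid = np.gradient(X, time) if r_x is None else np.asarray(r_x, float)
        obs_idx = np.arange(time.size)
    else:
        from scipy.interpolate import CubicSpline

        t_grid = np.arange(time[0], time[-1] + 1e-9, dt)
        if time[-1] - t_grid[-1] > 1e-9:
            t_grid = np.append(t_grid, time[-1])
        spl = CubicSpline(time, X)
        X_grid = spl(t_grid)
        if r_x is None:
            r_grid = spl.derivative()(t_grid)
        else:
            r_grid = CubicSpline(time, np.asarray(r_x, float))(t_grid)
        obs_idx = np.searchsorted(t_grid, time)
        obs_idx = np.clip(obs_idx, 0, t_grid.size - 1)
        left = np.clip(obs_idx - 1, 0, t_grid.size - 1)
        snap = np.abs(t_grid[left] - time) < np.abs(t_grid[obs_idx] - time)
        obs_idx = np.where(snap, left, obs_idx)

    def objective(alpha: float, beta: float) -> float:
        p = KineticParameters(
            mu_max=1.0, K_s=1.0, S_t=0.0, Y_xs=1.0,
            alpha=max(alpha, 0.0), beta=max(beta, 0.0),
        )
        P = euler_integrate_product(t_grid, X_grid, r_grid, p, P0=P0)
        d = P[obs_idx] - P_obs
        return float(d @ d)

    # natural scales from the data: alpha ~ dP/dX, beta ~ dP/(X dt)
    dP = max(float(P_obs.max() - P_obs.min()), 1e-30)
    dX = max(float(np.abs(np.diff(X)).sum()), 1e-30)
    span = float(time[-1] - time[0])
    Xbar = max(float(np.mean(X)), 1e-30)
    a_scale = max(dP / dX, initial_guess[0], 1e-30)
    b_scale = max(dP / (Xbar * span), initial_guess[1], 1e-30)

    # Powell over scaled (alpha, beta): derivative-free, deterministic, and
    # unaffected by the 1e7-fold scale gap between the two constants
    res = minimize(
        lambda uv: objective(uv[0] * a_scale, uv[1] * b_scale),
        x0=np.array([initial_guess[0] / a_scale, initial_guess[1] / b_scale]),
        method="Powell",
        bounds=[(0.0, 100.0), (0.0, 100.0)],
        options={"ftol": rtol, "xtol": 1e-12, "maxiter": max_iter},
    )
    if not res.success:
        raise RuntimeError(
            f"fit_lp_integral did not converge in {max_iter} iterations: "
            f"{res.message}; last point alpha={res.x[0] * a_scale:.3e}, "
            f"beta={res.x[1] * b_scale:.3e}, objective={res.fun:.3e}"
        )
    alpha = float(res.x[0] * a_scale)
    beta = float(res.x[1] * b_scale)
    P_fit = euler_integrate_product(
        t_grid, X_grid, r_grid,
        KineticParameters(mu_max=1.0, K_s=1.0, S_t=0.0, Y_xs=1.0,
                          alpha=alpha, beta=beta),
        P0=P0,
    )
    resid = P_obs - P_fit[obs_idx]
    ss_tot = float(np.sum((P_obs - P_obs.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return FitResult(
        estimates={"alpha": alpha, "beta": beta},
        r_squared=r2, n_points=int(P_obs.size), valid=True, residuals=resid,
    )


def recalibrate_at_temperature(
    series: CultureTimeSeries,
    base: KineticParameters,
    *,
    dt: float = 0.5,
    xatol: float = 1e-5,
    fatol: float = 1e-12,
    max_iter: int = 2000,
) -> KineticParameters:
    """Refit (mu_max, Y_xs, beta) to a culture at a new temperature.

    S_t, K_s and alpha stay at their base values; the three free parameters
    minimize the combined squared error between a batch simulation (started
    from the series' initial state) and the observed X, S and P, each
    variable normalized by its observed maximum so the cell counts (1e6
    scale) do not swamp the concentrations.  Optimized as multiplicative
    factors on the base values (Nelder-Mead), which conditions the three
    very different scales.
    """
    t_obs = series.time - series.time[0]
    obs = {}
    for name in ("X", "S", "P"):
        arr = getattr(series, name)
        if arr is None or not np.any(np.isfinite(arr)):
            raise ValueError(f"series must provide {name} for recalibration")
        obs[name] = arr
    scales = {k: max(float(np.nanmax(v)), 1e-30) for k, v in obs.items()}
    X0, S0 = float(obs["X"][0]), float(obs["S"][0])
    P0 = float(obs["P"][0]) if np.isfinite(obs["P"][0]) else 0.0

    def objective(logfac: np.ndarray) -> float:
        fac = np.exp(logfac)
        p = base.with_(
            mu_max=base.mu_max * fac[0],
            Y_xs=base.Y_xs * fac[1],
            beta=base.beta * fac[2],
        )
        sim = simulate_batch(
            p, X0, S0, float(t_obs[-1]), dt, P0=P0, sample_times=t_obs
        )
        err = 0.0
        for name in ("X", "S", "P"):
            o = obs[name]
            m = np.isfinite(o)
            d = (sim.variable(name)[m] - o[m]) / scales[name]
            err += float(d @ d)
        return err

    res = minimize(
        objective, np.zeros(3), method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol,
                 "maxiter": max_iter, "maxfev": max_iter},
    )
    if not res.success:
        raise RuntimeError(
            f"recalibration optimizer failed ({res.message}); base retained"
        )
    fac = np.exp(res.x)
    return base.with_(
        mu_max=base.mu_max * float(fac[0]),
        Y_xs=base.Y_xs * float(fac[1]),
        beta=base.beta * float(fac[2]),
    )
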