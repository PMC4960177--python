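"""Polynomial smoothing, analytic differentiation, and IVCC-normalized rates.

Measured profiles are smoothed with ordinary least-squares polynomials
(degree 2 for the exponential-phase X and S profiles, degree 6 for the
full-culture X profile used in production fitting), differentiated
analytically, and specific consumption/production rates are normalized by
the integral of viable cell concentration (IVCC, cell*h/mL) over a
metabolic phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .core_model import CultureTimeSeries, RateSeries

__all__ = [
    "SmoothedProfile",
    "Phase",
    "fit_polynomial_window",
    "differentiate",
    "rate_series_from_profiles",
    "integral_viable_cells",
    "specific_rate",
    "suggest_phase_boundaries",
]

# unit conversions for specific rates (internal mg/cell/h -> reported units)
_NG_PER_MG = 1e6
_PG_PER_MG = 1e9
_H_PER_DAY = 24.0


@dataclass(frozen=True)
class SmoothedProfile:
    """A polynomial fit to one variable over a time window.

    ``coefficients`` are in ascending degree on the raw time axis (h).
    Evaluation or differentiation outside ``[t_start, t_end]`` is refused:
    off-window values of high-degree polynomials are meaningless.
    """

    variable: str
    coefficients: np.ndarray
    t_start: float
    t_end: float
    r_squared: float

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        self._check_window(times)
        return Polynomial(self.coefficients)(times)

    def _check_window(self, times: np.ndarray) -> None:
        tol = 1e-9 * max(1.0, abs(self.t_end))
        if np.any(times < self.t_start - tol) or np.any(times > self.t_end + tol):
            raise ValueError(
                f"times outside fit window [{self.t_start}, {self.t_end}] "
                f"for {self.variable!r}"
            )


@dataclass(frozen=True)
class Phase:
    """A labelled metabolic phase: a half-open time window [t_start, t_end)."""

    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("phase window must have t_end > t_start")


def fit_polynomial_window(
    series: CultureTimeSeries,
    variable: str,
    degree: int,
    window: tuple[float, float] | None = None,
) -> SmoothedProfile:
    """OLS polynomial fit of one variable over a time window.

    Missing values (NaN) are dropped.  Requires at least ``degree + 1``
    usable points.  r^2 is 1 - SS_res/SS_tot (defined as 1.0 for a
    zero-variance target that the fit reproduces).
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    y = series.variable(variable)
    if window is None:
        window = (float(series.time[0]), float(series.time[-1]))
    t_start, t_end = window
    mask = series.window_mask(t_start, t_end) & np.isfinite(y)
    t, yv = series.time[mask], y[mask]
    if t.size < degree + 1:
        raise ValueError(
            f"window [{t_start}, {t_end}] has {t.size} usable points for "
            f"{variable!r}; degree {degree} needs at least {degree + 1}"
        )
    # domain=[] keeps coefficients on the raw time axis
    poly = Polynomial.fit(t, yv, deg=degree, domain=[])
    resid = yv - poly(t)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res <= 1e-12 else 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return SmoothedProfile(
        variable=variable,
        coefficients=np.asarray(poly.coef, dtype=float),
        t_start=float(t_start),
        t_end=float(t_end),
        r_squared=r2,
    )


def differentiate(profile: SmoothedProfile, times) -> np.ndarray:
    """Analytic derivative of the smoothing polynomial, evaluated at ``times``.

    Raises if any time lies outside the fit window.
    """
    times = np.asarray(times, dtype=float)
    profile._check_window(times)
    return Polynomial(profile.coefficients).deriv()(times)


def rate_series_from_profiles(
    times,
    x_profile: SmoothedProfile | None = None,
    s_profile: SmoothedProfile | None = None,
    p_profile: SmoothedProfile | None = None,
) -> RateSeries:
    """Bundle analytic derivatives of smoothed profiles into a RateSeries."""
    times = np.asarray(times, dtype=float)
    prov = {}
    out = {}
    for key, prof in (("r_x", x_profile), ("r_s", s_profile), ("r_p", p_profile)):
        if prof is not None:
            out[key] = differentiate(prof, times)
            prov[key] = {"degree": prof.degree,
                         "window": (prof.t_start, prof.t_end),
                         "r_squared": prof.r_squared}
    return RateSeries(time=times, provenance=prov, **out)


def integral_viable_cells(
    series: CultureTimeSeries, window: tuple[float, float] | None = None
) -> float:
    """IVCC: trapezoidal integral of X over a window, in cell*h/mL."""
    if window is None:
        window = (float(series.time[0]), float(series.time[-1]))
    t_start, t_end = window
    if t_start < series.time[0] - 1e-9 or t_end > series.time[-1] + 1e-9:
        raise ValueError(
            f"window [{t_start}, {t_end}] outside sampled span "
            f"[{series.time[0]}, {series.time[-1]}]"
        )
    mask = series.window_mask(t_start, t_end) & np.isfinite(series.X)
    t, x = series.time[mask], series.X[mask]
    if t.size < 2:
        raise ValueError(f"window [{t_start}, {t_end}] has fewer than 2 samples")
    return float(np.trapezoid(x, t))


_SPECIFIC_RATE_UNITS = {
    "S": ("ng/cell/day", _NG_PER_MG),
    "Lac": ("ng/cell/day", _NG_PER_MG),
    "P": ("pg/cell/day", _PG_PER_MG),
}


def specific_rate(
    series: CultureTimeSeries, variable: str, phase: Phase
) -> tuple[float, str]:
    """IVCC-normalized specific rate of one variable over a phase.

    q = dC / IVCC(phase), converted to per-day units.  Sign conventions
    follow the study's rate tables: glucose consumption is reported
    positive (q_Glu = -dS/IVCC), lactate is signed as measured (production
    positive, consumption negative), and mAb production is positive.

    Returns ``(value, units)`` with units ng/cell/day for glucose and
    lactate and pg/cell/day for mAb.
    """
    if variable not in _SPECIFIC_RATE_UNITS:
        raise KeyError(f"no specific-rate convention for variable {variable!r}")
    y = series.variable(variable)
    mask = series.window_mask(phase.t_start, phase.t_end) & np.isfinite(y)
    t, yv = series.time[mask], y[mask]
    if t.size < 2:
        raise ValueError(f"phase {phase.label!r} has fewer than 2 samples")
    ivcc = integral_viable_cells(series, (float(t[0]), float(t[-1])))
    if ivcc == 0:
        raise ZeroDivisionError(
            f"IVCC is zero over phase {phase.label!r}; specific rate undefined"
        )
    # concentrations are g/L == mg/mL (S, Lac) or mg/L == ug/mL (P);
    # delta / IVCC is then mg/cell/h resp. ug/cell/h
    delta = float(yv[-1] - yv[0])
    units, scale = _SPECIFIC_RATE_UNITS[variable]
    per_mg_scale = scale if variable != "P" else 1e6  # ug/cell/h -> pg/cell/h
    q = delta / ivcc * per_mg_scale * _H_PER_DAY
    if variable == "S":
        q = -q  # consumption reported positive
    return q, units


def suggest_phase_boundaries(
    series: CultureTimeSeries, degree: int = 6
) -> list[float]:
    """Convenience heuristic: candidate phase boundaries from smoothed rates.

    Returns interior times at which the smoothed dS/dt or dLac/dt changes
    sign.  Purely advisory — analyses must pass explicit :class:`Phase`
    windows; this helper is never applied implicitly.
    """
    bounds: set[float] = set()
    tgrid = np.linspace(series.time[0], series.time[-1], 200)
    for var in ("S", "Lac"):
        try:
            y = series.variable(var)
        except KeyError:
            continue
        if y is None or not np.any(np.isfinite(y)):
            continue
        n_ok = int(np.isfinite(y).sum())
        deg = min(degree, n_ok - 1)
        if deg < 2:
            continue
        prof = fit_polynomial_window(series, var, deg)
        d = differentiate(prof, tgrid)
        sign_flips = np.where(np.diff(np.sign(d)) != 0)[0]
        bounds.update(float(tgrid[i]) for i in sign_flips)
    return sorted(bounds)
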