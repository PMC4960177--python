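"""Forward integration of the batch and fed-batch culture ODE system.

State variables: viable cells X (cells/mL), glucose S (g/L), mAb P (mg/L),
and optionally lactate Lac (g/L).  Dynamics:

    dX/dt = mu(S) * X - k_d * X * 1[S <= S_t]
    dS/dt = -mu(S) * X / Y_xs - m_s * X
    dP/dt = alpha * dX/dt + beta * X
    dLac/dt = y_lac_x * mu(S) * X        while S > S_t
            = -q_lac_cons * X (converted) while S <= S_t

mu is the threshold-Monod law.  Death (k_d) and maintenance (m_s) are
optional extensions (default 0) that produce the post-peak decline and the
full glucose depletion seen in real cultures; with both at 0 the state obeys
the exact yield balance X + Y_xs*S = const, a linear invariant that the
Runge-Kutta steppers preserve to rounding.

Fed-batch: between events the dynamics are the batch dynamics; at a feed
the volume jumps and every concentration is diluted by the mixing balance,
with the feed contributing glucose only (cell-, lactate- and product-free);
at a temperature shift the parameter set swaps to the registry entry for
the new temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import (
    CultureTimeSeries,
    KineticParameters,
    ParameterRegistry,
    monod_mu,
)

__all__ = ["FeedEvent", "TemperatureShift", "simulate_batch", "simulate_fed_batch"]

_NG_PER_MG = 1e6
_H_PER_DAY = 24.0


@dataclass(frozen=True)
class FeedEvent:
    """An instantaneous cell-free, product-free feed addition."""

    time: float          # h
    volume: float        # mL added
    glucose: float       # g/L in the feed

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError("feed volume must be > 0")
        if self.glucose < 0:
            raise ValueError("feed glucose must be >= 0")


@dataclass(frozen=True)
class TemperatureShift:
    """A set-point change that swaps the active kinetic parameter set."""

    time: float          # h
    temperature: float   # degC


def _rhs(state: np.ndarray, p: KineticParameters, lactate: bool) -> np.ndarray:
    X, S, P = state[0], state[1], state[2]
    mu = monod_mu(max(S, 0.0), p)
    dead = p.k_d * X if S <= p.S_t else 0.0
    dX = mu * X - dead
    dS = -mu * X / p.Y_xs - p.m_s * X
    dP = p.alpha * dX + p.beta * X
    if not lactate:
        return np.array([dX, dS, dP])
    if S > p.S_t:
        dL = (p.y_lac_x or 0.0) * mu * X
    else:
        # q_lac_cons is ng/cell/day; convert to mg/cell/h
        dL = -(p.q_lac_cons or 0.0) / _NG_PER_MG / _H_PER_DAY * X
    return np.array([dX, dS, dP, dL])


def _step_rk4(state, dt, p, lactate):
    k1 = _rhs(state, p, lactate)
    k2 = _rhs(state + 0.5 * dt * k1, p, lactate)
    k3 = _rhs(state + 0.5 * dt * k2, p, lactate)
    k4 = _rhs(state + dt * k3, p, lactate)
    return state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def _step_euler(state, dt, p, lactate):
    return state + dt * _rhs(state, p, lactate)


_STEPPERS = {"rk4": _step_rk4, "euler": _step_euler}


def _integrate_span(state, t0, t1, dt, p, lactate, method):
    """March from t0 to t1 with fixed steps of dt (shorter final step).

    Step times are computed arithmetically (t0 + k*dt), not accumulated,
    so span ends land exactly on event times.  Clamps the state at 0.
    """
    step = _STEPPERS[method]
    span = t1 - t0
    n_full = int(np.floor(span / dt + 1e-9))
    times = [t0 + k * dt for k in range(1, n_full + 1)]
    if not times or t1 - times[-1] > 1e-9:
        times.append(t1)
    out_t, out_y = [], []
    t_prev = t0
    for t in times:
        state = step(state, t - t_prev, p, lactate)
        state = np.maximum(state, 0.0)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(f"non-finite state at t={t:.4f} h: {state}")
        t_prev = t
        out_t.append(t)
        out_y.append(state.copy())
    return state, out_t, out_y


def simulate_batch(
    params: KineticParameters,
    X0: float,
    S0: float,
    t_end: float,
    dt: float = 0.1,
    *,
    P0: float = 0.0,
    Lac0: float = 0.0,
    method: str = "rk4",
    lactate: bool = False,
    sample_times=None,
) -> CultureTimeSeries:
    """Integrate a batch culture on a fixed grid.

    ``method`` is "rk4" (default) or "euler" (the textbook product-balance
    scheme).  If ``sample_times`` is given, the trajectory is returned at
    those times (which must be multiples-compatible with the grid only in
    the sense that dt must resolve them: dt smaller than their spacing);
    otherwise at every integrator step.
    """
    if not X0 > 0:
        raise ValueError("X0 must be > 0")
    if S0 < 0 or P0 < 0 or Lac0 < 0:
        raise ValueError("initial concentrations must be >= 0")
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if method not in _STEPPERS:
        raise ValueError(f"unknown method {method!r}; use 'rk4' or 'euler'")
    if sample_times is not None:
        sample_times = np.asarray(sample_times, dtype=float)
        spacing = np.min(np.diff(sample_times)) if sample_times.size > 1 else np.inf
        if np.isfinite(spacing) and dt >= spacing - 1e-12:
            raise ValueError(
                f"dt={dt} must be smaller than the sampling interval {spacing}"
            )

    lactate = lactate or (params.y_lac_x is not None or params.q_lac_cons is not None)
    n_state = 4 if lactate else 3
    state = np.array([X0, S0, P0, Lac0][:n_state], dtype=float)

    times = [0.0]
    traj = [state.copy()]
    state, ts, ys = _integrate_span(state, 0.0, t_end, dt, params, lactate, method)
    times.extend(ts)
    traj.extend(ys)
    t_arr = np.asarray(times)
    y_arr = np.asarray(traj)

    if sample_times is not None:
        idx = np.searchsorted(t_arr, sample_times)
        idx = np.clip(idx, 0, t_arr.size - 1)
        # snap to nearest grid point (grid resolves sample spacing)
        left = np.clip(idx - 1, 0, t_arr.size - 1)
        choose_left = np.abs(t_arr[left] - sample_times) < np.abs(t_arr[idx] - sample_times)
        idx = np.where(choose_left, left, idx)
        t_arr = sample_times
        y_arr = y_arr[idx]

    return CultureTimeSeries(
        time=t_arr,
        X=y_arr[:, 0],
        S=y_arr[:, 1],
        P=y_arr[:, 2],
        Lac=y_arr[:, 3] if lactate else None,
    )


def simulate_fed_batch(
    registry: ParameterRegistry,
    cell_line: str,
    X0: float,
    S0: float,
    V0: float,
    feeds: list[FeedEvent],
    shifts: list[TemperatureShift],
    t_end: float,
    dt: float = 0.1,
    *,
    temperature0: float = 33.0,
    source: str = "table2",
    P0: float = 0.0,
    Lac0: float = 0.0,
    method: str = "rk4",
    lactate: bool = False,
) -> CultureTimeSeries:
    """Integrate a fed-batch culture with feed dilutions and parameter shifts.

    All registry entries needed by the shift schedule are resolved before
    integration starts, so a missing entry fails fast.  Output includes the
    vessel volume V(t) and the active temperature.
    """
    if not V0 > 0:
        raise ValueError("V0 must be > 0")
    feeds = sorted(feeds, key=lambda f: f.time)
    shifts = sorted(shifts, key=lambda s: s.time)
    # resolve every parameter set up front
    params_by_T = {temperature0: registry.get(cell_line, temperature0, source)}
    for sh in shifts:
        params_by_T[sh.temperature] = registry.get(cell_line, sh.temperature, source)

    p = params_by_T[temperature0]
    lactate = lactate or (p.y_lac_x is not None or p.q_lac_cons is not None)
    n_state = 4 if lactate else 3
    state = np.array([X0, S0, P0, Lac0][:n_state], dtype=float)
    V = float(V0)
    T = float(temperature0)

    events: list[tuple[float, str, object]] = [(f.time, "feed", f) for f in feeds]
    events += [(s.time, "shift", s) for s in shifts]
    events.sort(key=lambda e: e[0])
    for t_ev, _, _ in events:
        if t_ev < 0 or t_ev > t_end:
            raise ValueError(f"event at t={t_ev} outside simulation span [0, {t_end}]")

    times = [0.0]
    traj = [state.copy()]
    vols = [V]
    temps = [T]

    def record(ts, ys):
        times.extend(ts)
        traj.extend(ys)
        vols.extend([V] * len(ts))
        temps.extend([T] * len(ts))

    t_cursor = 0.0
    for t_ev, kind, ev in events:
        if t_ev > t_cursor:
            state, ts, ys = _integrate_span(
                state, t_cursor, t_ev, dt, p, lactate, method
            )
            record(ts, ys)
            t_cursor = t_ev
        if kind == "feed":
            f: FeedEvent = ev
            V_new = V + f.volume
            dilution = V / V_new
            state = state * dilution
            state[1] += f.glucose * f.volume / V_new  # feed carries glucose only
            V = V_new
        else:
            sh: TemperatureShift = ev
            T = float(sh.temperature)
            p = params_by_T[T]
        # record the post-event state just after the event time so the
        # series stays strictly increasing (pre-event state sits at t_ev)
        times.append(max(t_cursor, times[-1]) + 1e-9)
        traj.append(state.copy())
        vols.append(V)
        temps.append(T)
    if t_end > t_cursor:
        state, ts, ys = _integrate_span(
            state, t_cursor, t_end, dt, p, lactate, method
        )
        record(ts, ys)

    t_arr = np.asarray(times)
    y_arr = np.asarray(traj)
    return CultureTimeSeries(
        time=t_arr,
        X=y_arr[:, 0],
        S=y_arr[:, 1],
        P=y_arr[:, 2],
        Lac=y_arr[:, 3] if lactate else None,
        volume=np.asarray(vols),
        temperature=np.asarray(temps),
    )
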