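"""Design-matched synthetic culture datasets and noiseless golden fixtures.

The generator emulates the study design the shipped parameters came from:
shake-flask batches seeded at ~2e5 cells/mL in medium diluted to initial
glucose levels of 4.8/3.6/2.4/1.2 g/L, triplicates, daily sampling, 7-day
(r-CHO) or 10-day (n-CHO) duration, a lag phase for naive cells that
lengthens as the medium is diluted, a post-peak death phase, and fed-batch
bioreactor runs with five 10%-volume feeds and a temperature shift.

Measurement noise is applied to the sampled values only, never inside the
ODE: cell counts and mAb titers get multiplicative lognormal noise (counting
and ELISA errors scale with the value), glucose and lactate get additive
Gaussian noise (HPLC has a roughly constant detection error).  The same
seed always reproduces the same dataset bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_model import (
    CultureTimeSeries,
    KineticParameters,
    ParameterRegistry,
    default_registry,
    monod_mu,
)
from .simulate import FeedEvent, TemperatureShift, simulate_batch, simulate_fed_batch

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "generate_batch_dataset",
    "generate_fedbatch_dataset",
    "make_golden_fixtures",
    "fixture_params_rcho",
    "default_fedbatch_schedule",
]

# beyond-basic-model scaffolding used for realistic fixtures: first-order
# death after depletion, maintenance consumption sized so glucose empties
# ~2 days after the growth phase ends, and the lactate shuttle at the
# magnitudes seen in the study's rate tables
FIXTURE_K_D = 0.01          # 1/h
FIXTURE_M_S = 3e-9          # mg/cell/h: empties residual glucose ~day 6
FIXTURE_Y_LAC_X = 1.2e-7    # mg lactate per cell grown (~0.1 ng/cell/day at mu~0.035)
FIXTURE_Q_LAC_CONS = 0.05   # ng/cell/day, post-depletion


def fixture_params_rcho(base: KineticParameters | None = None) -> KineticParameters:
    """The r-CHO 33 C registry entry dressed with death/maintenance/lactate
    scaffolding, the default generator for realistic batch fixtures."""
    if base is None:
        base = default_registry().get("r-CHO", 33.0, "table2")
    return base.with_(
        k_d=FIXTURE_K_D,
        m_s=FIXTURE_M_S,
        y_lac_x=FIXTURE_Y_LAC_X,
        q_lac_cons=FIXTURE_Q_LAC_CONS,
    )


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings; all zero means noiseless."""

    cv_X: float = 0.05     # lognormal CV on cell counts
    sd_S: float = 0.05     # g/L additive on glucose
    sd_Lac: float = 0.05   # g/L additive on lactate
    cv_P: float = 0.10     # lognormal CV on mAb
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cv_X", "sd_S", "sd_Lac", "cv_P"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseModel":
        return cls(cv_X=0.0, sd_S=0.0, sd_Lac=0.0, cv_P=0.0, seed=seed)


# default lag times (h) for naive cells by S0 level: dilution lengthens lag
_NCHO_LAG_BY_S0 = {4.8: 0.0, 3.6: 24.0, 2.4: 48.0, 1.2: 48.0}


@dataclass(frozen=True)
class ExperimentDesign:
    """The batch study design: levels, seeding, sampling, duration, lag."""

    S0_levels: tuple[float, ...] = (4.8, 3.6, 2.4, 1.2)
    X0: float = 2e5                      # cells/mL
    replicates: int = 3
    sampling_interval: float = 24.0      # h
    duration: float | None = None        # h; default by cell line
    cell_line: str = "r-CHO"
    temperature: float = 33.0
    lag_by_S0: dict = field(default_factory=dict)  # h per S0 level

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.S0_levels):
            raise ValueError("S0 levels must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def duration_h(self) -> float:
        if self.duration is not None:
            return self.duration
        return 240.0 if self.cell_line == "n-CHO" else 168.0

    def lag_for(self, S0: float) -> float:
        if S0 in self.lag_by_S0:
            return self.lag_by_S0[S0]
        if self.cell_line == "n-CHO":
            return _NCHO_LAG_BY_S0.get(S0, 0.0)
        return 0.0

    @property
    def sample_times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_h + 1e-9, self.sampling_interval)


def _apply_noise(series: CultureTimeSeries, noise: NoiseModel,
                 rng: np.random.Generator) -> CultureTimeSeries:
    def lognorm(arr, cv):
        if cv == 0:
            return arr
        sigma = np.sqrt(np.log1p(cv**2))
        # mean-one multiplicative factors
        return arr * rng.lognormal(-0.5 * sigma**2, sigma, size=arr.shape)

    def additive(arr, sd):
        if sd == 0:
            return arr
        return np.maximum(arr + rng.normal(0.0, sd, size=arr.shape), 0.0)

    return CultureTimeSeries(
        time=series.time,
        X=lognorm(series.X, noise.cv_X),
        S=additive(series.S, noise.sd_S),
        Lac=None if series.Lac is None else additive(series.Lac, noise.sd_Lac),
        P=None if series.P is None else lognorm(series.P, noise.cv_P),
        volume=series.volume,
        temperature=series.temperature,
        cell_line=series.cell_line,
        condition=series.condition,
        replicate=series.replicate,
    )


def _simulate_with_lag(
    params: KineticParameters, X0: float, S0: float, t_lag: float,
    t_end: float, dt: float, sample_times: np.ndarray,
) -> CultureTimeSeries:
    """Batch trajectory with the culture held static until t_lag."""
    if t_lag <= 0:
        return simulate_batch(params, X0, S0, t_end, dt,
                              sample_times=sample_times)
    lagged = sample_times < t_lag
    post_times = sample_times[~lagged] - t_lag
    post = simulate_batch(params, X0, S0, t_end - t_lag, dt,
                          sample_times=post_times)
    n_lag = int(lagged.sum())

    def pad(arr, fill):
        if arr is None:
            return None
        return np.concatenate([np.full(n_lag, fill), arr])

    return CultureTimeSeries(
        time=sample_times,
        X=pad(post.X, X0),
        S=pad(post.S, S0),
        P=pad(post.P, 0.0),
        Lac=pad(post.Lac, 0.0),
    )


def generate_batch_dataset(
    design: ExperimentDesign,
    params: KineticParameters,
    noise: NoiseModel,
    dt: float = 0.1,
) -> list[CultureTimeSeries]:
    """Simulate the full batch design and sample it with measurement noise.

    Returns one series per (S0 level, replicate), deterministically seeded:
    each series draws from its own child stream of ``noise.seed``.
    """
    root = np.random.SeedSequence(noise.seed)
    children = root.spawn(len(design.S0_levels) * design.replicates)
    out: list[CultureTimeSeries] = []
    k = 0
    for S0 in design.S0_levels:
        truth = _simulate_with_lag(
            params, design.X0, S0, design.lag_for(S0),
            design.duration_h, dt, design.sample_times,
        )
        for rep in range(design.replicates):
            rng = np.random.default_rng(children[k])
            k += 1
            noisy = _apply_noise(truth, noise, rng)
            noisy.cell_line = design.cell_line
            noisy.condition = f"S0={S0:g}"
            noisy.replicate = str(rep + 1)
            out.append(noisy)
    return out


def default_fedbatch_schedule(
    V0: float = 1000.0, feed_glucose: float = 30.0
) -> tuple[list[FeedEvent], list[TemperatureShift]]:
    """The study's fed-batch protocol: five daily 10%-of-initial-volume
    feeds starting on day 1, and a temperature drop to 31 C on day 7."""
    feeds = [
        FeedEvent(time=24.0 * d, volume=0.1 * V0, glucose=feed_glucose)
        for d in range(1, 6)
    ]
    shifts = [TemperatureShift(time=24.0 * 7, temperature=31.0)]
    return feeds, shifts


def generate_fedbatch_dataset(
    design: ExperimentDesign,
    registry: ParameterRegistry,
    feeds: list[FeedEvent],
    shifts: list[TemperatureShift],
    noise: NoiseModel,
    *,
    S0: float = 4.8,
    V0: float = 1000.0,
    duration: float = 480.0,
    source: str = "table2",
    dt: float = 0.1,
) -> CultureTimeSeries:
    """One fed-batch series on the design's sampling grid, with noise."""
    sample_times = np.arange(0.0, duration + 1e-9, design.sampling_interval)
    truth = simulate_fed_batch(
        registry, design.cell_line, design.X0, S0, V0,
        feeds, shifts, duration, dt,
        temperature0=design.temperature, source=source,
    )
    # sample at the grid (nearest trajectory point)
    idx = np.searchsorted(truth.time, sample_times)
    idx = np.clip(idx, 0, truth.time.size - 1)
    sampled = CultureTimeSeries(
        time=sample_times,
        X=truth.X[idx], S=truth.S[idx], P=truth.P[idx],
        Lac=None if truth.Lac is None else truth.Lac[idx],
        volume=truth.volume[idx],
        temperature=truth.temperature[idx],
        cell_line=design.cell_line,
        condition=f"fed-batch S0={S0:g}",
        replicate="1",
    )
    rng = np.random.default_rng(np.random.SeedSequence(noise.seed))
    return _apply_noise(sampled, noise, rng)


def make_golden_fixtures(path: str | Path, dt: float = 0.1) -> dict:
    """Write the noiseless fixtures used by the acceptance checks.

    Writes, under ``path``: a Monod mu-vs-S0 table for every registry entry,
    a Luedeking-Piret product profile on a logistic-then-decline cell
    profile, an exponential-phase yield series, a post-depletion lactate
    series, and a JSON manifest of every generating parameter.  Output is a
    pure function of the shipped registry (bit-identical on regeneration).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    reg = default_registry()
    manifest: dict = {"registry": {}, "fixtures": {}}
    s0_grid = (4.8, 3.6, 2.4, 1.2)

    lines = ["cell_line,temperature_c,source,s0_g_per_l,mu_per_h"]
    for (cl, T, src), p in reg.items():
        manifest["registry"][f"{cl}|{T:g}|{src}"] = {
            "mu_max": p.mu_max, "K_s": p.K_s, "S_t": p.S_t, "Y_xs": p.Y_xs,
            "alpha": p.alpha, "beta": p.beta,
        }
        for s0 in s0_grid:
            mu = monod_mu(s0, p)
            lines.append(f"{cl},{T:g},{src},{s0},{mu!r}")
    (path / "monod_mu_tables.csv").write_text("\n".join(lines) + "\n")
    manifest["fixtures"]["monod_mu_tables.csv"] = {"S0_levels": list(s0_grid)}

    # LP product profile: logistic rise to plateau, then first-order decline
    p_rcho = reg.get("r-CHO", 33.0, "table2")
    t = np.arange(0.0, 240.0 + 1e-9, dt)
    X = logistic_decline_profile(t)
    r_x = np.gradient(X, t)
    from .core_model import euler_integrate_product

    P = euler_integrate_product(t, X, r_x, p_rcho, P0=0.0)
    rows = ["time_h,viable_cells_per_ml,r_x_cells_per_ml_h,mab_mg_per_l"]
    rows += [f"{ti!r},{xi!r},{ri!r},{pi!r}" for ti, xi, ri, pi in zip(t, X, r_x, P)]
    (path / "lp_product_profile.csv").write_text("\n".join(rows) + "\n")
    manifest["fixtures"]["lp_product_profile.csv"] = {
        "alpha": p_rcho.alpha, "beta": p_rcho.beta, "dt": dt,
        "profile": "logistic rise to 7e6 by 96 h, then 0.02/h decline",
    }

    # yield fixture: pure exponential phase at the undiluted-medium yield
    y_gen = 2.79e6
    p_yield = p_rcho.with_(Y_xs=y_gen, k_d=0.0, m_s=0.0)
    series = simulate_batch(p_yield, 2e5, 4.8, 96.0, dt,
                            sample_times=np.arange(0.0, 96.0 + 1e-9, 24.0))
    rows = ["time_h,viable_cells_per_ml,glucose_g_per_l"]
    rows += [f"{ti!r},{xi!r},{si!r}"
             for ti, xi, si in zip(series.time, series.X, series.S)]
    (path / "yield_phase_series.csv").write_text("\n".join(rows) + "\n")
    manifest["fixtures"]["yield_phase_series.csv"] = {
        "Y_xs": y_gen, "mu_max": p_rcho.mu_max, "K_s": p_rcho.K_s,
        "S_t": p_rcho.S_t, "X0": 2e5, "S0": 4.8,
    }

    # post-depletion lactate fixture: constant X, linear lactate decline
    lac = lactate_depletion_series()
    rows = ["time_h,viable_cells_per_ml,glucose_g_per_l,lactate_g_per_l"]
    rows += [f"{ti!r},{xi!r},{si!r},{li!r}"
             for ti, xi, si, li in zip(lac.time, lac.X, lac.S, lac.Lac)]
    (path / "lactate_depletion_series.csv").write_text("\n".join(rows) + "\n")
    manifest["fixtures"]["lactate_depletion_series.csv"] = {
        "q_lac_cons_ng_cell_day": FIXTURE_Q_LAC_CONS, "X": 2e6, "Lac0": 0.9,
    }

    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def logistic_decline_profile(
    t: np.ndarray,
    X0: float = 2e5,
    X_peak: float = 7e6,
    t_peak: float = 96.0,
    k_logistic: float = 0.1,
    k_decline: float = 0.02,
) -> np.ndarray:
    """Viable-cell profile: logistic rise to ~X_peak by t_peak, then
    first-order decline — the canonical shape of a producer batch culture."""
    t = np.asarray(t, dtype=float)
    A = (X_peak - X0) / X0
    rise = X_peak / (1.0 + A * np.exp(-k_logistic * t))
    X_at_peak = X_peak / (1.0 + A * np.exp(-k_logistic * t_peak))
    fall = X_at_peak * np.exp(-k_decline * (t - t_peak))
    return np.where(t <= t_peak, rise, fall)


def lactate_depletion_series(
    X: float = 2e6,
    Lac0: float = 0.9,
    q_cons: float = FIXTURE_Q_LAC_CONS,
    duration: float = 72.0,
    interval: float = 24.0,
) -> CultureTimeSeries:
    """Glucose-depleted phase with constant X and lactate consumed at a
    constant specific rate q_cons (ng/cell/day)."""
    t = np.arange(0.0, duration + 1e-9, interval)
    # ng/cell/day * cells/mL -> mg/mL/day == g/L/day
    dlac_per_h = q_cons * 1e-6 * X / 24.0
    lac = np.maximum(Lac0 - dlac_per_h * t, 0.0)
    return CultureTimeSeries(
        time=t,
        X=np.full_like(t, X),
        S=np.zeros_like(t),
        Lac=lac,
        cell_line="r-CHO",
        condition="post-depletion",
    )
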