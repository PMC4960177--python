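"""Domain types, closed-form kinetic laws, and the shipped parameter registry.

The growth model is a threshold-modified Monod law: the specific growth rate
``mu`` saturates in the above-threshold glucose concentration ``S - S_t`` and
is exactly zero at or below the threshold ``S_t``.  Product (mAb) formation
follows a Luedeking-Piret law, ``r_p = alpha * r_x + beta * X``, mixing a
growth-associated term and a biomass-associated term.

Canonical internal units throughout the package:

========================  =====================
time                      h
viable cell density X     cells/mL
glucose, lactate S, Lac   g/L  (== mg/mL)
mAb P                     mg/L (== ug/mL)
mu_max, k_d               1/h
K_s, S_t                  g/L
Y_xs                      cells/mg
alpha                     ug/cell
beta                      ug/cell/h
m_s                       mg/cell/h
========================  =====================

With these units no conversion factors appear inside the math:
``alpha * r_x`` and ``beta * X`` are both ug/mL/h == mg/L/h.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "KineticParameters",
    "ParameterRegistry",
    "CultureTimeSeries",
    "RateSeries",
    "FitResult",
    "monod_mu",
    "luedeking_piret_rate",
    "euler_integrate_product",
    "get_default_parameters",
    "default_registry",
    "load_registry",
    "dump_registry",
]

# r^2 floor above which the study's linearizations were accepted
R2_VALID_FLOOR = 0.97


@dataclass(frozen=True)
class KineticParameters:
    """One complete kinetic parameter set for a cell line at one temperature.

    ``k_d`` (first-order death after glucose depletion) and ``m_s``
    (maintenance glucose consumption) extend the basic model so simulated
    batches show the death phase and full glucose depletion seen in real
    cultures; both default to 0 (basic model).  Lactate production/consumption
    is optional and only used when the lactate sub-model is enabled.
    """

    mu_max: float            # 1/h
    K_s: float               # g/L
    S_t: float               # g/L
    Y_xs: float              # cells/mg
    alpha: float = 0.0       # ug/cell
    beta: float = 0.0        # ug/cell/h
    k_d: float = 0.0         # 1/h, active only when S <= S_t
    m_s: float = 0.0         # mg/cell/h
    y_lac_x: float | None = None      # mg lactate per cell grown
    q_lac_cons: float | None = None   # ng/cell/day, post-depletion

    def __post_init__(self) -> None:
        if not self.mu_max > 0:
            raise ValueError(f"mu_max must be > 0, got {self.mu_max}")
        if not self.K_s > 0:
            raise ValueError(f"K_s must be > 0, got {self.K_s}")
        if self.S_t < 0:
            raise ValueError(f"S_t must be >= 0, got {self.S_t}")
        if not self.Y_xs > 0:
            raise ValueError(f"Y_xs must be > 0, got {self.Y_xs}")
        for name in ("alpha", "beta", "k_d", "m_s"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def with_(self, **changes) -> "KineticParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class FitResult:
    """A parameter fit: estimates, goodness of fit, and a validity flag.

    ``valid`` follows the study's acceptance rule for linearizations
    (r^2 > 0.97); fits the study does not gate carry ``valid=True``.
    """

    estimates: Mapping[str, float]
    r_squared: float
    n_points: int
    valid: bool
    residuals: np.ndarray | None = None

    def __getitem__(self, key: str) -> float:
        return self.estimates[key]


@dataclass
class CultureTimeSeries:
    """One culture's sampled trajectory.

    Arrays share a strictly increasing time grid (h).  Missing measurements
    are NaN, never zero-filled.  ``volume`` and ``temperature`` are optional
    (fed-batch bookkeeping).
    """

    time: np.ndarray                     # h
    X: np.ndarray                        # cells/mL
    S: np.ndarray                        # g/L
    Lac: np.ndarray | None = None        # g/L
    P: np.ndarray | None = None          # mg/L
    volume: np.ndarray | None = None     # mL
    temperature: np.ndarray | None = None  # degC
    cell_line: str = ""
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size == 0:
            raise ValueError("time must be a non-empty 1-D array")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        for name in ("X", "S", "Lac", "P", "volume", "temperature"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.time.shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {self.time.shape}"
                )
            if name in ("X", "S", "Lac", "P", "volume"):
                if np.any(arr[np.isfinite(arr)] < 0):
                    raise ValueError(f"{name} contains negative values")
            setattr(self, name, arr)

    @property
    def n_samples(self) -> int:
        return self.time.size

    def variable(self, name: str) -> np.ndarray:
        """Return one measured variable by canonical name (X, S, Lac, P)."""
        arr = getattr(self, name, None)
        if arr is None:
            raise KeyError(f"series has no variable {name!r}")
        return arr

    def window_mask(self, t_start: float, t_end: float) -> np.ndarray:
        return (self.time >= t_start) & (self.time <= t_end)


@dataclass
class RateSeries:
    """Time-aligned derivatives of smoothed profiles.

    ``r_s`` is kept signed: negative while glucose is being consumed.
    ``provenance`` records the polynomial degree and window that produced
    each component.
    """

    time: np.ndarray                 # h
    r_x: np.ndarray | None = None    # cells/mL/h
    r_s: np.ndarray | None = None    # g/L/h (signed)
    r_p: np.ndarray | None = None    # mg/L/h
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Kinetic laws
# ---------------------------------------------------------------------------

def monod_mu(S, params: KineticParameters):
    """Threshold-Monod specific growth rate (1/h).

    mu = mu_max * (S - S_t) / (K_s + (S - S_t))   for S > S_t
    mu = 0                                        for S <= S_t

    Continuous at S = S_t, monotone in S, bounded by mu_max.
    Accepts a scalar or array glucose concentration in g/L.
    """
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise ValueError("glucose concentration must be >= 0")
    excess = S_arr - params.S_t
    mu = np.where(
        excess > 0,
        params.mu_max * excess / (params.K_s + np.where(excess > 0, excess, 1.0)),
        0.0,
    )
    if np.isscalar(S) or S_arr.ndim == 0:
        return float(mu)
    return mu


def luedeking_piret_rate(r_x, X, params: KineticParameters):
    """Volumetric mAb formation rate r_p = alpha*r_x + beta*X, in mg/L/h.

    r_x may be negative (death phase), in which case the growth-associated
    term reduces r_p; this is the literal model contract.
    """
    X_arr = np.asarray(X, dtype=float)
    if np.any(X_arr < 0):
        raise ValueError("cell density must be >= 0")
    rp = params.alpha * np.asarray(r_x, dtype=float) + params.beta * X_arr
    if np.isscalar(X) and np.isscalar(r_x):
        return float(rp)
    return rp


def euler_integrate_product(
    time: Sequence[float],
    X: Sequence[float],
    r_x: Sequence[float],
    params: KineticParameters,
    P0: float = 0.0,
) -> np.ndarray:
    """Forward-Euler integration of the Luedeking-Piret product balance.

    P_n = P_{n-1} + (alpha*r_x + beta*X) * dt, stepped on the input grid
    with left-endpoint rates; P is clamped at 0 (no product degradation
    in the model, so negative P is unphysical).  Returns P aligned to the
    input grid, P[0] = P0.
    """
    t = np.asarray(time, dtype=float)
    if t.size == 0:
        raise ValueError("empty profile")
    if not np.all(np.diff(t) > 0):
        raise ValueError("time must be strictly increasing")
    if P0 < 0:
        raise ValueError("P0 must be >= 0")
    X = np.asarray(X, dtype=float)
    r_x = np.asarray(r_x, dtype=float)
    if X.shape != t.shape or r_x.shape != t.shape:
        raise ValueError("time, X and r_x must have identical shapes")
    dt = np.diff(t)
    rate = params.alpha * r_x + params.beta * X
    increments = rate[:-1] * dt
    P = P0 + np.concatenate([[0.0], np.cumsum(increments)])
    if np.any(P < 0):
        # clamping is path-dependent; redo stepwise
        P = np.empty_like(t)
        P[0] = P0
        for i in range(1, t.size):
            P[i] = max(P[i - 1] + increments[i - 1], 0.0)
    return P


# ---------------------------------------------------------------------------
# Parameter registry
# ---------------------------------------------------------------------------

class ParameterRegistry:
    """Keyed store of shipped kinetic parameter sets.

    Keys are (cell_line, temperature_C, source).  ``source`` tags the origin
    of the numbers (e.g. ``table2`` vs ``fig3caption``) because the study
    reports conflicting fits for the same condition; the tags keep them
    separate and every report echoes which was used.  Missing keys raise,
    never default.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, float, str], KineticParameters] = {}

    def add(
        self, cell_line: str, temperature: float, source: str,
        params: KineticParameters,
    ) -> None:
        self._entries[(cell_line, float(temperature), source)] = params

    def get(self, cell_line: str, temperature: float, source: str) -> KineticParameters:
        key = (cell_line, float(temperature), source)
        try:
            return self._entries[key]
        except KeyError:
            available = ", ".join(
                f"({c}, {t:g}, {s})" for c, t, s in sorted(self._entries)
            )
            raise KeyError(
                f"no parameter set for {key}; available: {available}"
            ) from None

    def __contains__(self, key: tuple[str, float, str]) -> bool:
        c, t, s = key
        return (c, float(t), s) in self._entries

    def __iter__(self) -> Iterator[tuple[str, float, str]]:
        return iter(sorted(self._entries))

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return [(k, self._entries[k]) for k in sorted(self._entries)]


_OPTIONAL_FIELDS = ("alpha", "beta", "k_d", "m_s", "y_lac_x", "q_lac_cons")


def load_registry(text: str) -> ParameterRegistry:
    """Parse a TOML registry document into a :class:`ParameterRegistry`."""
    doc = tomllib.loads(text)
    reg = ParameterRegistry()
    for name, table in doc.items():
        kwargs = {
            "mu_max": table["mu_max"],
            "K_s": table["K_s"],
            "S_t": table["S_t"],
            "Y_xs": table["Y_xs"],
        }
        for f in _OPTIONAL_FIELDS:
            if f in table:
                kwargs[f] = table[f]
        reg.add(table["cell_line"], table["temperature"], table["source"],
                KineticParameters(**kwargs))
    return reg


def dump_registry(reg: ParameterRegistry) -> str:
    """Serialize a registry to TOML text (round-trips bit-identically)."""
    lines: list[str] = []
    for (cell_line, temperature, source), p in reg.items():
        section = f"{cell_line}_{temperature:g}C_{source}".replace("-", "_")
        lines.append(f"[{section}]")
        lines.append(f'cell_line = "{cell_line}"')
        lines.append(f"temperature = {temperature!r}")
        lines.append(f'source = "{source}"')
        for f in ("mu_max", "K_s", "S_t", "Y_xs"):
            lines.append(f"{f} = {getattr(p, f)!r}")
        for f in _OPTIONAL_FIELDS:
            v = getattr(p, f)
            if v is not None and v != 0.0:
                lines.append(f"{f} = {v!r}")
        lines.append("")
    return "\n".join(lines)


def _shipped_registry() -> ParameterRegistry:
    text = (
        resources.files("chokinetics").joinpath("data/parameters.toml")
        .read_text(encoding="utf-8")
    )
    return load_registry(text)


_DEFAULT_REGISTRY: ParameterRegistry | None = None


def default_registry() -> ParameterRegistry:
    """The shipped registry (loaded once from the packaged TOML file)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = _shipped_registry()
    return _DEFAULT_REGISTRY


def get_default_parameters(
    cell_line: str, temperature: float, source: str = "table2"
) -> KineticParameters:
    """Look up a shipped parameter set; unknown keys raise with the key list."""
    return default_registry().get(cell_line, temperature, source)
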