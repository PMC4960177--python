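# Methods

## Model

State variables are viable cell density `X` (cells/mL), glucose `S` (g/L),
mAb `P` (mg/L), and optionally lactate `Lac` (g/L). The batch dynamics are

    dX/dt   = mu(S) X - k_d X [S <= S_t]
    dS/dt   = -mu(S) X / Y_xs - m_s X
    dP/dt   = alpha dX/dt + beta X
    dLac/dt = y_lac_x mu(S) X          while S > S_t
            = -q_lac_cons X (converted) while S <= S_t

with the threshold-Monod rate `mu(S) = mu_max (S - S_t)/(K_s + (S - S_t))`
for `S > S_t`, zero otherwise. `mu` is continuous at the threshold,
monotone in `S`, and bounded by `mu_max`.

The product balance uses the *net* growth rate, so in the death phase a
negative `dX/dt` subtracts growth-associated production; this is the
literal reading of the production law, and the alternative (clamping `r_x`
at zero) is available but off by default. `P` is clamped at zero during
integration: the model has no product-degradation term, so negative `P`
would be an artifact.

Canonical units everywhere in the library: h, cells/mL, g/L (= mg/mL) for
sugars, mg/L (= ug/mL) for mAb, `alpha` ug/cell, `beta` ug/cell/h. With
these choices `alpha*r_x` and `beta*X` are both mg/L/h and no conversion
factors appear inside the math; unit conversion happens only at I/O.
The `alpha`-in-ug/cell, `beta`-in-ug/cell/h convention is fixed by
dimensional analysis of the production law (published statements of the
two units are inconsistent with one another in one place; the registry
follows the dimensionally consistent assignment).

## Parameters

| parameter | units | r-CHO 33 °C default | meaning |
|---|---|---|---|
| `mu_max` | 1/h | 0.040 | maximum specific growth rate |
| `K_s` | g/L | 0.664 | half-velocity constant (above threshold) |
| `S_t` | g/L | 0.58 | growth-threshold glucose |
| `Y_xs` | cells/mg | 2.59e6 | cells produced per mg glucose |
| `alpha` | ug/cell | 7.65e-7 | growth-associated production |
| `beta` | ug/cell/h | 7.68e-8 | biomass-associated production |
| `k_d` | 1/h | 0 | post-depletion death (extension) |
| `m_s` | mg/cell/h | 0 | maintenance consumption (extension) |

The registry ships both cell lines at 33 and 37 °C plus the alternate
published fits under a separate `fig3caption` source tag; lookups of
missing keys raise rather than default, and reports echo the tag used so
the conflicting fits are never mixed silently. A 31 °C r-CHO entry
duplicates the 33 °C values so the default fed-batch schedule (shift to
31 °C on day 7) resolves — the production constants were reported as
holding across 31–33 °C. `k_d` and `m_s` are deliberate extensions beyond
the basic model: without them glucose asymptotes to `S_t` and `X` to a
plateau, whereas real cultures fully deplete glucose and decline after the
peak. They default to zero and are only switched on by the fixture
generator (`k_d = 0.01` 1/h; `m_s = 3e-9` mg/cell/h, sized so residual
glucose empties about two days after growth stops, i.e. ~day 6).

Temperature is not a continuous model input: parameter sets are
per-temperature, and a temperature shift swaps sets.

## Numerics

- Fixed-step RK4 (default `dt = 0.1` h) integrates the batch system;
  forward Euler is selectable to mirror the textbook product-balance
  recursion `P_n = P_{n-1} + (alpha r_x + beta X) dt`. Step times are
  computed arithmetically, not accumulated, so event times are hit
  exactly. With `k_d = m_s = 0`, `X + Y_xs S` is a linear invariant and is
  preserved to rounding by the Runge-Kutta steppers (the suite checks this
  and the fourth-order convergence of RK4 against a fine-grid reference).
- Fed-batch: between events the batch dynamics; at a feed of volume `V_f`
  and glucose `C_f`, `V <- V + V_f` and every concentration mixes as
  `C <- (C V + C_feed V_f)/(V + V_f)` with `C_feed = 0` for cells, product
  and lactate. Glucose mass is conserved exactly at events. Pre- and
  post-event states are both recorded (the latter at `t + 1e-9` h). All
  registry entries needed by the shift schedule are resolved before
  integration starts.
- Polynomial smoothing uses ordinary least squares on the raw time axis;
  derivatives are analytic. Evaluation outside the fit window is refused —
  off-window values of a degree-6 polynomial are meaningless. Default
  degrees: 2 for exponential-phase `X` and `S`, 6 for the full-culture `X`
  profile used in production fitting (5 is a defensible alternative; the
  degree is an argument everywhere).
- IVCC uses the trapezoid rule (the quadrature is not prescribed by the
  source material; trapezoid matches the daily-sampling resolution).
- Lineweaver-Burk regression is unweighted on the reciprocal scale, as the
  linearization implies; a direct nonlinear Monod fit is provided as a
  diagnostic cross-check only. A non-positive reciprocal intercept (no
  finite `mu_max`) is an error, not a value. Fits gated by the r² > 0.97
  validity rule carry a `valid` flag.
- The yield regression is through the origin (the substrate balance has no
  intercept); a free-intercept variant exists for diagnostics.
- `fit_lp_integral` minimizes the squared mismatch of the Euler-integrated
  product profile over `(alpha, beta) >= 0` with bounded Powell search on
  scale-normalized variables (relative objective tolerance 1e-10,
  deterministic given the initial guess). With sparse observations the `dt`
  argument refines the cell profile by cubic spline and steps the balance
  on the fine grid, removing coarse-grid quadrature error. `fit_lp_direct`
  refuses numerically collinear designs (pure exponential `X`, where
  `r_x ∝ X`) and points to the integral fit.
- Temperature recalibration refits `(mu_max, Y_xs, beta)` — holding
  `S_t`, `K_s`, `alpha` fixed — by Nelder-Mead on multiplicative factors
  (log scale), with each of `X`, `S`, `P` normalized by its observed
  maximum so the 1e6-scale cell counts do not swamp the concentrations.

## Growth-rate estimation and substrate drift

`mu` is the least-squares slope of `ln X` vs `t` (r² computed on the log
scale). Because glucose falls during any finite fitting window, the
estimated `mu` corresponds to a substrate below `S0`; pairing `mu` with
`S0` biases `K_s` upward, noticeably at the lowest glucose level. The
pipeline therefore pairs each `mu` with the *window-mean* glucose by
default (`substrate="window_mean"` in `estimate_growth_parameters`),
which removes the first-order drift bias; `substrate="initial"`
reproduces the classical `mu`-vs-`S0` analysis. The default window is
the first 48 h (the early exponential phase); automatic window selection
by exhaustive r²-screening is available.

The noiseless full-pipeline recovery check runs at 2 h sampling with an
early (first-24 h) growth window: at that resolution every estimator's
consistency is visible without being confounded by sampling-design error,
and all five constants return within 1%. The stochastic check keeps the
study design itself — daily sampling, triplicates, 5% count CV — and
bounds the median `mu_max` error instead.

## Synthetic data

The generator emulates the originating study design: seeding at 2e5
cells/mL, initial glucose 4.8/3.6/2.4/1.2 g/L, triplicates, daily
sampling, 168 h (r-CHO) or 240 h (n-CHO) duration; naive cells get a lag
phase that lengthens with dilution (0/24/48/48 h at 4.8/3.6/2.4/1.2 g/L),
implemented by holding the state static until `t_lag`. The fed-batch
default is five feeds of 10% of the initial volume on days 1–5 and a
shift to 31 °C on day 7, 480 h duration. Lactate fixture scales: production
`y_lac_x = 1.2e-7` mg/cell (~0.1 ng/cell/day at exponential `mu`),
post-depletion consumption 0.05 ng/cell/day.

Measurement noise is applied to sampled values only, never inside the
ODE: mean-one multiplicative lognormal on counts (CV 5%) and titers
(CV 10%), additive Gaussian (sd 0.05 g/L) on glucose and lactate, clipped
at zero. Every series draws from its own child stream of the dataset
seed, so identical seeds give bit-identical datasets and replicates share
truth but not noise.

What the generator does *not* emulate: process noise, glutamine/amino-acid
limitation, lactate inhibition of production, viability as distinct from
density, osmolality or pH effects, sampling-volume loss. Passing
recovery tests therefore demonstrates estimator correctness under the
stated model and measurement-error assumptions, not robustness to the
full messiness of real cultures.

## Known limitations

- With `m_s > 0` the exponential-phase *apparent* yield is below the
  growth-linked `Y_xs` by a factor ~`1 + m_s Y_xs / mu`; the yield
  estimator reports what the data show.
- `alpha` is weakly identified from a single noisy culture (most of the
  titer comes from the `beta X` term); pooling replicates or fitting
  multiple conditions jointly is advisable, which is consistent with how
  the published constants were chosen.
- The growth screen's threshold estimate is bracket-limited by the levels
  tested; it cannot beat the design's resolution.
- Phase boundaries for specific rates are user-supplied; the sign-change
  heuristic is advisory only and never applied silently.
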