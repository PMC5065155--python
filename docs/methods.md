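# Methods

## Reaction system and observable

Each repair channel *i* (fast, slow, intermediate/A-EJ) is a two-step
mechanism on free double-strand breaks *x*:
recruitment `x + E_i -> y_i` with propensity `K_i · x · E_i`, then ligation
`y_i -> ∅ + E_i` with propensity `K'_i · y_i`.  The recruitment protein is
conserved per channel, `E_i = C_i − y_i`, so a channel's throughput is
limited both by substrate and by its own occupancy.  The system is
simulated exactly (Gillespie direct method, numba-compiled) with
piecewise-constant output sampling, which preserves integer semantics;
every ligation event time is recorded, giving exact per-break completion
times for the closed-form oracles.

The measured observable mirrors PFGE: a break counts as damage until it is
ligated, whether free or bound, so the signal is `(x + Σ_i y_i) · 0.0286`
Gy.  Initial condition: `x(0) = round(dose / 0.0286)`, all pools free.

**Rate conventions.**  Rates quoted at the dataset level (and everywhere in
configs and outputs) are per-break specific rates in hr⁻¹ — the scale on
which a channel's half-time reads `t_1/2 = ln 2 / K`.  Internally the SSA
uses pair-rate constants; `simulate_dataset` divides the recruitment
constant by the pool size (`K_sim = K / C_i`) so the initial per-break
recruitment hazard equals the configured K.  With the default
non-saturating pools `C_i = x0`, competition between channels then splits
breaks in proportion to their K's while the conservation structure still
produces self-crowding of slow channels (E_i falls as complexes
accumulate).  This convention is what makes the wild-type configuration
repair ~90% of breaks inside 2 h while the Ku-deficient configuration's
A-EJ half-maximum lands near 8 h — both properties of the fitted rates it
reproduces.

**Binding-only channels.**  A knockout downstream of the recruiting
protein (DNA-PKcs⁻/⁻ fast channel; Rad52⁻/⁻ slow channel) keeps
recruitment (governed by the dedicated hyperparameter μ₄) but has ligation
propensity identically zero.  Complexes persist, sequestering at most
`C_i` breaks; the measured curve then plateaus at the sequestered
fraction, which is the model's account of incomplete repair in those
lines.

## Hierarchical model

For dataset *d* and channel slot *s*, `log K_s^d ~ N(μ_assigned(s), σ²)`.
Recruitment and ligation of the same channel draw independently from the
same μ (one hyperparameter pair per channel).  Hyperpriors are uniform,
`μ_i ~ U(log 0.001, log 20)` — equal ranges for all four process means,
bracketing every plausible repair rate from ~min⁻¹ to ~days⁻¹.  σ² is
fixed at 0.25 (log-space sd 0.5, a coefficient of variation of ~53% across
knockout lines); it can instead be inferred under U(0.05, 1), which adds a
fifth coordinate to the SMC state.

## ABC sequential Monte Carlo

Each proposal follows the generative scheme: hyperparameters from the
prior (or perturbed from an ancestor), per-dataset rates redrawn fresh
from the hierarchy (this is the Monte-Carlo marginalisation of the rate
level), one SSA realisation per dataset, and a distance

    ρ = Σ_d (1 / dose_d) · sqrt( Σ_t (sim_d(t) − obs_d(t))² )

(dose-normalised so 20 Gy and 80 Gy panels contribute comparably).
Acceptance requires ρ ≤ ε; ε starts at ∞ (prior sampling) and then shrinks
to the median of the previous generation's accepted distances.  Only
hyperparameters are perturbed: a component-wise uniform kernel with
half-width equal to half the previous population's component range,
truncated to the prior by resampling.  Importance weights are the standard
SMC form (uniform prior ⇒ reciprocal kernel-mixture density); systematic
resampling restores uniform weights whenever the effective sample size
drops below N/2.  Evaluation is serial from a single generator stream, so
a run is bit-reproducible given its seed.

Defaults are N = 500 particles and 8 generations; the acceptance script
uses N = 400 and 7 generations as its scaled-down setting, and the quick
examples use 48–128 particles.  A generation aborts with a diagnostic if
its acceptance rate falls below 10⁻³.

## Model selection

Variants M1 (fast only), M2 (fast + slow), M3 (all three) are fitted with
identical schedules; excluded channels are set absent, which can leave a
knockout dataset with no channel at all — the resulting flat prediction is
deliberate, informative misfit.  Scores use a surrogate likelihood: a
Gaussian kernel in the per-dataset distance with bandwidth h equal to the
variant's own final ε, `loglik = Σ_d [−½(ρ_d/h)² − log h]`.  The −log h
term penalises variants whose SMC cannot drive ε down, which is exactly
the misfit signal of a model with too few processes; absolute values are
meaningless, only ranking is contractual.  AIC-like (−2·max loglik + 2k),
BIC-like (k·log n_obs) and DIC-like (mean deviance + p_D, with p_D
estimated against re-simulation at the posterior-mean hyperparameters) are
all reported, k counting the hyperparameters the variant actually uses.
Because bandwidths are per-variant, the epsilons must be given enough
generations to separate (≥8 on the full panel); the DIC ranking stabilises
earlier than the AIC ranking.  Per-variant RNG streams are derived from
(seed, label-hash) so duplicated variants score identically.

## Synthetic data generator

The generator emulates the eight-dataset knockout panel: doses 20–80 Gy,
the knockout/channel structure above, one SSA realisation per dataset at
the ground-truth rates (populations of 699–2797 breaks, so single-run
curves are already population-averaged), sampled on the default grid
{0, 0.25, 0.5, 1, 2, 4, 8, 12, 24} h, plus additive Gaussian noise of
sd = 5% of dose on the Gy axis (digitisation noise on traced curves is
roughly homoscedastic in Gy), truncated to [0, 1.2·dose].  Ground truth
defaults to the package's reference median rates; the full truth (rates,
seeds, noise sd) is emitted as a sidecar record.

What the generator does **not** emulate: real grids and replicate
structure of the original assays (unknown — the published curves were
traced from figures), gel-physics artefacts, break-complexity classes,
cell-cycle heterogeneity.  Passing recovery tests therefore demonstrate
the pipeline's correctness under the model's own assumptions, not fidelity
of the original data acquisition.

**Identifiability at the 24 h horizon.**  The fast and intermediate
processes (half-times of minutes to ~2 h) are fully resolved by this grid,
and their hyperparameters recover well.  The slow process has a two-step
half-time of 2–3 days: inside 24 h its curves decay only 10–20%, with
noise of similar size.  A direct Gaussian-likelihood computation
(marginalising the lognormal rate draws numerically) shows that the true
posterior for μ₂ under these conditions sits below the generating value —
with 0.04 hr⁻¹ truth, the exact posterior median of the slow rate is near
0.02 hr⁻¹ with IQR ≈ [0.015, 0.027] — because the flat log-uniform prior
leaves much more room on the too-slow side, where the data barely push
back.  The ABC posterior reproduces this; a recovered slow rate below the
generating value is the information content of the design, not an
inference bug.  Rate recovery assertions in the test suite therefore
target the identifiable (fast and intermediate) components.

## Numerical choices

- Grid sampling is last-event-holds (piecewise constant), never linear
  interpolation.
- The pathway-influx integral Ñ_i = ∫K_i x E_i dt is reported both as the
  exact recruitment event count and as a trapezoid quadrature over the
  output grid; the two agree within Monte-Carlo error on dense grids and
  the quadrature serves as an independent cross-check.
- Weighted posterior quantiles use empirical-CDF inversion with the lower
  interpolation convention.
- Half-maximum times use the channel's cumulative ligations (half of the
  ligations the channel will eventually perform), evaluated on the output
  grid.
- The 30%-activity rule counts bound complexes only (free breaks are not
  yet assigned to a mechanism) and uses a strict inequality.
- SSA seeds are 32-bit values drawn from the run's master generator;
  identical inputs and seed give bit-identical trajectories.

## Known limitations

- No spatial structure, no per-protein recruitment cascade, no
  break-complexity classes, no cross-talk/repression terms between
  channels.
- The surrogate likelihood is a declared substitute: its selection
  behaviour is validated, its absolute scale is not interpretable.
- Binding-only sequestration is irreversible (no unbinding reaction), so
  binding-only channels impose a hard plateau.
- The slow process is under-determined by the default observation window
  (see above); extending the grid beyond ~48 h would be needed to pin
  half-times of days.
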