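"""Hierarchical lognormal model linking knockout datasets to shared rates.

Each dataset d owns rate constants K_i^d, K'_i^d for its active channels,
but the datasets are not independent: the log-rates of a given repair mode
share a population-level mean.  Concretely

    mu_i      ~ U(alpha_i, beta_i)          i in {1..4}   (hyperprior)
    log K     ~ N(mu_assigned, sigma^2)                    (per parameter)

so K is lognormal with location mu and a common variance sigma^2.  mu_1,
mu_2, mu_3 govern the fast, slow and intermediate channels respectively;
mu_4 governs "binding-only" channels, where the recruitment protein still
binds breaks but downstream repair is knocked out.  Recruitment and
ligation of the same channel draw (independently) from the same mu.

Rates at this level are per-break specific rates in hr^-1, the scale on
which repair half-times read t_1/2 = ln2/K.  :func:`simulate_dataset`
converts them to the bimolecular convention of the SSA layer by dividing
the recruitment constant by the enzyme pool size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import reference
from .model import CHANNELS, RateParams, Trajectory, dose_to_dsb, simulate

MU_INDICES = (1, 2, 3, 4)


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class PathwaySpec:
    """One channel's role in one dataset.

    ``mode`` is ``full`` (recruitment + ligation), ``binding_only``
    (recruitment only, governed by mu_4) or ``absent``.  ``mu_recruit`` /
    ``mu_ligate`` are hyperparameter indices in 1..4.
    """

    channel: str
    mode: str
    mu_recruit: Optional[int] = None
    mu_ligate: Optional[int] = None

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.mode == "full":
            if self.mu_recruit not in MU_INDICES or self.mu_ligate not in MU_INDICES:
                raise ValueError(f"full channel {self.channel} needs mu indices")
        elif self.mode == "binding_only":
            if self.mu_recruit != 4 or self.mu_ligate is not None:
                raise ValueError("binding_only channels are governed by mu_4 only")
        elif self.mode == "absent":
            if self.mu_recruit is not None or self.mu_ligate is not None:
                raise ValueError("absent channels carry no hyperparameter indices")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_parameters(self) -> int:
        return {"full": 2, "binding_only": 1, "absent": 0}[self.mode]


@dataclass
class DatasetSpec:
    """One repair-curve experiment: design, time grid, observations, channels."""

    id: str
    dose_gy: float
    phase: str
    timepoints: np.ndarray
    pathways: dict
    observed: Optional[np.ndarray] = None
    pools: Optional[dict] = None  # per-channel enzyme pool override

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.observed is not None:
            self.observed = np.asarray(self.observed, dtype=float)

    def validate(self, require_active: bool = True) -> "DatasetSpec":
        if self.dose_gy <= 0:
            raise ValueError(f"{self.id}: dose must be positive")
        if self.timepoints.size == 0 or np.any(np.diff(self.timepoints) <= 0):
            raise ValueError(f"{self.id}: timepoints must be strictly increasing")
        if self.timepoints[0] < 0:
            raise ValueError(f"{self.id}: timepoints must start at or after 0")
        if require_active and not self.active_channels:
            raise ValueError(f"{self.id}: at least one channel must be active")
        if self.observed is not None:
            if self.observed.shape != self.timepoints.shape:
                raise ValueError(f"{self.id}: observed/timepoints length mismatch")
            if np.any(self.observed < 0) or np.any(self.observed > 1.2 * self.dose_gy):
                raise ValueError(
                    f"{self.id}: observed values must lie in [0, 1.2 * dose]"
                )
        return self

    @property
    def active_channels(self) -> tuple:
        return tuple(ch for ch in CHANNELS if self.pathways[ch].mode != "absent")

    @property
    def n_parameters(self) -> int:
        """Number of rate parameters the dataset contributes (2 per full
        channel, 1 per binding-only channel)."""
        return sum(self.pathways[ch].n_parameters for ch in CHANNELS)

    def with_observed(self, observed) -> "DatasetSpec":
        return DatasetSpec(
            id=self.id, dose_gy=self.dose_gy, phase=self.phase,
            timepoints=self.timepoints.copy(), pathways=dict(self.pathways),
            observed=np.asarray(observed, dtype=float),
            pools=dict(self.pools) if self.pools else None,
        )


@dataclass(frozen=True)
class HyperPrior:
    """Uniform hyperprior on the four log-rate means, mu_i ~ U(alpha_i, beta_i).

    ``sigma2`` is the lognormal variance in log-space: a fixed float by
    default, or an ``(lo, hi)`` interval to infer it under a uniform prior
    (it then becomes a fifth SMC coordinate).  Default bounds bracket
    per-break rates from 0.001 to 20 hr^-1 with equal ranges for every
    process.
    """

    alpha: np.ndarray = field(default_factory=lambda: np.full(4, np.log(1e-3)))
    beta: np.ndarray = field(default_factory=lambda: np.full(4, np.log(20.0)))
    sigma2: object = 0.25

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.alpha.shape != (4,) or self.beta.shape != (4,):
            raise ValueError("alpha and beta must have one bound per mu index")
        if np.any(self.alpha >= self.beta):
            raise ValueError("require alpha_i < beta_i")
        if self.infer_sigma2:
            lo, hi = self.sigma2
            if not (0 < lo < hi):
                raise ValueError("sigma2 interval must satisfy 0 < lo < hi")
        elif not float(self.sigma2) > 0:
            raise ValueError("sigma2 must be positive")

    @property
    def infer_sigma2(self) -> bool:
        return isinstance(self.sigma2, (tuple, list))

    @property
    def n_free(self) -> int:
        return 5 if self.infer_sigma2 else 4

    def theta_bounds(self):
        """Lower/upper bounds of the flat SMC parameter vector."""
        if self.infer_sigma2:
            lo, hi = self.sigma2
            return (np.append(self.alpha, lo), np.append(self.beta, hi))
        return (self.alpha.copy(), self.beta.copy())

    def sample_theta(self, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.theta_bounds()
        return rng.uniform(lo, hi)

    def theta_to_hyperparams(self, theta) -> "HyperParams":
        theta = np.asarray(theta, dtype=float)
        if self.infer_sigma2:
            return HyperParams(mu=theta[:4], sigma2=float(theta[4]))
        return HyperParams(mu=theta[:4], sigma2=float(self.sigma2))


@dataclass(frozen=True)
class HyperParams:
    """Population-level parameters: log-rate means mu_1..mu_4 and sigma^2."""

    mu: np.ndarray
    sigma2: float = 0.25

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        if self.mu.shape != (4,):
            raise ValueError("mu must hold four components")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


def default_pathway_config() -> dict:
    """The eight-dataset channel/hyperparameter map as ``{id: {channel: PathwaySpec}}``."""
    out = {}
    for did in reference.DATASET_IDS:
        row = {}
        for ch in CHANNELS:
            mode, mu = reference.PATHWAY_TABLE[did][ch]
            if mode == "full":
                row[ch] = PathwaySpec(ch, "full", mu_recruit=mu, mu_ligate=mu)
            elif mode == "binding_only":
                row[ch] = PathwaySpec(ch, "binding_only", mu_recruit=4)
            else:
                row[ch] = PathwaySpec(ch, "absent")
        out[did] = row
    return out


def default_dataset_specs(timepoints=None) -> dict:
    """Skeleton :class:`DatasetSpec` per dataset (no observations attached)."""
    from .synthetic import default_timepoints

    table = default_pathway_config()
    tp = np.asarray(timepoints, dtype=float) if timepoints is not None else default_timepoints()
    return {
        did: DatasetSpec(
            id=did, dose_gy=reference.DOSES_GY[did], phase=reference.PHASES[did],
            timepoints=tp.copy(), pathways=table[did],
        ).validate()
        for did in reference.DATASET_IDS
    }


def sample_hyperparams(prior: HyperPrior, seed_or_rng) -> HyperParams:
    """Draw mu (and sigma^2 if inferred) from the uniform hyperprior."""
    rng = _as_rng(seed_or_rng)
    return prior.theta_to_hyperparams(prior.sample_theta(rng))


def sample_rates(hp: HyperParams, spec: DatasetSpec, seed_or_rng) -> RateParams:
    """Draw the dataset's per-break rates from the hierarchical lognormal.

    Each required slot gets an independent ``exp(N(mu_assigned, sigma^2))``
    draw; binding-only channels draw recruitment only, absent channels
    nothing.  Draw order is fixed (channel order, K before K') so results
    are reproducible for a given generator state.
    """
    rng = _as_rng(seed_or_rng)
    sd = float(np.sqrt(hp.sigma2))
    channels = {}
    for ch in CHANNELS:
        ps = spec.pathways[ch]
        if ps.mode == "absent":
            continue
        k = float(np.exp(rng.normal(hp.mu[ps.mu_recruit - 1], sd)))
        if ps.mode == "full":
            kp = float(np.exp(rng.normal(hp.mu[ps.mu_ligate - 1], sd)))
        else:
            kp = 0.0
        channels[ch] = (k, kp, ps.mode)
    return RateParams.from_channels(channels)


def pools_for(spec: DatasetSpec) -> np.ndarray:
    """Enzyme pool per channel: the dataset's initial break count by default
    (non-saturating), zero for absent channels, overridable via ``spec.pools``."""
    x0 = dose_to_dsb(spec.dose_gy)
    C = np.zeros(len(CHANNELS), dtype=np.int64)
    for i, ch in enumerate(CHANNELS):
        if spec.pathways[ch].mode == "absent":
            continue
        C[i] = (spec.pools or {}).get(ch, x0)
    return C


def to_bimolecular(rates: RateParams, C) -> RateParams:
    """Convert per-break recruitment rates to SSA pair-rate constants.

    With pool C_i and propensity K_sim * x * E_i, choosing K_sim = K / C_i
    makes the initial per-break recruitment hazard equal K (E_i starts at
    C_i), so the configured rates keep their half-time reading ln2/K.
    Ligation is already per-complex and passes through unchanged.
    """
    C = np.asarray(C, dtype=float)
    K = np.where(C > 0, rates.K / np.where(C > 0, C, 1.0), 0.0)
    return RateParams(K, rates.Kprime.copy(), rates.mode)


def simulate_dataset(
    spec: DatasetSpec, rates: RateParams, seed: int, t_grid=None
) -> Trajectory:
    """Simulate one dataset at per-break rates ``rates``.

    Initial condition x(0) = dose_to_dsb(dose), all pools free.  The output
    grid defaults to the dataset's timepoints.
    """
    x0 = dose_to_dsb(spec.dose_gy)
    C = pools_for(spec)
    sim_rates = to_bimolecular(rates, C)
    grid = spec.timepoints if t_grid is None else np.asarray(t_grid, dtype=float)
    return simulate(sim_rates, x0, C, grid, seed)
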