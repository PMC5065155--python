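"""Likelihood-free sequential Monte Carlo inference of the hyperparameters.

The sampler targets the hyperparameter posterior pi_eps(gamma | D) jointly
over all datasets.  Each proposal follows the generative scheme

    gamma ~ prior (or perturbed ancestor)      -> mu_1..mu_4 (, sigma^2)
    K     ~ LN(mu_assigned, sigma^2)           fresh for every dataset slot
    D*    ~ SSA(K)                             one realisation per dataset

and is accepted when the summed, dose-normalised Euclidean distance between
simulated and observed curves falls below the generation's epsilon.  Only
the hyperparameters are perturbed between generations; the rate draws are
always resampled from the (perturbed) hierarchy, which marginalises the K
level implicitly.  Epsilon shrinks adaptively to a quantile (default the
median) of the previous generation's accepted distances.  Importance
weights follow the standard SMC form w ~ pi(gamma) / sum_j w_j K(gamma |
gamma_j), here with a component-wise uniform perturbation kernel whose
half-width is half the previous population's component range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hierarchy import DatasetSpec, HyperPrior, sample_rates, simulate_dataset
from .model import CHANNELS, measured_curve

logger = logging.getLogger("dsbrepair.abc")

#: Table-style column stem per channel: K1 = fast, K2 = slow, K3 = aej.
_CHANNEL_NUM = {"fast": 1, "slow": 2, "aej": 3}


def per_dataset_distance(sim, obs, dose_gy: float, normalise: bool = True) -> float:
    """Euclidean distance between one simulated and observed curve,
    divided by the dose so differently-dosed datasets contribute comparably."""
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("simulated and observed grids do not match")
    d = float(np.sqrt(np.sum((sim - obs) ** 2)))
    return d / dose_gy if normalise else d


def distance(simulated: dict, observed: dict, doses: Optional[dict] = None) -> float:
    """Summed dose-normalised distance over datasets.

    ``simulated`` and ``observed`` map dataset id to curves on identical
    grids; ``doses`` maps id to dose in Gy (omit to skip normalisation).
    Symmetric, and zero iff every curve pair is identical.
    """
    if set(simulated) != set(observed):
        raise ValueError("simulated and observed dataset ids do not match")
    total = 0.0
    for did in simulated:
        dose = doses[did] if doses is not None else 1.0
        total += per_dataset_distance(simulated[did], observed[did], dose, normalise=True)
    return total


@dataclass(frozen=True)
class SMCSchedule:
    """Population size, generation count and epsilon policy.

    ``epsilons`` fixes the schedule explicitly (strictly decreasing);
    otherwise the next epsilon is the ``quantile`` of the previous
    generation's accepted distances.  Generation 1 always samples from the
    prior (epsilon = inf).  ``replicates`` averages the distance over that
    many SSA runs per proposal (same rate draw).
    """

    n_particles: int = 500
    n_generations: int = 8
    quantile: float = 0.5
    epsilons: Optional[Sequence[float]] = None
    replicates: int = 1
    min_acceptance: float = 1e-3
    max_proposals_per_generation: Optional[int] = None

    def __post_init__(self):
        if self.n_particles < 2:
            raise ValueError("need at least two particles")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must lie in (0, 1)")
        if self.n_generations < 1:
            raise ValueError("need at least one generation")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.epsilons is not None:
            eps = np.asarray(self.epsilons, dtype=float)
            if np.any(np.diff(eps) >= 0):
                raise ValueError("explicit epsilon sequence must be strictly decreasing")


def perturb(theta, prev_thetas, bounds, rng: np.random.Generator, max_tries: int = 10000):
    """Uniform-kernel proposal centred on ``theta``.

    The component half-width is half the previous population's range;
    proposals outside the prior box are resampled.  A population with zero
    spread returns the particle unchanged.
    """
    theta = np.asarray(theta, dtype=float)
    prev = np.asarray(prev_thetas, dtype=float)
    lo, hi = bounds
    h = 0.5 * (prev.max(axis=0) - prev.min(axis=0))
    if np.all(h == 0):
        return theta.copy()
    for _ in range(max_tries):
        prop = theta + rng.uniform(-h, h)
        if np.all(prop >= lo) and np.all(prop <= hi):
            return prop
    raise RuntimeError("perturbation kernel failed to land inside the prior support")


def _kernel_half_width(prev_thetas) -> np.ndarray:
    prev = np.asarray(prev_thetas, dtype=float)
    return 0.5 * (prev.max(axis=0) - prev.min(axis=0))


def smc_weights(cur_thetas, prev_thetas, prev_weights) -> np.ndarray:
    """Normalised importance weights for the current population.

    Under the uniform hyperprior the numerator is constant, so the weight is
    the reciprocal kernel mixture density at each particle.  ``prev_thetas``
    of None marks the first generation (uniform weights).
    """
    cur = np.asarray(cur_thetas, dtype=float)
    n = cur.shape[0]
    if prev_thetas is None:
        return np.full(n, 1.0 / n)
    prev = np.asarray(prev_thetas, dtype=float)
    w_prev = np.asarray(prev_weights, dtype=float)
    h = _kernel_half_width(prev)
    dens = np.empty(n)
    # component factor: 1/(2h) inside the kernel box; degenerate components
    # (h == 0) contribute a unit factor when the offset is exactly zero.
    for i in range(n):
        diff = np.abs(cur[i] - prev)  # (n_prev, d)
        inside = np.ones(prev.shape[0], dtype=bool)
        val = np.ones(prev.shape[0])
        for c in range(cur.shape[1]):
            if h[c] > 0:
                inside &= diff[:, c] <= h[c] + 1e-12
                val /= 2.0 * h[c]
            else:
                inside &= diff[:, c] == 0.0
        dens[i] = np.sum(w_prev[inside] * val[inside])
    if np.any(dens <= 0):
        raise RuntimeError(
            "zero kernel density under an accepted particle -- perturbation "
            "kernel support bug"
        )
    w = 1.0 / dens
    return w / w.sum()


def _systematic_resample(weights, rng: np.random.Generator) -> np.ndarray:
    n = len(weights)
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


@dataclass
class PosteriorEnsemble:
    """Weighted hyperparameter particles with their attached rate draws."""

    thetas: np.ndarray            # (N, d): mu1..mu4 (, sigma2)
    weights: np.ndarray           # (N,)
    distances: np.ndarray         # (N,)
    per_dataset: np.ndarray       # (N, n_datasets) per-dataset distances
    rate_K: dict                  # dataset id -> (N, 3) recruitment draws
    rate_Kprime: dict             # dataset id -> (N, 3) ligation draws
    datasets: list                # list[DatasetSpec], fixed order
    prior: HyperPrior
    eps_history: list = field(default_factory=list)
    acceptance_history: list = field(default_factory=list)
    seed: Optional[int] = None

    @property
    def n_particles(self) -> int:
        return self.thetas.shape[0]

    @property
    def dataset_ids(self) -> list:
        return [d.id for d in self.datasets]

    def hyperparams(self, i: int):
        return self.prior.theta_to_hyperparams(self.thetas[i])

    @staticmethod
    def weighted_quantile(values, weights, q) -> np.ndarray:
        """Weighted empirical-CDF inversion, lower-interpolation convention."""
        values = np.asarray(values, dtype=float)
        order = np.argsort(values)
        v = values[order]
        cw = np.cumsum(np.asarray(weights, dtype=float)[order])
        cw /= cw[-1]
        idx = np.searchsorted(cw, np.atleast_1d(q), side="left")
        out = v[np.clip(idx, 0, len(v) - 1)]
        return out if np.ndim(q) else float(out[0])

    def posterior_median_rate(self, dataset_id: str, channel: str, prime: bool = False) -> float:
        """Weighted posterior median of an attached per-dataset rate draw."""
        store = self.rate_Kprime if prime else self.rate_K
        vals = store[dataset_id][:, CHANNELS.index(channel)]
        if np.all(np.isnan(vals)):
            raise ValueError(f"{dataset_id} has no {'K prime' if prime else 'K'} for {channel}")
        return float(self.weighted_quantile(vals, self.weights, 0.5))

    def resample_indices(self, n: int, seed) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return rng.choice(self.n_particles, size=n, p=self.weights)

    def to_dataframe(self) -> pd.DataFrame:
        """Posterior table: particle_id, mu1..mu4, sigma2, weight, distance,
        plus per-dataset rate columns named like ``K1D1`` / ``K1D1p``."""
        n = self.n_particles
        cols = {"particle_id": np.arange(n)}
        for j in range(4):
            cols[f"mu{j + 1}"] = self.thetas[:, j]
        if self.prior.infer_sigma2:
            cols["sigma2"] = self.thetas[:, 4]
        else:
            cols["sigma2"] = np.full(n, float(self.prior.sigma2))
        cols["weight"] = self.weights
        cols["distance"] = self.distances
        for k, spec in enumerate(self.datasets):
            cols[f"dist_{spec.id}"] = self.per_dataset[:, k]
        for spec in self.datasets:
            for ch in CHANNELS:
                ps = spec.pathways[ch]
                if ps.mode == "absent":
                    continue
                stem = f"K{_CHANNEL_NUM[ch]}{spec.id}"
                cols[stem] = self.rate_K[spec.id][:, CHANNELS.index(ch)]
                if ps.mode == "full":
                    cols[stem + "p"] = self.rate_Kprime[spec.id][:, CHANNELS.index(ch)]
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, datasets, prior: HyperPrior) -> "PosteriorEnsemble":
        n = len(df)
        d = prior.n_free
        thetas = np.column_stack([df[f"mu{j + 1}"].to_numpy() for j in range(4)])
        if prior.infer_sigma2:
            thetas = np.column_stack([thetas, df["sigma2"].to_numpy()])
        assert thetas.shape == (n, d)
        rate_K, rate_Kp = {}, {}
        per_ds = np.column_stack(
            [df[f"dist_{s.id}"].to_numpy() for s in datasets]
        ) if f"dist_{datasets[0].id}" in df else np.full((n, len(datasets)), np.nan)
        for spec in datasets:
            K = np.full((n, len(CHANNELS)), np.nan)
            Kp = np.full((n, len(CHANNELS)), np.nan)
            for ch in CHANNELS:
                ps = spec.pathways[ch]
                if ps.mode == "absent":
                    continue
                stem = f"K{_CHANNEL_NUM[ch]}{spec.id}"
                K[:, CHANNELS.index(ch)] = df[stem].to_numpy()
                if ps.mode == "full":
                    Kp[:, CHANNELS.index(ch)] = df[stem + "p"].to_numpy()
            rate_K[spec.id] = K
            rate_Kp[spec.id] = Kp
        return cls(
            thetas=thetas, weights=df["weight"].to_numpy().astype(float),
            distances=df["distance"].to_numpy().astype(float), per_dataset=per_ds,
            rate_K=rate_K, rate_Kprime=rate_Kp, datasets=list(datasets), prior=prior,
        )


def _evaluate(theta, datasets, prior, rng, replicates):
    """Simulate every dataset under one hyperparameter draw.

    Returns (total distance, per-dataset distances, K draws, K' draws).
    Rates are drawn once; the distance is averaged over ``replicates`` SSA
    runs with those rates.
    """
    hp = prior.theta_to_hyperparams(theta)
    n_ds = len(datasets)
    per_ds = np.zeros(n_ds)
    K = np.full((n_ds, len(CHANNELS)), np.nan)
    Kp = np.full((n_ds, len(CHANNELS)), np.nan)
    for k, spec in enumerate(datasets):
        rates = sample_rates(hp, spec, rng)
        for i, ch in enumerate(CHANNELS):
            ps = spec.pathways[ch]
            if ps.mode == "absent":
                continue
            K[k, i] = rates.K[i]
            if ps.mode == "full":
                Kp[k, i] = rates.Kprime[i]
        acc = 0.0
        for _ in range(replicates):
            traj = simulate_dataset(spec, rates, seed=int(rng.integers(2**32)))
            acc += per_dataset_distance(measured_curve(traj), spec.observed, spec.dose_gy)
        per_ds[k] = acc / replicates
    return float(per_ds.sum()), per_ds, K, Kp


def fit(
    datasets,
    prior: Optional[HyperPrior] = None,
    schedule: Optional[SMCSchedule] = None,
    seed: int = 0,
) -> PosteriorEnsemble:
    """Run ABC SMC on one or more observed datasets.

    Deterministic for a given seed (evaluation is serial from a single
    generator stream).  Raises ``RuntimeError`` if a generation's acceptance
    rate collapses below ``schedule.min_acceptance``.
    """
    # model-selection variants may strip a dataset of all its channels (the
    # flat curve is then an informative misfit), so activity is not required
    datasets = [d.validate(require_active=False) for d in datasets]
    if not datasets:
        raise ValueError("need at least one dataset")
    for d in datasets:
        if d.observed is None:
            raise ValueError(f"dataset {d.id} has no observed curve")
    prior = prior or HyperPrior()
    schedule = schedule or SMCSchedule()
    rng = np.random.default_rng(seed)
    n = schedule.n_particles
    max_prop = schedule.max_proposals_per_generation or max(
        int(np.ceil(n / schedule.min_acceptance)), 10 * n
    )
    bounds = prior.theta_bounds()
    d_free = prior.n_free

    thetas = np.empty((n, d_free))
    dists = np.empty(n)
    per_ds = np.empty((n, len(datasets)))
    Ks = np.empty((n, len(datasets), len(CHANNELS)))
    Kps = np.empty((n, len(datasets), len(CHANNELS)))
    eps_history, acc_history = [], []
    prev_thetas = prev_weights = None
    weights = np.full(n, 1.0 / n)
    eps = np.inf

    for gen in range(1, schedule.n_generations + 1):
        if gen > 1:
            if schedule.epsilons is not None:
                eps = float(schedule.epsilons[min(gen - 2, len(schedule.epsilons) - 1)])
            else:
                eps = float(np.quantile(dists, schedule.quantile))
            prev_thetas, prev_weights = thetas.copy(), weights.copy()
        accepted = 0
        proposals = 0
        new_thetas = np.empty_like(thetas)
        new_dists = np.empty_like(dists)
        new_per = np.empty_like(per_ds)
        new_K = np.empty_like(Ks)
        new_Kp = np.empty_like(Kps)
        while accepted < n:
            proposals += 1
            if proposals > max_prop:
                raise RuntimeError(
                    f"generation {gen}: acceptance rate fell below "
                    f"{schedule.min_acceptance:g} ({accepted}/{proposals} at "
                    f"epsilon={eps:.4g}); loosen the schedule or add particles"
                )
            if gen == 1:
                theta = prior.sample_theta(rng)
            else:
                anc = rng.choice(n, p=prev_weights)
                theta = perturb(prev_thetas[anc], prev_thetas, bounds, rng)
            dist, pd_, K, Kp = _evaluate(theta, datasets, prior, rng, schedule.replicates)
            if dist <= eps:
                new_thetas[accepted] = theta
                new_dists[accepted] = dist
                new_per[accepted] = pd_
                new_K[accepted] = K
                new_Kp[accepted] = Kp
                accepted += 1
        thetas, dists, per_ds, Ks, Kps = new_thetas, new_dists, new_per, new_K, new_Kp
        weights = smc_weights(thetas, prev_thetas, prev_weights)
        ess = 1.0 / np.sum(weights**2)
        if ess < n / 2:
            idx = _systematic_resample(weights, rng)
            thetas, dists, per_ds = thetas[idx], dists[idx], per_ds[idx]
            Ks, Kps = Ks[idx], Kps[idx]
            weights = np.full(n, 1.0 / n)
        eps_history.append(eps)
        acc_history.append(accepted / proposals)
        logger.info(
            "generation %d: epsilon=%.4g acceptance=%.3f ess=%.1f",
            gen, eps, accepted / proposals, ess,
        )

    rate_K = {spec.id: Ks[:, k, :] for k, spec in enumerate(datasets)}
    rate_Kp = {spec.id: Kps[:, k, :] for k, spec in enumerate(datasets)}
    return PosteriorEnsemble(
        thetas=thetas, weights=weights, distances=dists, per_dataset=per_ds,
        rate_K=rate_K, rate_Kprime=rate_Kp, datasets=datasets, prior=prior,
        eps_history=eps_history, acceptance_history=acc_history, seed=seed,
    )
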