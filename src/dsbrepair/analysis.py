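"""Posterior and trajectory analyses downstream of the SMC fit.

Covers the questions the fitted model is actually asked: how many breaks
each mechanism handles (the cumulative pathway influx, both as exact event
counts and as the quadrature of K x E over the output grid), posterior
predictive repair curves with credible envelopes, channel half-maximum
repair times, the time-resolved share of in-process breaks per pathway,
threshold-based activity timelines, knockout re-simulation, and
Kolmogorov-Smirnov comparisons between posterior samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abc_smc import PosteriorEnsemble
from .hierarchy import DatasetSpec, sample_rates, simulate_dataset
from .model import CHANNELS, Trajectory, measured_curve

QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)
_QLABEL = {0.025: "q025", 0.25: "q25", 0.5: "q50", 0.75: "q75", 0.975: "q975"}


@dataclass
class MechanismTally:
    """Cumulative pathway usage for one trajectory.

    ``n_entered[i]`` counts recruitment firings into channel i (the
    event-count realisation of the pathway-influx integral), ``completed``
    counts ligations, ``quadrature`` is the trapezoid value of
    ``K_i x E_i`` over the output grid, and ``proportions`` divides entries
    by the initial break count.
    """

    n_entered: np.ndarray
    completed: np.ndarray
    quadrature: np.ndarray
    x0: int
    x_final: int

    @property
    def proportions(self) -> np.ndarray:
        return self.n_entered / self.x0 if self.x0 else np.zeros(len(CHANNELS))

    @property
    def unentered(self) -> int:
        """Breaks never recruited by any channel (still free at the end)."""
        return self.x_final


def tally_mechanisms(traj: Trajectory) -> MechanismTally:
    """Count DSBs entering each pathway, with a quadrature cross-check.

    The quadrature integrates the recruitment propensity over the grid and
    equals the expected event count; on dense grids the two routes agree to
    within Monte-Carlo error.
    """
    E = traj.C[None, :] - traj.y
    flux = traj.params.K[None, :] * traj.x[:, None] * E
    quad = np.trapezoid(flux, traj.t, axis=0)
    return MechanismTally(
        n_entered=traj.n_recruit[-1].copy(),
        completed=traj.n_ligate[-1].copy(),
        quadrature=quad,
        x0=traj.x0,
        x_final=int(traj.x[-1]),
    )


def _draw_trajectories(ensemble, spec, grid, n_draws, seed, zero_channels=()):
    """Resample particles by weight, draw fresh rates, re-simulate."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(ensemble.n_particles, size=n_draws, p=ensemble.weights)
    trajs, rate_list = [], []
    for i in idx:
        hp = ensemble.hyperparams(i)
        rates = sample_rates(hp, spec, rng)
        if zero_channels:
            rates = rates.with_zeroed(zero_channels)
        traj = simulate_dataset(spec, rates, seed=int(rng.integers(2**32)), t_grid=grid)
        trajs.append(traj)
        rate_list.append(rates)
    return trajs, rate_list


def predictive_bands(
    ensemble: PosteriorEnsemble,
    spec: DatasetSpec,
    grid=None,
    n_draws: int = 200,
    seed: int = 0,
    zero_channels=(),
) -> pd.DataFrame:
    """Posterior predictive repair curve with credible envelopes.

    Particles are resampled by weight, per-dataset rates are redrawn from
    each particle's hyperparameters and the system re-simulated; pointwise
    quantiles (0.025, 0.25, 0.5, 0.75, 0.975) of the dose-equivalent
    observable are returned as a tidy frame.
    """
    if n_draws < 10:
        raise ValueError("need at least 10 posterior draws for bands")
    grid = np.asarray(grid, dtype=float) if grid is not None else spec.timepoints
    trajs, _ = _draw_trajectories(ensemble, spec, grid, n_draws, seed, zero_channels)
    curves = np.stack([measured_curve(t) for t in trajs])
    out = {"time_hr": grid}
    for q in QUANTILES:
        out[_QLABEL[q]] = np.quantile(curves, q, axis=0)
    return pd.DataFrame(out)


def channel_knockout_resim(
    ensemble: PosteriorEnsemble,
    spec: DatasetSpec,
    channels_to_zero,
    grid=None,
    n_draws: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Predictive bands with the listed channels' rates forced to zero.

    Used to ask what the remaining mechanisms alone could achieve (e.g.
    A-EJ capacity when NHEJ and SSA are silenced in silico).
    """
    return predictive_bands(
        ensemble, spec, grid=grid, n_draws=n_draws, seed=seed,
        zero_channels=tuple(channels_to_zero),
    )


def time_to_half_max(traj: Trajectory, channel: str) -> float:
    """Earliest grid time by which a channel has completed half of all the
    ligations it will eventually perform.  Requires a full channel."""
    i = CHANNELS.index(channel)
    if traj.params.mode[i] != "full":
        raise ValueError(f"channel {channel} is {traj.params.mode[i]}, not full")
    final = traj.n_ligate[-1, i]
    if final == 0:
        return float("nan")
    hit = np.nonzero(traj.n_ligate[:, i] >= 0.5 * final)[0]
    return float(traj.t[hit[0]])


def half_max_ensemble(
    ensemble: PosteriorEnsemble,
    spec: DatasetSpec,
    channel: str,
    grid=None,
    n_draws: int = 100,
    seed: int = 0,
) -> dict:
    """Posterior distribution of the half-maximum time: median and 0.5 CR."""
    grid = np.asarray(grid, dtype=float) if grid is not None else spec.timepoints
    trajs, _ = _draw_trajectories(ensemble, spec, grid, n_draws, seed)
    times = np.array([time_to_half_max(t, channel) for t in trajs])
    times = times[~np.isnan(times)]
    return {
        "median": float(np.median(times)),
        "q25": float(np.quantile(times, 0.25)),
        "q75": float(np.quantile(times, 0.75)),
        "n": int(times.size),
    }


def occupancy_series(traj: Trajectory) -> np.ndarray:
    """Share of in-process (bound) breaks per channel over time, shape
    (n_t, 3).  Rows with no bound breaks are all zero."""
    total = traj.y.sum(axis=1).astype(float)
    shares = np.zeros_like(traj.y, dtype=float)
    nz = total > 0
    shares[nz] = traj.y[nz] / total[nz, None]
    return shares


def activity_from_trajectories(trajs, threshold: float = 0.30):
    """Boolean activity matrix over draws: channel i is active at time t
    when it holds strictly more than ``threshold`` of the bound breaks."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    return np.stack([occupancy_series(t).T > threshold for t in trajs])


def activity_timeline(
    ensemble: PosteriorEnsemble,
    spec: DatasetSpec,
    grid=None,
    n_draws: int = 100,
    seed: int = 0,
    threshold: float = 0.30,
) -> dict:
    """Per-draw activity matrix plus the summaries used to relate activity
    duration to repair rate.

    Returns ``active`` of shape (n_draws, 3, n_t), the recruitment rates of
    each draw (n_draws, 3) and each draw's total active duration per
    channel in hours (n_draws, 3).
    """
    grid = np.asarray(grid, dtype=float) if grid is not None else spec.timepoints
    trajs, rate_list = _draw_trajectories(ensemble, spec, grid, n_draws, seed)
    active = activity_from_trajectories(trajs, threshold)
    dt = np.diff(grid, append=grid[-1])
    durations = (active * dt[None, None, :]).sum(axis=2)
    rates = np.stack([r.K for r in rate_list])
    return {"time_hr": grid, "active": active, "rates": rates, "durations": durations}


def ks_two_sample(samples_a, samples_b):
    """Two-sided two-sample Kolmogorov-Smirnov test.

    Returns ``(D, p)``.  Weighted posterior samples should be resampled to
    unweighted first (see :func:`resample_unweighted`).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 8 or b.size < 8:
        raise ValueError("need at least 8 points per sample")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def resample_unweighted(values, weights, size: int, seed: int = 0) -> np.ndarray:
    """Draw an unweighted sample from a weighted empirical distribution."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    return rng.choice(values, size=size, p=w / w.sum())
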