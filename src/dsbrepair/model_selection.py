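"""Comparison of one-, two- and three-process repair models.

The nested variants M1 (fast only), M2 (fast + slow) and M3 (fast + slow +
intermediate) are each fitted with the same SMC schedule, and scored with
information criteria built on a surrogate likelihood: a Gaussian kernel in
the summed curve distance rho with bandwidth h equal to the variant's
final-generation epsilon,

    loglik(particle) = sum_d [ -0.5 (rho_d / h)^2 - log h ].

Absolute values of this pseudo-likelihood are not meaningful; the contract
is selection behaviour.  The -log h term penalises variants whose SMC run
cannot drive epsilon down, which is exactly the misfit signal of a model
with too few processes.  AIC-like, BIC-like and DIC-like scores are all
reported; lower is better throughout.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abc_smc import PosteriorEnsemble, SMCSchedule, _evaluate, fit
from .hierarchy import DatasetSpec, HyperPrior, PathwaySpec
from .model import CHANNELS


@dataclass(frozen=True)
class ModelVariant:
    """A nested channel subset applied to every dataset."""

    label: str
    channels: tuple

    def __post_init__(self):
        for ch in self.channels:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")

    def restrict(self, spec: DatasetSpec) -> DatasetSpec:
        """Copy of ``spec`` with excluded channels set absent.

        Datasets may end up with no active channel (a flat predicted
        curve); that misfit is informative for selection, so no activity
        check is applied here.
        """
        pathways = {}
        for ch in CHANNELS:
            ps = spec.pathways[ch]
            if ch in self.channels:
                pathways[ch] = ps
            else:
                pathways[ch] = PathwaySpec(ch, "absent")
        return DatasetSpec(
            id=spec.id, dose_gy=spec.dose_gy, phase=spec.phase,
            timepoints=spec.timepoints.copy(), pathways=pathways,
            observed=None if spec.observed is None else spec.observed.copy(),
            pools=dict(spec.pools) if spec.pools else None,
        )


M1 = ModelVariant("M1", ("fast",))
M2 = ModelVariant("M2", ("fast", "slow"))
M3 = ModelVariant("M3", ("fast", "slow", "aej"))


def variant_hyper_indices(variant: ModelVariant, datasets) -> tuple:
    """Hyperparameter indices a variant actually uses across the datasets;
    its count is the free-parameter number k in the penalised scores."""
    used = set()
    for spec in datasets:
        restricted = variant.restrict(spec)
        for ch in CHANNELS:
            ps = restricted.pathways[ch]
            if ps.mu_recruit is not None:
                used.add(ps.mu_recruit)
            if ps.mu_ligate is not None:
                used.add(ps.mu_ligate)
    return tuple(sorted(used))


def surrogate_loglik(per_dataset_rho, bandwidth: float):
    """Gaussian-kernel pseudo-log-likelihood, summed over the last axis.

    Monotone decreasing in every rho; maximal (per dataset, at fixed h) at
    rho = 0.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    rho = np.asarray(per_dataset_rho, dtype=float)
    ll = -0.5 * (rho / bandwidth) ** 2 - np.log(bandwidth)
    return ll.sum(axis=-1)


def _variant_seed(seed: int, label: str) -> int:
    # stable per-label stream: duplicated variants score identically
    return (int(seed) * 1000003 + zlib.crc32(label.encode())) % (2**31)


def score_ensemble(
    ensemble: PosteriorEnsemble,
    k: int,
    n_obs: int,
    deviance_replicates: int = 5,
    seed: int = 0,
) -> dict:
    """AIC-, BIC- and DIC-like scores for one fitted variant.

    The deviance is -2x the surrogate log-likelihood with bandwidth h =
    final epsilon; the DIC effective-parameter penalty is p_D = mean
    deviance - deviance at the posterior-mean hyperparameters (estimated by
    re-simulating ``deviance_replicates`` times).
    """
    h = float(ensemble.eps_history[-1])
    if not np.isfinite(h):
        # single-generation fit: fall back to the median accepted distance
        h = float(np.median(ensemble.distances))
    ll = surrogate_loglik(ensemble.per_dataset, h)
    max_ll = float(np.max(ll))
    dev = -2.0 * ll
    dbar = float(np.sum(ensemble.weights * dev))
    theta_bar = ensemble.weights @ ensemble.thetas
    rng = np.random.default_rng(seed)
    dev_hat = []
    for _ in range(deviance_replicates):
        _, per_ds, _, _ = _evaluate(theta_bar, ensemble.datasets, ensemble.prior, rng, 1)
        dev_hat.append(-2.0 * float(surrogate_loglik(per_ds, h)))
    dhat = float(np.mean(dev_hat))
    p_d = dbar - dhat
    return {
        "k": k,
        "max_loglik": max_ll,
        "aic": -2.0 * max_ll + 2.0 * k,
        "bic": -2.0 * max_ll + k * np.log(n_obs),
        "dic": dbar + p_d,
        "p_d": p_d,
        "final_eps": h,
    }


def compare_models(
    variants,
    datasets,
    prior: HyperPrior = None,
    schedule: SMCSchedule = None,
    seed: int = 0,
    deviance_replicates: int = 5,
):
    """Fit every variant with an identical schedule and tabulate scores.

    Returns ``(table, ensembles)`` where ``table`` is a DataFrame with one
    row per variant (lower scores are better) and ``ensembles`` maps label
    to the fitted :class:`PosteriorEnsemble`.
    """
    prior = prior or HyperPrior()
    schedule = schedule or SMCSchedule()
    datasets = list(datasets)
    n_obs = sum(d.timepoints.size for d in datasets)
    rows, ensembles = [], {}
    for variant in variants:
        restricted = [variant.restrict(d) for d in datasets]
        vseed = _variant_seed(seed, variant.label)
        ens = fit(restricted, prior=prior, schedule=schedule, seed=vseed)
        k = len(variant_hyper_indices(variant, datasets))
        scores = score_ensemble(
            ens, k=k, n_obs=n_obs,
            deviance_replicates=deviance_replicates, seed=vseed + 1,
        )
        rows.append({"model": variant.label, **scores})
        ensembles[variant.label] = ens
    return pd.DataFrame(rows), ensembles
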