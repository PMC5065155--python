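"""Published reference values for the eight knockout repair-curve datasets.

The package's study system is a panel of eight PFGE repair experiments,
D1-D8, spanning wild-type and knockout cell lines (DNA-PKcs, Rad52, Ku70,
PARP-1 inhibition) at doses of 20-80 Gy.  This module freezes, as plain
data:

* the experimental design (dose, cell-cycle phase) per dataset,
* which repair channel is active / binding-only / absent in each dataset
  and which population-level hyperparameter (mu_1..mu_4) each rate maps to,
* the fitted posterior median rate constants with their interquartile
  (0.5) credible regions, used as default ground truth by the synthetic
  generator and as the reference surface for recovery checks.

Rates are per-break specific rates in hr^-1.  A ``binding_only`` channel
("dagger" convention: the recruitment protein binds but downstream repair
is genetically ablated) has a recruitment rate governed by the shared
hyperparameter mu_4 and no ligation rate.
"""

from __future__ import annotations

DATASET_IDS = ("D1", "D2", "D3", "D4", "D5", "D6", "D7", "D8")

#: Radiation dose (Gy) per dataset.
DOSES_GY = {
    "D1": 20.0, "D2": 20.0, "D3": 20.0, "D4": 80.0,
    "D5": 80.0, "D6": 54.0, "D7": 52.0, "D8": 32.0,
}

#: Cell-cycle phase of the assayed population.
PHASES = {
    "D1": "asynchronous", "D2": "G1", "D3": "G2", "D4": "asynchronous",
    "D5": "asynchronous", "D6": "asynchronous", "D7": "asynchronous",
    "D8": "asynchronous",
}

#: Mutant / treatment behind each dataset (documentation only).
GENOTYPES = {
    "D1": "wild type MEF",
    "D2": "DNA-PKcs -/- MEF (G1)",
    "D3": "DNA-PKcs -/- MEF (G2)",
    "D4": "Rad52 -/- DT40",
    "D5": "Ku70 -/- / Rad54 -/- DT40",
    "D6": "Ku70 -/- DT40",
    "D7": "Ku70 -/- MEF + PARP-1 inhibitor (DPQ)",
    "D8": "wild type MEF + PARP-1 inhibitor (3'-AB)",
}

#: Channel configuration per dataset: ``{channel: (mode, mu_index)}`` where
#: ``mu_index`` is the hyperparameter governing the channel's rates (None
#: for absent channels).  Binding-only channels are always governed by mu_4.
PATHWAY_TABLE = {
    "D1": {"fast": ("full", 1), "slow": ("full", 2), "aej": ("full", 3)},
    "D2": {"fast": ("binding_only", 4), "slow": ("full", 2), "aej": ("full", 3)},
    "D3": {"fast": ("binding_only", 4), "slow": ("full", 2), "aej": ("full", 3)},
    "D4": {"fast": ("full", 1), "slow": ("binding_only", 4), "aej": ("full", 3)},
    "D5": {"fast": ("absent", None), "slow": ("full", 2), "aej": ("full", 3)},
    "D6": {"fast": ("absent", None), "slow": ("full", 2), "aej": ("full", 3)},
    "D7": {"fast": ("absent", None), "slow": ("full", 2), "aej": ("absent", None)},
    "D8": {"fast": ("full", 1), "slow": ("full", 2), "aej": ("absent", None)},
}

#: Posterior median recruitment rates K (hr^-1) with 0.5 credible regions,
#: ``{dataset: {channel: (median, (q25, q75))}}``.  Binding-only channels
#: appear here (their recruitment still fires); absent channels do not.
MEDIAN_K = {
    "D1": {"fast": (3.06, (1.9, 5.36)), "slow": (0.04, (0.022, 0.078)), "aej": (0.34, (0.19, 0.62))},
    "D2": {"fast": (0.05, (0.023, 0.094)), "slow": (0.037, (0.019, 0.067)), "aej": (0.4, (0.26, 0.63))},
    "D3": {"fast": (0.04, (0.022, 0.081)), "slow": (0.038, (0.021, 0.08)), "aej": (0.5, (0.31, 0.84))},
    "D4": {"fast": (2.24, (1.52, 3.56)), "slow": (0.056, (0.027, 0.11)), "aej": (0.45, (0.26, 0.75))},
    "D5": {"slow": (0.066, (0.034, 0.13)), "aej": (0.22, (0.13, 0.42))},
    "D6": {"slow": (0.057, (0.03, 0.102)), "aej": (0.29, (0.16, 0.53))},
    "D7": {"slow": (0.042, (0.022, 0.077))},
    "D8": {"fast": (2.34, (1.75, 3.16)), "slow": (0.048, (0.03, 0.092))},
}

#: Posterior median ligation rates K' (hr^-1) with 0.5 credible regions.
#: Binding-only channels have no ligation rate and do not appear.
MEDIAN_KPRIME = {
    "D1": {"fast": (2.87, (2.03, 4.49)), "slow": (0.04, (0.024, 0.08)), "aej": (0.4, (0.22, 0.65))},
    "D2": {"slow": (0.041, (0.021, 0.08)), "aej": (0.62, (0.4, 0.97))},
    "D3": {"slow": (0.041, (0.023, 0.08)), "aej": (0.91, (0.58, 1.33))},
    "D4": {"fast": (4.35, (3.07, 6.57)), "aej": (0.29, (0.19, 0.46))},
    "D5": {"slow": (0.025, (0.016, 0.046)), "aej": (0.16, (0.12, 0.31))},
    "D6": {"slow": (0.034, (0.02, 0.058)), "aej": (0.19, (0.15, 0.28))},
    "D7": {"slow": (0.022, (0.015, 0.032))},
    "D8": {"fast": (3.2, (2.6, 4.4)), "slow": (0.041, (0.022, 0.085))},
}


def median_rate_params(dataset_id: str):
    """Reference-median :class:`~dsbrepair.model.RateParams` for a dataset.

    Per-break rates; binding-only channels get their (mu_4-scale) median
    recruitment rate and zero ligation; absent channels get zeros.
    """
    from .model import CHANNELS, RateParams

    channels = {}
    for ch in CHANNELS:
        mode, _ = PATHWAY_TABLE[dataset_id][ch]
        if mode == "absent":
            continue
        k = MEDIAN_K[dataset_id][ch][0]
        kp = MEDIAN_KPRIME[dataset_id][ch][0] if mode == "full" else 0.0
        channels[ch] = (k, kp, mode)
    return RateParams.from_channels(channels)
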