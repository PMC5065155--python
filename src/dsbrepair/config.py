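"""Structured-text configuration: datasets, channel modes and priors.

A config file is a YAML document with three top-level keys -- ``prior``
(uniform hyperprior bounds on the rate scale plus sigma^2), a shared
``timepoints_hr`` grid, and ``datasets`` (id, dose, phase, per-channel mode
and hyperparameter index, optional per-dataset timepoints and pools).  The
packaged default reproduces the eight-knockout study design.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .hierarchy import DatasetSpec, HyperPrior, PathwaySpec
from .model import CHANNELS


def _parse_prior(raw: dict) -> HyperPrior:
    lo = float(raw.get("rate_lower_hr", 1e-3))
    hi = float(raw.get("rate_upper_hr", 20.0))
    sigma2 = raw.get("sigma2", 0.25)
    if isinstance(sigma2, (list, tuple)):
        sigma2 = tuple(float(v) for v in sigma2)
    else:
        sigma2 = float(sigma2)
    return HyperPrior(
        alpha=np.full(4, np.log(lo)), beta=np.full(4, np.log(hi)), sigma2=sigma2
    )


def _parse_dataset(raw: dict, default_timepoints) -> DatasetSpec:
    pathways = {}
    channels = raw.get("channels", {})
    for ch in CHANNELS:
        if ch not in channels:
            pathways[ch] = PathwaySpec(ch, "absent")
            continue
        entry = channels[ch]
        mode = entry.get("mode", "full")
        if mode == "absent":
            pathways[ch] = PathwaySpec(ch, "absent")
        elif mode == "binding_only":
            pathways[ch] = PathwaySpec(ch, "binding_only", mu_recruit=4)
        else:
            mu = int(entry["mu"])
            pathways[ch] = PathwaySpec(ch, "full", mu_recruit=mu, mu_ligate=mu)
    tp = raw.get("timepoints_hr", default_timepoints)
    return DatasetSpec(
        id=str(raw["id"]),
        dose_gy=float(raw["dose_gy"]),
        phase=str(raw.get("phase", "asynchronous")),
        timepoints=np.asarray(tp, dtype=float),
        pathways=pathways,
        pools=raw.get("pools"),
    ).validate()


def parse_config(doc: dict) -> dict:
    """Parse a loaded YAML document into ``{'prior': HyperPrior,
    'datasets': {id: DatasetSpec}}``."""
    default_tp = doc.get("timepoints_hr", [0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0])
    specs = {}
    for raw in doc.get("datasets", []):
        spec = _parse_dataset(raw, default_tp)
        if spec.id in specs:
            raise ValueError(f"duplicate dataset id {spec.id}")
        specs[spec.id] = spec
    return {"prior": _parse_prior(doc.get("prior", {})), "datasets": specs}


def load_config(path) -> dict:
    """Load and parse a YAML config file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc)


def default_config() -> dict:
    """The packaged default study configuration."""
    text = resources.files("dsbrepair").joinpath("data/default_config.yaml").read_text()
    return parse_config(yaml.safe_load(text))


def write_default_config(path) -> Path:
    """Copy the packaged default config to ``path`` (for editing)."""
    text = resources.files("dsbrepair").joinpath("data/default_config.yaml").read_text()
    path = Path(path)
    path.write_text(text)
    return path
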