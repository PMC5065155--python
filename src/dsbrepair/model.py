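"""Stochastic three-process model of DNA double-strand-break repair.

A population of DSBs (count ``x``) is processed by up to three competing
repair channels -- fast (NHEJ-like), slow (SSA-like) and intermediate
(A-EJ-like).  Each channel is a two-step mechanism: a recruitment protein
binds a free break to form a complex ``y_i`` and the complex is then
resolved by ligation, releasing the protein.  The enzyme pool of each
channel is conserved (``E_i = C_i - y_i``), so channels compete both for
substrate and against their own occupancy.

The system is simulated exactly with the Gillespie algorithm.  The
observable mirrors pulsed-field gel electrophoresis: a break registers as
damage until it is ligated, so the measured signal is
``(x + sum_i y_i)`` converted to a dose equivalent in Gray via the
calibration 1 DSB = 0.0286 Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._ssa import ssa_core

#: Dose-equivalent of a single double-strand break (Gray per DSB).
GY_PER_DSB = 0.0286

#: Canonical channel order used for every per-channel array in the package.
CHANNELS = ("fast", "slow", "aej")

#: Valid per-channel modes.  ``binding_only`` models a knockout in which the
#: recruitment protein still binds breaks but downstream repair is ablated:
#: the ligation propensity is identically zero and complexes persist.
MODES = ("full", "binding_only", "absent")


def dose_to_dsb(dose_gy: float) -> int:
    """Number of DSBs induced by an X-ray dose, 1 DSB per 0.0286 Gy.

    Rounded to the nearest integer; the inverse is :func:`dsb_to_dose`.
    """
    if dose_gy < 0:
        raise ValueError(f"dose must be non-negative, got {dose_gy} Gy")
    return int(round(dose_gy / GY_PER_DSB))


def dsb_to_dose(n_dsb) -> float:
    """Dose equivalent (Gy) of a DSB count."""
    return np.asarray(n_dsb, dtype=float) * GY_PER_DSB if np.ndim(n_dsb) else float(n_dsb) * GY_PER_DSB


def half_time(rate: float) -> float:
    """Half time ``t_1/2 = ln(2) / K`` of a first-order process (hours)."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate <= 0):
        raise ValueError("rate constant must be positive")
    out = np.log(2.0) / rate
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RateParams:
    """Per-channel rate constants in canonical ``(fast, slow, aej)`` order.

    ``K`` is the recruitment rate constant and ``Kprime`` the ligation rate
    constant (both hr^-1).  At the propensity level ``K`` acts on the pair
    product ``x * E_i`` (bimolecular convention); the dataset layer in
    :mod:`dsbrepair.hierarchy` converts table-scale per-break rates into
    this convention by dividing by the pool size.
    """

    K: np.ndarray
    Kprime: np.ndarray
    mode: tuple = ("full", "full", "full")

    def __post_init__(self):
        object.__setattr__(self, "K", np.asarray(self.K, dtype=float))
        object.__setattr__(self, "Kprime", np.asarray(self.Kprime, dtype=float))
        object.__setattr__(self, "mode", tuple(self.mode))
        if self.K.shape != (len(CHANNELS),) or self.Kprime.shape != (len(CHANNELS),):
            raise ValueError("K and Kprime must have one entry per channel")
        for i, m in enumerate(self.mode):
            if m not in MODES:
                raise ValueError(f"unknown mode {m!r}")
            if m == "absent":
                if self.K[i] != 0 or self.Kprime[i] != 0:
                    raise ValueError(f"absent channel {CHANNELS[i]} must have zero rates")
            elif m == "binding_only":
                if self.K[i] <= 0 or self.Kprime[i] != 0:
                    raise ValueError(
                        f"binding_only channel {CHANNELS[i]} needs K > 0 and Kprime == 0"
                    )
            else:
                if self.K[i] <= 0 or self.Kprime[i] <= 0:
                    raise ValueError(f"full channel {CHANNELS[i]} needs positive rates")

    @classmethod
    def from_channels(cls, channels: dict) -> "RateParams":
        """Build from ``{channel: (K, Kprime, mode)}``; missing channels are absent."""
        K = np.zeros(len(CHANNELS))
        Kp = np.zeros(len(CHANNELS))
        mode = []
        for i, ch in enumerate(CHANNELS):
            k, kp, m = channels.get(ch, (0.0, 0.0, "absent"))
            K[i], Kp[i] = k, kp
            mode.append(m)
        return cls(K, Kp, tuple(mode))

    def with_zeroed(self, channels) -> "RateParams":
        """Copy with the listed channels knocked out (rates set to zero)."""
        K = self.K.copy()
        Kp = self.Kprime.copy()
        mode = list(self.mode)
        for ch in channels:
            i = CHANNELS.index(ch)
            K[i] = 0.0
            Kp[i] = 0.0
            mode[i] = "absent"
        return RateParams(K, Kp, tuple(mode))


@dataclass
class SystemState:
    """Instantaneous integer state: free breaks, complexes, conserved pools."""

    x: int
    y: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int64)
        self.C = np.asarray(self.C, dtype=np.int64)
        if self.x < 0 or np.any(self.y < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.E < 0):
            raise ValueError("enzyme conservation violated: y exceeds pool C")

    @property
    def E(self) -> np.ndarray:
        """Free enzyme per channel, ``E_i = C_i - y_i`` (conservation)."""
        return self.C - self.y


def propensities(state: SystemState, params: RateParams) -> np.ndarray:
    """Reaction propensities ``[recruit_fast, recruit_slow, recruit_aej,
    ligate_fast, ligate_slow, ligate_aej]`` (events per hour).

    Recruitment channel i fires at ``K_i * x * E_i``; ligation at
    ``K'_i * y_i``.  Degenerate states simply yield zeros.
    """
    rec = params.K * state.x * state.E
    lig = params.Kprime * state.y
    return np.concatenate([rec, lig]).astype(float)


@dataclass
class Trajectory:
    """One SSA realisation sampled on an output grid.

    Grid arrays hold the state immediately before the first event after each
    grid time (piecewise-constant interpolation, preserving integer
    semantics).  ``ligation_times``/``ligation_channels`` record every
    completed break exactly.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray                 # (n_t, 3)
    n_recruit: np.ndarray         # (n_t, 3) cumulative recruitment firings
    n_ligate: np.ndarray          # (n_t, 3) cumulative ligation firings
    ligation_times: np.ndarray
    ligation_channels: np.ndarray
    x0: int
    C: np.ndarray
    params: RateParams = field(repr=False)

    @property
    def remaining(self) -> np.ndarray:
        """Breaks still measurable at each grid time: free plus bound."""
        return self.x + self.y.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_hr": self.t, "x": self.x}
        for i, ch in enumerate(CHANNELS):
            cols[f"y_{ch}"] = self.y[:, i]
        for i, ch in enumerate(CHANNELS):
            cols[f"cum_ligated_{ch}"] = self.n_ligate[:, i]
        cols["dose_equiv_gy"] = measured_curve(self)
        return pd.DataFrame(cols)


def simulate(params: RateParams, x0: int, C, t_grid, seed: int) -> Trajectory:
    """Exact Gillespie realisation of the repair system.

    Parameters
    ----------
    params
        Rate constants in the bimolecular convention of :func:`propensities`.
    x0
        Initial number of free DSBs; ``y_i(0) = 0``.
    C
        Conserved enzyme pool per channel (zero for absent channels).
    t_grid
        Strictly increasing output times in hours, starting at 0.
    seed
        Integer seed; identical inputs and seed give bit-identical output.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid must not be empty")
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")
    if x0 < 0:
        raise ValueError("x0 must be non-negative")
    C = np.asarray(C, dtype=np.int64)
    if C.shape != (len(CHANNELS),) or np.any(C < 0):
        raise ValueError("C must hold a non-negative pool per channel")
    x_out, y_out, nrec, nlig, lig_t, lig_ch = ssa_core(
        int(x0), params.K, params.Kprime, C, t_grid, int(seed) & 0xFFFFFFFF
    )
    return Trajectory(
        t=t_grid, x=x_out, y=y_out, n_recruit=nrec, n_ligate=nlig,
        ligation_times=lig_t, ligation_channels=lig_ch,
        x0=int(x0), C=C, params=params,
    )


def measured_curve(traj: Trajectory) -> np.ndarray:
    """PFGE-style observable: dose equivalent (Gy) of still-broken DNA.

    A break contributes until it is ligated, whether free or bound in a
    repair complex, so the signal is ``(x + sum_i y_i) * 0.0286``.
    """
    return traj.remaining * GY_PER_DSB
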