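"""Host human ventricular cell model (TNNP 2006) with Markov-chain IKs.

This module owns the state layout, initial conditions and parameter
packing for the compiled kernels in :mod:`sqt2sim._kernels`.  The native
slow delayed-rectifier gate of the host model is replaced by the
17-state Markov IKs open probability; everything else (fast Na+, L-type
Ca2+ with subspace dynamics, transient outward, rapid delayed rectifier,
inward rectifier, pumps and exchangers, ion concentrations) follows the
published 2006 formulation with its EPI / MIDDLE / ENDO variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Optional, Tuple

import numpy as np

from . import _kernels as K
from .iks_markov import (
    GENOTYPES,
    IKsParams,
    steady_state,
    wt_params,
    v307l_params,
    edge_arrays,
)

__all__ = [
    "CELL_TYPES",
    "CellModel",
    "PacingSpec",
    "default_gks",
    "STIM_AMPLITUDE",
    "STIM_DURATION",
]

CELL_TYPES = ("ENDO", "MIDDLE", "EPI")
_CT_CODE = {"ENDO": K.ENDO, "MIDDLE": K.MIDDLE, "EPI": K.EPI}

#: supra-threshold stimulus used everywhere (host-model convention)
STIM_AMPLITUDE = -52.0  # pA/pF, inward
STIM_DURATION = 1.0     # ms

# resting initial conditions of the published model (1 Hz, EPI)
_Y0 = {
    "V": -86.2, "m": 0.0, "h": 0.75, "j": 0.75, "d": 0.0, "f": 1.0,
    "f2": 1.0, "fcass": 1.0, "r": 0.0, "s": 1.0, "xr1": 0.0, "xr2": 1.0,
    "Cai": 0.00007, "CaSR": 1.3, "CaSS": 0.00007, "Nai": 7.67,
    "Ki": 138.3, "Rbar": 1.0,
}

_GATE_ORDER = ("m", "h", "j", "d", "f", "f2", "fcass", "r", "s",
               "xr1", "xr2")


@dataclass
class PacingSpec:
    """Periodic stimulation: basic cycle length, beat count, stimulus."""

    bcl: float = 1000.0
    n_beats: int = 50
    amplitude: float = STIM_AMPLITUDE
    duration: float = STIM_DURATION

    def __post_init__(self) -> None:
        if not self.bcl > self.duration > 0:
            raise ValueError("require BCL > stimulus duration > 0")
        if self.n_beats < 1:
            raise ValueError("beat count must be >= 1")


@lru_cache(maxsize=8)
def _tables(dt: float):
    vmin, inv_dv, tab = K.build_gate_tables(dt)
    return vmin, inv_dv, tab, K.build_ik1_table()


@lru_cache(maxsize=4)
def _rate_tables(genotype: str) -> Tuple[np.ndarray, np.ndarray]:
    wt = K.build_mc_rate_table(wt_params().coefficient_vector())
    mut = K.build_mc_rate_table(v307l_params().coefficient_vector())
    if genotype == "WT":
        return wt, wt
    if genotype == "V307L":
        return mut, mut
    return wt, mut


_EDGES = edge_arrays()


def _genotype_pack(genotype: str, g_ks: float, mutant_scale: float,
                   block: float) -> Tuple[np.ndarray, np.ndarray,
                                          float, float, int]:
    """(rtab0, rtab1, gks0, gks1, npop) kernel arguments for a genotype.

    Rate tables share the gate-table voltage grid; population weights
    and the block factor are folded into the conductances; MIDDLE-cell
    scaling happens inside the kernel.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    rtab0, rtab1 = _rate_tables(genotype)
    gb = g_ks * (1.0 - block)
    if genotype == "WT":
        return rtab0, rtab1, gb, 0.0, 1
    if genotype == "V307L":
        return rtab0, rtab1, gb * mutant_scale, 0.0, 1
    return rtab0, rtab1, 0.5 * gb, 0.5 * gb * mutant_scale, 2


def initial_state(genotype: str = "WT",
                  holding_potential: float = -86.2) -> np.ndarray:
    """Fresh state vector: host resting state, channels equilibrated."""
    s = np.zeros(K.NVAR)
    s[K._IV] = _Y0["V"]
    for i, g in enumerate(_GATE_ORDER):
        s[1 + i] = _Y0[g]
    s[K._ICAI] = _Y0["Cai"]
    s[K._ICASR] = _Y0["CaSR"]
    s[K._ICASS] = _Y0["CaSS"]
    s[K._INAI] = _Y0["Nai"]
    s[K._IKI] = _Y0["Ki"]
    s[K._IRBAR] = _Y0["Rbar"]
    mc_wt = steady_state(holding_potential, wt_params()).occupancy
    mc_mut = steady_state(holding_potential, v307l_params()).occupancy
    if genotype == "WT":
        s[K._IMC0:K._IMC0 + 17] = mc_wt
        s[K._IMC1] = 1.0
    elif genotype == "V307L":
        s[K._IMC0:K._IMC0 + 17] = mc_mut
        s[K._IMC1] = 1.0
    elif genotype == "WT-V307L":
        s[K._IMC0:K._IMC0 + 17] = mc_wt
        s[K._IMC1:K._IMC1 + 17] = mc_mut
    else:
        raise ValueError(f"unknown genotype {genotype!r}")
    return s


# default conductances; replaced by the anchor calibration (see
# sqt2sim.calibrate).  Units nS/pF for the EPI/ENDO WT population.
_DEFAULTS: Dict[str, float] = {}


def default_gks() -> float:
    """Calibrated WT maximal IKs conductance (nS/pF, EPI/ENDO)."""
    if "g_ks" not in _DEFAULTS:
        from .calibrate import calibrated_constants
        _DEFAULTS["g_ks"] = calibrated_constants()["g_ks"]
    return _DEFAULTS["g_ks"]


def default_mutant_scale() -> float:
    """Relative-amplitude multiplier of the mutant population."""
    if "mutant_scale" not in _DEFAULTS:
        from .calibrate import calibrated_constants
        _DEFAULTS["mutant_scale"] = calibrated_constants()["mutant_scale"]
    return _DEFAULTS["mutant_scale"]


@dataclass
class CellModel:
    """A single ventricular cell of one transmural type and genotype.

    Thin stateful wrapper around the compiled kernel; ``state`` is the
    packed vector documented in :mod:`sqt2sim._kernels`.
    """

    cell_type: str = "EPI"
    genotype: str = "WT"
    g_ks: Optional[float] = None
    mutant_scale: Optional[float] = None
    block: float = 0.0
    dt: float = 0.02
    state: np.ndarray = field(default=None, repr=False)  # type: ignore

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if not 0.0 <= self.block <= 1.0:
            raise ValueError("block fraction must lie in [0, 1]")
        if self.g_ks is None:
            self.g_ks = default_gks()
        if self.mutant_scale is None:
            self.mutant_scale = default_mutant_scale()
        if self.state is None:
            self.state = initial_state(self.genotype)

    def _kernel_args(self):
        vmin, inv_dv, tab, ktab = _tables(self.dt)
        rtab0, rtab1, gks0, gks1, npop = _genotype_pack(
            self.genotype, self.g_ks, self.mutant_scale, self.block)
        return (vmin, inv_dv, tab, ktab, rtab0, rtab1, gks0, gks1, npop,
                *_EDGES)

    def run(self, duration: float, stim_starts: np.ndarray,
            stim_amp: float = STIM_AMPLITUDE,
            stim_dur: float = STIM_DURATION,
            record_dt: float = 1.0) -> Tuple[np.ndarray, np.ndarray,
                                             np.ndarray]:
        """Integrate for ``duration`` ms; returns (t, V, IKs) records."""
        rec_stride = max(int(round(record_dt / self.dt)), 1)
        n_steps = int(round(duration / self.dt))
        n_steps -= n_steps % rec_stride
        (vmin, inv_dv, tab, ktab, rtab0, rtab1, gks0, gks1, npop,
         es, ed, ec, em) = self._kernel_args()
        v, iks = K.run_cell(
            self.state, _CT_CODE[self.cell_type], vmin, inv_dv, tab, ktab,
            rtab0, rtab1, self.dt, n_steps, gks0, gks1, npop,
            es, ed, ec, em,
            np.asarray(stim_starts, float), stim_amp, stim_dur, rec_stride)
        t = np.arange(len(v)) * rec_stride * self.dt
        return t, v, iks

    def pace(self, pacing: PacingSpec,
             record_last: int = 1,
             record_dt: float = 1.0) -> Tuple[np.ndarray, np.ndarray,
                                              np.ndarray]:
        """Pace to (quasi) steady state; record the last beat(s).

        Returns (t, V, IKs) covering the final ``record_last`` beats,
        with t = 0 at the first recorded stimulus.
        """
        n_pre = pacing.n_beats - record_last
        if n_pre > 0:
            self.run(n_pre * pacing.bcl,
                     np.arange(n_pre) * pacing.bcl,
                     pacing.amplitude, pacing.duration,
                     record_dt=pacing.bcl)
        return self.run(record_last * pacing.bcl,
                        np.arange(record_last) * pacing.bcl,
                        pacing.amplitude, pacing.duration,
                        record_dt=record_dt)

    def copy(self) -> "CellModel":
        return CellModel(self.cell_type, self.genotype, self.g_ks,
                         self.mutant_scale, self.block, self.dt,
                         self.state.copy())
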