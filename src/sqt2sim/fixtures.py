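"""Synthetic clamp-target fixtures emulating the experimental constraints.

The experimental characterisation that the channel model is fitted to is
not available as tabulated data, so this module generates it
synthetically.  Channel activation follows a Boltzmann curve per
genotype (the mutant half-activation shifted -36 mV relative to WT);
the end-of-step I-V target is that activation multiplied by the ohmic
driving force and normalised at the most depolarised step, which is the
shape an end-of-pulse current measurement actually produces
(quasi-linear growth once activation saturates).  The kinetic factors
(two-fold slower deactivation, two-fold faster activation in the
mutant) and absolute WT reference kinetics are typical of IKs at
physiological temperature.

All fixture tables are regenerable from a :class:`FixtureConfig` and are
deterministic; optional Gaussian measurement noise (used by robustness
tests) is driven by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .clamp_and_fit import IVCurve, FitTargets

__all__ = ["FixtureConfig", "FixtureSet", "generate_fixtures",
           "boltzmann", "ap_clamp_waveform"]


def boltzmann(v: np.ndarray, v_half: float, slope: float) -> np.ndarray:
    """Boltzmann activation function 1 / (1 + exp((V_half - V) / k))."""
    return 1.0 / (1.0 + np.exp((v_half - np.asarray(v, float)) / slope))


@dataclass
class FixtureConfig:
    """Configuration of the synthetic fitting targets.

    Defaults encode the study conditions: WT activation V_half +20 mV
    with 12 mV slope (the shape of the WT activation relation at 37 C),
    a -36 mV mutant shift, and two-fold mutant kinetic factors.
    """

    wt_v_half: float = 20.0       # mV
    wt_slope: float = 12.0        # mV
    mutant_shift: float = -36.0   # mV, V307L minus WT
    mutant_slope: Optional[float] = None  # defaults to WT slope
    deactivation_slowdown: float = 2.0    # mutant/WT tail tau ratio
    activation_speedup: float = 2.0       # WT/mutant half-activation time
    wt_tau_deact: float = 150.0   # ms at -40 mV
    wt_t_half_act: float = 350.0  # ms at +20 mV
    v_min: float = -70.0
    v_max: float = 60.0
    v_step: float = 10.0
    noise_sd: float = 0.0         # additive noise on normalised currents
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wt_slope <= 0:
            raise ValueError("Boltzmann slope must be positive")
        if self.mutant_slope is not None and self.mutant_slope <= 0:
            raise ValueError("Boltzmann slope must be positive")
        if self.deactivation_slowdown <= 0 or self.activation_speedup <= 0:
            raise ValueError("kinetic factors must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class FixtureSet:
    """Generated fitting targets plus their tabular representations."""

    config: FixtureConfig
    fit_targets: FitTargets
    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, directory) -> None:
        """Write the target tables as CSV (voltage_mV, current_norm)."""
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(directory / f"iv_targets_{name}.csv", index=False)


def generate_fixtures(config: Optional[FixtureConfig] = None) -> FixtureSet:
    """Build the synthetic target set for both genotypes.

    The mutant activation is the WT Boltzmann translated by exactly
    ``config.mutant_shift`` mV; the I-V targets multiply activation by
    the driving force and are normalised to the value at the most
    depolarised test potential, matching the end-of-step measurement
    convention.
    """
    from .clamp_and_fit import E_KS_CLAMP

    config = config or FixtureConfig()
    v = np.arange(config.v_min, config.v_max + 1e-9, config.v_step)
    rng = np.random.default_rng(config.seed)
    iv: Dict[str, IVCurve] = {}
    tables: Dict[str, pd.DataFrame] = {}
    mut_slope = (config.wt_slope if config.mutant_slope is None
                 else config.mutant_slope)
    specs = {
        "WT": (config.wt_v_half, config.wt_slope),
        "V307L": (config.wt_v_half + config.mutant_shift, mut_slope),
    }
    for genotype, (v_half, slope) in specs.items():
        act = boltzmann(v, v_half, slope)
        y = act * (v - E_KS_CLAMP)
        y = y / y[-1]
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, size=y.shape)
        iv[genotype] = IVCurve(v, y, "end-of-step")
        tables[genotype] = pd.DataFrame(
            {"voltage_mV": v, "current_norm": y,
             "activation_norm": act / act[-1]}
        )
    targets = FitTargets(
        iv=iv,
        shift_target=config.mutant_shift,
        deactivation_slowdown=config.deactivation_slowdown,
        activation_speedup=config.activation_speedup,
        wt_tau_deact=config.wt_tau_deact,
        wt_t_half_act=config.wt_t_half_act,
    )
    return FixtureSet(config, targets, tables)


def ap_clamp_waveform(dt: float = 1.0, bcl: float = 1000.0) -> np.ndarray:
    """Ventricular AP voltage command for AP-clamp experiments.

    A steady-state EPI action potential generated by the host cell model,
    sampled at ``dt`` ms over one cycle; stands in for a digitised
    experimental AP waveform.  Returns an (n, 2) array of (time_ms, V_mV).
    """
    from .tnnp2006 import PacingSpec
    from .ventricle_cell import pace
    tr = pace("EPI", "WT", PacingSpec(bcl, 50), record_dt=dt)
    return np.column_stack([tr.time, tr.v])
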