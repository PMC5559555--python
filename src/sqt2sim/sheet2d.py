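"""Idealised 2D monodomain sheet: S1-S2 spiral-wave initiation, re-entry
lifespan and dominant-frequency analysis.

The sheet is an isotropic rectangle (uniform cell type or transmurally
layered rows) with no-flux boundaries.  A planar S1 wave is launched
from the left edge; a premature cross-field S2 rectangle applied behind
the S1 wavetail during the tissue's vulnerable phase produces
unidirectional block and a re-entrant spiral.  Re-entry is quantified by
its lifespan (last activation after S2) and by the dominant frequency of
the whole-field mean potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.signal import periodogram

from . import _kernels as K
from .tnnp2006 import (
    STIM_AMPLITUDE,
    _EDGES,
    _genotype_pack,
    _tables,
    default_gks,
    default_mutant_scale,
)
from .ventricle_cell import steady_cell

__all__ = [
    "SheetSpec",
    "SheetResult",
    "ReentryMetrics",
    "simulate_sheet",
    "vulnerable_s2_time",
    "reentry_lifespan",
    "dominant_frequency",
    "reentry_metrics",
]

_CT_NAME = {K.ENDO: "ENDO", K.MIDDLE: "MIDDLE", K.EPI: "EPI"}


@dataclass
class SheetSpec:
    """Geometry and numerics of the 2D sheet.

    Spiral waves need room: at least ~100x100 nodes (the default is a
    60 x 60 mm sheet at 0.2 mm).  Smaller grids are permitted for strip
    equivalence checks and scaled-down comparisons.
    """

    nx: int = 300
    ny: int = 300
    dx: float = 0.2                     # mm
    diffusion: Optional[float] = None   # mm^2/ms; None -> calibrated
    cell_type: str = "EPI"              # uniform layout
    layout: str = "uniform"             # "uniform" | "layered"
    fractions: Tuple[float, float, float] = (0.25, 0.35, 0.40)
    dt: float = 0.02                    # ms

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must be non-empty")
        if self.layout not in ("uniform", "layered"):
            raise ValueError(f"unknown layout {self.layout!r}")
        d = self.d()
        if 4.0 * d * self.dt / self.dx ** 2 > 0.5:
            raise ValueError("explicit diffusion unstable: reduce dt or "
                             "increase dx")

    def d(self) -> float:
        if self.diffusion is not None:
            return self.diffusion
        from .calibrate import calibrated_constants
        return calibrated_constants()["diffusion"]

    def cell_types(self) -> np.ndarray:
        """Per-node type codes, row-major (ny*nx,)."""
        if self.layout == "uniform":
            code = {"ENDO": K.ENDO, "MIDDLE": K.MIDDLE,
                    "EPI": K.EPI}[self.cell_type]
            return np.full(self.nx * self.ny, code, dtype=np.int64)
        # layered: ENDO rows at the bottom, then MIDDLE, then EPI
        n_endo = int(round(self.fractions[0] * self.ny))
        n_mid = int(round(self.fractions[1] * self.ny))
        rows = np.full(self.ny, K.EPI, dtype=np.int64)
        rows[:n_endo] = K.ENDO
        rows[n_endo:n_endo + n_mid] = K.MIDDLE
        return np.repeat(rows, self.nx)


@dataclass
class SheetResult:
    """Output of one sheet simulation."""

    spec: SheetSpec
    t_signal: np.ndarray        # ms, 1 kHz
    mean_v: np.ndarray          # whole-field mean potential
    last_activation: np.ndarray  # (ny, nx) ms, -1 where never activated
    snapshots: np.ndarray       # (n_frames, ny, nx)
    snapshot_dt: float          # ms
    s2_time: float              # ms, -1 if no S2


@dataclass
class ReentryMetrics:
    lifespan: float             # s, last activation after S2
    dominant_frequency: float   # Hz
    sustained: bool             # activity at simulation end

    def __post_init__(self) -> None:
        if self.lifespan < 0 or self.dominant_frequency < 0:
            raise ValueError("metrics must be non-negative")


def simulate_sheet(spec: SheetSpec, genotype: str = "WT",
                   duration: float = 2000.0,
                   s2_time: float = -1.0,
                   s2_rect_mm: Optional[Tuple[float, float, float, float]]
                   = None,
                   block: float = 0.0,
                   snapshot_dt: float = 10.0,
                   s1: bool = True,
                   g_ks: Optional[float] = None,
                   mutant_scale: Optional[float] = None) -> SheetResult:
    """Run the S1(-S2) protocol on the sheet.

    S1 is a planar stimulus on the left-edge columns at t = 0; S2
    (enabled when ``s2_time >= 0``) stimulates the rectangle
    ``s2_rect_mm = (x0, x1, y0, y1)`` (default: the lower-left quadrant,
    the classic cross-field geometry).  Nodes start from the 1 Hz
    single-cell steady state of their cell type.
    """
    g_ks = default_gks() if g_ks is None else g_ks
    mutant_scale = default_mutant_scale() if mutant_scale is None \
        else mutant_scale
    ct = spec.cell_types()
    S = np.empty((spec.nx * spec.ny, K.NVAR))
    for code in np.unique(ct):
        cell = steady_cell(_CT_NAME[int(code)], genotype, 1000.0,
                           n_beats=50, block=block, g_ks=g_ks,
                           mutant_scale=mutant_scale)
        S[ct == code] = cell.state
    vmin, inv_dv, tab, ktab = _tables(spec.dt)
    rtab0, rtab1, gks0, gks1, npop = _genotype_pack(
        genotype, g_ks, mutant_scale, block)
    if s2_rect_mm is None:
        s2_rect_mm = (0.0, spec.nx * spec.dx / 2.0,
                      0.0, spec.ny * spec.dx / 2.0)
    x0, x1, y0, y1 = s2_rect_mm
    snap_stride = max(int(round(snapshot_dt / spec.dt)), 1)
    n_steps = int(round(duration / spec.dt))
    n_steps -= n_steps % snap_stride
    mean_v, last_act, snaps = K.run_sheet(
        S, ct, spec.nx, spec.ny, vmin, inv_dv, tab, ktab, rtab0, rtab1,
        spec.dt, n_steps, gks0, gks1, npop, *_EDGES,
        spec.d(), spec.dx,
        0.0 if s1 else -1.0, STIM_AMPLITUDE, 2.0, max(spec.nx // 40, 2),
        float(s2_time), 2.0 * STIM_AMPLITUDE, 2.0,
        int(round(x0 / spec.dx)), int(round(x1 / spec.dx)),
        int(round(y0 / spec.dx)), int(round(y1 / spec.dx)),
        snap_stride)
    t_signal = np.arange(len(mean_v), dtype=float)
    return SheetResult(spec, t_signal, mean_v,
                       last_act.reshape(spec.ny, spec.nx),
                       snaps.reshape(-1, spec.ny, spec.nx),
                       snap_stride * spec.dt, float(s2_time))


def vulnerable_s2_time(spec: SheetSpec, genotype: str = "WT",
                       margin: float = 5.0, recovery_v: float = -70.0,
                       block: float = 0.0,
                       g_ks: Optional[float] = None,
                       mutant_scale: Optional[float] = None) -> float:
    """S2 time inside the tissue's vulnerable phase (per genotype).

    Runs the S1-only protocol and returns the moment the centre of the
    S2 quadrant's leading edge has just recovered (crossed
    ``recovery_v`` downwards) plus a small margin: a premature stimulus
    then falls on partially recovered tissue behind the S1 wavetail.
    """
    probe_x, probe_y = spec.nx // 2, spec.ny // 4
    res = simulate_sheet(spec, genotype, duration=800.0, s2_time=-1.0,
                         block=block, snapshot_dt=1.0, g_ks=g_ks,
                         mutant_scale=mutant_scale)
    v = res.snapshots[:, probe_y, probe_x]
    t = np.arange(len(v)) * res.snapshot_dt
    act = np.nonzero(v > -20.0)[0]
    if len(act) == 0:
        raise RuntimeError("S1 wave failed to reach the probe")
    after = act[0]
    rec = np.nonzero(v[after:] < recovery_v)[0]
    if len(rec) == 0:
        raise RuntimeError("probe did not recover within the S1 run")
    return float(t[after + rec[0]] + margin)


def reentry_lifespan(activation_times: np.ndarray,
                     s2_time: float) -> float:
    """Lifespan (s): last upstroke anywhere after S2, minus S2 time.

    ``activation_times`` holds each node's last -20 mV upstroke crossing
    in ms (negative where the node never activated); returns 0 when no
    activation followed the premature stimulus.
    """
    last = float(np.max(activation_times))
    if last <= s2_time:
        return 0.0
    return (last - s2_time) / 1000.0


def dominant_frequency(signal: np.ndarray, fs: float = 1000.0,
                       band: Tuple[float, float] = (0.5, 20.0),
                       resolution: float = 0.2) -> float:
    """Dominant frequency (Hz) of a mean-potential signal.

    Detrended, Hann-windowed periodogram zero-padded to at least the
    requested spectral resolution; returns the frequency of the maximal
    power in ``band``.
    """
    x = np.asarray(signal, float)
    if len(x) < 2 * fs:
        raise ValueError("signal must cover at least 2 s")
    x = x - x.mean()
    if np.max(np.abs(x)) < 1e-9:
        raise ValueError("constant signal: no spectral peak")
    nfft = max(len(x), int(fs / resolution))
    f, p = periodogram(x, fs=fs, window="hann", nfft=nfft)
    sel = (f > band[0]) & (f < band[1])
    if not np.any(sel) or np.max(p[sel]) <= 0:
        raise ValueError("no spectral peak in the search band")
    return float(f[sel][np.argmax(p[sel])])


def reentry_metrics(result: SheetResult) -> ReentryMetrics:
    """Lifespan, dominant frequency and persistence of one sheet run."""
    s2 = result.s2_time if result.s2_time >= 0 else 0.0
    life = reentry_lifespan(result.last_activation, s2)
    try:
        df = dominant_frequency(result.mean_v)
    except ValueError:
        df = 0.0
    sustained = bool(np.any(result.snapshots[-1] > -20.0))
    return ReentryMetrics(life, df, sustained)
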