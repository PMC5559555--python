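"""Single-cell electrophysiology operations: pacing, APD, ERP, restitution
and IKs-block titration.

All operations run the host ventricular cell model (:mod:`tnnp2006`) for
one of the three transmural cell types (ENDO / MIDDLE / EPI) and one of
the three genotypes (WT, heterozygous WT-V307L, homozygous V307L).
Conditioning trains are cached per configuration so that protocol scans
(restitution curves, refractory-period bisection, block titration) reuse
the expensive steady-state pacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .tnnp2006 import (
    CELL_TYPES,
    CellModel,
    PacingSpec,
    STIM_AMPLITUDE,
    STIM_DURATION,
)
from .iks_markov import GENOTYPES

__all__ = [
    "APTrace",
    "RestitutionCurve",
    "apd90",
    "pace",
    "steady_cell",
    "erp",
    "apd_restitution",
    "erp_restitution",
    "titrate_block",
]


@dataclass
class APTrace:
    """Membrane-potential record of >= 1 paced beat on a uniform grid."""

    time: np.ndarray
    v: np.ndarray
    iks: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.time) != len(self.v):
            raise ValueError("time and V must have equal length")


@dataclass
class RestitutionCurve:
    """APD or ERP restitution: ordinate vs DI (APD-R) or BCL (ERP-R)."""

    kind: str                  # "DI" or "BCL"
    abscissa: np.ndarray       # ms
    ordinate: np.ndarray       # ms
    max_slope: Optional[float] = None
    max_slope_at: Optional[float] = None

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, float)
        self.ordinate = np.asarray(self.ordinate, float)
        if np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")

    @classmethod
    def from_points(cls, kind: str, x: Sequence[float],
                    y: Sequence[float]) -> "RestitutionCurve":
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        order = np.argsort(x)
        x, y = x[order], y[order]
        if len(x) >= 2:
            slopes = np.diff(y) / np.diff(x)
            i = int(np.argmax(slopes))
            return cls(kind, x, y, float(slopes[i]),
                       float(0.5 * (x[i] + x[i + 1])))
        return cls(kind, x, y, None, None)


def apd90(trace: APTrace, stim_time: float = 0.0) -> float:
    """APD at 90 % repolarisation of the beat stimulated at ``stim_time``.

    Measured from the time of maximal upstroke velocity to 90 % recovery
    of the AP amplitude (beat resting potential to peak), with linear
    interpolation at the crossing.
    """
    t, v = trace.time, trace.v
    sel = t >= stim_time
    t, v = t[sel], v[sel]
    if len(t) < 3:
        raise ValueError("trace too short for APD measurement")
    dv = np.diff(v) / np.diff(t)
    i_up = int(np.argmax(dv))
    t_up = t[i_up]
    v_rest = v[0]
    i_peak = i_up + int(np.argmax(v[i_up:]))
    v_peak = v[i_peak]
    level = v_peak - 0.9 * (v_peak - v_rest)
    after = v[i_peak:]
    below = np.nonzero(after <= level)[0]
    if len(below) == 0:
        raise ValueError("AP did not repolarise to the 90% level")
    k = i_peak + below[0]
    if k == 0 or v[k] == v[k - 1]:
        t_cross = t[k]
    else:
        t_cross = t[k - 1] + (t[k] - t[k - 1]) \
            * (v[k - 1] - level) / (v[k - 1] - v[k])
    return float(t_cross - t_up)


# ---------------------------------------------------------------------------
# Pacing and conditioning cache
# ---------------------------------------------------------------------------

_STEADY_CACHE: Dict[tuple, np.ndarray] = {}


def steady_cell(cell_type: str, genotype: str, bcl: float = 1000.0,
                n_beats: int = 50, block: float = 0.0,
                g_ks: Optional[float] = None,
                mutant_scale: Optional[float] = None) -> CellModel:
    """A cell paced to quasi steady state, from a conditioning cache.

    The returned model's state sits at the instant the next stimulus is
    due.  The cached array is copied, so callers may integrate freely.
    """
    cell = CellModel(cell_type, genotype, g_ks, mutant_scale, block)
    key = (cell_type, genotype, float(bcl), int(n_beats), float(block),
           float(cell.g_ks), float(cell.mutant_scale))
    state = _STEADY_CACHE.get(key)
    if state is None:
        cell.run(n_beats * bcl, np.arange(n_beats) * bcl,
                 record_dt=float(bcl))
        _STEADY_CACHE[key] = cell.state.copy()
    else:
        cell.state = state.copy()
    return cell


def pace(cell_type: str, genotype: str,
         pacing: Optional[PacingSpec] = None,
         block: float = 0.0, record_dt: float = 0.1,
         g_ks: Optional[float] = None,
         mutant_scale: Optional[float] = None) -> APTrace:
    """Steady-state paced AP: conditioning train plus one recorded beat.

    Raises if the cell fails to repolarise below -70 mV between the last
    beats (non-repolarising at this rate).
    """
    pacing = pacing or PacingSpec()
    cell = steady_cell(cell_type, genotype, pacing.bcl,
                       max(pacing.n_beats - 1, 1), block, g_ks,
                       mutant_scale)
    t, v, iks = cell.run(pacing.bcl, np.array([0.0]), pacing.amplitude,
                         pacing.duration, record_dt=record_dt)
    if v[-1] > -70.0:
        raise RuntimeError(
            f"{cell_type}/{genotype} failed to repolarise below -70 mV "
            f"at BCL {pacing.bcl} ms")
    return APTrace(t, v, iks)


# ---------------------------------------------------------------------------
# Effective refractory period
# ---------------------------------------------------------------------------

def _s2_captures(cell: CellModel, s2_time: float, s1_amplitude: float,
                 observe: float = 500.0) -> bool:
    """Deliver S1 at t=0 and S2 at ``s2_time``; test for a regenerative AP.

    Capture criterion: the S2 response overshoots 0 mV and its amplitude
    reaches at least 80 % of the S1 amplitude.
    """
    probe = cell.copy()
    t, v, _ = probe.run(s2_time + observe,
                        np.array([0.0, s2_time]), record_dt=0.5)
    v_diastolic = float(v[t < s2_time][-1])
    peak = float(v[t >= s2_time].max())
    amplitude = peak - v_diastolic
    return peak > 0.0 and amplitude >= 0.8 * s1_amplitude


def erp(cell_type: str, genotype: str, bcl: float = 1000.0,
        block: float = 0.0, resolution: float = 1.0,
        n_condition: int = 50,
        g_ks: Optional[float] = None,
        mutant_scale: Optional[float] = None) -> float:
    """Effective refractory period (ms) at a given pacing rate.

    After steady pacing at ``bcl``, the shortest S1-S2 interval whose S2
    elicits a regenerative AP is located by bisection to ``resolution``.
    """
    base = steady_cell(cell_type, genotype, bcl, n_condition, block,
                       g_ks, mutant_scale)
    # S1 amplitude from one recorded beat
    ref = base.copy()
    t, v, _ = ref.run(min(bcl, 600.0), np.array([0.0]), record_dt=0.5)
    s1_amplitude = float(v.max() - v[0])
    lo, hi = 20.0, float(bcl)
    if not _s2_captures(base, hi, s1_amplitude):
        raise RuntimeError(
            f"no S2 in (0, {bcl}] captures for {cell_type}/{genotype}")
    if _s2_captures(base, lo, s1_amplitude):
        return lo
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if _s2_captures(base, mid, s1_amplitude):
            hi = mid
        else:
            lo = mid
    return float(hi)


# ---------------------------------------------------------------------------
# Restitution
# ---------------------------------------------------------------------------

def apd_restitution(cell_type: str, genotype: str,
                    di_list: Iterable[float], bcl: float = 1000.0,
                    s1_beats: int = 10, block: float = 0.0,
                    g_ks: Optional[float] = None,
                    mutant_scale: Optional[float] = None
                    ) -> RestitutionCurve:
    """APD restitution by the S1-S2 protocol.

    An S1 train (``s1_beats`` at ``bcl``) conditions the cell; a single
    S2 follows the last S1 at each diastolic interval; the curve is
    APD90 of the S2 beat against DI, with the maximal slope from finite
    differences of adjacent points.  S2 beats that fail to capture are
    omitted.
    """
    base = steady_cell(cell_type, genotype, bcl, 50, block, g_ks,
                       mutant_scale)
    train = base.copy()
    if s1_beats > 1:
        train.run((s1_beats - 1) * bcl, np.arange(s1_beats - 1) * bcl,
                  record_dt=float(bcl))
    # last S1 beat: record to locate its 90 % repolarisation time
    probe = train.copy()
    t, v, _ = probe.run(bcl, np.array([0.0]), record_dt=0.1)
    tr = APTrace(t, v)
    last_apd = apd90(tr)
    dv = np.diff(v) / np.diff(t)
    t_up = t[int(np.argmax(dv))]
    t_rep = t_up + last_apd
    pts: List[Tuple[float, float]] = []
    for di in di_list:
        s2_time = t_rep + float(di)
        run = train.copy()
        t2, v2, _ = run.run(s2_time + 700.0, np.array([0.0, s2_time]),
                            record_dt=0.1)
        seg = APTrace(t2, v2)
        try:
            a = apd90(seg, stim_time=s2_time)
        except ValueError:
            continue
        v_after = v2[t2 >= s2_time + STIM_DURATION]
        if v_after.max() <= 0.0:   # no capture
            continue
        pts.append((float(di), a))
    if not pts:
        raise RuntimeError("no S2 captured at any requested DI")
    return RestitutionCurve.from_points(
        "DI", [p[0] for p in pts], [p[1] for p in pts])


def erp_restitution(cell_type: str, genotype: str,
                    bcl_list: Iterable[float], block: float = 0.0,
                    g_ks: Optional[float] = None,
                    mutant_scale: Optional[float] = None
                    ) -> RestitutionCurve:
    """ERP restitution: ERP against basic cycle length (dynamic pacing).

    BCLs at which the cell fails to repolarise (rate not supported) are
    omitted from the curve.
    """
    pts: List[Tuple[float, float]] = []
    for bcl in bcl_list:
        try:
            pace(cell_type, genotype, PacingSpec(float(bcl), 50),
                 block=block, g_ks=g_ks, mutant_scale=mutant_scale)
            e = erp(cell_type, genotype, float(bcl), block,
                    g_ks=g_ks, mutant_scale=mutant_scale)
        except RuntimeError:
            continue
        pts.append((float(bcl), e))
    if not pts:
        raise RuntimeError("no BCL in the list supported 1:1 capture")
    return RestitutionCurve.from_points(
        "BCL", [p[0] for p in pts], [p[1] for p in pts])


# ---------------------------------------------------------------------------
# IKs-block titration
# ---------------------------------------------------------------------------

def _steady_apd(cell_type: str, genotype: str, block: float,
                bcl: float = 1000.0,
                g_ks: Optional[float] = None,
                mutant_scale: Optional[float] = None) -> float:
    tr = pace(cell_type, genotype, PacingSpec(bcl, 50), block=block,
              g_ks=g_ks, mutant_scale=mutant_scale)
    return apd90(tr)


def titrate_block(cell_type: str, genotype: str, reference_apd: float,
                  bcl: float = 1000.0, tol: float = 1.0,
                  g_ks: Optional[float] = None,
                  mutant_scale: Optional[float] = None) -> float:
    """Smallest IKs-block fraction normalising the steady-state APD90.

    Block scales the maximal conductance of every channel population by
    ``1 - fraction``.  APD90 increases monotonically with block in the
    gain-of-function mutant conditions, so the crossing with
    ``reference_apd`` is found by bisection and refined until the APD
    matches within ``tol`` ms (grid resolution 1 %).
    """
    lo, hi = 0.0, 1.0
    apd_lo = _steady_apd(cell_type, genotype, lo, bcl, g_ks, mutant_scale)
    if abs(apd_lo - reference_apd) <= tol:
        return 0.0
    apd_hi = _steady_apd(cell_type, genotype, hi, bcl, g_ks, mutant_scale)
    if apd_hi < reference_apd - tol:
        raise RuntimeError(
            f"reference APD {reference_apd:.1f} ms unreachable: "
            f"achieved {apd_hi:.1f} ms at 100% block")
    while hi - lo > 0.005:
        mid = 0.5 * (lo + hi)
        a = _steady_apd(cell_type, genotype, mid, bcl, g_ks, mutant_scale)
        if abs(a - reference_apd) <= tol:
            # refine to the smallest such fraction on a 1 % grid
            return float(np.round(mid / 0.01) * 0.01)
        if a < reference_apd:
            lo = mid
        else:
            hi = mid
    return float(np.round(0.5 * (lo + hi) / 0.01) * 0.01)
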