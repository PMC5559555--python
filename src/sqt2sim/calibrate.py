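"""One-off calibration of the model's two free tissue-scale constants.

The absolute maximal IKs conductance and the monodomain diffusion
coefficient are not identifiable from normalised clamp data, so they are
anchored once:

* ``g_ks`` (WT, EPI/ENDO; MIDDLE keeps the host model's 1:4 ratio) is
  tuned so the WT EPI steady-state APD90 at 1 Hz equals 325.6 ms.  All
  other single-cell durations, and everything downstream (mutant APDs,
  QT intervals, refractoriness, titration fractions), are predictions.
* ``D`` is tuned so a planar wave in the WT transmural strand conducts
  at 70 cm/s, a standard human ventricular value.

The mutant population's relative amplitude multiplier is left at 1: both
fitted channel models share the WT conductance, and the larger mutant
current emerges from its kinetics alone.  The AP-clamp peak-current
ratio between the fitted models is reported as a validation metric
(:func:`sqt2sim.clamp_and_fit.ap_clamp_peak_ratio`).

Calibrated values are frozen in :mod:`sqt2sim._presets` for everyday
use; :func:`calibrate_gks` and :func:`calibrate_diffusion` recompute
them from scratch.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

__all__ = [
    "APD90_ANCHOR",
    "CV_TARGET",
    "calibrate_gks",
    "calibrate_diffusion",
    "calibrated_constants",
]

APD90_ANCHOR = 325.6   # ms, WT EPI APD90 at 1 Hz
CV_TARGET = 0.70       # mm/ms (70 cm/s), WT planar conduction velocity

_CACHE: Dict[str, float] = {}


def _apd_at(g: float, n_beats: int = 50) -> float:
    from .tnnp2006 import CellModel, PacingSpec
    from .ventricle_cell import APTrace, apd90
    cell = CellModel("EPI", "WT", g_ks=g, mutant_scale=1.0)
    n_pre = n_beats - 1
    cell.run(n_pre * 1000.0, np.arange(n_pre) * 1000.0, record_dt=1000.0)
    t, v, _ = cell.run(1000.0, np.array([0.0]), record_dt=0.1)
    return apd90(APTrace(t, v))


def calibrate_gks(target: float = APD90_ANCHOR, tol: float = 0.05,
                  lo: float = 0.02, hi: float = 0.4,
                  n_beats: int = 50) -> float:
    """Bisect the WT EPI conductance onto the anchor APD90 (1 Hz).

    APD90 decreases monotonically with g_ks over the bracket.
    """
    a_lo = _apd_at(lo, n_beats)
    a_hi = _apd_at(hi, n_beats)
    if not (a_hi < target < a_lo):
        raise RuntimeError(
            f"anchor {target} ms outside bracket ({a_hi:.1f}, {a_lo:.1f})")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        a = _apd_at(mid, n_beats)
        if abs(a - target) <= tol:
            return mid
        if a > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_diffusion(target_cv: float = CV_TARGET, tol: float = 0.005,
                        lo: float = 0.05, hi: float = 0.5,
                        g_ks: Optional[float] = None) -> float:
    """Bisect the diffusion coefficient onto the WT planar CV target.

    CV scales as sqrt(D), so a few bisection steps on the transmural
    strand suffice.
    """
    from .strand_ecg import StrandSpec, conduction_velocity
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        cv = conduction_velocity(StrandSpec(diffusion=mid), "WT",
                                 g_ks=g_ks)
        if abs(cv - target_cv) <= tol:
            return mid
        if cv < target_cv:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrated_constants(recompute: bool = False) -> Dict[str, float]:
    """The calibrated (g_ks, mutant_scale, D) constants.

    Frozen values from :mod:`sqt2sim._presets` are used when available;
    ``recompute=True`` (or absent frozen values) triggers the full
    anchor calibrations.
    """
    if _CACHE and not recompute:
        return dict(_CACHE)
    if not recompute:
        try:
            from . import _presets
            _CACHE.update({
                "g_ks": _presets.G_KS_WT,
                "mutant_scale": _presets.MUTANT_SCALE,
                "diffusion": _presets.DIFFUSION,
            })
            return dict(_CACHE)
        except (ImportError, AttributeError):
            pass
    g = calibrate_gks()
    _CACHE.update({"g_ks": g, "mutant_scale": 1.0})
    _CACHE["diffusion"] = calibrate_diffusion()
    return dict(_CACHE)
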