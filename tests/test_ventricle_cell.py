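"""Single-cell operations: APD measurement, pacing, ERP, restitution."""

import numpy as np
import pytest

from sqt2sim.tnnp2006 import CellModel, PacingSpec
from sqt2sim import ventricle_cell as vc


def test_apd90_triangle_is_analytic():
    """Rest -80, peak +40, linear 300 ms decline: APD90 = 270 ms."""
    t = np.arange(0.0, 400.0, 0.5)
    v = np.full_like(t, -80.0)
    decline = (t >= 10.0) & (t <= 310.0)
    v[decline] = 40.0 - 120.0 * (t[decline] - 10.0) / 300.0
    assert vc.apd90(vc.APTrace(t, v)) == pytest.approx(270.0, abs=1.0)


def test_apd90_requires_repolarisation():
    t = np.arange(0.0, 100.0, 1.0)
    v = np.where(t < 5, -80.0, 30.0)
    with pytest.raises(ValueError, match="repolarise"):
        vc.apd90(vc.APTrace(t, v))


def test_pacing_is_deterministic():
    a = CellModel("EPI", "WT")
    b = CellModel("EPI", "WT")
    ta, va, _ = a.run(2000.0, np.array([0.0, 1000.0]))
    tb, vb, _ = b.run(2000.0, np.array([0.0, 1000.0]))
    assert np.array_equal(va, vb)


def test_pacing_spec_validation():
    with pytest.raises(ValueError):
        PacingSpec(bcl=0.5, n_beats=10)
    with pytest.raises(ValueError):
        PacingSpec(n_beats=0)
    with pytest.raises(ValueError):
        CellModel("SEPTAL", "WT")


def test_resting_cell_is_stable():
    """After settling, V drifts < 0.1 mV over 10 unstimulated seconds."""
    cell = CellModel("EPI", "WT")
    cell.run(20000.0, np.empty(0), record_dt=20000.0)   # settle
    t, v, _ = cell.run(10000.0, np.empty(0), record_dt=100.0)
    assert np.max(np.abs(v - v[0])) < 0.1


def test_erp_within_bounds_and_matches_exhaustive_scan():
    """Bisection agrees with a 1 ms scan around the refractory edge."""
    e = vc.erp("EPI", "WT", 1000.0)
    assert 0.0 < e < 1000.0
    base = vc.steady_cell("EPI", "WT", 1000.0, 50)
    probe = base.copy()
    t, v, _ = probe.run(600.0, np.array([0.0]), record_dt=0.5)
    amp = float(v.max() - v[0])
    scan = np.arange(e - 6.0, e + 6.0, 1.0)
    captured = np.array([vc._s2_captures(base, s, amp) for s in scan])
    first = scan[np.argmax(captured)]
    assert abs(first - e) <= 1.0


def test_restitution_linear_slope_and_degenerate_cases():
    curve = vc.RestitutionCurve.from_points(
        "DI", [50.0, 150.0, 400.0], [225.0, 275.0, 400.0])
    assert curve.max_slope == pytest.approx(0.5)
    single = vc.RestitutionCurve.from_points("BCL", [800.0], [270.0])
    assert single.max_slope is None
    with pytest.raises(ValueError):
        vc.RestitutionCurve("DI", np.array([2.0, 1.0]),
                            np.array([1.0, 2.0]))


def test_apd_restitution_returns_monotone_curve_for_wt():
    curve = vc.apd_restitution("EPI", "WT", [40.0, 120.0, 400.0],
                               s1_beats=3)
    assert curve.kind == "DI"
    assert len(curve.abscissa) >= 2
    assert np.all(np.diff(curve.ordinate) > -1.0)


def test_titration_identity_is_zero_block():
    from sqt2sim.ventricle_cell import pace, apd90, titrate_block
    ref = apd90(pace("EPI", "WT", PacingSpec(1000.0, 50)))
    assert titrate_block("EPI", "WT", ref) == 0.0


def test_titration_unreachable_reference_raises():
    with pytest.raises(RuntimeError, match="unreachable"):
        vc.titrate_block("EPI", "V307L", 900.0)


def test_erp_restitution_single_bcl_degenerate():
    """A one-BCL ERP-R curve has length 1 and no defined slope."""
    curve = vc.erp_restitution("EPI", "WT", [1000.0])
    assert len(curve.abscissa) == 1
    assert curve.max_slope is None
    assert 0.0 < curve.ordinate[0] < 1000.0
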