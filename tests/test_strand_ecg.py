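"""Strand propagation, pseudo-ECG computation and derived metrics."""

import numpy as np
import pytest

from sqt2sim import strand_ecg as se
from sqt2sim.ventricle_cell import APTrace


def _uniform_map(n=75, nt=400):
    x = (np.arange(n) + 0.5) * 0.2
    t = np.arange(nt, dtype=float)
    v = np.tile(np.linspace(-85, 30, nt)[:, None], (1, n))
    return se.SpaceTimeMap(x, t, v, np.zeros(n, dtype=np.int64))


def test_spatially_uniform_potential_gives_zero_ecg():
    ecg = se.pseudo_ecg(_uniform_map())
    assert np.allclose(ecg.phi, 0.0, atol=1e-12)


def test_electrode_inside_strand_rejected():
    with pytest.raises(ValueError):
        se.pseudo_ecg(_uniform_map(), electrode_mm=-1.0)


def test_strand_spec_validation():
    with pytest.raises(ValueError):
        se.StrandSpec(fractions=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        se.StrandSpec(length=15.1)
    with pytest.raises(ValueError):
        se.StrandSpec(diffusion=-1.0)


def test_gaussian_t_wave_end_is_analytic():
    """T_end = centre + sigma * sqrt(2 ln 50) under the 2 % rule."""
    t = np.arange(0.0, 600.0, 1.0)
    phi = np.exp(-((t - 300.0) ** 2) / (2 * 20.0 ** 2))
    phi[:3] = 0.3   # QRS-like deflection at the start
    met = se.ecg_metrics(se.PseudoECG(t, phi, 20.0))
    expected_end = 300.0 + 20.0 * np.sqrt(2 * np.log(50.0))
    assert met.t_peak == pytest.approx(300.0, abs=1.0)
    assert met.t_end == pytest.approx(expected_end, abs=2.0)
    assert met.qt == pytest.approx(expected_end, abs=3.0)


def test_flat_ecg_rejected():
    t = np.arange(0.0, 400.0, 1.0)
    with pytest.raises(ValueError, match="flat"):
        se.ecg_metrics(se.PseudoECG(t, np.zeros_like(t), 20.0))


def test_homogeneous_strand_has_constant_cv():
    """All-EPI strand: activation time linear in distance (2 %)."""
    spec = se.StrandSpec(fractions=(0.0, 0.0, 1.0))
    S = se._strand_state(spec, "WT", 0.0, None, None, 50, 1000.0)
    m = se._run(spec, S, "WT", 0.0, None, None, 80.0, np.array([0.0]),
                record_dt=0.1)
    act = m.activation_times()
    n = spec.n_nodes
    sel = slice(n // 4, 3 * n // 4)
    fit = np.polyfit(m.x[sel], act[sel], 1)
    resid = act[sel] - np.polyval(fit, m.x[sel])
    segment_cv = np.diff(m.x[sel]) / np.diff(act[sel])
    assert np.max(np.abs(segment_cv / (1.0 / fit[0]) - 1.0)) < 0.02
    assert np.max(np.abs(resid)) < 0.5


def test_cv_scales_as_sqrt_of_diffusion():
    """Quadrupling D doubles conduction velocity (within 10 %)."""
    d0 = se.StrandSpec().d()
    cv1 = se.conduction_velocity(se.StrandSpec(diffusion=d0 / 2))
    cv2 = se.conduction_velocity(se.StrandSpec(diffusion=2 * d0))
    assert cv2 / cv1 == pytest.approx(2.0, rel=0.1)


def test_wt_repolarisation_latest_in_middle_segment():
    m = se.simulate_strand(genotype="WT", n_beats=3)
    repol = m.activation_times() + m.apd90_profile()
    mid = m.cell_types == 1
    assert np.nanmax(repol[mid]) == pytest.approx(np.nanmax(repol),
                                                  abs=1e-9)


def test_heterogeneity_identical_traces_zero():
    t = np.arange(0.0, 500.0, 1.0)
    v = -85.0 + 100.0 * np.exp(-t / 100.0)
    tr = APTrace(t, v)
    m = _uniform_map()
    res = se.heterogeneity({"EPI": tr, "MIDDLE": tr, "ENDO": tr}, m)
    assert all(val == 0.0 for val in res.delta_v.values())


def test_heterogeneity_rejects_unequal_grids():
    t1 = np.arange(0.0, 500.0, 1.0)
    t2 = np.arange(0.0, 500.0, 2.0)
    with pytest.raises(ValueError):
        se.heterogeneity({"EPI": APTrace(t1, np.zeros_like(t1)),
                          "MIDDLE": APTrace(t2, np.zeros_like(t2)),
                          "ENDO": APTrace(t1, np.zeros_like(t1))},
                         _uniform_map())


def test_vulnerable_window_rejects_outside_site():
    with pytest.raises(ValueError):
        se.vulnerable_window(genotype="WT", s2_site_mm=20.0)


def test_mutation_augments_transmural_heterogeneity():
    """Mutant EPI-MIDDLE and ENDO-MIDDLE potential divergence and the
    spatial APD90 gradient exceed their WT values."""
    from sqt2sim.tnnp2006 import PacingSpec
    from sqt2sim.ventricle_cell import pace
    out = {}
    for gt in ("WT", "V307L"):
        traces = {ct: pace(ct, gt, PacingSpec(1000.0, 50), record_dt=1.0)
                  for ct in ("EPI", "MIDDLE", "ENDO")}
        m = se.simulate_strand(genotype=gt, n_beats=3)
        out[gt] = se.heterogeneity(traces, m)
    for pair in ("EPI-MIDDLE", "ENDO-MIDDLE"):
        assert out["V307L"].delta_v[pair] > out["WT"].delta_v[pair]
    assert np.nanmax(out["V307L"].abs_gradient) > \
        np.nanmax(out["WT"].abs_gradient)
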