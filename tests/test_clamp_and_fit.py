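"""Voltage-clamp simulation, I-V analysis and fitting machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sqt2sim import clamp_and_fit as cf
from sqt2sim.fixtures import boltzmann
from sqt2sim.iks_markov import genotype_model, IKsParams


def test_standard_protocol_arithmetic():
    """14 sweeps covering hold + 50 + 3000 + 5000 ms of command."""
    proto = cf.standard_protocol()
    traces = cf.run_voltage_clamp(genotype_model("WT"), proto,
                                  dt_sample=10.0)
    assert len(traces) == 14
    for tr in traces:
        assert tr.time[-1] == pytest.approx(8050.0, abs=10.0)
        assert tr.segment_edges[-1] == pytest.approx(8050.0)


def test_zero_test_potentials_rejected():
    with pytest.raises(ValueError):
        cf.VClampProtocol(test_potentials=())


def test_zero_conductance_gives_zero_current():
    traces = cf.run_voltage_clamp(genotype_model("WT", g_ks=0.0),
                                  cf.standard_protocol(), dt_sample=50.0)
    for tr in traces:
        assert np.all(tr.current == 0.0)
    with pytest.raises(ValueError, match="degenerate"):
        cf.iv_curve(traces)


def test_mutant_activates_faster_at_0mv():
    """V307L reaches half its end-step current earlier than WT."""
    proto = cf.VClampProtocol(test_potentials=(0.0,))
    out = {}
    for gt in ("WT", "V307L"):
        tr = cf.run_voltage_clamp(genotype_model(gt), proto,
                                  dt_sample=2.0)[0]
        step = (tr.time >= 50.0) & (tr.time < 3050.0)
        i_step = tr.current[step]
        t_step = tr.time[step] - 50.0
        half = 0.5 * i_step[-1]
        out[gt] = t_step[np.argmax(i_step >= half)]
    assert out["V307L"] < out["WT"]


def test_iv_curve_normalised_and_rule_recorded():
    traces = cf.run_voltage_clamp(genotype_model("WT"),
                                  cf.standard_protocol(), dt_sample=10.0)
    for rule in ("end-of-step", "tail-peak"):
        curve = cf.iv_curve(traces, rule)
        assert np.max(np.abs(curve.current)) == pytest.approx(1.0)
        assert curve.rule == rule
    with pytest.raises(ValueError):
        cf.iv_curve(traces, "bogus")


@given(v_half=st.floats(-30, 30), slope=st.floats(6, 18))
@settings(max_examples=20, deadline=None)
def test_boltzmann_fit_recovers_exact_samples(v_half, slope):
    v = np.arange(-70.0, 61.0, 10.0)
    curve = cf.IVCurve(v, boltzmann(v, v_half, slope))
    vh, k = cf.boltzmann_fit(curve)
    assert vh == pytest.approx(v_half, abs=1e-6)
    assert k == pytest.approx(slope, abs=1e-6)


def test_boltzmann_fit_scale_invariant():
    v = np.arange(-70.0, 61.0, 10.0)
    y = boltzmann(v, 20.0, 12.0)
    fit1 = cf.boltzmann_fit(cf.IVCurve(v, y / y.max()))
    fit2 = cf.boltzmann_fit(cf.IVCurve(v, (2.0 * y) / (2.0 * y).max()))
    assert fit1 == pytest.approx(fit2)


def test_boltzmann_fit_rejects_flat_data():
    v = np.arange(-70.0, 61.0, 10.0)
    with pytest.raises(ValueError, match="flat"):
        cf.boltzmann_fit(cf.IVCurve(v, np.full_like(v, 0.5)))


def test_fitted_mutant_exceeds_wt_at_minus20(preset_params):
    wt = cf.activation_curve(preset_params["WT"])
    mut = cf.activation_curve(preset_params["V307L"])
    i = np.argmin(np.abs(wt.voltages + 20.0))
    assert mut.current[i] > wt.current[i]


def test_fit_from_truth_is_a_fixed_point(self_targets):
    """Starting at the optimum, the simplex cannot do better than ~0."""
    truth, targets = self_targets
    start_obj = cf.fit_objective(truth, targets)
    res = cf.fit_params(truth, targets, max_iterations=300, restarts=0)
    assert start_obj < 1e-3
    assert res.objective <= start_obj + 1e-12


def test_fit_is_deterministic(self_targets):
    truth, targets = self_targets
    pert = {c: (a * 1.3, b * 1.3)
            for c, (a, b) in truth.rate_coefficients.items()}
    start = IKsParams("WT", pert)
    r1 = cf.fit_params(start, targets, max_iterations=150, restarts=0)
    r2 = cf.fit_params(start, targets, max_iterations=150, restarts=0)
    assert r1.objective == r2.objective
    assert r1.params.rate_coefficients == r2.params.rate_coefficients


def test_parameter_vector_round_trip(preset_params):
    p = preset_params["WT"]
    q = cf.vector_to_params(cf.params_to_vector(p), p)
    for c in p.rate_coefficients:
        assert q.rate_coefficients[c] == pytest.approx(
            p.rate_coefficients[c], rel=1e-12)


# ---------------------------------------------------------------------------
# AP clamp
# ---------------------------------------------------------------------------

def _toy_ap_waveform():
    t = np.arange(0.0, 400.0, 1.0)
    v = np.full_like(t, -85.0)
    plateau = (t >= 2) & (t < 300)
    v[plateau] = 20.0 - 0.15 * (t[plateau] - 2)
    return np.column_stack([t, v])


def test_ap_clamp_zero_conductance():
    tr = cf.run_ap_clamp(genotype_model("WT", g_ks=0.0),
                         _toy_ap_waveform())
    assert np.all(tr.current == 0.0)


def test_ap_clamp_short_waveform_rejected():
    wf = _toy_ap_waveform()[:5]
    with pytest.raises(ValueError, match="10 ms"):
        cf.run_ap_clamp(genotype_model("WT"), wf)


def test_mutant_ap_clamp_activates_earlier_with_more_charge():
    """Under a ventricular AP command the mutant current rises earlier,
    peaks higher and carries more repolarising charge than WT."""
    from sqt2sim.fixtures import ap_clamp_waveform
    wf = ap_clamp_waveform()
    i_wt = cf.run_ap_clamp(genotype_model("WT", g_ks=0.1), wf).current
    i_mut = cf.run_ap_clamp(genotype_model("V307L", g_ks=0.1),
                            wf).current

    def t_half_rise(i):
        return wf[np.argmax(i >= 0.5 * i.max()), 0]

    assert t_half_rise(i_mut) < t_half_rise(i_wt)
    assert i_mut.max() > i_wt.max()
    assert np.trapezoid(i_mut) > np.trapezoid(i_wt)
    ratio = cf.ap_clamp_peak_ratio(genotype_model("WT", g_ks=0.1),
                                   genotype_model("V307L", g_ks=0.1), wf)
    assert ratio > 1.0
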