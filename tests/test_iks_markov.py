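"""Unit and property tests of the 17-state IKs Markov model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sqt2sim import iks_markov as mk


@given(v=st.floats(-120, 80))
@settings(max_examples=40, deadline=None)
def test_generator_conserves_probability(v, ):
    """Column sums of the generator vanish at any voltage."""
    q = mk.build_generator(v, mk.wt_params())
    assert np.allclose(q.sum(axis=0), 0.0, atol=1e-12)
    off = q - np.diag(np.diag(q))
    assert np.all(off >= 0)


def test_generator_sparsity_matches_scheme():
    """Non-zero off-diagonal entries are exactly the 44 scheme edges."""
    q = mk.build_generator(0.0, mk.wt_params())
    src, dst, _, _ = mk.edge_arrays()
    off = q - np.diag(np.diag(q))
    nz = {(int(j), int(i)) for i, j in zip(*np.nonzero(off.T))}
    assert nz == set(zip(dst.tolist(), src.tolist()))
    assert len(src) == 44


def test_generator_voltage_independent_when_sensitivities_zero():
    coeffs = {c: (a, 0.0) for c, (a, _) in
              mk.wt_params().rate_coefficients.items()}
    p = mk.IKsParams("WT", coeffs)
    assert np.array_equal(mk.build_generator(-80.0, p),
                          mk.build_generator(40.0, p))


def test_forward_activation_rates_grow_with_depolarisation():
    p = mk.wt_params()
    r_neg = mk.transition_rates(-40.0, p)
    r_pos = mk.transition_rates(40.0, p)
    i_gamma = mk.TRANSITION_CLASSES.index("gamma")
    assert r_pos[i_gamma] > r_neg[i_gamma]


def test_non_finite_voltage_rejected():
    with pytest.raises(ValueError, match="finite"):
        mk.build_generator(np.nan, mk.wt_params())


@pytest.mark.parametrize("v", [-80.0, -40.0, 0.0, 40.0])
def test_steady_state_matches_relaxation_oracle(v):
    """The null-space equilibrium equals long fixed-V relaxation."""
    p = mk.wt_params()
    ss = mk.steady_state(v, p)
    assert abs(ss.occupancy.sum() - 1.0) < 1e-12
    relaxed = mk.advance_exact(mk.ChannelState.ground(), v, 2e5, p)
    assert np.allclose(ss.occupancy, relaxed.occupancy, atol=1e-8)


def test_resting_open_probability_negligible():
    assert mk.steady_state(-80.0, mk.wt_params()).open_probability < 0.01


def test_advance_matches_matrix_exponential_oracle():
    """RK4 sub-stepping agrees with the exact propagator to 1e-6."""
    p = mk.wt_params()
    y0 = mk.steady_state(-80.0, p)
    got = mk.advance(y0, 0.0, 100.0, p)
    want = mk.advance_exact(y0, 0.0, 100.0, p)
    assert np.allclose(got.occupancy, want.occupancy, atol=1e-6)


def test_advance_zero_dt_identity_and_conservation():
    p = mk.v307l_params()
    y0 = mk.steady_state(-80.0, p)
    assert np.array_equal(mk.advance(y0, 0.0, 0.0, p).occupancy,
                          y0.occupancy)
    y = y0
    for v, dt in [(-40, 5.0), (20, 17.0), (40, 3.0), (-80, 50.0)]:
        y = mk.advance(y, v, dt, p)
        assert abs(y.occupancy.sum() - 1.0) < 1e-8


def test_heterozygote_is_exact_mixture():
    """Het current is the 50:50 average of the population currents."""
    het = mk.genotype_model("WT-V307L", g_ks=0.4)
    for v, dt in [(10.0, 40.0), (30.0, 80.0), (-30.0, 60.0)]:
        het.step(v, dt)
        i_het = mk.iks(het, v, -80.0)
        parts = [p.g_ks * p.scale_factor * s.open_probability * (v + 80.0)
                 for (_, p, s) in het.populations]
        assert i_het == pytest.approx(0.5 * parts[0] + 0.5 * parts[1],
                                      abs=1e-15)


def test_identical_population_heterozygote_equals_homozygote():
    wt = mk.genotype_model("WT", g_ks=0.4)
    twin = mk.GenotypeModel("WT-V307L", [
        (0.5, mk.wt_params(0.4), mk.ChannelState.ground()),
        (0.5, mk.wt_params(0.4), mk.ChannelState.ground()),
    ])
    twin.initialise(-80.0)
    for v, dt in [(0.0, 30.0), (40.0, 50.0)]:
        wt.step(v, dt)
        twin.step(v, dt)
        assert mk.iks(twin, v, -80.0) == pytest.approx(
            mk.iks(wt, v, -80.0), rel=1e-12)


def test_zero_driving_force_zero_current():
    m = mk.genotype_model("V307L", g_ks=1.0)
    m.step(20.0, 500.0)
    assert mk.iks(m, -30.0, -30.0) == 0.0


@pytest.mark.parametrize("params_fn", [mk.wt_params, mk.v307l_params])
def test_monotone_steady_activation(params_fn):
    """Equilibrium open probability is non-decreasing in V."""
    p = params_fn()
    po = [mk.steady_state(v, p).open_probability
          for v in np.arange(-80.0, 61.0, 10.0)]
    assert np.all(np.diff(po) >= -1e-10)


def test_channel_state_validation():
    with pytest.raises(ValueError):
        mk.ChannelState(np.ones(17))       # sums to 17
    with pytest.raises(ValueError):
        mk.ChannelState(np.zeros(16))      # wrong length
    with pytest.raises(ValueError):
        mk.IKsParams("WT", {c: (-1.0, 0.0)
                            for c in mk.TRANSITION_CLASSES})
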