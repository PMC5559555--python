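"""Fixture generation, configuration round-trips and report plumbing."""

import numpy as np
import pytest


from sqt2sim.fixtures import FixtureConfig, generate_fixtures
from sqt2sim.harness_io import RunConfig, load_config


def test_fixture_shift_is_exact():
    """Mutant activation Boltzmann sits exactly -36 mV left of WT's.

    The activation tables are normalised to the +60 mV point, so the
    underlying half-activation is recovered with a free-amplitude
    Boltzmann fit.
    """
    from scipy.optimize import curve_fit

    def scaled(v, amp, vh, k):
        return amp / (1.0 + np.exp((vh - v) / k))

    fx = generate_fixtures()
    halves = {}
    for g in ("WT", "V307L"):
        tab = fx.tables[g]
        p, _ = curve_fit(scaled, tab["voltage_mV"],
                         tab["activation_norm"], p0=[1.0, 0.0, 12.0])
        halves[g] = p[1]
    assert halves["V307L"] - halves["WT"] == pytest.approx(-36.0,
                                                           abs=1e-6)


def test_fixture_seed_reproducibility():
    cfg = FixtureConfig(noise_sd=0.02, seed=11)
    a = generate_fixtures(cfg)
    b = generate_fixtures(cfg)
    for g in ("WT", "V307L"):
        assert np.array_equal(a.fit_targets.iv[g].current,
                              b.fit_targets.iv[g].current)


def test_zero_shift_degenerates_to_identical_tables():
    fx = generate_fixtures(FixtureConfig(mutant_shift=-1e-9))
    assert np.allclose(fx.fit_targets.iv["WT"].current,
                       fx.fit_targets.iv["V307L"].current, atol=1e-9)


def test_invalid_fixture_config_rejected():
    with pytest.raises(ValueError):
        FixtureConfig(wt_slope=-2.0)
    with pytest.raises(ValueError):
        FixtureConfig(noise_sd=-0.1)


def test_fixture_tables_written(tmp_path):
    generate_fixtures().write(tmp_path)
    assert (tmp_path / "iv_targets_WT.csv").exists()
    assert (tmp_path / "iv_targets_V307L.csv").exists()


def test_run_config_round_trip(tmp_path):
    cfg = RunConfig(genotype="V307L", bcl=800.0, seed=42,
                    fixture=FixtureConfig(noise_sd=0.01, seed=5))
    path = tmp_path / "run.cfg"
    cfg.save(path)
    back = load_config(path)
    assert back == cfg
    assert back.hash() == cfg.hash()


def test_malformed_config_rejected(tmp_path):
    p = tmp_path / "bad.cfg"
    p.write_text("genotype WT\n")
    with pytest.raises(ValueError):
        load_config(p)
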