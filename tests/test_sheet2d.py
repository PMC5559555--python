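"""2D sheet: spectral analysis, lifespan bookkeeping, strip equivalence."""

import numpy as np
import pytest

from sqt2sim import sheet2d as sh


def test_dominant_frequency_pure_tone():
    t = np.arange(0.0, 5.0, 0.001)
    f = sh.dominant_frequency(np.sin(2 * np.pi * 3.0 * t), fs=1000.0)
    assert f == pytest.approx(3.0, abs=0.2)


def test_dominant_frequency_picks_larger_component():
    t = np.arange(0.0, 5.0, 0.001)
    x = np.sin(2 * np.pi * 2.0 * t) + 3.0 * np.sin(2 * np.pi * 5.0 * t)
    assert sh.dominant_frequency(x, fs=1000.0) == pytest.approx(5.0,
                                                               abs=0.2)


def test_dominant_frequency_rejects_constant_and_short_signals():
    with pytest.raises(ValueError, match="constant"):
        sh.dominant_frequency(np.ones(4000), fs=1000.0)
    with pytest.raises(ValueError, match="2 s"):
        sh.dominant_frequency(np.random.default_rng(0).normal(size=500),
                              fs=1000.0)


def test_reentry_lifespan_trivial_records():
    acts = np.array([[-1.0, 120.0], [2300.0, 40.0]])
    assert sh.reentry_lifespan(acts, 300.0) == pytest.approx(2.0)
    assert sh.reentry_lifespan(acts, 2400.0) == 0.0


def test_lifespan_matches_snapshot_scan():
    """Kernel upstroke bookkeeping equals a frame-by-frame snapshot scan."""
    spec = sh.SheetSpec(nx=40, ny=20, dx=0.4, dt=0.05)
    res = sh.simulate_sheet(spec, "WT", duration=150.0, snapshot_dt=1.0)
    # oracle: last -20 mV upstroke crossing found from the snapshots
    v = res.snapshots.reshape(res.snapshots.shape[0], -1)
    up = (v[1:] >= -20.0) & (v[:-1] < -20.0)
    frames = np.nonzero(up.any(axis=1))[0]
    oracle_last = (frames[-1] + 1) * res.snapshot_dt
    assert np.max(res.last_activation) == pytest.approx(oracle_last,
                                                        abs=1.0)


def test_strip_reproduces_strand_conduction_velocity():
    """A 1-node-wide sheet matches strand propagation within 2 %."""
    from sqt2sim.strand_ecg import StrandSpec, conduction_velocity
    spec = sh.SheetSpec(nx=75, ny=1, dx=0.2, dt=0.02)
    res = sh.simulate_sheet(spec, "WT", duration=120.0, snapshot_dt=0.5)
    v = res.snapshots[:, 0, :]
    t = np.arange(v.shape[0]) * res.snapshot_dt
    act = np.full(75, np.nan)
    for i in range(75):
        idx = np.nonzero((v[1:, i] >= -20) & (v[:-1, i] < -20))[0]
        if len(idx):
            act[i] = t[idx[0]]
    x = np.arange(75) * 0.2
    cv_sheet = 1.0 / np.polyfit(x[18:56], act[18:56], 1)[0]
    cv_strand = conduction_velocity(StrandSpec())
    assert cv_sheet == pytest.approx(cv_strand, rel=0.02)


def test_sheet_determinism():
    spec = sh.SheetSpec(nx=30, ny=12, dx=0.4, dt=0.05)
    r1 = sh.simulate_sheet(spec, "V307L", duration=60.0, snapshot_dt=5.0)
    r2 = sh.simulate_sheet(spec, "V307L", duration=60.0, snapshot_dt=5.0)
    assert np.array_equal(r1.snapshots, r2.snapshots)
    assert np.array_equal(r1.mean_v, r2.mean_v)


def test_sheet_spec_validation():
    with pytest.raises(ValueError):
        sh.SheetSpec(nx=0, ny=10)
    with pytest.raises(ValueError, match="unstable"):
        sh.SheetSpec(nx=50, ny=50, dx=0.1, dt=0.1, diffusion=0.145)
    with pytest.raises(ValueError):
        sh.SheetSpec(nx=50, ny=50, layout="hexagonal")
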