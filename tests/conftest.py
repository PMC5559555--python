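import numpy as np
import pytest

from sqt2sim import clamp_and_fit as cf
from sqt2sim.fixtures import generate_fixtures
from sqt2sim.iks_markov import wt_params, v307l_params


@pytest.fixture(scope="session")
def fit_targets():
    """Default synthetic clamp targets (both genotypes)."""
    return generate_fixtures().fit_targets


@pytest.fixture(scope="session")
def preset_params():
    """The packaged fitted channel presets."""
    return {"WT": wt_params(), "V307L": v307l_params()}


@pytest.fixture(scope="session")
def self_targets():
    """Targets generated from the WT preset itself (truth objective ~ 0)."""
    truth = wt_params()
    eng = cf._Engine(truth)
    y60 = eng.steady(60.0)
    return truth, cf.FitTargets(
        iv={"WT": eng.activation_iv(cf.standard_protocol())},
        shift_target=-36.0,
        wt_tau_deact=eng.tau_deactivation(),
        wt_t_half_act=eng.t_half_activation(),
        po_max_target=float(y60[-2] + y60[-1]),
    )
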