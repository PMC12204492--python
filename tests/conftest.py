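import numpy as np
import pytest

import avoidpop as ap
from avoidpop.preprocess import build_trial_tensor, zscore_session

NULL_MOTIF = [ap.MotifSpec("null", {})]


def make_session(seed=0, n_neurons=20, n_trials=20, motifs=None, mixing=None,
                 **kw):
    cfg = ap.SimConfig(
        n_neurons=n_neurons, n_trials=n_trials, seed=seed,
        motifs=motifs, mixing=mixing, **kw,
    )
    return ap.generate_session(cfg)


def session_tensors(bundle, align="cs_onset", window=(-2.0, 3.0)):
    z = zscore_session(bundle)
    return z, build_trial_tensor(bundle, z, align, window)


@pytest.fixture(scope="session")
def default_session():
    """One session drawn from the default motif dictionary."""
    return make_session(seed=7, n_neurons=40, n_trials=20)


@pytest.fixture(scope="session")
def default_tensors(default_session):
    bundle, truth = default_session
    z = zscore_session(bundle)
    cs = build_trial_tensor(bundle, z, "cs_onset", (-2.0, 3.0))
    return dict(
        z=z,
        cs=cs,
        cs_success=cs.select("success"),
        cs_failure=cs.select("failure"),
        avrun=build_trial_tensor(bundle, z, "avrun_onset", (-3.0, 3.0)),
        shock=build_trial_tensor(bundle, z, "shock_onset", (-2.0, 3.0)),
        truth=truth,
        bundle=bundle,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
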