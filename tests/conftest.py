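import numpy as np
import pytest

from cuedreach.behavior import Reach, Trial, WindowSpec


def make_trial(t_cue=10.0, reaches=(), start=0.0, end=25.0, **kw):
    """Hand-built trial; reaches are (dt_from_cue, outcome) pairs."""
    return Trial(
        trial_start=start, trial_end=end, t_cue=t_cue,
        reaches=[Reach(t_arm=t_cue + dt, outcome=out) for dt, out in reaches],
        **kw,
    )


@pytest.fixture(scope="session")
def window_spec():
    return WindowSpec()


@pytest.fixture(scope="session")
def learned_session():
    """A session with planted cue response and reinforcement, reused by
    several analyses."""
    import cuedreach as cr

    cfg = cr.BehaviorGenConfig(n_trials=300, cue_gain=6.0,
                               reinforcement_delta=0.3)
    session, truth = cr.generate_session(cfg, seed=11)
    return session, truth


@pytest.fixture(scope="session")
def spn_population(learned_session):
    import cuedreach as cr

    session, _ = learned_session
    units, truth = cr.generate_population_spikes(
        session, cr.SpikeGenConfig(n_units=12), seed=21)
    return session, units, truth
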