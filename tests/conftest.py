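import numpy as np
import pytest

from msart.engine import SessionConfig, run_session
from msart.responder import MarkovResponder, ResponderParams


@pytest.fixture
def short_config():
    """A 2-minute session config: enough trials to exercise every code
    path, fast enough to simulate in bulk."""
    return SessionConfig(session_duration=120.0, rng_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def simulate():
    """Factory: simulate a Markov-responder session at a given severity,
    duration and seed."""

    def _sim(severity=0.5, duration=300.0, seed=0, **param_kw):
        cfg = SessionConfig(session_duration=duration, rng_seed=seed)
        params = ResponderParams(severity=severity, **param_kw)
        return run_session(cfg, MarkovResponder(params))

    return _sim


def replay_mode_trace(trials):
    """Hand-written fold of the mode-machine rules over a trial sequence.

    Returns the list of modes at which each stimulus should have been
    presented, plus the final (mode, consecutive_errors) pair.  Written
    directly from the transition rules, independent of the engine.
    """
    mode, cons = 1, 0
    expected_modes = []
    for t in trials:
        expected_modes.append(mode)
        if t.outcome == "nogo_correct":
            mode, cons = 1, 0
        elif t.outcome == "nogo_commission":
            mode, cons = min(mode + 1, 9), cons + 1
        if t.corrected:  # effective b-press after an error
            mode, cons = 1, 0
    return expected_modes, (mode, cons)
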