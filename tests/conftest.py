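"""Shared fixtures: small synthetic sessions built once per test run."""

from __future__ import annotations

import numpy as np
import pytest

from oddballv1 import core, stimgen, synth


def short_sequence(seed: int = 0, reps: int = 3, n_oddball: int = 40,
                   n_omission: int = 40) -> core.StimulusSequence:
    """A structurally complete but short session sequence."""
    rng = np.random.default_rng(seed)
    tun = stimgen.make_tuning_sequence(reps=reps,
                                       seed=int(rng.integers(2**31)))
    t = tun.events[-1].onset_s + 0.5 + 10.0
    odd = stimgen.make_oddball_sequence(n_trials=n_oddball,
                                        seed=int(rng.integers(2**31)),
                                        t_start_s=t)
    t = odd.events[-1].onset_s + 0.5 + 10.0
    omi = stimgen.make_omission_sequence(n_trials=n_omission,
                                         seed=int(rng.integers(2**31)),
                                         t_start_s=t)
    return tun + odd + omi


@pytest.fixture(scope="session")
def tiny_recording() -> tuple[core.Recording, list]:
    """16-unit wt-like session on a short 538-event-free sequence.

    Short blocks keep the simulation fast while exercising every stage
    (tuning, oddball, omission, 64-channel LFP).
    """
    regime = synth.wt_regime()
    units = synth.simulate_units(16, regime, seed=101)
    rec = synth.simulate_session(units, short_sequence(seed=7, reps=5),
                                 regime, seed=202)
    return rec, units


@pytest.fixture(scope="session")
def oddball_sequence() -> core.StimulusSequence:
    return stimgen.make_oddball_sequence(n_trials=200, seed=3)
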