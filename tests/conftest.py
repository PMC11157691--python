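"""Shared fixtures: synthetic arrays, field functions, and the two
expensive end-to-end simulations (drift and walking), run once per session."""

from __future__ import annotations

import numpy as np
import pytest

import opmloop as o
from opmloop.loop_simulator import LoopConfig
from opmloop.scenario_generator import (default_room_field, make_brain_noise,
                                        make_field, make_neural, make_stimuli,
                                        make_walk)


def homogeneous_field(vec):
    """Field function for a static homogeneous field (tesla 3-vector)."""
    vec = np.asarray(vec, dtype=float)

    def fn(pos, t):
        t = np.atleast_1d(t)
        return np.broadcast_to(vec, (t.shape[0], 3)).copy()

    return fn


def step_field(vec, t_on=0.05):
    """Homogeneous field switching on at t_on (initial nulling sees zero)."""
    vec = np.asarray(vec, dtype=float)

    def fn(pos, t):
        t = np.atleast_1d(t)
        out = np.zeros((t.shape[0], 3))
        out[t > t_on] = vec
        return out

    return fn


@pytest.fixture(scope="session")
def helmet21():
    """21-OPM array (42 channels) with feedback to 11 OPMs (22 channels),
    the split-array layout of the environmental-noise recording."""
    return o.make_helmet_array(21, feedback=11)


@pytest.fixture(scope="session")
def helmet17():
    """17-OPM array with feedback everywhere (the walking experiment)."""
    return o.make_helmet_array(17, feedback="all")


@pytest.fixture(scope="session")
def drift_result(helmet21):
    """160 s stationary recording in a drifting room with feedback to half
    the array: the split feedback-on/off noise comparison."""
    field_fn = make_field(default_room_field(drift_seed=7, with_gradient=False))
    res = o.simulate_closed_loop(helmet21, field_fn, duration=160.0,
                                 config=LoopConfig(), seed=3, store_truth=False)
    return res


@pytest.fixture(scope="session")
def walking_bundle(helmet17):
    """100 s walking run, feedback off and on, same background field and
    neural signal (evoked template + ongoing background activity)."""
    array = helmet17
    field_fn = make_field(default_room_field(drift_seed=11, with_gradient=True))
    traj = make_walk(100.0, seed=2)
    sched = make_stimuli(30, seed=9)
    fs, dur = 6000.0, 100.0
    n = int(dur * fs)
    neural = make_neural(sched, array, sample_rate=fs, duration=dur)
    neural = neural + make_brain_noise(array.n_channels, n, fs, seed=21)
    cfg = LoopConfig()
    runs = {
        onoff: o.simulate_closed_loop(
            array, field_fn, trajectory=traj, neural=neural, config=cfg,
            seed=4, feedback_on=(onoff == "on"), store_truth=False)
        for onoff in ("off", "on")
    }
    return {"array": array, "traj": traj, "sched": sched, "runs": runs,
            "sample_rate": fs}
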