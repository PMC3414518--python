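import numpy as np
import pytest

from smfm.event_model import (EventLog, Individual, InteractionBout,
                              ObservationEvent, Session)
from smfm.smfm_core import SMFMParams
from smfm.simulator import OutcomeModel, make_design, simulate_experiment


@pytest.fixture
def hand_log():
    """A small hand-built two-session log exercising every record type.

    Group g with three individuals (one demonstrator).  Session 1: the
    demonstrator solves the flap-left option twice, observed by a and
    (once) by b; a then abandons a tube-right bout.  Session 2: a solves
    flap-left (unobserved by b mid-bout), b abandons flap-right.
    """
    inds = (
        Individual("a", "g", "juvenile", "F", "subordinate"),
        Individual("b", "g", "adult", "M", "dominant"),
        Individual("d", "g", "adult", "M", "subordinate", True, "flap"),
    )
    sessions = (
        Session("s1", "g", 1, 0.0, 300.0, frozenset({"a", "b", "d"})),
        Session("s2", "g", 2, 0.0, 200.0, frozenset({"a", "b", "d"})),
    )
    bouts = (
        InteractionBout("b1", "s1", "d", "flap", "left", 10.0, 30.0,
                        True, True, "solved"),
        InteractionBout("b2", "s1", "d", "flap", "left", 100.0, 118.0,
                        True, True, "solved"),
        InteractionBout("b3", "s1", "a", "tube", "right", 150.0, 170.0,
                        False, False, "abandoned"),
        InteractionBout("b4", "s2", "a", "flap", "left", 50.0, 90.0,
                        True, True, "solved"),
        InteractionBout("b5", "s2", "b", "flap", "right", 120.0, 140.0,
                        False, False, "abandoned"),
    )
    obs = (
        ObservationEvent("a", "b1", 12.0, 30.0, True, True),
        ObservationEvent("a", "b2", 100.0, 110.0, True, False),
        ObservationEvent("b", "b2", 104.0, 118.0, True, True),
        ObservationEvent("b", "b4", 60.0, 80.0, True, False),
    )
    return EventLog(inds, sessions, bouts, obs).validate()


@pytest.fixture
def rich_params():
    """Parameters with every mechanism switched on (distinct magnitudes)."""
    return SMFMParams.build(
        r={"flap": 0.004, "tube": 0.0025},
        lambda_a={"subordinate": 0.06, "dominant": 0.01},
        s={"manipulation": 0.002, "entry": 0.005, "feeding": 0.003},
        gamma=2.5,
        g_general=0.8,
        g_box={"pup": 1.5, "juvenile": 1.2, "subadult": 1.0, "adult": 0.7},
        g_specific={"pup": 6.0, "juvenile": 4.0, "subadult": 3.0,
                    "adult": 2.0},
        g_sametype=0.4,
        rho=np.log(2) / 15.0,
        beta={"age_class=juvenile": 0.3, "sex=M": -0.2,
              "dominance=dominant": -0.5},
        u={"a": 0.1}, v={"g": -0.05},
    ).validate()


def small_sim(seed=0, n_groups=2, n_sessions=2, length=120.0, size=5,
              r=0.01, p_obs=0.5, condition="any", **param_kw):
    """A quick simulated experiment for tests needing a realistic log."""
    kw = dict(lambda_a=0.05, s={"entry": 0.004}, gamma=2.0, g_general=1.0,
              g_box=1.0, g_specific=4.0)
    kw.update(param_kw)
    params = SMFMParams.build(r=r, **kw)
    outcome = OutcomeModel(solve_rate={"flap": 0.05, "tube": 0.05},
                           abandon_rate={"flap": 0.1, "tube": 0.1})
    design = make_design(n_groups=n_groups, group_size_range=(size, size),
                         n_sessions=n_sessions,
                         session_length_range=(length, length),
                         n_seeded=max(1, n_groups - 1),
                         demo_bouts_per_session=2, demo_bout_duration=5.0,
                         p_obs=p_obs, condition=condition, seed=seed)
    log, truth = simulate_experiment(params, outcome, design, seed=seed)
    return log, params, outcome, design


@pytest.fixture
def sim_log():
    log, params, _, _ = small_sim(seed=7)
    return log, params
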