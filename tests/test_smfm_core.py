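"""Rate model: learning rule, transient kernels, rates, likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import oracles
from conftest import small_sim
from smfm.event_model import (EventLog, Individual, InteractionBout,
                              OBS_CLASSES, Session,
                              build_experience_timeline)
from smfm.smfm_core import (ContractError, OPTIONS, SMFMLikelihood,
                            SMFMParams, association_strength, half_life,
                            interaction_rate, kernel_contrasts,
                            linear_predictor, segment_integrated_hazard,
                            smfm_log_likelihood, specificity,
                            strengths_from_contrasts, transient_addend)


class TestAssociationStrength:
    def test_no_experience_is_zero(self):
        assert association_strength(0, {}, 0.05, {}) == 0.0

    @pytest.mark.parametrize("lam,R,expected", [
        (0.05, 2, 1 - 0.95 ** 2),       # closed form
        (0.051, 1, 0.051),              # one reward = the learning rate
        (0.0, 10, 0.0),
    ])
    def test_asocial_closed_form(self, lam, R, expected):
        assert association_strength(R, {}, lam, {}) == \
            pytest.approx(expected, abs=1e-12)

    def test_social_counts_multiply_in(self):
        got = association_strength(2, {"entry": 3, "feeding": 1}, 0.1,
                                   {"entry": 0.02, "feeding": 0.05})
        want = 1 - 0.9 ** 2 * 0.98 ** 3 * 0.95
        assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_rates_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            association_strength(1, {}, bad, {})
        with pytest.raises(ValueError):
            association_strength(1, {"entry": 2}, 0.1, {"entry": bad})

    @settings(max_examples=60, derandomize=True)
    @given(lam=st.floats(0, 0.99), s=st.floats(0, 0.99),
           R=st.integers(0, 50), O=st.integers(0, 50))
    def test_monotone_and_bounded(self, lam, s, R, O):
        a0 = association_strength(R, {"entry": O}, lam, {"entry": s})
        a1 = association_strength(R + 1, {"entry": O}, lam, {"entry": s})
        a2 = association_strength(R, {"entry": O + 1}, lam, {"entry": s})
        # bounded by 1 (attained only by floating-point saturation)
        assert 0.0 <= a0 <= a1 <= 1.0
        assert a0 <= a2 <= 1.0


class TestTransientKernels:
    def _obs_at(self, k, l, te):
        lo = {"any": te, "box": {"left": None, "right": None},
              "option": {"flap": None, "tube": None},
              "option_box": {o: None for o in OPTIONS}}
        lo["box"][l] = te
        lo["option"][k] = te
        lo["option_box"][(k, l)] = te
        return lo

    def test_no_observation_gives_zero_everywhere(self, rich_params):
        lo = {"any": None, "box": {"left": None, "right": None},
              "option": {"flap": None, "tube": None},
              "option_box": {o: None for o in OPTIONS}}
        T = transient_addend(5.0, lo, rich_params, "pup")
        assert all(v == 0.0 for v in T.values())

    def test_kernel_structure_at_zero_lag(self):
        p = SMFMParams.build(r=0.01, g_general=1.0, g_box=2.0,
                             g_specific=4.0)
        T = transient_addend(10.0, self._obs_at("flap", "left", 10.0), p,
                             "adult")
        assert T[("flap", "left")] == pytest.approx(1 + 2 + 4)
        assert T[("tube", "left")] == pytest.approx(1 + 2)
        assert T[("flap", "right")] == pytest.approx(1)
        assert T[("tube", "right")] == pytest.approx(1)

    def test_sametype_kernel_reaches_other_box(self):
        p = SMFMParams.build(r=0.01, g_general=1.0, g_sametype=3.0)
        T = transient_addend(0.0, self._obs_at("flap", "left", 0.0), p,
                             "adult")
        assert T[("flap", "right")] == pytest.approx(4.0)
        assert T[("tube", "right")] == pytest.approx(1.0)

    def test_half_life_halves_every_term(self, rich_params):
        lo = self._obs_at("tube", "right", 0.0)
        hl = rich_params.half_life
        T0 = transient_addend(0.0, lo, rich_params, "juvenile")
        T1 = transient_addend(hl, lo, rich_params, "juvenile")
        for o in OPTIONS:
            assert T1[o] == pytest.approx(0.5 * T0[o], rel=1e-12)

    def test_query_before_observation_is_an_error(self, rich_params):
        with pytest.raises(ValueError):
            transient_addend(1.0, self._obs_at("flap", "left", 2.0),
                             rich_params, "pup")

    def test_contrast_map_round_trips(self, rich_params):
        c = kernel_contrasts(rich_params, "juvenile")
        back = strengths_from_contrasts(**c)
        assert back["g_general"] == pytest.approx(
            rich_params.g_general["juvenile"])
        assert back["g_box"] == pytest.approx(
            rich_params.g_box["juvenile"])
        assert back["g_specific"] == pytest.approx(
            rich_params.g_specific["juvenile"])
        assert back["g_sametype"] == pytest.approx(
            rich_params.g_sametype["juvenile"])

    def test_three_kernel_model_recovered_when_sametype_zero(self):
        p = SMFMParams.build(r=0.01, g_general=1.0, g_box=2.0,
                             g_specific=3.0, g_sametype=0.0)
        c = kernel_contrasts(p, "adult")
        assert c["SODB"] == c["DODB"]  # no stimulus enhancement


class TestHalfLife:
    def test_field_scale_value(self):
        assert half_life(math.log(2) / 20.0) == pytest.approx(20.0)

    def test_unit_value(self):
        assert half_life(math.log(2)) == pytest.approx(1.0)

    def test_doubling_rho_halves_half_life(self):
        assert half_life(0.2) == pytest.approx(half_life(0.1) / 2)

    def test_requires_positive_rho(self):
        with pytest.raises(ValueError):
            half_life(0.0)


class TestInteractionRate:
    def test_collapses_to_baseline(self, hand_log):
        p = SMFMParams.build(r={"flap": 0.02, "tube": 0.03}, gamma=0.0)
        tl = build_experience_timeline(hand_log)
        for iid in ("a", "b"):
            for k, l in OPTIONS:
                dec = interaction_rate(iid, k, l, 250.0, "s1", p, tl)
                assert dec.total == pytest.approx(p.r[k])

    def test_learning_multiplier_case(self, hand_log):
        # A = 0.5 exactly: lambda such that 1-(1-lam)^1 = 0.5 after one
        # reward; a has one flap reward by late s2
        p = SMFMParams.build(r=0.02, lambda_a=0.5, gamma=1.0)
        tl = build_experience_timeline(hand_log)
        dec = interaction_rate("a", "flap", "left", 195.0, "s2", p, tl)
        assert dec.learning_multiplier == pytest.approx(1.5)
        assert dec.total == pytest.approx(1.5 * 0.02)

    def test_matches_independent_formula(self, hand_log, rich_params):
        tl = build_experience_timeline(hand_log)
        rng = np.random.default_rng(1)
        inds = {i.id: i for i in hand_log.individuals}
        for _ in range(25):
            s = hand_log.sessions[rng.integers(2)]
            iid = ("a", "b")[rng.integers(2)]
            t = float(rng.uniform(s.start_time, s.end_time))
            k, l = OPTIONS[rng.integers(4)]
            dec = interaction_rate(iid, k, l, t, s.session_id,
                                   rich_params, tl)
            # independent recompute from brute-force replayed state
            R, _, O = oracles.replay_counts(hand_log, iid, k,
                                            s.session_id, t)
            lam = rich_params.lambda_a[inds[iid].dominance]
            un = (1 - lam) ** R
            for c in OBS_CLASSES:
                un *= (1 - rich_params.s[c]) ** O[c]
            A = 1 - un
            lo = oracles.replay_last_obs(hand_log, iid, s.session_id, t)
            age = inds[iid].age_class
            T = 0.0
            for g, tau in ((rich_params.g_general[age], lo["any"]),
                           (rich_params.g_box[age], lo["box"][l]),
                           (rich_params.g_specific[age],
                            lo["option_box"][(k, l)]),
                           (rich_params.g_sametype[age],
                            lo["option"][k])):
                if tau is not None:
                    T += g * math.exp(-rich_params.rho * (t - tau))
            lp = sum(rich_params.beta.get(key, 0.0) for key in
                     (f"age_class={inds[iid].age_class}",
                      f"sex={inds[iid].sex}",
                      f"dominance={inds[iid].dominance}")) + \
                rich_params.u.get(iid, 0.0) + \
                rich_params.v.get(inds[iid].group_id, 0.0)
            want = rich_params.r[k] * math.exp(lp) * \
                (1 + rich_params.gamma * A + T)
            assert dec.total == pytest.approx(want, rel=1e-12)

    def test_monotone_in_strengths(self, hand_log):
        tl = build_experience_timeline(hand_log)
        base = SMFMParams.build(r=0.01, lambda_a=0.1, s={"entry": 0.01},
                                gamma=2.0, g_general=0.5, g_specific=1.0)
        t, sid = 40.0, "s1"  # a has an active clock from b1
        r0 = interaction_rate("a", "flap", "left", t, sid, base, tl).total
        for bump in ("g_general", "g_specific"):
            p = base.copy()
            getattr(p, bump)["juvenile"] += 1.0
            assert interaction_rate("a", "flap", "left", t, sid, p,
                                    tl).total > r0
        p = base.copy()
        p.gamma += 1.0
        assert interaction_rate("a", "flap", "left", t, sid, p,
                                tl).total >= r0


class TestSegmentIntegratedHazard:
    def test_constant_rate_segment(self, hand_log):
        p = SMFMParams.build(r=0.02, gamma=0.0)
        tl = build_experience_timeline(hand_log)
        got = segment_integrated_hazard(200.0, 260.0, "a", "flap", "left",
                                        "s1", p, tl)
        assert got == pytest.approx(0.02 * 60.0, rel=1e-12)

    def test_full_transient_mass_is_g_over_rho(self, hand_log):
        # b's only s2 clock is set at t=80 (end of its observation of b4)
        p = SMFMParams.build(r=0.01, g_specific=2.0, rho=0.5)
        tl = build_experience_timeline(hand_log)
        got = segment_integrated_hazard(80.0, 119.9, "b", "flap", "left",
                                        "s2", p, tl)
        # transient part converges to baseline * g/rho for a long window
        assert got == pytest.approx(0.01 * (39.9 + 2.0 / 0.5), rel=1e-3)

    def test_agrees_with_adaptive_quadrature(self, hand_log, rich_params):
        tl = build_experience_timeline(hand_log)
        t0, t1 = 80.0, 119.0  # within s2, no state change for b
        for k, l in OPTIONS:
            got = segment_integrated_hazard(t0, t1, "b", k, l, "s2",
                                            rich_params, tl)
            val, err = integrate.quad(
                lambda t: interaction_rate("b", k, l, t, "s2",
                                           rich_params, tl).total,
                t0, t1, epsabs=1e-10, epsrel=1e-10, limit=200)
            assert got == pytest.approx(val, abs=1e-8)

    def test_state_change_inside_segment_is_rejected(self, hand_log,
                                                     rich_params):
        tl = build_experience_timeline(hand_log)
        with pytest.raises(ContractError):
            segment_integrated_hazard(25.0, 35.0, "a", "flap", "left",
                                      "s1", rich_params, tl)


class TestLogLikelihood:
    def test_zero_events_survival_of_four_risks(self):
        ind = (Individual("x", "g", "adult", "F", "subordinate"),)
        sess = (Session("s", "g", 1, 0.0, 100.0, frozenset({"x"})),)
        log = EventLog(ind, sess, (), ())
        p = SMFMParams.build(r=0.02, gamma=0.0)
        v = smfm_log_likelihood(p, log)
        assert v.loglik == pytest.approx(-4 * 0.02 * 100.0)
        assert v.n_events == 0

    def test_single_event_exponential_density(self):
        ind = (Individual("x", "g", "adult", "F", "subordinate"),)
        sess = (Session("s", "g", 1, 0.0, 100.0, frozenset({"x"})),)
        eps = 1e-7
        bout = InteractionBout("b1", "s", "x", "flap", "left", 40.0,
                               40.0 + eps, False, False, "abandoned")
        log = EventLog(ind, sess, (bout,), ())
        r = 0.02
        p = SMFMParams.build(r=r, gamma=0.0)
        v = smfm_log_likelihood(p, log)
        want = math.log(r) - 4 * r * (100.0 - eps)
        assert v.loglik == pytest.approx(want, abs=1e-9)
        assert v.n_events == 1

    def test_invalid_params_yield_minus_inf_flag(self, hand_log):
        p = SMFMParams.build(r=0.01)
        p.rho = -1.0
        v = smfm_log_likelihood(p, hand_log)
        assert v.loglik == -np.inf and not v.valid

    @pytest.mark.parametrize("condition", ["any", "entry", "all_present"])
    def test_matches_grid_integration_oracle(self, condition):
        log, params, _, _ = small_sim(seed=2, length=60.0, size=4,
                                      n_groups=1, n_sessions=2,
                                      condition=condition)
        tl = build_experience_timeline(log)
        fast = SMFMLikelihood(log, condition=condition).loglik(params)
        slow = oracles.grid_loglik(log, params, tl, condition=condition,
                                   dt=0.01)
        assert fast == pytest.approx(slow, abs=1e-4)

    def test_homogeneous_collapse_matches_closed_form(self):
        log, _, _, _ = small_sim(seed=9, length=80.0, size=4, n_groups=1,
                                 n_sessions=1, lambda_a=0.0, s=0.0,
                                 gamma=0.0, g_general=0.0, g_box=0.0,
                                 g_specific=0.0)
        r = 0.01
        p = SMFMParams.build(r=r, gamma=0.0)
        inds = {i.id: i for i in log.individuals}
        closed = 0.0
        for s in log.sessions:
            for iid in s.attendees:
                if inds[iid].is_demonstrator:
                    continue
                at_risk = s.duration - sum(
                    b.t_end - b.t_start for b in log.bouts
                    if b.individual_id == iid and
                    b.session_id == s.session_id)
                closed -= 4 * r * at_risk
        closed += sum(math.log(r) for b in log.bouts
                      if not inds[b.individual_id].is_demonstrator)
        assert smfm_log_likelihood(p, log).loglik == \
            pytest.approx(closed, rel=1e-12)


class TestSpecificity:
    def test_symmetric_general_effect_gives_half(self):
        p = SMFMParams.build(r=0.01, g_general=2.0)
        assert specificity(p, "adult") == pytest.approx(0.5)

    def test_dominant_specific_effect_approaches_one(self):
        p = SMFMParams.build(r=0.01, g_specific=1e9)
        assert specificity(p, "adult") == pytest.approx(1.0, abs=1e-6)

    def test_matches_first_choice_simulation(self):
        p = SMFMParams.build(r=0.01, g_general=1.0, g_box=1.0,
                             g_specific=1.0)
        want = specificity(p, "adult", observed=("flap", "left"))
        # competing-exponential first choice immediately after observation
        rng = np.random.default_rng(0)
        rates = np.array([p.r[k] * (1 + 1.0 +
                                    (1.0 if l == "left" else 0.0) +
                                    (1.0 if (k, l) == ("flap", "left")
                                     else 0.0))
                          for k, l in OPTIONS])
        winners = rng.exponential(1 / rates, size=(20000, 4)).argmin(axis=1)
        freq_same = np.isin(winners, [0, 1]).mean()
        assert want == pytest.approx(freq_same, abs=0.01)

    def test_rate_asymmetry_shifts_specificity(self):
        p = SMFMParams.build(r={"flap": 0.02, "tube": 0.01},
                             g_general=1.0)
        assert specificity(p, "adult", observed=("flap", "left")) > 0.5


class TestParams:
    def test_validation_catches_bad_values(self):
        p = SMFMParams.build(r=0.01)
        p.lambda_a["dominant"] = 1.5
        assert any("lambda_a" in e for e in p.validation_errors())
        with pytest.raises(ValueError):
            p.validate()

    def test_dict_round_trip(self, rich_params):
        d = rich_params.to_dict()
        assert SMFMParams.from_dict(d) == rich_params

    def test_linear_predictor_uses_contrasts(self, rich_params):
        juv = Individual("a", "g", "juvenile", "F", "subordinate")
        ref = Individual("z", "g", "adult", "F", "subordinate")
        assert linear_predictor(juv, rich_params) == pytest.approx(
            0.3 + 0.1 - 0.05)   # age contrast + u_a + v_g
        assert linear_predictor(ref, rich_params) == pytest.approx(-0.05)
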