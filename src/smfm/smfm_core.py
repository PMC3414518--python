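"""Stochastic mechanism-fitting model (SMFM) of task interaction.

The model treats each individual's initiation of interaction bouts as a
competing-risks inhomogeneous point process over the four options
(option-type k in {flap, tube} x box side l in {left, right}).  The rate
at which individual *i* of group *j* initiates a bout at option (k, l) at
time *t* of a session is

    rate_ikl(t) = r_k * exp(beta.x_i + u_i + v_j)
                      * (1 + gamma * A_ik(t) + T_ikl(t))

where

* ``r_k`` is the baseline rate for option-type k (events/second),
* ``beta.x_i`` collects time-constant covariate effects (age class, sex,
  dominance) and ``u_i``, ``v_j`` are log-scale individual and group
  random effects,
* ``A_ik(t)`` is i's learned association of option-type k with reward —
  the count-based closed form of the Rescorla-Wagner rule extended with
  observation counts,

      A = 1 - (1 - lambda_a)^R * prod_c (1 - s_c)^{O_c},

  with R the number of past rewarded bouts at k, O_c the number of past
  observations of others manipulating k in class c (manipulation seen /
  entry seen / feeding seen, as nested increments), ``lambda_a`` the
  asocial learning rate (per dominance class) and ``s_c`` the social
  learning rates,
* ``gamma`` scales the influence of learning on the interaction rate, and
* ``T_ikl(t)`` is the transient social effect: exponentially decaying
  kernels keyed on the time since the last qualifying observation this
  session.  The kernels are parameterized hierarchically: a general term
  (any option observed), a box-level local-enhancement term (same box), a
  specific local-enhancement term (same option and box) and an optional
  same-option-type (stimulus enhancement) term,

      T = g_general * exp(-rho (t - tau_any))
        + g_box     * exp(-rho (t - tau_box=l))
        + g_specific* exp(-rho (t - tau_(k,l)))
        + g_sametype* exp(-rho (t - tau_option=k)),

  each term using only the most recent qualifying observation and equal
  to zero before the first such observation of the session.  A single
  decay rate ``rho`` is shared; ln(2)/rho is the half-life of the
  transient effects.

The additive composition of the learning multiplier and the transient
term (the decomposition total = baseline * (1 + gamma*A + T)) is a
reconstruction; see docs/methods.md.  It is isolated here so that an
alternative fully multiplicative composition can be swapped in one place.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .event_model import (AGE_CLASSES, BOX_SIDES, CONDITIONS, DOMINANCE,
                          EventLog, ExperienceTimeline, Individual,
                          OBS_CLASSES, OPTION_TYPES,
                          build_experience_timeline)

#: Flat option order used throughout: (flap,left), (flap,right),
#: (tube,left), (tube,right).
OPTIONS = tuple((k, l) for k in OPTION_TYPES for l in BOX_SIDES)
_OPT_K = np.array([0, 0, 1, 1])  # option-type index per flat option
_OPT_L = np.array([0, 1, 0, 1])  # box-side index per flat option

#: Covariate keys for the linear predictor (treatment contrasts; reference
#: levels are adult, F, subordinate).
BETA_KEYS = ("age_class=pup", "age_class=juvenile", "age_class=subadult",
             "sex=M", "dominance=dominant")

KERNELS = ("general", "box", "specific", "sametype")


class ContractError(ValueError):
    """A closed-form segment was asked to span a state change."""


def _per(keys, x, fill=0.0) -> dict:
    if isinstance(x, dict):
        out = {k: float(fill) for k in keys}
        for k, v in x.items():
            if k not in out:
                raise ValueError(f"unknown key {k!r}; expected one of {keys}")
            out[k] = float(v)
        return out
    return {k: float(x) for k in keys}


def per_age(x) -> dict:
    return _per(AGE_CLASSES, x)


def per_dominance(x) -> dict:
    return _per(DOMINANCE, x)


def per_option_type(x) -> dict:
    return _per(OPTION_TYPES, x)


def per_obs_class(x) -> dict:
    return _per(OBS_CLASSES, x)


@dataclass
class SMFMParams:
    """Full parameter vector of the rate model.

    ``r`` per option-type; ``lambda_a`` per dominance class; ``s`` per
    observation class; transient strengths per age class (dimensionless
    multiples of baseline); ``rho`` in 1/seconds.  ``beta`` maps
    :data:`BETA_KEYS` entries to contrasts; ``u``/``v`` are log-scale
    individual/group random-effect values.
    """

    r: dict
    lambda_a: dict
    s: dict
    gamma: float
    g_general: dict
    g_box: dict
    g_specific: dict
    g_sametype: dict
    rho: float
    beta: dict = field(default_factory=dict)
    sigma_ind: float = 0.0
    sigma_group: float = 0.0
    u: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    @classmethod
    def build(cls, r=1.6e-4, lambda_a=0.0, s=0.0, gamma=1.0, g_general=0.0,
              g_box=0.0, g_specific=0.0, g_sametype=0.0,
              rho=math.log(2) / 20.0, **kw) -> "SMFMParams":
        """Construct from scalars (broadcast) or partial dicts (rest 0)."""
        return cls(r=per_option_type(r), lambda_a=per_dominance(lambda_a),
                   s=per_obs_class(s), gamma=float(gamma),
                   g_general=per_age(g_general), g_box=per_age(g_box),
                   g_specific=per_age(g_specific),
                   g_sametype=per_age(g_sametype), rho=float(rho), **kw)

    @property
    def half_life(self) -> float:
        return half_life(self.rho)

    def validation_errors(self) -> list[str]:
        errs = []
        for k in OPTION_TYPES:
            if not self.r.get(k, -1.0) > 0:
                errs.append(f"r[{k}] must be > 0")
        for d in DOMINANCE:
            if not 0 <= self.lambda_a.get(d, -1.0) < 1:
                errs.append(f"lambda_a[{d}] must be in [0, 1)")
        for c in OBS_CLASSES:
            if not 0 <= self.s.get(c, -1.0) < 1:
                errs.append(f"s[{c}] must be in [0, 1)")
        if not self.gamma >= 0:
            errs.append("gamma must be >= 0")
        for name in ("g_general", "g_box", "g_specific", "g_sametype"):
            g = getattr(self, name)
            for a in AGE_CLASSES:
                if not g.get(a, -1.0) >= 0:
                    errs.append(f"{name}[{a}] must be >= 0")
        if not self.rho > 0:
            errs.append("rho must be > 0")
        if self.sigma_ind < 0 or self.sigma_group < 0:
            errs.append("random-effect SDs must be >= 0")
        for key in self.beta:
            if key not in BETA_KEYS:
                errs.append(f"unknown covariate key {key!r}")
        return errs

    def validate(self) -> "SMFMParams":
        errs = self.validation_errors()
        if errs:
            raise ValueError("invalid SMFMParams: " + "; ".join(errs))
        return self

    def copy(self) -> "SMFMParams":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return {"r": dict(self.r), "lambda_a": dict(self.lambda_a),
                "s": dict(self.s), "gamma": self.gamma,
                "g_general": dict(self.g_general), "g_box": dict(self.g_box),
                "g_specific": dict(self.g_specific),
                "g_sametype": dict(self.g_sametype), "rho": self.rho,
                "beta": dict(self.beta), "sigma_ind": self.sigma_ind,
                "sigma_group": self.sigma_group, "u": dict(self.u),
                "v": dict(self.v)}

    @classmethod
    def from_dict(cls, d: dict) -> "SMFMParams":
        return cls(r=dict(d["r"]), lambda_a=dict(d["lambda_a"]),
                   s=dict(d["s"]), gamma=float(d["gamma"]),
                   g_general=dict(d["g_general"]), g_box=dict(d["g_box"]),
                   g_specific=dict(d["g_specific"]),
                   g_sametype=dict(d["g_sametype"]), rho=float(d["rho"]),
                   beta=dict(d.get("beta", {})),
                   sigma_ind=float(d.get("sigma_ind", 0.0)),
                   sigma_group=float(d.get("sigma_group", 0.0)),
                   u=dict(d.get("u", {})), v=dict(d.get("v", {})))


@dataclass(frozen=True)
class ModelVariant:
    """Flags selecting a fitted model structure.

    ``condition`` filters which events set the transient clocks ("any",
    "entry", "feeding", "all_present"); ``transient=False`` removes the
    transient kernels (and rho) entirely; ``social_classes`` lists the
    observation classes whose s parameters are free; ``lambda_by_dominance``
    and ``g_by_age`` untie the respective class-level parameters;
    ``covariates`` lists free ``beta`` keys; ``random_effects`` adds
    centred individual/group effects with half-normal hyper-SD priors.
    """

    label: str = "full"
    condition: str = "any"
    transient: bool = True
    social_classes: tuple = ("entry",)
    lambda_by_dominance: bool = False
    g_by_age: bool = False
    sametype_kernel: bool = False
    covariates: tuple = ()
    random_effects: bool = False

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class RateDecomposition:
    """One evaluated rate split into its components.

    ``total = baseline * learning_multiplier + baseline * transient_addend``
    with ``baseline = r_k * exp(linear predictor)`` and
    ``learning_multiplier = 1 + gamma * A``.  ``transient_terms`` lists the
    active kernel terms as (strength, seconds-since-observation) pairs.
    """

    baseline: float
    learning_multiplier: float
    transient_addend: float
    transient_terms: tuple
    total: float


@dataclass(frozen=True)
class LikelihoodValue:
    loglik: float
    n_events: int
    n_segments: int
    valid: bool = True


def half_life(rho: float) -> float:
    """Half-life ln(2)/rho (seconds) of the transient social effects."""
    if not rho > 0:
        raise ValueError("rho must be > 0")
    return math.log(2.0) / rho


def association_strength(R: int, O_by_class: dict, lambda_a: float,
                         s_by_class: dict) -> float:
    """Rescorla-Wagner association A = 1 - (1-lambda)^R prod_c (1-s_c)^O_c.

    Non-decreasing in every count and bounded by [0, 1).
    """
    if not 0 <= lambda_a < 1:
        raise ValueError("lambda_a must be in [0, 1)")
    if R < 0:
        raise ValueError("counts must be >= 0")
    unlearned = (1.0 - lambda_a) ** R
    for c in OBS_CLASSES:
        s_c = s_by_class.get(c, 0.0)
        if not 0 <= s_c < 1:
            raise ValueError(f"s[{c}] must be in [0, 1)")
        O_c = O_by_class.get(c, 0)
        if O_c < 0:
            raise ValueError("counts must be >= 0")
        unlearned *= (1.0 - s_c) ** O_c
    return 1.0 - unlearned


def linear_predictor(individual: Individual, params: SMFMParams) -> float:
    """Time-constant covariate effects plus random effects, on log scale."""
    lp = 0.0
    for key in (f"age_class={individual.age_class}",
                f"sex={individual.sex}",
                f"dominance={individual.dominance}"):
        lp += params.beta.get(key, 0.0)
    lp += params.u.get(individual.id, 0.0)
    lp += params.v.get(individual.group_id, 0.0)
    return lp


def _kernel_terms(last_obs: dict, option_type: str, box_side: str,
                  params: SMFMParams, age_class: str, t: float) -> list:
    """Active (strength, dt) transient terms for one option at time *t*."""
    terms = []
    for g, tau in ((params.g_general[age_class], last_obs["any"]),
                   (params.g_box[age_class], last_obs["box"][box_side]),
                   (params.g_specific[age_class],
                    last_obs["option_box"][(option_type, box_side)]),
                   (params.g_sametype[age_class],
                    last_obs["option"][option_type])):
        if tau is None:
            continue
        dt = t - tau
        if dt < 0:
            raise ValueError(f"query time {t} precedes an observation at "
                             f"{tau}")
        terms.append((g, dt))
    return terms


def transient_addend(t: float, last_obs: dict, params: SMFMParams,
                     age_class: str) -> dict:
    """Transient addend T for each of the four options at time *t*.

    *last_obs* is the structure returned by
    :meth:`ExperienceTimeline.last_observation_times`.  Each kernel term is
    ``g * exp(-rho dt)`` with dt the time since the most recent qualifying
    observation; the value halves every ln(2)/rho seconds.
    """
    out = {}
    for k, l in OPTIONS:
        total = 0.0
        for g, dt in _kernel_terms(last_obs, k, l, params, age_class, t):
            total += g * math.exp(-params.rho * dt)
        out[(k, l)] = total
    return out


def kernel_contrasts(params: SMFMParams, age_class: str) -> dict:
    """Raw transient contrasts from the hierarchical strengths.

    SOSB (same option, same box) = general + box + specific + sametype;
    SODB = general + sametype; DOSB = general + box; DODB = general.
    Stimulus enhancement corresponds to SODB > DODB, i.e. g_sametype > 0.
    """
    gg = params.g_general[age_class]
    gb = params.g_box[age_class]
    gs = params.g_specific[age_class]
    gt = params.g_sametype[age_class]
    return {"SOSB": gg + gb + gs + gt, "SODB": gg + gt,
            "DOSB": gg + gb, "DODB": gg}


def strengths_from_contrasts(SOSB: float, SODB: float, DOSB: float,
                             DODB: float) -> dict:
    """Exact inverse of :func:`kernel_contrasts`."""
    return {"g_general": DODB, "g_sametype": SODB - DODB,
            "g_box": DOSB - DODB,
            "g_specific": SOSB - SODB - DOSB + DODB}


def interaction_rate(individual_id: str, option_type: str, box_side: str,
                     t: float, session_id: str, params: SMFMParams,
                     timeline: ExperienceTimeline,
                     condition: str = "any") -> RateDecomposition:
    """Instantaneous initiation rate for one individual and option.

    Experience counts use the state strictly before *t*; transient clocks
    include observations ending exactly at *t* (full-strength effect
    immediately after observation).  The caller is responsible for only
    querying times at which the individual is at risk (attending and not
    mid-bout).
    """
    ind = timeline.log.individual(individual_id)
    R = timeline.reward_count(individual_id, option_type, session_id, t)
    O = {c: timeline.observation_count(individual_id, option_type, c,
                                       session_id, t) for c in OBS_CLASSES}
    A = association_strength(R, O, params.lambda_a[ind.dominance], params.s)
    last_obs = timeline.last_observation_times(individual_id, session_id, t,
                                               condition)
    terms = tuple(_kernel_terms(last_obs, option_type, box_side, params,
                                ind.age_class, t))
    T = sum(g * math.exp(-params.rho * dt) for g, dt in terms)
    baseline = params.r[option_type] * math.exp(linear_predictor(ind, params))
    mult = 1.0 + params.gamma * A
    return RateDecomposition(baseline=baseline, learning_multiplier=mult,
                             transient_addend=T, transient_terms=terms,
                             total=baseline * (mult + T))


def segment_integrated_hazard(t0: float, t1: float, individual_id: str,
                              option_type: str, box_side: str,
                              session_id: str, params: SMFMParams,
                              timeline: ExperienceTimeline,
                              condition: str = "any") -> float:
    """Exact integral of the rate over a state-constant segment (t0, t1].

    Raises :class:`ContractError` if any event changes the individual's
    experience state, transient clocks or at-risk status inside the segment.
    """
    if not t1 >= t0:
        raise ValueError("t1 must be >= t0")
    ind = timeline.log.individual(individual_id)
    # state-change guard: counts and clocks at the segment start (inclusive)
    # must match those just before the segment end.
    state0 = _state_key(timeline, individual_id, session_id, t0,
                        inclusive=True, condition=condition)
    state1 = _state_key(timeline, individual_id, session_id, t1,
                        inclusive=False, condition=condition)
    if state0 != state1:
        raise ContractError(
            f"segment ({t0}, {t1}] of {individual_id!r} spans a state change")
    for b in timeline.log.bouts:
        if b.individual_id == individual_id and b.session_id == session_id \
                and t0 < b.t_start < t1:
            raise ContractError(
                f"segment ({t0}, {t1}] spans bout {b.bout_id!r} of the "
                f"individual")
    R = timeline.reward_count(individual_id, option_type, session_id, t0,
                              inclusive=True)
    O = {c: timeline.observation_count(individual_id, option_type, c,
                                       session_id, t0, inclusive=True)
         for c in OBS_CLASSES}
    A = association_strength(R, O, params.lambda_a[ind.dominance], params.s)
    last_obs = timeline.last_observation_times(individual_id, session_id, t0,
                                               condition)
    baseline = params.r[option_type] * math.exp(linear_predictor(ind, params))
    total = (1.0 + params.gamma * A) * (t1 - t0)
    for g, dt in _kernel_terms(last_obs, option_type, box_side, params,
                               ind.age_class, t0):
        total += g / params.rho * (math.exp(-params.rho * dt) -
                                   math.exp(-params.rho * (dt + t1 - t0)))
    return baseline * total


def _state_key(timeline, individual_id, session_id, t, inclusive, condition):
    counts = tuple(
        (timeline.reward_count(individual_id, k, session_id, t, inclusive),
         timeline.failure_count(individual_id, k, session_id, t, inclusive))
        + tuple(timeline.observation_count(individual_id, k, c, session_id,
                                           t, inclusive)
                for c in OBS_CLASSES)
        for k in OPTION_TYPES)
    lo = timeline.last_observation_times(individual_id, session_id, t,
                                         condition)
    taus = (lo["any"],) + tuple(lo["box"][l] for l in BOX_SIDES) + \
        tuple(lo["option"][k] for k in OPTION_TYPES) + \
        tuple(lo["option_box"][o] for o in OPTIONS)
    return counts, taus


def specificity(params: SMFMParams, age_class: str,
                observed: tuple = ("flap", "left")) -> float:
    """Probability a naive observer uses the observed option-type.

    Evaluated immediately after observing a manipulation at *observed*
    (dt = 0), for a naive individual (A = 0), given that it initiates a bout
    at one of the four options: the ratio of the summed rates of the two
    same-option-type options to the total.
    """
    k_obs, l_obs = observed
    gg = params.g_general[age_class]
    gb = params.g_box[age_class]
    gs = params.g_specific[age_class]
    gt = params.g_sametype[age_class]
    rates = {}
    for k, l in OPTIONS:
        T = gg
        if l == l_obs:
            T += gb
        if k == k_obs:
            T += gt
        if (k, l) == (k_obs, l_obs):
            T += gs
        rates[(k, l)] = params.r[k] * (1.0 + T)
    same = sum(v for (k, _), v in rates.items() if k == k_obs)
    return same / sum(rates.values())


# ---------------------------------------------------------------------------
# Exact log-likelihood over an event log
# ---------------------------------------------------------------------------

class SMFMLikelihood:
    """Compiled exact log-likelihood of bout initiations for one event log.

    Compilation walks every attended (individual, session) pair once,
    cutting the session into segments on which the individual's experience
    state, transient clocks and at-risk status are all constant; the
    integrated hazard is then closed-form per segment and the log-likelihood
    is a vectorized function of the parameters.  Demonstrators' bouts feed
    other individuals' experience but demonstrators themselves are excluded
    from the fitted process.
    """

    def __init__(self, log: EventLog, condition: str = "any",
                 exclude_demonstrators: bool = True):
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        log.validate()
        self.log = log
        self.condition = condition
        self.timeline = build_experience_timeline(log)
        self.individual_ids = [i.id for i in log.individuals
                               if not (exclude_demonstrators and
                                       i.is_demonstrator)]
        idx = {iid: n for n, iid in enumerate(self.individual_ids)}
        self.group_ids = list(log.group_ids)
        gidx = {g: n for n, g in enumerate(self.group_ids)}
        inds = log._ind_index()
        # design matrix for the linear predictor
        X = np.zeros((len(self.individual_ids), len(BETA_KEYS)))
        ind_group = np.zeros(len(self.individual_ids), dtype=int)
        ind_age = np.zeros(len(self.individual_ids), dtype=int)
        ind_dom = np.zeros(len(self.individual_ids), dtype=int)
        for n, iid in enumerate(self.individual_ids):
            ind = inds[iid]
            for m, key in enumerate(BETA_KEYS):
                fieldname, level = key.split("=")
                if getattr(ind, fieldname) == level:
                    X[n, m] = 1.0
            ind_group[n] = gidx[ind.group_id]
            ind_age[n] = AGE_CLASSES.index(ind.age_class)
            ind_dom[n] = DOMINANCE.index(ind.dominance)
        self._X, self._ind_group = X, ind_group

        seg = {"dur": [], "ind": [], "dom": [], "age": [], "R": [], "O": [],
               "Dgen": [], "Dbox": [], "Dspec": [], "Dsame": []}
        ev = {"ind": [], "dom": [], "age": [], "opt": [], "R": [], "O": [],
              "dgen": [], "dbox": [], "dspec": [], "dsame": []}
        tl = self.timeline
        bouts_by = {}
        for b in log.bouts:
            bouts_by.setdefault((b.individual_id, b.session_id),
                                []).append(b)
        obs_by = tl._session_obs
        for s in log.sessions:
            manip_ends = [te for te, _, _, _
                          in tl._session_manips[s.session_id]]
            for iid in s.attendees:
                if iid not in idx:
                    continue
                n = idx[iid]
                own = sorted(bouts_by.get((iid, s.session_id), []),
                             key=lambda b: b.t_start)
                pts = {s.start_time, s.end_time}
                for b in own:
                    pts.add(b.t_start)
                    pts.add(b.t_end)
                for row in obs_by.get((iid, s.session_id), []):
                    pts.add(row[0])
                if condition == "all_present":
                    pts.update(te for te in manip_ends
                               if s.start_time <= te <= s.end_time)
                pts = sorted(t for t in pts
                             if s.start_time <= t <= s.end_time)
                own_iv = [(b.t_start, b.t_end) for b in own]
                for a, b_t in zip(pts, pts[1:]):
                    if b_t <= a:
                        continue
                    mid = 0.5 * (a + b_t)
                    if any(lo < mid < hi for lo, hi in own_iv):
                        continue  # mid-bout: not at risk for initiation
                    self._append_segment(seg, n, ind_dom[n], ind_age[n],
                                         iid, s.session_id, a, b_t)
                for b in own:
                    if b.option_type not in OPTION_TYPES:
                        continue
                    self._append_event(ev, n, ind_dom[n], ind_age[n], iid,
                                       s.session_id, b)
        self._seg_dur = np.asarray(seg["dur"])
        self._seg_ind = np.asarray(seg["ind"], dtype=int)
        self._seg_dom = np.asarray(seg["dom"], dtype=int)
        self._seg_age = np.asarray(seg["age"], dtype=int)
        self._seg_R = np.asarray(seg["R"], dtype=float).reshape(-1, 2)
        self._seg_O = np.asarray(seg["O"], dtype=float).reshape(-1, 2, 3)
        n_seg = len(self._seg_dur)
        self._seg_D = {
            "general": np.repeat(np.asarray(seg["Dgen"]).reshape(-1, 1), 4,
                                 axis=1),
            "box": np.asarray(seg["Dbox"]).reshape(-1, 2)[:, _OPT_L],
            "specific": np.asarray(seg["Dspec"]).reshape(-1, 4),
            "sametype": np.asarray(seg["Dsame"]).reshape(-1, 2)[:, _OPT_K],
        } if n_seg else {k: np.zeros((0, 4)) for k in KERNELS}
        self._ev_ind = np.asarray(ev["ind"], dtype=int)
        self._ev_dom = np.asarray(ev["dom"], dtype=int)
        self._ev_age = np.asarray(ev["age"], dtype=int)
        self._ev_opt = np.asarray(ev["opt"], dtype=int)
        self._ev_R = np.asarray(ev["R"], dtype=float)
        self._ev_O = np.asarray(ev["O"], dtype=float).reshape(-1, 3)
        self._ev_D = {"general": np.asarray(ev["dgen"]),
                      "box": np.asarray(ev["dbox"]),
                      "specific": np.asarray(ev["dspec"]),
                      "sametype": np.asarray(ev["dsame"])}
        self.n_events = len(self._ev_ind)
        self.n_segments = n_seg

    def _append_segment(self, seg, n, dom, age, iid, sid, a, b):
        tl = self.timeline
        seg["dur"].append(b - a)
        seg["ind"].append(n)
        seg["dom"].append(dom)
        seg["age"].append(age)
        seg["R"].append([tl.reward_count(iid, k, sid, a, inclusive=True)
                         for k in OPTION_TYPES])
        seg["O"].append([[tl.observation_count(iid, k, c, sid, a,
                                               inclusive=True)
                          for c in OBS_CLASSES] for k in OPTION_TYPES])
        lo = tl.last_observation_times(iid, sid, a, self.condition)
        inf = np.inf
        seg["Dgen"].append(a - lo["any"] if lo["any"] is not None else inf)
        seg["Dbox"].append([a - lo["box"][l] if lo["box"][l] is not None
                            else inf for l in BOX_SIDES])
        seg["Dspec"].append([a - lo["option_box"][o]
                             if lo["option_box"][o] is not None else inf
                             for o in OPTIONS])
        seg["Dsame"].append([a - lo["option"][k]
                             if lo["option"][k] is not None else inf
                             for k in OPTION_TYPES])

    def _append_event(self, ev, n, dom, age, iid, sid, bout):
        tl = self.timeline
        t = bout.t_start
        k = bout.option_type
        opt = OPTIONS.index((k, bout.box_side))
        ev["ind"].append(n)
        ev["dom"].append(dom)
        ev["age"].append(age)
        ev["opt"].append(opt)
        ev["R"].append(tl.reward_count(iid, k, sid, t))
        ev["O"].append([tl.observation_count(iid, k, c, sid, t)
                        for c in OBS_CLASSES])
        lo = tl.last_observation_times(iid, sid, t, self.condition)
        inf = np.inf
        ev["dgen"].append(t - lo["any"] if lo["any"] is not None else inf)
        ev["dbox"].append(t - lo["box"][bout.box_side]
                          if lo["box"][bout.box_side] is not None else inf)
        ev["dspec"].append(t - lo["option_box"][(k, bout.box_side)]
                           if lo["option_box"][(k, bout.box_side)] is not None
                           else inf)
        ev["dsame"].append(t - lo["option"][k]
                           if lo["option"][k] is not None else inf)

    # -- evaluation --------------------------------------------------------
    def loglik(self, params: SMFMParams) -> float:
        p = params
        lam = np.array([p.lambda_a[d] for d in DOMINANCE])
        s = np.array([p.s[c] for c in OBS_CLASSES])
        rk = np.array([p.r[k] for k in OPTION_TYPES])
        r_opt = rk[_OPT_K]
        g = {"general": np.array([p.g_general[a] for a in AGE_CLASSES]),
             "box": np.array([p.g_box[a] for a in AGE_CLASSES]),
             "specific": np.array([p.g_specific[a] for a in AGE_CLASSES]),
             "sametype": np.array([p.g_sametype[a] for a in AGE_CLASSES])}
        rho, gamma = p.rho, p.gamma
        beta_vec = np.array([p.beta.get(k, 0.0) for k in BETA_KEYS])
        u_vec = np.array([p.u.get(iid, 0.0) for iid in self.individual_ids])
        v_vec = np.array([p.v.get(gid, 0.0) for gid in self.group_ids])
        E = np.exp(self._X @ beta_vec + u_vec +
                   (v_vec[self._ind_group] if len(v_vec) else 0.0))

        total = 0.0
        if self.n_segments:
            one_m_lam = (1.0 - lam)[self._seg_dom]
            A = 1.0 - one_m_lam[:, None] ** self._seg_R * \
                np.prod((1.0 - s)[None, None, :] ** self._seg_O, axis=2)
            mult = 1.0 + gamma * A[:, _OPT_K]
            dur = self._seg_dur[:, None]
            Ti = np.zeros_like(mult)
            for kern in KERNELS:
                gk = g[kern][self._seg_age]
                if not gk.any():
                    continue
                D = self._seg_D[kern]
                Ti += gk[:, None] * (np.exp(-rho * D) -
                                     np.exp(-rho * (D + dur))) / rho
            total -= float(np.sum(E[self._seg_ind, None] * r_opt[None, :] *
                                  (mult * dur + Ti)))
        if self.n_events:
            A_e = 1.0 - (1.0 - lam)[self._ev_dom] ** self._ev_R * \
                np.prod((1.0 - s)[None, :] ** self._ev_O, axis=1)
            T_e = np.zeros(self.n_events)
            for kern in KERNELS:
                gk = g[kern][self._ev_age]
                if not gk.any():
                    continue
                T_e += gk * np.exp(-rho * self._ev_D[kern])
            rate_e = r_opt[self._ev_opt] * E[self._ev_ind] * \
                (1.0 + gamma * A_e + T_e)
            total += float(np.sum(np.log(rate_e)))
        return total

    def value(self, params: SMFMParams) -> LikelihoodValue:
        if params.validation_errors():
            return LikelihoodValue(-np.inf, self.n_events, self.n_segments,
                                   valid=False)
        return LikelihoodValue(self.loglik(params), self.n_events,
                               self.n_segments, valid=True)


def smfm_log_likelihood(params: SMFMParams, log: EventLog,
                        condition: str = "any") -> LikelihoodValue:
    """Exact log-likelihood of all bout initiations under the SMFM.

    Convenience wrapper that compiles the log each call; repeated
    evaluations (optimization, MCMC) should hold an :class:`SMFMLikelihood`.
    Invalid parameters yield ``-inf`` with ``valid=False``.
    """
    lik = SMFMLikelihood(log, condition=condition)
    return lik.value(params)
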