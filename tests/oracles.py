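"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities by naive full-log re-scans or
dense numerical integration, deliberately sharing no state-tracking or
segmentation code with the package implementation.
"""

from __future__ import annotations

import numpy as np

from smfm.event_model import BOX_SIDES, OBS_CLASSES, OPTION_TYPES
from smfm.smfm_core import interaction_rate


def session_order(log):
    return {s.session_id: n for n, s in enumerate(
        sorted(log.sessions, key=lambda s: (s.group_id, s.index)))}


def replay_counts(log, individual_id, option_type, session_id, t,
                  inclusive=False):
    """Re-scan the full log for (R, F, O-by-class) strictly before t."""
    order = session_order(log)
    key = (order[session_id], t)

    def before(sid, te):
        k = (order[sid], te)
        return k <= key if inclusive else k < key

    R = F = 0
    O = {c: 0 for c in OBS_CLASSES}
    bindex = {b.bout_id: b for b in log.bouts}
    for b in log.bouts:
        if b.individual_id != individual_id or \
                b.option_type != option_type:
            continue
        if before(b.session_id, b.t_end):
            if b.outcome == "solved":
                R += 1
            else:
                F += 1
    for o in log.observations:
        b = bindex[o.target_bout_id]
        if o.observer_id != individual_id or b.option_type != option_type:
            continue
        if before(b.session_id, o.t_end):
            O["manipulation"] += 1
            if o.saw_entry:
                O["entry"] += 1
            if o.saw_feeding:
                O["feeding"] += 1
    return R, F, O


def replay_last_obs(log, individual_id, session_id, t, condition="any"):
    """Re-scan the full log for the transient clocks at time t."""
    out = {"any": None, "box": {l: None for l in BOX_SIDES},
           "option": {k: None for k in OPTION_TYPES},
           "option_box": {(k, l): None for k in OPTION_TYPES
                          for l in BOX_SIDES}}
    bindex = {b.bout_id: b for b in log.bouts}
    events = []
    if condition == "all_present":
        for b in log.bouts:
            if b.session_id == session_id and \
                    b.individual_id != individual_id and \
                    b.option_type in OPTION_TYPES and b.t_end <= t:
                events.append((b.t_end, b.option_type, b.box_side))
    else:
        for o in log.observations:
            b = bindex[o.target_bout_id]
            if o.observer_id != individual_id or \
                    b.session_id != session_id or \
                    b.option_type not in OPTION_TYPES or o.t_end > t:
                continue
            if condition == "entry" and not o.saw_entry:
                continue
            if condition == "feeding" and not o.saw_feeding:
                continue
            events.append((o.t_end, b.option_type, b.box_side))
    for te, k, l in events:
        for d, key in ((out, "any"),):
            cur = d[key]
            d[key] = te if cur is None else max(cur, te)
        for d, key in ((out["box"], l), (out["option"], k),
                       (out["option_box"], (k, l))):
            cur = d[key]
            d[key] = te if cur is None else max(cur, te)
    return out


def brute_hpd(draws, mass):
    """Shortest window by exhaustive scan over all start indices."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    m = int(np.ceil(mass * n))
    best = (np.inf, None)
    for j in range(n - m + 1):
        width = x[j + m - 1] - x[j]
        if width < best[0]:
            best = (width, (x[j], x[j + m - 1]))
    return best[1]


def exact_two_group_option_bias_p(n1, x1, n2, x2):
    """Exact Monte-Carlo-free p-value for the two-group test.

    Under the null every unit is flap with the pooled probability; the
    statistic for counts (y1, y2) is n1|y1/n1 - q| + n2|y2/n2 - q| with q
    the pooled proportion of that permuted table.  Enumerates all
    (n1+1)(n2+1) outcomes.
    """
    from scipy import stats

    pooled = (x1 + x2) / (n1 + n2)
    obs = n1 * abs(x1 / n1 - pooled) + n2 * abs(x2 / n2 - pooled)
    total = 0.0
    for y1 in range(n1 + 1):
        p1 = stats.binom.pmf(y1, n1, pooled)
        for y2 in range(n2 + 1):
            q = (y1 + y2) / (n1 + n2)
            stat = n1 * abs(y1 / n1 - q) + n2 * abs(y2 / n2 - q)
            if stat >= obs - 1e-12:
                total += p1 * stats.binom.pmf(y2, n2, pooled)
    return total


def grid_loglik(log, params, timeline, condition="any", dt=0.01,
                exclude_demonstrators=True):
    """Dense numerical integration of the pointwise interaction rate.

    Breakpoints are taken (conservatively) as every recorded time in the
    log, so each inter-breakpoint span has constant experience state;
    within a span the rate values on a fine grid come from the package's
    pointwise rate decomposition at the span start and the integral is a
    trapezoid sum.  Events contribute log(rate) at their start times.
    """
    total = 0.0
    inds = {i.id: i for i in log.individuals}
    rho = params.rho
    for s in log.sessions:
        times = {s.start_time, s.end_time}
        for b in log.bouts:
            if b.session_id == s.session_id:
                times.update((b.t_start, b.t_end))
        bindex = {b.bout_id: b for b in log.bouts}
        for o in log.observations:
            if bindex[o.target_bout_id].session_id == s.session_id:
                times.update((o.t_start, o.t_end))
        times = sorted(tt for tt in times
                       if s.start_time <= tt <= s.end_time)
        for iid in s.attendees:
            if exclude_demonstrators and inds[iid].is_demonstrator:
                continue
            own = [(b.t_start, b.t_end) for b in log.bouts
                   if b.individual_id == iid and
                   b.session_id == s.session_id]
            for a, b_t in zip(times, times[1:]):
                if b_t <= a:
                    continue
                mid = 0.5 * (a + b_t)
                if any(lo < mid < hi for lo, hi in own):
                    continue
                span = b_t - a
                n = max(2, int(np.ceil(span / dt)) + 1)
                u = np.linspace(0.0, span, n)
                for k in OPTION_TYPES:
                    for l in BOX_SIDES:
                        dec = interaction_rate(
                            iid, k, l, a + 1e-12 * max(1.0, a), s.session_id,
                            params, timeline, condition)
                        vals = np.full(n, dec.baseline *
                                       dec.learning_multiplier)
                        for g, d0 in dec.transient_terms:
                            vals += dec.baseline * g * np.exp(-rho *
                                                              (d0 + u))
                        total -= float(np.trapezoid(vals, u))
        for b in log.bouts:
            if b.session_id != s.session_id or \
                    b.option_type not in OPTION_TYPES:
                continue
            if exclude_demonstrators and \
                    inds[b.individual_id].is_demonstrator:
                continue
            dec = interaction_rate(b.individual_id, b.option_type,
                                   b.box_side, b.t_start, s.session_id,
                                   params, timeline, condition)
            total += float(np.log(dec.total))
    return total
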