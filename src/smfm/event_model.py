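"""Event-log data model for seeded diffusion experiments.

A seeded diffusion experiment presents free-living animal groups with a
novel foraging task offering discrete solution options — here two
option-types (``flap``, ``tube``), one of each on two identical boxes
(``left``, ``right``), giving four options in total.  Some groups are
seeded with a trained demonstrator proficient at one option-type.

Everything downstream — the continuous-time rate model, the survival
analysis of bout outcomes and the traditions test — consumes the
validated event log defined here: a roster of individuals, a set of
timed sessions, the interaction bouts recorded in each session, and the
observation events linking bystanders to bouts.  The
:class:`ExperienceTimeline` compiles a log into per-individual,
time-indexed experience state (reward/failure counts, observation counts
by class, and times of last observation per option and box).

Time convention: all times are seconds from the start of the session
they belong to.  Experience counters carry over across sessions of a
group; the transient "last observation" clocks reset at each session
start.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

AGE_CLASSES = ("pup", "juvenile", "subadult", "adult")
SEXES = ("F", "M")
DOMINANCE = ("subordinate", "dominant")
OPTION_TYPES = ("flap", "tube")
BOX_SIDES = ("left", "right")
#: Contact locations allowed in bout records; "other" contacts are kept in the
#: log but excluded from the four-option rate model and from experience counts.
CONTACT_TYPES = OPTION_TYPES + ("other",)
#: Observation classes, ordered from least to most informative.  An
#: observation always counts as "manipulation"; it additionally counts as
#: "entry" if the observer saw the actor enter the box, and as "feeding" if it
#: saw the actor feed.  Counts are therefore nested increments.
OBS_CLASSES = ("manipulation", "entry", "feeding")
OUTCOMES = ("solved", "abandoned")
SCHEMA_VERSION = "1"

_INDIVIDUAL_COLS = ["id", "group_id", "age_class", "sex", "dominance",
                    "is_demonstrator", "trained_option_type"]
_SESSION_COLS = ["session_id", "group_id", "index", "start_time", "end_time",
                 "attendees"]
_BOUT_COLS = ["bout_id", "session_id", "individual_id", "option_type",
              "box_side", "t_start", "t_end", "entered_box", "obtained_food",
              "outcome"]
_OBS_COLS = ["observer_id", "target_bout_id", "t_start", "t_end",
             "saw_entry", "saw_feeding"]


class EventLogError(ValueError):
    """Validation failure.  The message names the offending rows and rules."""


@dataclass(frozen=True)
class Individual:
    id: str
    group_id: str
    age_class: str
    sex: str
    dominance: str
    is_demonstrator: bool = False
    trained_option_type: str | None = None


@dataclass(frozen=True)
class Session:
    session_id: str
    group_id: str
    index: int
    start_time: float
    end_time: float
    attendees: frozenset[str]

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True)
class InteractionBout:
    bout_id: str
    session_id: str
    individual_id: str
    option_type: str
    box_side: str
    t_start: float
    t_end: float
    entered_box: bool
    obtained_food: bool
    outcome: str


@dataclass(frozen=True)
class ObservationEvent:
    observer_id: str
    target_bout_id: str
    t_start: float
    t_end: float
    saw_entry: bool
    saw_feeding: bool


@dataclass
class EventLog:
    """A validated collection of individuals, sessions, bouts and observations.

    Collections are normalised to a canonical sort order on construction so
    that two logs with the same content compare equal regardless of the order
    in which records were supplied.
    """

    individuals: tuple[Individual, ...]
    sessions: tuple[Session, ...]
    bouts: tuple[InteractionBout, ...]
    observations: tuple[ObservationEvent, ...]

    def __post_init__(self) -> None:
        self.individuals = tuple(sorted(self.individuals, key=lambda i: i.id))
        self.sessions = tuple(sorted(self.sessions,
                                     key=lambda s: (s.group_id, s.index)))
        sess_order = {s.session_id: n for n, s in enumerate(self.sessions)}
        self.bouts = tuple(sorted(
            self.bouts,
            key=lambda b: (sess_order.get(b.session_id, -1), b.t_start,
                           b.individual_id, b.bout_id)))
        bout_order = {b.bout_id: n for n, b in enumerate(self.bouts)}
        self.observations = tuple(sorted(
            self.observations,
            key=lambda o: (bout_order.get(o.target_bout_id, -1), o.t_start,
                           o.observer_id)))

    # -- lookups -----------------------------------------------------------
    def individual(self, individual_id: str) -> Individual:
        return self._ind_index()[individual_id]

    def session(self, session_id: str) -> Session:
        return self._sess_index()[session_id]

    def bout(self, bout_id: str) -> InteractionBout:
        return self._bout_index()[bout_id]

    def _ind_index(self) -> dict[str, Individual]:
        return {i.id: i for i in self.individuals}

    def _sess_index(self) -> dict[str, Session]:
        return {s.session_id: s for s in self.sessions}

    def _bout_index(self) -> dict[str, InteractionBout]:
        return {b.bout_id: b for b in self.bouts}

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(sorted({i.group_id for i in self.individuals}))

    # -- validation --------------------------------------------------------
    def validation_errors(self) -> list[str]:
        """Return every invariant violation as a human-readable message."""
        errs: list[str] = []
        inds = {}
        for i in self.individuals:
            if i.id in inds:
                errs.append(f"individual {i.id!r}: duplicate id")
            inds[i.id] = i
            if i.age_class not in AGE_CLASSES:
                errs.append(f"individual {i.id!r}: age_class {i.age_class!r} "
                            f"not in {AGE_CLASSES}")
            if i.sex not in SEXES:
                errs.append(f"individual {i.id!r}: sex {i.sex!r} not in {SEXES}")
            if i.dominance not in DOMINANCE:
                errs.append(f"individual {i.id!r}: dominance {i.dominance!r} "
                            f"not in {DOMINANCE}")
            if i.is_demonstrator and i.trained_option_type not in OPTION_TYPES:
                errs.append(f"individual {i.id!r}: demonstrators must have a "
                            f"trained_option_type in {OPTION_TYPES}")
            if not i.is_demonstrator and i.trained_option_type is not None:
                errs.append(f"individual {i.id!r}: non-demonstrators must not "
                            f"have a trained_option_type")

        sessions = {}
        seen_index: set[tuple[str, int]] = set()
        for s in self.sessions:
            if s.session_id in sessions:
                errs.append(f"session {s.session_id!r}: duplicate id")
            sessions[s.session_id] = s
            if not s.end_time > s.start_time:
                errs.append(f"session {s.session_id!r}: end_time must exceed "
                            f"start_time")
            if s.index < 1:
                errs.append(f"session {s.session_id!r}: index must be >= 1")
            if (s.group_id, s.index) in seen_index:
                errs.append(f"session {s.session_id!r}: duplicate index "
                            f"{s.index} within group {s.group_id!r}")
            seen_index.add((s.group_id, s.index))
            for a in s.attendees:
                if a not in inds:
                    errs.append(f"session {s.session_id!r}: attendee {a!r} "
                                f"not in roster")
                elif inds[a].group_id != s.group_id:
                    errs.append(f"session {s.session_id!r}: attendee {a!r} "
                                f"belongs to another group")

        bouts = {}
        by_ind_sess: dict[tuple[str, str], list[InteractionBout]] = {}
        for b in self.bouts:
            if b.bout_id in bouts:
                errs.append(f"bout {b.bout_id!r}: duplicate id")
            bouts[b.bout_id] = b
            if b.session_id not in sessions:
                errs.append(f"bout {b.bout_id!r}: unknown session "
                            f"{b.session_id!r}")
                continue
            s = sessions[b.session_id]
            if b.individual_id not in inds:
                errs.append(f"bout {b.bout_id!r}: unknown individual "
                            f"{b.individual_id!r}")
            elif b.individual_id not in s.attendees:
                errs.append(f"bout {b.bout_id!r}: individual "
                            f"{b.individual_id!r} not an attendee of session "
                            f"{b.session_id!r}")
            if b.option_type not in CONTACT_TYPES:
                errs.append(f"bout {b.bout_id!r}: option_type "
                            f"{b.option_type!r} not in {CONTACT_TYPES}")
            if b.box_side not in BOX_SIDES:
                errs.append(f"bout {b.bout_id!r}: box_side {b.box_side!r} "
                            f"not in {BOX_SIDES}")
            if not b.t_start < b.t_end:
                errs.append(f"bout {b.bout_id!r}: t_start must precede t_end")
            if b.t_start < s.start_time or b.t_end > s.end_time:
                errs.append(f"bout {b.bout_id!r}: interval outside session "
                            f"window")
            if b.outcome not in OUTCOMES:
                errs.append(f"bout {b.bout_id!r}: outcome {b.outcome!r} not "
                            f"in {OUTCOMES}")
            if (b.outcome == "solved") != b.obtained_food:
                errs.append(f"bout {b.bout_id!r}: outcome 'solved' must "
                            f"coincide with obtained_food")
            if b.obtained_food and not b.entered_box:
                errs.append(f"bout {b.bout_id!r}: obtained_food requires "
                            f"entered_box")
            by_ind_sess.setdefault((b.individual_id, b.session_id),
                                   []).append(b)
        for (ind, sid), bs in by_ind_sess.items():
            bs = sorted(bs, key=lambda b: b.t_start)
            for prev, nxt in zip(bs, bs[1:]):
                if nxt.t_start < prev.t_end:
                    errs.append(f"bouts {prev.bout_id!r} and {nxt.bout_id!r}: "
                                f"overlapping bouts of individual {ind!r}")

        for n, o in enumerate(self.observations):
            tag = f"observation row {n} (observer {o.observer_id!r})"
            if o.observer_id not in inds:
                errs.append(f"{tag}: unknown observer")
            if o.target_bout_id not in bouts:
                errs.append(f"{tag}: unknown target bout {o.target_bout_id!r}")
                continue
            b = bouts[o.target_bout_id]
            if o.observer_id == b.individual_id:
                errs.append(f"{tag}: observer equals the bout's actor")
            if b.session_id in sessions and \
                    o.observer_id not in sessions[b.session_id].attendees:
                errs.append(f"{tag}: observer not an attendee of session "
                            f"{b.session_id!r}")
            if o.t_start < b.t_start or o.t_end > b.t_end or \
                    not o.t_start < o.t_end:
                errs.append(f"{tag}: observation interval not inside target "
                            f"bout {b.bout_id!r}")
            if o.saw_feeding and not o.saw_entry:
                errs.append(f"{tag}: saw_feeding requires saw_entry")
            if o.saw_entry and not b.entered_box:
                errs.append(f"{tag}: saw_entry requires the target bout to "
                            f"have entered_box")
            if o.saw_feeding and not b.obtained_food:
                errs.append(f"{tag}: saw_feeding requires the target bout to "
                            f"have obtained_food")
        return errs

    def validate(self) -> "EventLog":
        errs = self.validation_errors()
        if errs:
            raise EventLogError(f"{len(errs)} validation error(s):\n" +
                                "\n".join(errs))
        return self


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def _fmt_bool(x: bool) -> str:
    return "true" if x else "false"


def _parse_bool(x: str, where: str) -> bool:
    if x == "true":
        return True
    if x == "false":
        return False
    raise EventLogError(f"{where}: expected 'true' or 'false', got {x!r}")


def _fmt_float(x: float) -> str:
    return repr(float(x))


def write_event_log(log: EventLog, path: str | Path) -> None:
    """Write a log to *path* as four CSV tables plus a schema manifest.

    Floats are written with ``repr`` so that ``read_event_log`` recovers the
    exact values (write/read is the identity on valid logs).
    """
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    rows = [{
        "id": i.id, "group_id": i.group_id, "age_class": i.age_class,
        "sex": i.sex, "dominance": i.dominance,
        "is_demonstrator": _fmt_bool(i.is_demonstrator),
        "trained_option_type": i.trained_option_type or "",
    } for i in log.individuals]
    pd.DataFrame(rows, columns=_INDIVIDUAL_COLS).to_csv(
        p / "individuals.csv", index=False)
    rows = [{
        "session_id": s.session_id, "group_id": s.group_id,
        "index": str(s.index), "start_time": _fmt_float(s.start_time),
        "end_time": _fmt_float(s.end_time),
        "attendees": ";".join(sorted(s.attendees)),
    } for s in log.sessions]
    pd.DataFrame(rows, columns=_SESSION_COLS).to_csv(
        p / "sessions.csv", index=False)
    rows = [{
        "bout_id": b.bout_id, "session_id": b.session_id,
        "individual_id": b.individual_id, "option_type": b.option_type,
        "box_side": b.box_side, "t_start": _fmt_float(b.t_start),
        "t_end": _fmt_float(b.t_end),
        "entered_box": _fmt_bool(b.entered_box),
        "obtained_food": _fmt_bool(b.obtained_food), "outcome": b.outcome,
    } for b in log.bouts]
    pd.DataFrame(rows, columns=_BOUT_COLS).to_csv(p / "bouts.csv", index=False)
    rows = [{
        "observer_id": o.observer_id, "target_bout_id": o.target_bout_id,
        "t_start": _fmt_float(o.t_start), "t_end": _fmt_float(o.t_end),
        "saw_entry": _fmt_bool(o.saw_entry),
        "saw_feeding": _fmt_bool(o.saw_feeding),
    } for o in log.observations]
    pd.DataFrame(rows, columns=_OBS_COLS).to_csv(
        p / "observations.csv", index=False)
    (p / "manifest.json").write_text(
        json.dumps({"schema_version": SCHEMA_VERSION}))


def _read_table(p: Path, name: str, columns: list[str]) -> pd.DataFrame:
    f = p / name
    if not f.exists():
        raise EventLogError(f"missing table {name}")
    df = pd.read_csv(f, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise EventLogError(f"{name}: missing columns {missing}")
    return df


def read_event_log(path: str | Path,
                   schema_version: str = SCHEMA_VERSION) -> EventLog:
    """Read and validate a four-table CSV event log from a directory."""
    p = Path(path)
    manifest = p / "manifest.json"
    if manifest.exists():
        found = json.loads(manifest.read_text()).get("schema_version")
        if found != schema_version:
            raise EventLogError(
                f"schema_version mismatch: file has {found!r}, "
                f"reader expects {schema_version!r}")
    inds = []
    for n, row in _read_table(p, "individuals.csv",
                              _INDIVIDUAL_COLS).iterrows():
        inds.append(Individual(
            id=row["id"], group_id=row["group_id"],
            age_class=row["age_class"], sex=row["sex"],
            dominance=row["dominance"],
            is_demonstrator=_parse_bool(row["is_demonstrator"],
                                        f"individuals.csv row {n}"),
            trained_option_type=row["trained_option_type"] or None))
    sessions = []
    for n, row in _read_table(p, "sessions.csv", _SESSION_COLS).iterrows():
        attendees = frozenset(a for a in row["attendees"].split(";") if a)
        sessions.append(Session(
            session_id=row["session_id"], group_id=row["group_id"],
            index=int(row["index"]), start_time=float(row["start_time"]),
            end_time=float(row["end_time"]), attendees=attendees))
    bouts = []
    for n, row in _read_table(p, "bouts.csv", _BOUT_COLS).iterrows():
        bouts.append(InteractionBout(
            bout_id=row["bout_id"], session_id=row["session_id"],
            individual_id=row["individual_id"],
            option_type=row["option_type"], box_side=row["box_side"],
            t_start=float(row["t_start"]), t_end=float(row["t_end"]),
            entered_box=_parse_bool(row["entered_box"],
                                    f"bouts.csv row {n}"),
            obtained_food=_parse_bool(row["obtained_food"],
                                      f"bouts.csv row {n}"),
            outcome=row["outcome"]))
    obs = []
    for n, row in _read_table(p, "observations.csv", _OBS_COLS).iterrows():
        obs.append(ObservationEvent(
            observer_id=row["observer_id"],
            target_bout_id=row["target_bout_id"],
            t_start=float(row["t_start"]), t_end=float(row["t_end"]),
            saw_entry=_parse_bool(row["saw_entry"],
                                  f"observations.csv row {n}"),
            saw_feeding=_parse_bool(row["saw_feeding"],
                                    f"observations.csv row {n}")))
    log = EventLog(tuple(inds), tuple(sessions), tuple(bouts), tuple(obs))
    log.validate()
    return log


# ---------------------------------------------------------------------------
# Experience timelines
# ---------------------------------------------------------------------------

#: Conditions under which the transient "last observation" clocks are set.
#: "any": any recorded observation of a manipulation; "entry"/"feeding":
#: only observations with the corresponding flag; "all_present": every bout
#: end sets the clocks of every other attendee, observed or not.
CONDITIONS = ("any", "entry", "feeding", "all_present")


class ExperienceTimeline:
    """Per-individual, time-indexed experience compiled from an event log.

    Counters step at bout/observation *end* times (experience from a bout is
    available only strictly after the bout terminates: a query at exactly the
    end time does not yet include it).  The last-observation clocks are set at
    observation end times, count an observation ending exactly at the query
    time (the transient effect is at full strength immediately after
    observation) and reset at each session start.  Bouts with
    ``option_type == "other"`` never touch counters or clocks.
    """

    def __init__(self, log: EventLog):
        log.validate()
        self.log = log
        self._order = {s.session_id: n for n, s in enumerate(log.sessions)}
        bindex = log._bout_index()
        self._rewards: dict = {}
        self._failures: dict = {}
        self._obs: dict = {}
        self._first_solve: dict = {}
        self._session_obs: dict = {}
        self._session_manips: dict = {}
        for i in log.individuals:
            for k in OPTION_TYPES:
                self._rewards[(i.id, k)] = []
                self._failures[(i.id, k)] = []
                self._first_solve[(i.id, k)] = None
                for c in OBS_CLASSES:
                    self._obs[(i.id, k, c)] = []
        for s in log.sessions:
            self._session_manips[s.session_id] = []
        for b in log.bouts:
            if b.option_type not in OPTION_TYPES:
                continue
            key = (self._order[b.session_id], b.t_end)
            if b.outcome == "solved":
                self._rewards[(b.individual_id, b.option_type)].append(key)
                cur = self._first_solve[(b.individual_id, b.option_type)]
                if cur is None or key < cur:
                    self._first_solve[(b.individual_id, b.option_type)] = key
            else:
                self._failures[(b.individual_id, b.option_type)].append(key)
            self._session_manips[b.session_id].append(
                (b.t_end, b.option_type, b.box_side, b.individual_id))
        for o in log.observations:
            b = bindex[o.target_bout_id]
            if b.option_type not in OPTION_TYPES:
                continue
            key = (self._order[b.session_id], o.t_end)
            classes = ["manipulation"]
            if o.saw_entry:
                classes.append("entry")
            if o.saw_feeding:
                classes.append("feeding")
            for c in classes:
                self._obs[(o.observer_id, b.option_type, c)].append(key)
            self._session_obs.setdefault(
                (o.observer_id, b.session_id), []).append(
                (o.t_end, b.option_type, b.box_side, o.saw_entry,
                 o.saw_feeding))
        for v in list(self._rewards.values()) + list(self._failures.values()) \
                + list(self._obs.values()):
            v.sort()
        for v in self._session_obs.values():
            v.sort()
        for v in self._session_manips.values():
            v.sort()

    # counts ---------------------------------------------------------------
    def _count(self, events: list, session_id: str, t: float,
               inclusive: bool) -> int:
        key = (self._order[session_id], t)
        return bisect_right(events, key) if inclusive else \
            bisect_left(events, key)

    def reward_count(self, individual_id: str, option_type: str,
                     session_id: str, t: float, inclusive: bool = False) -> int:
        """Number of rewarded bouts at *option_type* before time *t*.

        ``inclusive=True`` counts events ending exactly at *t* (the state on
        the segment starting at *t*).
        """
        return self._count(self._rewards[(individual_id, option_type)],
                           session_id, t, inclusive)

    def failure_count(self, individual_id: str, option_type: str,
                      session_id: str, t: float,
                      inclusive: bool = False) -> int:
        return self._count(self._failures[(individual_id, option_type)],
                           session_id, t, inclusive)

    def observation_count(self, individual_id: str, option_type: str,
                          obs_class: str, session_id: str, t: float,
                          inclusive: bool = False) -> int:
        return self._count(self._obs[(individual_id, option_type, obs_class)],
                           session_id, t, inclusive)

    def solved_ever(self, individual_id: str, option_type: str,
                    session_id: str, t: float,
                    inclusive: bool = False) -> bool:
        first = self._first_solve[(individual_id, option_type)]
        if first is None:
            return False
        key = (self._order[session_id], t)
        return first <= key if inclusive else first < key

    # transient clocks -----------------------------------------------------
    def last_observation_times(self, individual_id: str, session_id: str,
                               t: float, condition: str = "any") -> dict:
        """Most recent qualifying observation times at or before *t*.

        Returns a dict with keys ``"any"`` (any option, any box), ``"box"``
        (per box side), ``"option"`` (per option-type, any box) and
        ``"option_box"`` (per (option-type, box) pair); absent observations
        are ``None``.  Clocks only see the current session.
        """
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        out = {"any": None,
               "box": {l: None for l in BOX_SIDES},
               "option": {k: None for k in OPTION_TYPES},
               "option_box": {(k, l): None for k in OPTION_TYPES
                              for l in BOX_SIDES}}
        if condition == "all_present":
            events = [(te, k, l) for te, k, l, actor
                      in self._session_manips.get(session_id, [])
                      if actor != individual_id and te <= t]
        else:
            rows = self._session_obs.get((individual_id, session_id), [])
            events = []
            for te, k, l, saw_entry, saw_feeding in rows:
                if te > t:
                    break
                if condition == "entry" and not saw_entry:
                    continue
                if condition == "feeding" and not saw_feeding:
                    continue
                events.append((te, k, l))
        for te, k, l in events:
            out["any"] = te if out["any"] is None else max(out["any"], te)
            cur = out["box"][l]
            out["box"][l] = te if cur is None else max(cur, te)
            cur = out["option"][k]
            out["option"][k] = te if cur is None else max(cur, te)
            cur = out["option_box"][(k, l)]
            out["option_box"][(k, l)] = te if cur is None else max(cur, te)
        return out

    # totals ---------------------------------------------------------------
    def total_bout_count(self, individual_id: str, option_type: str) -> int:
        return len(self._rewards[(individual_id, option_type)]) + \
            len(self._failures[(individual_id, option_type)])


def build_experience_timeline(log: EventLog) -> ExperienceTimeline:
    """Compile *log* into an :class:`ExperienceTimeline`."""
    return ExperienceTimeline(log)
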