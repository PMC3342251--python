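"""Encoding of raw leave/return event logs into CTMC trajectories.

A session log records, for one pair and one hour-scale session, the times
(in seconds) at which each fish left or returned to cover.  Both fish start
under cover, so per fish the actions strictly alternate starting with a
leave.  From such a log we build:

* a two-state trajectory per fish (cover / exposed),
* the 12-state pair trajectory (locations + initiator + joined flag),
* its projection onto the 8-state one-step-memory space,
* the sequence of initiation events and the per-joint-trip counts of
  position changes.

The status variables of the interval before the first event are not
observable (no trip has started yet), so the pair trajectory begins with an
``unknown`` visit (state ``None``) that is excluded from likelihood
exposure; the first departure defines the first initiator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from .state_space import (
    BOLD,
    COVER,
    EXPOSED,
    FISHES,
    LEAVE,
    RETURN,
    SHY,
    StateSpace,
    enumerate_pair_states,
    location_collapse_map,
    location_of,
    one_step_memory_space,
    successor_table,
)

__all__ = [
    "Event",
    "SessionLog",
    "Trajectory",
    "InitiationRecord",
    "MalformedLogError",
    "encode_individual",
    "encode_pair",
    "project_one_step",
    "collapse_to_location",
    "initiation_sequence",
    "trip_position_changes",
    "read_session_logs",
    "write_session_logs",
    "read_covariates",
    "write_covariates",
]

EVENT_LOG_COLUMNS = ["pair_id", "session_id", "partition", "duration_s",
                     "fish", "time_s", "action"]


class MalformedLogError(ValueError):
    """An event log violating alternation or ordering invariants."""

    def __init__(self, message: str, event_index: Optional[int] = None,
                 line: Optional[int] = None):
        loc = ""
        if event_index is not None:
            loc = f" (event index {event_index})"
        if line is not None:
            loc = f" (line {line})"
        super().__init__(message + loc)
        self.event_index = event_index
        self.line = line


@dataclass(frozen=True)
class Event:
    time_s: float
    fish: str
    action: str


@dataclass
class SessionLog:
    """Raw timestamped leave/return events for one session of one pair."""

    pair_id: str
    session_id: str
    partition: str  # "opaque" or "transparent"
    duration_s: float
    events: list[Event] = field(default_factory=list)

    def validate(self) -> None:
        """Raise :class:`MalformedLogError` on any invariant violation."""
        if self.partition not in ("opaque", "transparent"):
            raise MalformedLogError(
                f"unknown partition {self.partition!r} in session "
                f"{self.pair_id}/{self.session_id}")
        if not self.duration_s > 0:
            raise MalformedLogError(
                f"non-positive duration in session {self.pair_id}/{self.session_id}")
        last_time = None
        last_action: dict[str, str] = {}
        for i, ev in enumerate(self.events):
            if ev.fish not in FISHES:
                raise MalformedLogError(f"unknown fish {ev.fish!r}", event_index=i)
            if ev.action not in (LEAVE, RETURN):
                raise MalformedLogError(f"unknown action {ev.action!r}", event_index=i)
            if not 0 <= ev.time_s <= self.duration_s:
                raise MalformedLogError(
                    f"event time {ev.time_s} outside [0, {self.duration_s}]",
                    event_index=i)
            if last_time is not None and ev.time_s <= last_time:
                raise MalformedLogError(
                    f"event times must strictly increase ({ev.time_s} after {last_time})",
                    event_index=i)
            last_time = ev.time_s
            expected = LEAVE if last_action.get(ev.fish, RETURN) == RETURN else RETURN
            if ev.action != expected:
                raise MalformedLogError(
                    f"{ev.fish} fish: expected {expected!r} but got {ev.action!r}",
                    event_index=i)
            last_action[ev.fish] = ev.action

    def events_of(self, fish: str) -> list[Event]:
        return [e for e in self.events if e.fish == fish]


@dataclass
class Trajectory:
    """A right-censored realisation over a state space.

    ``visits`` is an ordered list of ``(state_id, entry_time)`` pairs; a
    leading ``None`` state marks the unobservable pre-first-event interval
    of pair trajectories.  Times are in the units of the originating log
    (seconds for logs read from disk).
    """

    space_name: str
    visits: list[tuple[Optional[int], float]]
    end_time: float
    pair_id: Optional[str] = None
    session_id: Optional[str] = None

    def states(self) -> list[Optional[int]]:
        return [s for s, _ in self.visits]

    def known_visits(self) -> list[tuple[int, float]]:
        return [(s, t) for s, t in self.visits if s is not None]

    def sojourns(self):
        """Yield (state, duration, next_state) with next_state None if censored."""
        for i, (s, t) in enumerate(self.visits):
            if i + 1 < len(self.visits):
                nxt_s, nxt_t = self.visits[i + 1]
                yield s, nxt_t - t, nxt_s
            else:
                yield s, self.end_time - t, None


@dataclass(frozen=True)
class InitiationRecord:
    """One initiation: a fish first leaving cover from a both-covered pair.

    ``success`` is True if the partner joined before both fish were back
    under cover, False if the trip fizzled, and None if the session ended
    before the trip resolved (right-censored).
    """

    time: float
    initiator: str
    success: Optional[bool]


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

def encode_individual(log: SessionLog, fish: str) -> Trajectory:
    """Two-state (1 = cover, 2 = exposed) trajectory of one fish."""
    log.validate()
    if fish not in FISHES:
        raise ValueError(f"unknown fish {fish!r}")
    visits: list[tuple[Optional[int], float]] = [(1, 0.0)]
    for ev in log.events_of(fish):
        visits.append((2 if ev.action == LEAVE else 1, ev.time_s))
    return Trajectory("individual", visits, log.duration_s,
                      pair_id=log.pair_id, session_id=log.session_id)


def encode_pair(log: SessionLog, space: Optional[StateSpace] = None,
                require_transparent: bool = True) -> Trajectory:
    """Fold a session log into the 12-state pair trajectory.

    The interval before the first event carries unknown status variables and
    is emitted as a leading ``(None, 0.0)`` visit; the first departure sets
    the first initiator with ``joined = False``.
    """
    log.validate()
    if require_transparent and log.partition != "transparent":
        raise ValueError(
            "pair encoding requires a transparent-partition session "
            f"(got {log.partition!r}); pass require_transparent=False to override")
    if space is None:
        space = enumerate_pair_states()
    successors = successor_table()
    visits: list[tuple[Optional[int], float]] = [(None, 0.0)]
    state = None
    for i, ev in enumerate(log.events):
        if state is None:
            if ev.action != LEAVE:
                raise MalformedLogError("first event must be a departure", event_index=i)
            # first departure: the mover initiates, nobody has joined
            state = next(s for s in space.states
                         if location_of(s) == ((EXPOSED, COVER) if ev.fish == BOLD
                                               else (COVER, EXPOSED))
                         and s.initiator == ev.fish and not s.joined)
        else:
            state = successors[(state.id, ev.fish, ev.action)]
        visits.append((state.id, ev.time_s))
    return Trajectory(space.name, visits, log.duration_s,
                      pair_id=log.pair_id, session_id=log.session_id)


def project_one_step(pair_traj: Trajectory,
                     pair_space: Optional[StateSpace] = None,
                     one_step: Optional[StateSpace] = None) -> Trajectory:
    """Project a 12-state trajectory onto the 8-state one-step-memory space.

    Each visit's status variables are replaced by the location combination
    of the preceding visit; the first post-unknown visit's predecessor is
    the both-covered start.  Visit times are preserved exactly.
    """
    if pair_traj.space_name != "pair":
        raise ValueError("expected a trajectory over the 12-state pair space")
    pair_space = pair_space or enumerate_pair_states()
    one_step = one_step or one_step_memory_space()
    index = {(s.locations, s.prev_locations): s.id for s in one_step.states}
    visits: list[tuple[Optional[int], float]] = []
    prev_loc = (COVER, COVER)
    for s, t in pair_traj.visits:
        if s is None:
            visits.append((None, t))
            continue
        cur_loc = location_of(pair_space.state(s))
        visits.append((index[(cur_loc, prev_loc)], t))
        prev_loc = cur_loc
    return Trajectory("one_step", visits, pair_traj.end_time,
                      pair_id=pair_traj.pair_id, session_id=pair_traj.session_id)


def collapse_to_location(traj: Trajectory) -> Trajectory:
    """Drop memory variables, merging consecutive identical location states."""
    # locations are observable throughout, so the unknown-status prefix maps
    # to the both-covered location state
    if traj.space_name == "pair":
        pair_space = enumerate_pair_states()
        mapping = location_collapse_map(pair_space)
        mapped = [(1 if s is None else mapping[s], t) for s, t in traj.visits]
    elif traj.space_name == "one_step":
        space = one_step_memory_space()
        loc_ids = {(COVER, COVER): 1, (EXPOSED, COVER): 2,
                   (COVER, EXPOSED): 3, (EXPOSED, EXPOSED): 4}
        mapped = [(1 if s is None else loc_ids[space.state(s).locations], t)
                  for s, t in traj.visits]
    else:
        raise ValueError(f"cannot location-collapse a {traj.space_name!r} trajectory")
    visits: list[tuple[Optional[int], float]] = []
    for s, t in mapped:
        if visits and visits[-1][0] == s:
            continue
        visits.append((s, t))
    return Trajectory("location", visits, traj.end_time,
                      pair_id=traj.pair_id, session_id=traj.session_id)


# ---------------------------------------------------------------------------
# Initiation sequences and joint-trip statistics
# ---------------------------------------------------------------------------

_BOTH_COVERED = frozenset({1, 2, 3, 4})
_SOLO_UNJOINED = {5: BOLD, 9: SHY}
_BOTH_OUT = frozenset({6, 10})


def initiation_sequence(pair_traj: Trajectory) -> list[InitiationRecord]:
    """Initiation events: first departures from a both-covered pair.

    Success means the trajectory reaches a both-out state before next
    returning to a both-covered state; a trip unresolved at the session end
    gets ``success = None``.
    """
    if pair_traj.space_name != "pair":
        raise ValueError("expected a trajectory over the 12-state pair space")
    records = []
    visits = pair_traj.visits
    for i in range(1, len(visits)):
        prev_s = visits[i - 1][0]
        s, t = visits[i]
        from_covered = prev_s is None or prev_s in _BOTH_COVERED
        if from_covered and s in _SOLO_UNJOINED:
            success: Optional[bool] = None
            for s2, _ in visits[i + 1:]:
                if s2 in _BOTH_OUT:
                    success = True
                    break
                if s2 in _BOTH_COVERED:
                    success = False
                    break
            records.append(InitiationRecord(t, _SOLO_UNJOINED[s], success))
    return records


def trip_position_changes(pair_traj: Trajectory) -> list[int]:
    """Per joint trip, the number of position changes after the join.

    A joint trip runs from the join (entry into a both-out state) until both
    fish are back under cover.  The count excludes the final two returns
    that end the trip, so it tallies termination attempts and re-joinings.
    Trips unresolved at the session end are dropped.
    """
    if pair_traj.space_name != "pair":
        raise ValueError("expected a trajectory over the 12-state pair space")
    counts = []
    states = [s for s, _ in pair_traj.visits]
    i = 0
    n = len(states)
    while i < n:
        if states[i] in _BOTH_OUT and (i == 0 or states[i - 1] not in _BOTH_OUT):
            # scan to the end of the joint trip
            j = i
            while j < n and states[j] not in _BOTH_COVERED:
                j += 1
            if j < n:
                counts.append((j - i) - 2)
            i = j
        else:
            i += 1
    return counts


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_session_logs(logs: Iterable[SessionLog], path) -> None:
    """Write logs to the canonical CSV event-log dialect."""
    rows = []
    for log in logs:
        for ev in log.events:
            rows.append((log.pair_id, log.session_id, log.partition,
                         log.duration_s, ev.fish, ev.time_s, ev.action))
        if not log.events:
            # a session with no events still needs a duration record
            rows.append((log.pair_id, log.session_id, log.partition,
                         log.duration_s, "", "", ""))
    pd.DataFrame(rows, columns=EVENT_LOG_COLUMNS).to_csv(path, index=False)


def read_session_logs(path) -> list[SessionLog]:
    """Read the CSV event-log dialect with strict, line-numbered validation."""
    df = pd.read_csv(path, dtype={"pair_id": str, "session_id": str,
                                  "partition": str, "fish": str, "action": str},
                     keep_default_na=False)
    missing = [c for c in EVENT_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedLogError(f"missing columns: {', '.join(missing)}")
    logs: dict[tuple[str, str], SessionLog] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        key = (row["pair_id"], row["session_id"])
        try:
            duration = float(row["duration_s"])
        except ValueError:
            raise MalformedLogError(
                f"unparseable duration {row['duration_s']!r}", line=line)
        if key not in logs:
            logs[key] = SessionLog(key[0], key[1], row["partition"], duration)
        log = logs[key]
        if row["partition"] != log.partition or float(row["duration_s"]) != log.duration_s:
            raise MalformedLogError(
                f"inconsistent session metadata for {key[0]}/{key[1]}", line=line)
        if row["fish"] == "" and row["time_s"] == "":
            continue  # empty-session placeholder row
        try:
            t = float(row["time_s"])
        except ValueError:
            raise MalformedLogError(f"unparseable time {row['time_s']!r}", line=line)
        if row["fish"] not in FISHES:
            raise MalformedLogError(f"unknown fish {row['fish']!r}", line=line)
        if row["action"] not in (LEAVE, RETURN):
            raise MalformedLogError(f"unknown action {row['action']!r}", line=line)
        log.events.append(Event(t, row["fish"], row["action"]))
    out = list(logs.values())
    for log in out:
        log.events.sort(key=lambda e: e.time_s)
        log.validate()
    return out


def deduplicate_timestamps(log: SessionLog, epsilon: float = 1e-6) -> SessionLog:
    """Break timestamp ties deterministically by shifting later events +epsilon.

    Digitised logs sometimes quantise two events onto one timestamp, which
    single-mover dynamics cannot represent; this applies a small forward
    offset to the second and later events of each tied group.
    """
    events = []
    last = -float("inf")
    for ev in log.events:
        t = ev.time_s
        if t <= last:
            t = last + epsilon
        events.append(Event(t, ev.fish, ev.action))
        last = t
    return replace(log, events=events)


def write_covariates(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=["pair_id", "x_bold", "x_shy"])


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"pair_id": str})
    missing = [c for c in ("pair_id", "x_bold", "x_shy") if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table missing columns: {', '.join(missing)}")
    return df
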