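"""State spaces for two-fish movement models.

A pair of fish (labelled ``bold`` and ``shy`` by temperament score) moves
between cover and an exposed foraging area.  The pair's state combines two
*location* variables (where each fish is) with two *status* variables: the
identity of the fish that initiated the most recent trip out of cover, and
whether its partner has joined it on that trip.  Not every combination of
the four binary variables is feasible:

* if both fish are exposed the partner has, by definition, joined;
* a solo excursion that nobody has joined can only belong to the initiator.

Exactly 12 combinations survive, and they form the full pair state space.
Two reduced spaces are also provided: the 4-state location-only space
(status variables dropped) and an 8-state "one-step memory" space whose
states pair the current location combination with the immediately
preceding one.

Transitions are single-mover: each event is one fish leaving or returning
to cover, so every state has one outgoing edge per fish.  Model variants
are expressed as *tying schemes* that map the directed edges onto shared
rate-parameter classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

__all__ = [
    "BOLD",
    "SHY",
    "COVER",
    "EXPOSED",
    "LEAVE",
    "RETURN",
    "FISHES",
    "PairState",
    "Edge",
    "StateSpace",
    "TransitionClassScheme",
    "InvalidMoveError",
    "enumerate_pair_states",
    "transition_target",
    "tying_scheme",
    "location_space",
    "one_step_memory_space",
    "two_state_space",
    "location_of",
    "location_collapse_map",
]

BOLD = "bold"
SHY = "shy"
FISHES = (BOLD, SHY)

COVER = "cover"
EXPOSED = "exposed"

LEAVE = "leave"
RETURN = "return"


class InvalidMoveError(ValueError):
    """A move inconsistent with the mover's current location."""


@dataclass(frozen=True)
class PairState:
    """One feasible combination of locations and status variables.

    Attributes
    ----------
    id:
        Canonical state number, 1-12.
    loc_bold, loc_shy:
        ``"cover"`` or ``"exposed"``.
    initiator:
        Which fish initiated the most recent trip out of cover.
    joined:
        Whether the initiator's partner has joined it on that trip.
    """

    id: int
    loc_bold: str
    loc_shy: str
    initiator: str
    joined: bool

    def location(self, fish: str) -> str:
        return self.loc_bold if fish == BOLD else self.loc_shy

    @property
    def locations(self) -> tuple[str, str]:
        return (self.loc_bold, self.loc_shy)


@dataclass(frozen=True)
class Edge:
    """A directed transition: ``mover`` performs ``move``, source -> target."""

    source: int
    target: int
    mover: str
    move: str


@dataclass(frozen=True)
class StateSpace:
    """A set of states plus the single-mover transition edges between them."""

    name: str
    states: tuple
    edges: tuple[Edge, ...]
    _by_id: Mapping[int, object] = field(repr=False, default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_by_id", {s.id: s for s in self.states})

    def state(self, state_id: int):
        return self._by_id[state_id]

    @property
    def state_ids(self) -> tuple[int, ...]:
        return tuple(s.id for s in self.states)

    def out_edges(self, state_id: int) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.source == state_id)

    def find_edge(self, source: int, target: int) -> Edge:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        raise KeyError(f"no edge {source}->{target} in space '{self.name}'")

    def has_edge(self, source: int, target: int) -> bool:
        return any(e.source == source and e.target == target for e in self.edges)

    def to_dict(self) -> dict:
        """JSON-serializable description of the space."""
        states = []
        for s in self.states:
            d = {"id": s.id}
            for f in s.__dataclass_fields__:
                if f != "id":
                    d[f] = getattr(s, f)
            states.append(d)
        return {
            "name": self.name,
            "states": states,
            "edges": [
                {"source": e.source, "target": e.target,
                 "mover": e.mover, "move": e.move}
                for e in self.edges
            ],
        }


@dataclass(frozen=True)
class TransitionClassScheme:
    """Assignment of each directed edge to a shared rate-parameter class.

    ``full`` gives every edge its own class (24 free intensities on the
    pair space); ``initiator_only`` ties edges that agree on mover, move,
    partner location and initiator identity (16 classes); ``memory_free``
    drops the status variables entirely (8 classes).
    """

    name: str
    space_name: str
    assignment: Mapping[tuple[int, int], str]
    class_info: Mapping[str, tuple[str, str]]  # class -> (mover, move)

    @property
    def classes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for label in self.assignment.values():
            seen.setdefault(label)
        return tuple(seen)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def label(self, source: int, target: int) -> str:
        return self.assignment[(source, target)]

    def edges_of(self, label: str) -> tuple[tuple[int, int], ...]:
        return tuple(k for k, v in self.assignment.items() if v == label)

    def mover_of(self, label: str) -> str:
        return self.class_info[label][0]

    def is_refinement_of(self, other: "TransitionClassScheme") -> bool:
        """True if every class of ``other`` is a union of classes of self.

        This is the nesting condition for likelihood-ratio tests: the model
        with the finer scheme (self) contains the coarser one (other).
        """
        if self.space_name != other.space_name:
            return False
        if set(self.assignment) != set(other.assignment):
            return False
        # self is finer iff edges sharing a self-class share an other-class
        fine_to_coarse: dict[str, str] = {}
        for edge, fine in self.assignment.items():
            coarse = other.assignment[edge]
            if fine_to_coarse.setdefault(fine, coarse) != coarse:
                return False
        return True

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "space": self.space_name,
            "classes": list(self.classes),
            "assignment": [
                {"source": s, "target": t, "class": c}
                for (s, t), c in sorted(self.assignment.items())
            ],
        }


# ---------------------------------------------------------------------------
# The 12-state pair space
# ---------------------------------------------------------------------------

# Canonical numbering of the feasible (loc_bold, loc_shy, initiator, joined)
# combinations.  It is fixed so that every transition subscript q_{i,j} used
# when reporting results resolves to an edge of the space.
_PAIR_STATE_TABLE = (
    (1, COVER, COVER, BOLD, False),
    (2, COVER, COVER, SHY, False),
    (3, COVER, COVER, BOLD, True),
    (4, COVER, COVER, SHY, True),
    (5, EXPOSED, COVER, BOLD, False),
    (6, EXPOSED, EXPOSED, BOLD, True),
    (7, COVER, EXPOSED, BOLD, True),
    (8, EXPOSED, COVER, BOLD, True),
    (9, COVER, EXPOSED, SHY, False),
    (10, EXPOSED, EXPOSED, SHY, True),
    (11, EXPOSED, COVER, SHY, True),
    (12, COVER, EXPOSED, SHY, True),
)


def is_feasible(loc_bold: str, loc_shy: str, initiator: str, joined: bool) -> bool:
    """Feasibility filter for the four binary pair-state variables."""
    if loc_bold == EXPOSED and loc_shy == EXPOSED and not joined:
        return False  # both out => the partner has joined
    exposed = [f for f, loc in ((BOLD, loc_bold), (SHY, loc_shy)) if loc == EXPOSED]
    if len(exposed) == 1 and not joined and exposed[0] != initiator:
        return False  # an unjoined solo excursion belongs to the initiator
    return True


def transition_target(state: PairState, mover: str, move: str) -> PairState:
    """Successor of ``state`` when ``mover`` performs ``move``.

    Rules: a departure from a both-covered state opens a new trip (the
    mover becomes the initiator, joined resets to False); the non-initiator
    leaving cover while the initiator is out sets joined; every other move
    carries the status variables over unchanged.

    Raises
    ------
    InvalidMoveError
        If the move is inconsistent with the mover's location (e.g. an
        exposed fish "leaving" cover).
    """
    if mover not in FISHES:
        raise InvalidMoveError(f"unknown mover {mover!r}")
    loc = state.location(mover)
    if move == LEAVE and loc != COVER:
        raise InvalidMoveError(f"{mover} cannot leave cover from {loc!r} (state {state.id})")
    if move == RETURN and loc != EXPOSED:
        raise InvalidMoveError(f"{mover} cannot return to cover from {loc!r} (state {state.id})")
    if move not in (LEAVE, RETURN):
        raise InvalidMoveError(f"unknown move {move!r}")

    new_loc = EXPOSED if move == LEAVE else COVER
    loc_bold = new_loc if mover == BOLD else state.loc_bold
    loc_shy = new_loc if mover == SHY else state.loc_shy

    initiator, joined = state.initiator, state.joined
    if move == LEAVE and state.loc_bold == COVER and state.loc_shy == COVER:
        initiator, joined = mover, False
    elif move == LEAVE and mover != state.initiator:
        joined = True

    for sid, lb, ls, init, j in _PAIR_STATE_TABLE:
        if (lb, ls, init, j) == (loc_bold, loc_shy, initiator, joined):
            return PairState(sid, lb, ls, init, j)
    raise RuntimeError("transition produced an infeasible state")  # pragma: no cover


def _legal_move(state, fish: str) -> str:
    return LEAVE if state.location(fish) == COVER else RETURN


@lru_cache(maxsize=None)
def enumerate_pair_states() -> StateSpace:
    """The 12-state pair space with all 24 single-mover edges."""
    states = tuple(PairState(*row) for row in _PAIR_STATE_TABLE)
    edges = []
    for s in states:
        for fish in FISHES:
            move = _legal_move(s, fish)
            t = transition_target(s, fish, move)
            edges.append(Edge(s.id, t.id, fish, move))
    return StateSpace("pair", states, tuple(edges))


@lru_cache(maxsize=None)
def successor_table() -> Mapping[tuple[int, str, str], PairState]:
    """Lookup ``(state_id, mover, move) -> successor`` over all legal moves."""
    space = enumerate_pair_states()
    table = {}
    for s in space.states:
        for fish in FISHES:
            move = _legal_move(s, fish)
            table[(s.id, fish, move)] = transition_target(s, fish, move)
    return table


# ---------------------------------------------------------------------------
# Tying schemes
# ---------------------------------------------------------------------------

def _partner_location(space: StateSpace, edge: Edge) -> str:
    src = space.state(edge.source)
    partner = SHY if edge.mover == BOLD else BOLD
    return src.location(partner)


@lru_cache(maxsize=None)
def tying_scheme(space: StateSpace, name: str) -> TransitionClassScheme:
    """Build the ``full``, ``initiator_only`` or ``memory_free`` scheme.

    On the 12-state pair space the three schemes have 24, 16 and 8 free
    rate classes respectively.  ``full`` and ``memory_free`` are also
    defined on the reduced spaces (``full`` simply assigns one class per
    edge of whatever space it is given).
    """
    assignment: dict[tuple[int, int], str] = {}
    info: dict[str, tuple[str, str]] = {}
    for e in space.edges:
        if name == "full":
            label = f"q_{e.source}_{e.target}"
        elif name == "memory_free":
            label = f"{e.mover}_{e.move}_partner_{_partner_location(space, e)}"
        elif name == "initiator_only":
            src = space.state(e.source)
            label = (f"{e.mover}_{e.move}_partner_{_partner_location(space, e)}"
                     f"_init_{src.initiator}")
        else:
            raise ValueError(f"unknown tying scheme {name!r}")
        assignment[(e.source, e.target)] = label
        info[label] = (e.mover, e.move)
    return TransitionClassScheme(name, space.name, assignment, info)


# ---------------------------------------------------------------------------
# Reduced spaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocationState:
    """A location-only pair state (status variables dropped)."""

    id: int
    loc_bold: str
    loc_shy: str

    def location(self, fish: str) -> str:
        return self.loc_bold if fish == BOLD else self.loc_shy

    @property
    def locations(self) -> tuple[str, str]:
        return (self.loc_bold, self.loc_shy)


_LOCATION_TABLE = (
    (1, COVER, COVER),
    (2, EXPOSED, COVER),
    (3, COVER, EXPOSED),
    (4, EXPOSED, EXPOSED),
)
_LOC_ID = {(lb, ls): i for i, lb, ls in _LOCATION_TABLE}


def location_of(state) -> tuple[str, str]:
    """Location combination of any pair-like state."""
    return (state.loc_bold, state.loc_shy)


@lru_cache(maxsize=None)
def location_space() -> StateSpace:
    """The 4-state location-only space (8 edges)."""
    states = tuple(LocationState(*row) for row in _LOCATION_TABLE)
    edges = []
    for s in states:
        for fish in FISHES:
            move = _legal_move(s, fish)
            new_loc = EXPOSED if move == LEAVE else COVER
            lb = new_loc if fish == BOLD else s.loc_bold
            ls = new_loc if fish == SHY else s.loc_shy
            edges.append(Edge(s.id, _LOC_ID[(lb, ls)], fish, move))
    return StateSpace("location", states, tuple(edges))


def location_collapse_map(pair_space: StateSpace) -> dict[int, int]:
    """Map 12-state ids onto 4-state location-only ids."""
    return {s.id: _LOC_ID[location_of(s)] for s in pair_space.states}


@dataclass(frozen=True)
class OneStepState:
    """Current location combination plus the one that preceded it."""

    id: int
    loc_bold: str
    loc_shy: str
    prev_loc_bold: str
    prev_loc_shy: str

    def location(self, fish: str) -> str:
        return self.loc_bold if fish == BOLD else self.loc_shy

    @property
    def locations(self) -> tuple[str, str]:
        return (self.loc_bold, self.loc_shy)

    @property
    def prev_locations(self) -> tuple[str, str]:
        return (self.prev_loc_bold, self.prev_loc_shy)


@lru_cache(maxsize=None)
def one_step_memory_space() -> StateSpace:
    """The 8-state one-step-memory space (16 edges).

    Each of the 4 location combinations is paired with each of its feasible
    single-mover predecessors (two each), and an edge's successor remembers
    the edge's source location combination as its "previous" component.
    """
    combos = [(lb, ls) for _, lb, ls in _LOCATION_TABLE]
    states = []
    sid = 0
    index: dict[tuple, int] = {}
    for cur in combos:
        for prev in combos:
            # feasible predecessor: differs in exactly one fish's location
            if sum(a != b for a, b in zip(cur, prev)) == 1:
                sid += 1
                states.append(OneStepState(sid, cur[0], cur[1], prev[0], prev[1]))
                index[(cur, prev)] = sid
    edges = []
    for s in states:
        cur = s.locations
        for fish in FISHES:
            move = _legal_move(s, fish)
            new_loc = EXPOSED if move == LEAVE else COVER
            nxt = (new_loc if fish == BOLD else cur[0],
                   new_loc if fish == SHY else cur[1])
            edges.append(Edge(s.id, index[(nxt, cur)], fish, move))
    return StateSpace("one_step", tuple(states), tuple(edges))


@dataclass(frozen=True)
class IndividualState:
    """A single fish's location state."""

    id: int
    location: str


@lru_cache(maxsize=None)
def two_state_space() -> StateSpace:
    """The two-state individual space: 1 = cover, 2 = exposed."""
    states = (IndividualState(1, COVER), IndividualState(2, EXPOSED))
    edges = (Edge(1, 2, "self", LEAVE), Edge(2, 1, "self", RETURN))
    return StateSpace("individual", states, edges)


def individual_scheme() -> TransitionClassScheme:
    """Two classes (leave, return) for the individual two-state model."""
    space = two_state_space()
    assignment = {(1, 2): "leave", (2, 1): "return"}
    info = {"leave": ("self", LEAVE), "return": ("self", RETURN)}
    return TransitionClassScheme("two_state", space.name, assignment, info)
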