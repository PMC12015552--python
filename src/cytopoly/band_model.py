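"""Banding sequences as signed segment orders and the rearrangement algebra.

A polytene chromosome arm is modelled as an ordered list of band segments,
each read in a forward (+) or reversed (-) orientation — a signed
permutation.  A paracentric or pericentric inversion is a *reversal* of a
contiguous interval of segments (orientations flip).  The number of
inversion steps separating two banding sequences is the minimal number of
reversals turning one order into the other, found by exact breadth-first
search; the breakpoint count (broken segment adjacencies) gives the classic
lower bound ceil(b/2).

A squashed chromosome has no intrinsic left-right, so whole-order
reflection (reverse the list and flip every sign) is treated as the
identity throughout.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

import networkx as nx

__all__ = [
    "BandSegment",
    "BandOrder",
    "BandingSequence",
    "SequenceName",
    "ReversalSteps",
    "IncomparableOrdersError",
    "SequenceNameError",
    "parse_sequence_name",
    "format_sequence_name",
    "apply_reversal",
    "breakpoint_count",
    "reversal_steps",
    "classify_derivation",
    "enumerate_intermediates",
    "build_derivation_graph",
    "load_registry",
    "save_registry",
]

ARMS = ("A", "B", "C", "D", "E", "F", "G")

#: derivation kinds
SIMPLE_PARACENTRIC = "simple paracentric"
SIMPLE_PERICENTRIC = "simple pericentric"
COMPLEX = "complex"
TRANSLOCATION = "translocation"

SEQ_CLASSES = ("main", "alternative", "rare", "unique", "hypothetical")

#: exact-search regime: beyond this many segments BFS is not attempted and
#: the breakpoint lower bound is reported with the ``exact`` flag cleared.
EXACT_SEGMENT_LIMIT = 12


class IncomparableOrdersError(ValueError):
    """Two band orders do not share the same segment label set."""


class SequenceNameError(ValueError):
    """A banding-sequence designation string could not be parsed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandSegment:
    """One maximal band region shared by all sequences of an arm.

    ``label`` is a band-region identifier such as ``"1a-4h"``.  Segments
    moved across the centromere by a pericentric inversion keep a
    ``source_arm`` tag (e.g. the region ``B15c-B12v`` shown in arm A maps).
    """

    label: str
    orientation: int = 1  # +1 forward, -1 reversed
    source_arm: str | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("segment label must be non-empty")
        if self.orientation not in (1, -1):
            raise ValueError("orientation must be +1 or -1")

    def flipped(self) -> "BandSegment":
        return replace(self, orientation=-self.orientation)

    def __str__(self) -> str:
        prefix = "-" if self.orientation < 0 else ""
        return f"{prefix}{self.label}"


@dataclass(frozen=True)
class BandOrder:
    """Signed order of band segments of one arm, with a centromere marker.

    ``centromere_index`` is a boundary position in ``0..len(segments)``:
    0 places the centromere before the first segment (the mapping convention
    for most arms puts it at a defined end), ``len(segments)`` after the
    last.  A reversal of segments ``i..j`` spans the centromere iff
    ``i < centromere_index <= j``.
    """

    arm: str
    segments: tuple[BandSegment, ...]
    centromere_index: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        object.__setattr__(self, "segments", tuple(self.segments))
        labels = [s.label for s in self.segments]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate segment labels in arm {self.arm}: {labels}")
        if not 0 <= self.centromere_index <= len(self.segments):
            raise ValueError("centromere_index out of bounds")

    def __len__(self) -> int:
        return len(self.segments)

    @classmethod
    def from_labels(
        cls, arm: str, labels: Iterable[str], centromere_index: int = 0
    ) -> "BandOrder":
        """Build from signed label strings: a leading ``-`` marks a reversed segment."""
        segs = []
        for raw in labels:
            raw = raw.strip()
            if raw.startswith("-"):
                segs.append(BandSegment(raw[1:], -1))
            else:
                segs.append(BandSegment(raw.lstrip("+"), 1))
        return cls(arm, tuple(segs), centromere_index)

    def labels(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.segments)

    def reflected(self) -> "BandOrder":
        """Whole-order reflection: reverse the list, flip every orientation."""
        return BandOrder(
            self.arm,
            tuple(s.flipped() for s in reversed(self.segments)),
            len(self.segments) - self.centromere_index,
        )


class SequenceName(NamedTuple):
    """Parsed banding-sequence designation (e.g. ``p'borA5``)."""

    geography: str  # "Palearctic" or "Holarctic"
    species: str  # three-letter code, e.g. "bor"
    arm: str
    serial: int


@dataclass
class BandingSequence:
    """A named banding sequence with optional band order and annotations.

    ``order`` is ``None`` for registry stubs whose band-by-band mapping has
    not been transcribed.  ``parent``/``n_steps``/``kind`` record the
    derivation narrative; ``seq_class`` one of main/alternative/rare/unique
    (or ``hypothetical`` for unobserved intermediates on a minimal inversion
    path).
    """

    name: str
    arm: str
    order: BandOrder | None = None
    seq_class: str | None = None
    parent: str | None = None
    n_steps: int | None = None
    kind: str | None = None
    mapping_version: str | None = None  # KV/GV arm-E annotation
    notes: str = ""

    def __post_init__(self) -> None:
        parsed = parse_sequence_name(self.name)
        if parsed.arm != self.arm:
            raise ValueError(f"{self.name}: arm field {self.arm!r} contradicts designation")
        if parsed.serial < 1:
            raise ValueError("serial must be >= 1")
        if self.seq_class is not None and self.seq_class not in SEQ_CLASSES:
            raise ValueError(f"unknown sequence class {self.seq_class!r}")

    @property
    def serial(self) -> int:
        return parse_sequence_name(self.name).serial


# ---------------------------------------------------------------------------
# designation parsing
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"^(?P<prefix>[ph])['’](?P<species>[a-z]{3})(?P<arm>[A-Za-z])(?P<serial>\d+)$")

_GEOGRAPHY = {"p": "Palearctic", "h": "Holarctic"}
_PREFIX = {"Palearctic": "p", "Holarctic": "h"}


def parse_sequence_name(text: str) -> SequenceName:
    """Parse a designation like ``p'borA1`` into its components.

    The leading letter gives geographic distribution (p' Palearctic,
    h' Holarctic), then the three-letter species code, the arm letter and
    the serial number of the sequence within the arm.
    """
    m = _NAME_RE.match(text.strip())
    if not m:
        raise SequenceNameError(f"malformed banding-sequence designation: {text!r}")
    arm = m.group("arm")
    if arm not in ARMS:
        raise SequenceNameError(f"{text!r}: no chromosomal arm {arm!r} (expected A-G)")
    serial = int(m.group("serial"))
    if serial < 1:
        raise SequenceNameError(f"{text!r}: serial numbers start at 1")
    return SequenceName(_GEOGRAPHY[m.group("prefix")], m.group("species"), arm, serial)


def format_sequence_name(name: SequenceName) -> str:
    """Inverse of :func:`parse_sequence_name`."""
    return f"{_PREFIX[name.geography]}'{name.species}{name.arm}{name.serial}"


# ---------------------------------------------------------------------------
# signed-permutation plumbing
# ---------------------------------------------------------------------------


def _relabel(a: BandOrder, b: BandOrder) -> tuple[int, ...]:
    """Express ``a`` as a signed permutation relative to ``b`` read as identity."""
    if {s.label for s in a.segments} != {s.label for s in b.segments}:
        raise IncomparableOrdersError(
            f"segment sets differ: {sorted(s.label for s in a.segments)} vs "
            f"{sorted(s.label for s in b.segments)}"
        )
    index = {s.label: (k + 1, s.orientation) for k, s in enumerate(b.segments)}
    out = []
    for s in a.segments:
        k, orient = index[s.label]
        out.append(k if s.orientation == orient else -k)
    return tuple(out)


def _reflect(perm: Sequence[int]) -> tuple[int, ...]:
    return tuple(-v for v in reversed(perm))


def _canon(perm: Sequence[int]) -> tuple[int, ...]:
    p = tuple(perm)
    r = _reflect(p)
    return p if p <= r else r


def _perm_to_order(perm: Sequence[int], b: BandOrder, centromere_index: int) -> BandOrder:
    """Map a signed permutation (relative to ``b`` as identity) back to segments."""
    segs = []
    for v in perm:
        base = b.segments[abs(v) - 1]
        segs.append(base if v > 0 else base.flipped())
    return BandOrder(b.arm, tuple(segs), centromere_index)


def _signed_breakpoints(perm: Sequence[int]) -> int:
    """Breakpoints of a signed permutation vs identity, with end caps 0 and n+1."""
    n = len(perm)
    ext = (0, *perm, n + 1)
    return sum(1 for x, y in zip(ext, ext[1:]) if y != x + 1)


def _unsigned_breakpoints(perm: Sequence[int]) -> int:
    n = len(perm)
    ext = (0, *(abs(v) for v in perm), n + 1)
    return sum(1 for x, y in zip(ext, ext[1:]) if abs(y - x) != 1)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


class ReversalRecord(NamedTuple):
    i: int
    j: int
    pericentric: bool


def apply_reversal(order: BandOrder, i: int, j: int) -> tuple[BandOrder, ReversalRecord]:
    """Reverse segments ``i..j`` (inclusive), flipping their orientations.

    Returns the new order and a record noting whether the reversed interval
    spans the centromere (a pericentric inversion).  Applying the same
    reversal twice restores the original order.
    """
    n = len(order.segments)
    if not (0 <= i <= j < n):
        raise IndexError(f"reversal indices ({i}, {j}) out of range for {n} segments")
    segs = list(order.segments)
    segs[i : j + 1] = [s.flipped() for s in reversed(segs[i : j + 1])]
    pericentric = i < order.centromere_index <= j
    new = BandOrder(order.arm, tuple(segs), order.centromere_index)
    return new, ReversalRecord(i, j, pericentric)


def breakpoint_count(a: BandOrder, b: BandOrder, signed: bool = True) -> int:
    """Number of segment adjacencies (incl. the two end caps) of ``a`` broken in ``b``.

    Symmetric; zero iff the orders are identical up to whole-order
    reflection.  ``signed=False`` ignores segment orientation when matching
    adjacencies (the unsigned variant is provided for comparison; signed is
    the default and the faithful model of oriented band regions).
    """
    perm = _relabel(a, b)
    count = _signed_breakpoints if signed else _unsigned_breakpoints
    return min(count(perm), count(_reflect(perm)))


class ReversalSteps(int):
    """Minimal number of reversals; ``exact`` is False when only the
    breakpoint lower bound could be reported (search budget exceeded)."""

    exact: bool

    def __new__(cls, value: int, exact: bool = True) -> "ReversalSteps":
        obj = super().__new__(cls, value)
        obj.exact = exact
        return obj


def _neighbors(perm: tuple[int, ...]) -> Iterable[tuple[int, ...]]:
    n = len(perm)
    for i in range(n):
        for j in range(i, n):
            yield perm[:i] + tuple(-v for v in reversed(perm[i : j + 1])) + perm[j + 1 :]


def _bfs_reversal_distance(start: tuple[int, ...], max_steps: int) -> int | None:
    """Bidirectional BFS distance from ``start`` to the identity permutation,
    with whole-order reflection treated as identity."""
    n = len(start)
    ident = tuple(range(1, n + 1))
    s0, t0 = _canon(start), _canon(ident)
    if s0 == t0:
        return 0
    front = {s0: 0}
    back = {t0: 0}
    frontier_f, frontier_b = {s0}, {t0}
    depth_f = depth_b = 0
    while depth_f + depth_b < max_steps and frontier_f and frontier_b:
        # expand the smaller frontier
        if len(frontier_f) <= len(frontier_b):
            frontier, dist, other = frontier_f, front, back
            depth_f += 1
            new_depth = depth_f
        else:
            frontier, dist, other = frontier_b, back, front
            depth_b += 1
            new_depth = depth_b
        new_frontier = set()
        for perm in frontier:
            for nb in _neighbors(perm):
                c = _canon(nb)
                if c in dist:
                    continue
                if c in other:
                    return new_depth + other[c]
                dist[c] = new_depth
                new_frontier.add(c)
        if frontier is frontier_f:
            frontier_f = new_frontier
        else:
            frontier_b = new_frontier
    return None


def reversal_steps(a: BandOrder, b: BandOrder, max_steps: int = 16) -> ReversalSteps:
    """Length of the shortest reversal series turning ``a`` into ``b``.

    Exact breadth-first search over reversals (reflection-invariant); the
    result satisfies ceil(breakpoints/2) <= steps <= breakpoints and the
    metric axioms.  Orders with more than 12 segments, or searches
    exhausting ``max_steps``, fall back to the breakpoint lower bound with
    ``exact=False``.
    """
    perm = _relabel(a, b)
    bp = breakpoint_count(a, b)
    lower = math.ceil(bp / 2)
    if len(perm) > EXACT_SEGMENT_LIMIT:
        return ReversalSteps(lower, exact=False)
    d = _bfs_reversal_distance(perm, max_steps=max_steps)
    if d is None:
        return ReversalSteps(lower, exact=False)
    return ReversalSteps(d, exact=True)


def classify_derivation(parent: BandingSequence, child: BandingSequence) -> str:
    """Classify how ``child`` derives from ``parent``.

    One non-centromere-spanning reversal -> "simple paracentric"; one
    centromere-spanning reversal -> "simple pericentric"; two or more
    minimal steps -> "complex".
    """
    if parent.order is None or child.order is None:
        raise ValueError("both sequences need band orders to classify a derivation")
    d = reversal_steps(parent.order, child.order)
    if not d.exact:
        raise ValueError("derivation classification requires the exact-search regime")
    if d == 0:
        raise ValueError(f"{parent.name} and {child.name} have identical orders")
    if d >= 2:
        return COMPLEX
    # find every single reversal realizing the child (directly or reflected)
    child_perm = _relabel(parent.order, child.order)
    pericentric_only = True
    found = False
    n = len(child_perm)
    for i in range(n):
        for j in range(i, n):
            cand = (
                child_perm[:i]
                + tuple(-v for v in reversed(child_perm[i : j + 1]))
                + child_perm[j + 1 :]
            )
            if _canon(cand) == _canon(tuple(range(1, n + 1))):
                found = True
                if not (i < parent.order.centromere_index <= j):
                    pericentric_only = False
    assert found, "distance-1 pair must admit a single realizing reversal"
    return SIMPLE_PERICENTRIC if pericentric_only else SIMPLE_PARACENTRIC


def enumerate_intermediates(
    parent: BandingSequence, child: BandingSequence
) -> list[BandingSequence]:
    """All band orders on at least one minimal reversal path between two
    sequences, excluding the endpoints, labelled "hypothetical".

    Deterministic output order (sorted by signed permutation relative to the
    child).  Distance < 2 yields an empty list.
    """
    if parent.order is None or child.order is None:
        raise ValueError("both sequences need band orders to enumerate intermediates")
    d = reversal_steps(parent.order, child.order)
    if not d.exact:
        raise ValueError("intermediate enumeration requires the exact-search regime")
    if d < 2:
        return []
    start = _canon(_relabel(parent.order, child.order))
    n = len(start)
    goal = _canon(tuple(range(1, n + 1)))

    def layers(src: tuple[int, ...], depth: int) -> dict[tuple[int, ...], int]:
        dist = {src: 0}
        frontier = [src]
        for step in range(1, depth + 1):
            nxt = []
            for perm in frontier:
                for nb in _neighbors(perm):
                    c = _canon(nb)
                    if c not in dist:
                        dist[c] = step
                        nxt.append(c)
            frontier = nxt
        return dist

    from_parent = layers(start, d - 1)
    from_child = layers(goal, d - 1)
    mids = sorted(
        p
        for p, da in from_parent.items()
        if 0 < da < d and from_child.get(p, d + 1) == d - da
    )
    out = []
    base = parse_sequence_name(child.name)
    for k, perm in enumerate(mids, start=1):
        order = _perm_to_order(perm, child.order, parent.order.centromere_index)
        seq = BandingSequence(
            name=format_sequence_name(base._replace(serial=900 + k)),
            arm=child.arm,
            order=order,
            seq_class="hypothetical",
            notes=f"hypothetical intermediate between {parent.name} and {child.name}",
        )
        out.append(seq)
    return out


def build_derivation_graph(
    registry: Iterable[BandingSequence],
    roots: dict[str, str] | None = None,
) -> nx.DiGraph:
    """Derivation graph over a registry: one root (main sequence) per arm,
    every other sequence attached to its minimal-steps ancestor.

    Ancestors are chosen among registry members of the same arm (ties broken
    toward the root, then lexicographically).  Sequences without transcribed
    band orders fall back to their annotated parent/kind/steps; translocation
    -derived sequences are attached by annotation only (reversals cannot
    generate them).  Orders that cannot be attached are listed per arm in
    ``graph.graph["orphans"]``.
    """
    seqs = list(registry)
    by_arm: dict[str, list[BandingSequence]] = {}
    for s in seqs:
        by_arm.setdefault(s.arm, []).append(s)
    if roots is None:
        roots = {}
        for arm, members in by_arm.items():
            mains = [s for s in members if s.serial == 1]
            if not mains:
                raise ValueError(f"arm {arm}: no serial-1 root sequence in registry")
            roots[arm] = mains[0].name

    g = nx.DiGraph(orphans={})
    for s in seqs:
        g.add_node(s.name, sequence=s)

    for arm, members in by_arm.items():
        root = roots[arm]
        named = {s.name: s for s in members}
        orphans: list[str] = []
        for s in members:
            if s.name == root:
                continue
            if s.kind == TRANSLOCATION or s.order is None:
                if s.parent and s.parent in g:
                    g.add_edge(
                        s.parent,
                        s.name,
                        n_steps=s.n_steps if s.n_steps is not None else 1,
                        kind=s.kind or "unspecified",
                        annotated=True,
                    )
                else:
                    orphans.append(s.name)
                continue
            best: tuple[int, int, str] | None = None
            best_parent: BandingSequence | None = None
            for cand in members:
                if cand.name == s.name or cand.order is None or cand.kind == TRANSLOCATION:
                    continue
                try:
                    d = reversal_steps(cand.order, s.order)
                except IncomparableOrdersError:
                    continue
                if d == 0:
                    continue
                key = (int(d), 0 if cand.name == root else 1, cand.name)
                if best is None or key < best:
                    best, best_parent = key, cand
            if best is None or best_parent is None:
                orphans.append(s.name)
                continue
            g.add_edge(
                best_parent.name,
                s.name,
                n_steps=best[0],
                kind=classify_derivation(best_parent, s),
                annotated=False,
            )
        if orphans:
            g.graph["orphans"][arm] = orphans
    return g


# ---------------------------------------------------------------------------
# registry I/O
# ---------------------------------------------------------------------------

_REGISTRY_FIELDS = [
    "name",
    "arm",
    "segments",
    "centromere_index",
    "seq_class",
    "parent",
    "n_steps",
    "kind",
    "mapping_version",
    "notes",
]


def _row_to_sequence(row: dict[str, str]) -> BandingSequence:
    order = None
    if row.get("segments", "").strip():
        order = BandOrder.from_labels(
            row["arm"],
            row["segments"].split(";"),
            int(row.get("centromere_index") or 0),
        )
    n_steps = row.get("n_steps", "").strip()
    return BandingSequence(
        name=row["name"],
        arm=row["arm"],
        order=order,
        seq_class=row.get("seq_class") or None,
        parent=row.get("parent") or None,
        n_steps=int(n_steps) if n_steps else None,
        kind=row.get("kind") or None,
        mapping_version=row.get("mapping_version") or None,
        notes=row.get("notes", ""),
    )


def load_registry(path: str | None = None) -> list[BandingSequence]:
    """Load a banding-sequence registry CSV.

    With no path, loads the packaged registry of the 40 named sequences of
    *Chironomus borokensis* (band orders are stubs pending transcription of
    the full cytological maps; derivation annotations are recorded).
    """
    if path is None:
        ref = resources.files("cytopoly.data").joinpath("registry.csv")
        with ref.open("r", encoding="utf-8") as fh:
            return [_row_to_sequence(r) for r in csv.DictReader(fh)]
    with open(path, "r", encoding="utf-8") as fh:
        return [_row_to_sequence(r) for r in csv.DictReader(fh)]


def save_registry(registry: Iterable[BandingSequence], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_REGISTRY_FIELDS)
        w.writeheader()
        for s in registry:
            w.writerow(
                {
                    "name": s.name,
                    "arm": s.arm,
                    "segments": ";".join(s.order.labels()) if s.order else "",
                    "centromere_index": s.order.centromere_index if s.order else "",
                    "seq_class": s.seq_class or "",
                    "parent": s.parent or "",
                    "n_steps": s.n_steps if s.n_steps is not None else "",
                    "kind": s.kind or "",
                    "mapping_version": s.mapping_version or "",
                    "notes": s.notes,
                }
            )


def registry_arm_counts(registry: Iterable[BandingSequence]) -> dict[str, int]:
    """Number of named banding sequences per arm (hypotheticals excluded)."""
    counts = {arm: 0 for arm in ARMS}
    for s in registry:
        if s.seq_class != "hypothetical":
            counts[s.arm] += 1
    return counts
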