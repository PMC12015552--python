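"""Rearrangement algebra: designation parsing, reversals, breakpoints,
minimal inversion steps, derivation classification and graphs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytopoly.band_model import (
    BandOrder,
    BandingSequence,
    IncomparableOrdersError,
    SequenceNameError,
    apply_reversal,
    breakpoint_count,
    build_derivation_graph,
    classify_derivation,
    enumerate_intermediates,
    format_sequence_name,
    load_registry,
    parse_sequence_name,
    registry_arm_counts,
    reversal_steps,
)
from cytopoly.synthetic_data import generate_reversal_series

from conftest import perm_of
from oracles import (
    breakpoints_oracle,
    canon,
    iddfs_reversal_distance,
    shortest_path_intermediates,
)


# ---------------------------------------------------------------------------
# designations
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("p'borA1", ("Palearctic", "bor", "A", 1)),
        ("h'borE1", ("Holarctic", "bor", "E", 1)),
        ("p'borG2", ("Palearctic", "bor", "G", 2)),
        ("h’borD2", ("Holarctic", "bor", "D", 2)),  # typographic apostrophe
    ],
)
def test_parse_designation(text, expected):
    assert tuple(parse_sequence_name(text)) == expected


@pytest.mark.parametrize("bad", ["p'borX1", "borA1", "p'bA1", "p'borA0", "q'borA1", ""])
def test_parse_designation_rejects_malformed(bad):
    with pytest.raises(SequenceNameError):
        parse_sequence_name(bad)


@given(
    prefix=st.sampled_from(["p", "h"]),
    species=st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=3, max_size=3),
    arm=st.sampled_from(list("ABCDEFG")),
    serial=st.integers(min_value=1, max_value=99),
)
def test_designation_round_trip(prefix, species, arm, serial):
    text = f"{prefix}'{species}{arm}{serial}"
    assert format_sequence_name(parse_sequence_name(text)) == text


# ---------------------------------------------------------------------------
# reversals and breakpoints
# ---------------------------------------------------------------------------


def ident(n, arm="A", centromere=0):
    return BandOrder.from_labels(arm, [str(i) for i in range(1, n + 1)], centromere)


def test_reversal_definition():
    o = ident(5)
    rev, rec = apply_reversal(o, 1, 3)
    assert rev.labels() == ("1", "-4", "-3", "-2", "5")
    assert not rec.pericentric


def test_single_segment_reversal_flips_sign():
    o = ident(4)
    rev, _ = apply_reversal(o, 2, 2)
    assert rev.labels() == ("1", "2", "-3", "4")


def test_reversal_out_of_range():
    with pytest.raises(IndexError):
        apply_reversal(ident(4), 2, 4)


def test_pericentric_flag_depends_on_centromere():
    o = ident(5, centromere=2)
    _, rec = apply_reversal(o, 1, 3)  # boundary 2 inside [1, 3]
    assert rec.pericentric
    _, rec = apply_reversal(o, 2, 4)  # interval right of the centromere
    assert not rec.pericentric


@given(
    n=st.integers(min_value=2, max_value=8),
    data=st.data(),
)
def test_reversal_involution(n, data):
    i = data.draw(st.integers(min_value=0, max_value=n - 1))
    j = data.draw(st.integers(min_value=i, max_value=n - 1))
    o = ident(n)
    once, _ = apply_reversal(o, i, j)
    twice, _ = apply_reversal(once, i, j)
    assert twice == o


def test_breakpoint_examples():
    a = ident(5)
    b, _ = apply_reversal(a, 1, 3)
    assert breakpoint_count(a, a) == 0
    assert breakpoint_count(a, b) == 2
    assert breakpoint_count(b, a) == 2
    assert breakpoint_count(a, a.reflected()) == 0


def test_breakpoint_incomparable_orders():
    a = ident(4)
    c = BandOrder.from_labels("A", ["1", "2", "3", "9"])
    with pytest.raises(IncomparableOrdersError):
        breakpoint_count(a, c)


def test_breakpoints_match_adjacency_oracle(rng):
    """Random reversal products vs an independent adjacency-set scan."""
    for trial in range(200):
        n = int(rng.integers(3, 9))
        k = int(rng.integers(0, 4))
        anc, der, _ = generate_reversal_series(n, k, seed=int(rng.integers(2**31)))
        got = breakpoint_count(anc, der)
        assert got == breakpoints_oracle(perm_of(der, anc))
        assert 0 <= got <= n + 1


# ---------------------------------------------------------------------------
# minimal reversal steps
# ---------------------------------------------------------------------------


def test_steps_basics():
    a = ident(6)
    assert reversal_steps(a, a) == 0
    assert reversal_steps(a, a.reflected()) == 0
    b, _ = apply_reversal(a, 2, 4)
    assert reversal_steps(a, b) == 1
    assert reversal_steps(b, a) == 1


def test_steps_match_iddfs_oracle(rng):
    """BFS distance equals an independent iterative-deepening search and
    respects the breakpoint bounds, on random instances."""
    for trial in range(100):
        n = int(rng.integers(4, 9))
        k = int(rng.integers(0, 4))
        anc, der, _ = generate_reversal_series(n, k, seed=int(rng.integers(2**31)))
        d = reversal_steps(anc, der)
        assert d.exact
        assert d == iddfs_reversal_distance(perm_of(der, anc))
        bp = breakpoint_count(anc, der)
        assert math.ceil(bp / 2) <= d <= max(bp, 0)
        assert d <= k


def test_steps_known_count_with_non_overlapping_reversals(rng):
    """Non-overlapping generated series have distance exactly k."""
    for k in (0, 1, 2, 3):
        anc, der, revs = generate_reversal_series(
            10, k, seed=k + 5, non_overlapping=True
        )
        assert len(revs) == k
        assert reversal_steps(anc, der) == k


def test_steps_large_orders_fall_back_to_lower_bound():
    a = BandOrder.from_labels("A", [str(i) for i in range(1, 15)])
    b, _ = apply_reversal(a, 2, 7)
    d = reversal_steps(a, b)
    assert not d.exact
    assert d == 1  # ceil(2/2)


# ---------------------------------------------------------------------------
# derivation classification and intermediates
# ---------------------------------------------------------------------------


def seq(name, order):
    return BandingSequence(name=name, arm=order.arm, order=order)


def test_classify_simple_paracentric():
    parent = seq("p'borA1", ident(6, centromere=0))
    child_order, _ = apply_reversal(parent.order, 2, 4)
    assert classify_derivation(parent, seq("p'borA2", child_order)) == "simple paracentric"


def test_classify_simple_pericentric():
    parent = seq("p'borA1", ident(6, centromere=3))
    child_order, rec = apply_reversal(parent.order, 1, 4)
    assert rec.pericentric
    assert classify_derivation(parent, seq("p'borA7", child_order)) == "simple pericentric"


def test_classify_complex_two_disjoint_reversals():
    parent = seq("p'borF1", ident(7, arm="F"))
    o, _ = apply_reversal(parent.order, 0, 1)
    o, _ = apply_reversal(o, 3, 5)
    child = seq("p'borF5", o)
    assert reversal_steps(parent.order, child.order) == 2
    assert classify_derivation(parent, child) == "complex"


def test_intermediates_empty_below_distance_two():
    parent = seq("p'borA1", ident(5))
    child_order, _ = apply_reversal(parent.order, 1, 2)
    assert enumerate_intermediates(parent, seq("p'borA2", child_order)) == []


def test_intermediates_two_disjoint_reversals():
    parent = seq("p'borA1", ident(6))
    o, _ = apply_reversal(parent.order, 0, 1)
    mid1 = o
    o, _ = apply_reversal(o, 3, 4)
    child = seq("p'borA5", o)
    mids = enumerate_intermediates(parent, child)
    assert len(mids) == 2
    assert all(m.seq_class == "hypothetical" for m in mids)
    mid_perms = {canon(perm_of(m.order, child.order)) for m in mids}
    alt, _ = apply_reversal(parent.order, 3, 4)
    expected = {
        canon(perm_of(mid1, child.order)),
        canon(perm_of(alt, child.order)),
    }
    assert mid_perms == expected


def test_intermediates_match_path_enumeration_oracle(rng):
    """Distance >= 2 products: intermediates equal the states found by
    exhaustive minimal-path enumeration."""
    checked = 0
    for trial in range(30):
        anc, der, _ = generate_reversal_series(
            7, int(rng.integers(2, 4)), seed=int(rng.integers(2**31)), non_overlapping=True
        )
        d = int(reversal_steps(anc, der))
        if d < 2:
            continue
        checked += 1
        parent, child = seq("p'borA1", anc), seq("p'borA5", der)
        mids = enumerate_intermediates(parent, child)
        got = {canon(perm_of(m.order, child.order)) for m in mids}
        expected = shortest_path_intermediates(perm_of(anc, der), d)
        assert got == expected
    assert checked >= 5


def test_intermediates_deterministic_order():
    parent = seq("p'borA1", ident(6))
    o, _ = apply_reversal(parent.order, 0, 1)
    o, _ = apply_reversal(o, 3, 4)
    child = seq("p'borA5", o)
    names1 = [m.order.labels() for m in enumerate_intermediates(parent, child)]
    names2 = [m.order.labels() for m in enumerate_intermediates(parent, child)]
    assert names1 == names2


# ---------------------------------------------------------------------------
# derivation graph
# ---------------------------------------------------------------------------


def test_derivation_graph_prefers_nearest_ancestor():
    root = seq("p'borA1", ident(7))
    x_order, _ = apply_reversal(root.order, 0, 2)
    x = seq("p'borA2", x_order)
    y_order, _ = apply_reversal(x_order, 4, 5)
    y = seq("p'borA3", y_order)
    g = build_derivation_graph([root, x, y])
    assert set(g.edges) == {("p'borA1", "p'borA2"), ("p'borA2", "p'borA3")}
    assert g.edges["p'borA1", "p'borA2"]["kind"] == "simple paracentric"
    assert g.edges["p'borA1", "p'borA2"]["n_steps"] == 1


def test_derivation_graph_annotated_fallback_and_orphans():
    root = seq("p'borB1", ident(5, arm="B"))
    stub = BandingSequence(
        name="p'borB2", arm="B", parent="p'borB1", n_steps=1, kind="simple paracentric"
    )
    translo = BandingSequence(name="p'borB3", arm="B", parent="p'borB1", kind="translocation")
    orphan = BandingSequence(name="p'borB4", arm="B")  # no order, no parent
    g = build_derivation_graph([root, stub, translo, orphan])
    assert g.edges["p'borB1", "p'borB2"]["annotated"]
    assert g.edges["p'borB1", "p'borB3"]["kind"] == "translocation"
    assert g.graph["orphans"]["B"] == ["p'borB4"]


# ---------------------------------------------------------------------------
# packaged registry
# ---------------------------------------------------------------------------


def test_registry_fixture_counts_and_classes():
    registry = load_registry()
    assert registry_arm_counts(registry) == {
        "A": 9, "B": 7, "C": 3, "D": 5, "E": 7, "F": 7, "G": 2,
    }
    assert len(registry) == 40
    classes = {}
    for s in registry:
        classes[s.seq_class] = classes.get(s.seq_class, 0) + 1
    assert classes == {"main": 7, "alternative": 6, "rare": 4, "unique": 23}
    # every name parses and matches its arm column
    for s in registry:
        assert parse_sequence_name(s.name).arm == s.arm


def test_registry_derivation_annotations():
    registry = {s.name: s for s in load_registry()}
    assert registry["p'borA5"].n_steps == 3 and registry["p'borA5"].kind == "complex"
    assert registry["p'borA8"].parent == "p'borA5"
    assert registry["p'borD4"].kind == "translocation"
    assert registry["p'borA7"].kind == "simple pericentric"
    g = build_derivation_graph(registry.values())
    # every non-main sequence is attached via its annotation; no orphans
    assert g.graph["orphans"] == {}
    assert g.number_of_edges() == 33


def test_registry_breakpoint_rule_consistency(rng):
    """Annotated step counts respect the breakpoint rule on synthetic stand-ins:
    one reversal adds two breakpoints, three-step derivations need > 2."""
    anc, der, _ = generate_reversal_series(9, 3, seed=11, non_overlapping=True)
    assert breakpoint_count(anc, der) == 6
    assert reversal_steps(anc, der) == 3


def test_hypothetical_sequences_only_hypothetical_class():
    with pytest.raises(ValueError):
        BandingSequence(name="p'borA1", arm="A", seq_class="imaginary")
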