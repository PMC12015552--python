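"""Nei distances, distance matrices, neighbor joining, Newick/PHYLIP I/O."""

import io
import math

import dendropy
import numpy as np
import pytest

from cytopoly.distance_phylogeny import (
    DistanceMatrix,
    distance_matrix,
    nei_distance,
    neighbor_joining,
    read_phylip,
    within_between_means,
    write_newick,
    write_phylip,
)
from cytopoly.population_io import FrequencyTable


def one_locus(pop, *freqs):
    serials = {i + 1: f for i, f in enumerate(freqs) if f > 0}
    return FrequencyTable(pop, 10, {"A": serials})


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def test_nei_identical_tables_zero():
    t = one_locus("P1", 0.5, 0.5)
    assert nei_distance(t, one_locus("P2", 0.5, 0.5)) == 0.0


def test_nei_closed_form_single_locus():
    d = nei_distance(one_locus("P1", 1.0), one_locus("P2", 0.5, 0.5))
    assert d == pytest.approx(-math.log(0.5 / math.sqrt(0.5)), abs=1e-12)
    assert d == pytest.approx(0.34657, abs=1e-4)


def test_nei_disjoint_alleles_infinite():
    d = nei_distance(one_locus("P1", 1.0), one_locus("P2", 0.0, 1.0))
    assert math.isinf(d)


def test_nei_symmetry_and_multiple_loci():
    a = FrequencyTable("P1", 10, {"A": {1: 0.8, 2: 0.2}, "B": {1: 1.0}})
    b = FrequencyTable("P2", 10, {"A": {1: 0.3, 2: 0.7}, "B": {1: 1.0}})
    assert nei_distance(a, b) == pytest.approx(nei_distance(b, a))
    # hand-computed: Jab = .8*.3+.2*.7 + 1 = 1.38; Ja = .68+1; Jb = .58+1
    expected = -math.log(1.38 / math.sqrt(1.68 * 1.58))
    assert nei_distance(a, b) == pytest.approx(expected, abs=1e-12)


def test_alternative_metrics_basic_behavior():
    a = one_locus("P1", 1.0)
    b = one_locus("P2", 0.5, 0.5)
    per_locus = nei_distance(a, b, metric="nei_per_locus")
    chord = nei_distance(a, b, metric="cavalli_sforza")
    assert per_locus == pytest.approx(nei_distance(a, b))  # one locus: identical
    assert 0 < chord < 1
    assert nei_distance(a, a, metric="cavalli_sforza") == pytest.approx(0.0, abs=1e-8)


def test_distance_matrix_summary():
    tables = [
        one_locus("P1", 1.0),
        one_locus("P2", 1.0),
        one_locus("P3", 0.5, 0.5),
    ]
    dm = distance_matrix(tables)
    assert dm.get("P1", "P2") == 0.0
    assert dm.summary["min"] == 0.0
    assert dm.summary["min"] <= dm.summary["mean"] <= dm.summary["max"]
    assert np.allclose(dm.values, dm.values.T)
    assert np.all(np.diag(dm.values) == 0)


def test_distance_matrix_duplicate_population_is_zero_pair():
    tables = [one_locus("P1", 0.6, 0.4), one_locus("P2", 0.6, 0.4), one_locus("P3", 1.0)]
    dm = distance_matrix(tables)
    assert dm.get("P1", "P2") == 0.0


def test_within_between_partition():
    tables = [one_locus("P1", 1.0), one_locus("P2", 1.0), one_locus("P3", 0.2, 0.8)]
    dm = distance_matrix(tables)
    res = within_between_means(dm, {"P1": "r1", "P2": "r1", "P3": "r2"})
    assert res["within_mean"] < res["between_mean"]


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def rf_distance(newick_a, newick_b):
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


def test_three_leaf_closed_form():
    ids = ["A", "B", "C"]
    m = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
    tree = neighbor_joining(DistanceMatrix(ids, m))
    lengths = {child.name: length for child, length in tree.children}
    assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)


def test_four_leaf_additive_recovery():
    # tree ((A:1,B:2):1, C:1.5, D:2.5): additive distances
    ids = ["A", "B", "C", "D"]
    d = {
        ("A", "B"): 3.0,
        ("A", "C"): 3.5,
        ("A", "D"): 4.5,
        ("B", "C"): 4.5,
        ("B", "D"): 5.5,
        ("C", "D"): 4.0,
    }
    m = np.zeros((4, 4))
    for (a, b), v in d.items():
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = v
    tree = neighbor_joining(DistanceMatrix(ids, m))
    assert rf_distance(write_newick(tree), "((A:1,B:2):1,C:1.5,D:2.5);") == 0


def test_five_leaf_topology_matches_reference_implementation():
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj

    rng = np.random.default_rng(5)
    ids = list("ABCDE")
    m = np.zeros((5, 5))
    # random additive matrix from a fixed 5-leaf tree with random lengths
    bl = rng.uniform(0.2, 2.0, size=7)
    # topology ((A,B),(C,D),E) with internal edges bl[5], bl[6]
    d = {
        ("A", "B"): bl[0] + bl[1],
        ("C", "D"): bl[2] + bl[3],
        ("A", "C"): bl[0] + bl[5] + bl[6] + bl[2],
        ("A", "D"): bl[0] + bl[5] + bl[6] + bl[3],
        ("B", "C"): bl[1] + bl[5] + bl[6] + bl[2],
        ("B", "D"): bl[1] + bl[5] + bl[6] + bl[3],
        ("A", "E"): bl[0] + bl[5] + bl[4],
        ("B", "E"): bl[1] + bl[5] + bl[4],
        ("C", "E"): bl[2] + bl[6] + bl[4],
        ("D", "E"): bl[3] + bl[6] + bl[4],
    }
    for (a, b), v in d.items():
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = v
    ours = write_newick(neighbor_joining(DistanceMatrix(ids, m)))
    buf = io.StringIO()
    nj(SkDM(m, ids)).write(buf)
    assert rf_distance(ours, buf.getvalue()) == 0


def test_nj_requires_three_finite_leaves():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))
    m = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
    with pytest.raises(ValueError, match="non-finite"):
        neighbor_joining(DistanceMatrix(["A", "B", "C"], m))


def test_negative_branch_lengths_clamped_and_logged():
    # strongly non-additive matrix that induces a negative NJ estimate
    ids = list("ABCD")
    m = np.array(
        [
            [0.0, 1.0, 1.0, 1.0],
            [1.0, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 0.01],
            [1.0, 1.0, 0.01, 0.0],
        ]
    )
    log: list[str] = []
    tree = neighbor_joining(DistanceMatrix(ids, m), clamp_log=log)

    def all_lengths(node):
        out = []
        for child, length in node.children:
            out.append(length)
            out.extend(all_lengths(child))
        return out

    assert all(l >= 0 for l in all_lengths(tree))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_newick_round_trip_through_independent_parser(tmp_path):
    ids = ["P1", "P2", "P3", "P4"]
    m = np.array(
        [[0, 2.0, 3.0, 3.4], [2.0, 0, 3.2, 3.6], [3.0, 3.2, 0, 1.0], [3.4, 3.6, 1.0, 0]]
    )
    tree = neighbor_joining(DistanceMatrix(ids, m))
    path = tmp_path / "tree.nwk"
    write_newick(tree, path)
    parsed = dendropy.Tree.get(path=str(path), schema="newick")
    assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == ids
    assert parsed.length() == pytest.approx(
        sum_lengths(tree), abs=1e-9
    )


def sum_lengths(node):
    total = 0.0
    for child, length in node.children:
        total += length + sum_lengths(child)
    return total


def test_phylip_round_trip(tmp_path):
    ids = ["POPULATION-ONE", "P2", "P3"]  # first name truncated to 10 chars
    m = np.array([[0, 0.5, 0.25], [0.5, 0, 0.125], [0.25, 0.125, 0]])
    path = tmp_path / "dist.phylip"
    write_phylip(DistanceMatrix(ids, m), path)
    back = read_phylip(path)
    assert back.ids[0] == "POPULATION"
    assert np.allclose(back.values, m, atol=1e-6)


def test_phylip_duplicate_truncated_names_rejected(tmp_path):
    ids = ["POPULATION-ONE", "POPULATION-TWO", "P3"]
    m = np.zeros((3, 3))
    with pytest.raises(ValueError, match="truncation"):
        write_phylip(DistanceMatrix(ids, m), tmp_path / "d.phylip")
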