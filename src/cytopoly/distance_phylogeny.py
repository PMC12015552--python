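"""Cytogenetic distances between populations and neighbor-joining trees.

Populations are compared through their banding-sequence frequency tables,
treating each chromosomal arm as a locus and each banding sequence as an
allele.  The default metric is Nei's (1972) standard genetic distance

    D = -ln( J_ab / sqrt(J_a * J_b) )

with the gene identities J summed over all arms; the per-locus-averaged Nei
distance and the Cavalli-Sforza & Edwards chord distance are available as
alternatives.  Trees are built with the Saitou-Nei neighbor-joining
algorithm (standard Q-criterion, lexicographic tie-breaking, exact on
additive matrices) and serialized as Newick; distance matrices are written
in the square PHYLIP format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .population_io import FrequencyTable

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "nei_distance",
    "distance_matrix",
    "neighbor_joining",
    "write_newick",
    "write_phylip",
    "read_phylip",
]

METRICS = ("nei_standard", "nei_per_locus", "cavalli_sforza")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _arm_vectors(fa: FrequencyTable, fb: FrequencyTable, arm: str):
    serials = sorted(set(fa.serials(arm)) | set(fb.serials(arm)))
    pa = np.array([fa.frequency(arm, s) for s in serials])
    pb = np.array([fb.frequency(arm, s) for s in serials])
    return pa, pb


def nei_distance(fa: FrequencyTable, fb: FrequencyTable, metric: str = "nei_standard") -> float:
    """Genetic distance between two populations over arms-as-loci.

    Returns ``math.inf`` (flagged degenerate case, no smoothing applied)
    when the cross-population identity is zero under the Nei metrics.
    """
    arms = sorted(set(fa.freqs) & set(fb.freqs))
    if not arms:
        raise ValueError(
            f"no shared arms between {fa.population} and {fb.population}"
        )
    if metric == "nei_standard":
        jab = ja = jb = 0.0
        for arm in arms:
            pa, pb = _arm_vectors(fa, fb, arm)
            jab += float(pa @ pb)
            ja += float(pa @ pa)
            jb += float(pb @ pb)
        if jab == 0.0:
            return math.inf
        return max(0.0, -math.log(jab / math.sqrt(ja * jb)))
    if metric == "nei_per_locus":
        total = 0.0
        for arm in arms:
            pa, pb = _arm_vectors(fa, fb, arm)
            jab = float(pa @ pb)
            if jab == 0.0:
                return math.inf
            total += -math.log(jab / math.sqrt(float(pa @ pa) * float(pb @ pb)))
        return max(0.0, total / len(arms))
    if metric == "cavalli_sforza":
        total = 0.0
        for arm in arms:
            pa, pb = _arm_vectors(fa, fb, arm)
            cos_theta = min(1.0, float(np.sqrt(pa * pb).sum()))
            total += (2.0 / math.pi) * math.sqrt(2.0 * (1.0 - cos_theta))
        return total / len(arms)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("diagonal must be exactly 0")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T], atol=1e-12):
            raise ValueError("matrix must be symmetric")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def distance_matrix(
    tables: Sequence[FrequencyTable], metric: str = "nei_standard"
) -> DistanceMatrix:
    """Pairwise distance matrix plus summary (min/max/mean +/- SE over
    unordered off-diagonal pairs; infinite pairs counted separately)."""
    if len(tables) < 2:
        raise ValueError("need at least 2 populations for a distance matrix")
    ids = [t.population for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate population ids")
    k = len(tables)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = nei_distance(tables[i], tables[j], metric=metric)
    pairs = m[np.triu_indices(k, 1)]
    finite = pairs[np.isfinite(pairs)]
    sd = float(finite.std(ddof=1)) if len(finite) > 1 else 0.0
    summary = {
        "n_pairs": int(len(pairs)),
        "n_infinite": int(np.sum(~np.isfinite(pairs))),
        "min": float(finite.min()),
        "max": float(finite.max()),
        "mean": float(finite.mean()),
        "se": sd / math.sqrt(len(finite)),
        "sd": sd,
        "metric": metric,
    }
    return DistanceMatrix(ids, m, summary)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of an (unrooted) tree, stored rooted at the final NJ join."""

    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, digits: int = 10) -> str:
        return f"{self._newick(digits)};"

    def _newick(self, digits: int) -> str:
        if not self.children:
            return self.name
        inner = ",".join(
            f"{child._newick(digits)}:{length:.{digits}g}"
            for child, length in self.children
        )
        return f"({inner}){self.name}"


def neighbor_joining(dm: DistanceMatrix, clamp_log: list[str] | None = None) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Q(i,j) = (r-2) d(i,j) - R(i) - R(j) is minimized at each step; ties are
    broken by the lexicographic order of the smallest leaf labels under the
    two nodes.  Negative branch-length estimates are clamped to 0 (logged).
    Exact on additive matrices.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs >= 3 leaves")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("non-finite distances; resolve infinite pairs first")

    def clamp(x: float, context: str) -> float:
        if x < 0:
            if clamp_log is not None:
                clamp_log.append(f"clamped negative branch length {x:.3g} at {context}")
            return 0.0
        return x

    nodes: dict[str, TreeNode] = {name: TreeNode(name) for name in dm.ids}
    # sort key of a node = smallest leaf label beneath it
    keys: dict[str, str] = {name: name for name in dm.ids}
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(dm.ids):
        for j, b in enumerate(dm.ids):
            if i != j:
                d[(a, b)] = float(dm.values[i, j])
    active = list(dm.ids)
    counter = 0
    while len(active) > 3:
        r = len(active)
        row_sums = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                a, b = active[ai], active[bi]
                q = (r - 2) * d[(a, b)] - row_sums[a] - row_sums[b]
                tie = tuple(sorted((keys[a], keys[b])))
                cand = (q, tie, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        la = 0.5 * d[(a, b)] + (row_sums[a] - row_sums[b]) / (2 * (r - 2))
        lb = d[(a, b)] - la
        la, lb = clamp(la, f"{a}"), clamp(lb, f"{b}")
        counter += 1
        u = f"__nj{counter}"
        nodes[u] = TreeNode("", [(nodes[a], la), (nodes[b], lb)])
        keys[u] = min(keys[a], keys[b])
        for c in active:
            if c in (a, b):
                continue
            d[(u, c)] = d[(c, u)] = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
        active = [c for c in active if c not in (a, b)] + [u]
    a, b, c = sorted(active, key=lambda x: keys[x])
    la = clamp(0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)]), a)
    lb = clamp(0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)]), b)
    lc = clamp(0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)]), c)
    return TreeNode("", [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_newick(tree: TreeNode, path=None) -> str:
    text = tree.newick()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP distance format; taxon names truncated/padded to 10 chars."""
    short = [name[:10] for name in dm.ids]
    if len(set(short)) != len(short):
        raise ValueError("duplicate taxon names after truncation to 10 characters")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(dm.ids):5d}\n")
        for name, row in zip(short, dm.values):
            cells = " ".join(f"{x:.6f}" for x in row)
            fh.write(f"{name:<10s} {cells}\n")


def read_phylip(path) -> DistanceMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    n = int(lines[0])
    ids, rows = [], []
    for line in lines[1 : n + 1]:
        name, values = line[:10].strip(), line[10:].split()
        ids.append(name)
        rows.append([float(v) for v in values])
    return DistanceMatrix(ids, np.array(rows))


def within_between_means(dm: DistanceMatrix, regions: dict[str, str]) -> dict:
    """Mean distance within vs between region groups (structure check)."""
    within, between = [], []
    for i, a in enumerate(dm.ids):
        for j in range(i + 1, len(dm.ids)):
            b = dm.ids[j]
            (within if regions.get(a) == regions.get(b) else between).append(
                dm.values[i, j]
            )
    return {
        "within_mean": float(np.mean(within)) if within else math.nan,
        "between_mean": float(np.mean(between)) if between else math.nan,
    }
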