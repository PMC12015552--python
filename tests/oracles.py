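"""Independent brute-force oracles used only by the test suite.

Each oracle reimplements a quantity from first principles (exhaustive
enumeration, exact rational arithmetic, iterative-deepening search) without
touching the package's own algorithms, so that implementation and oracle
can disagree.
"""

from fractions import Fraction
from math import factorial


# ---------------------------------------------------------------------------
# signed-permutation rearrangement oracles (reflection treated as identity)
# ---------------------------------------------------------------------------


def reflect(perm):
    return tuple(-v for v in reversed(perm))


def all_reversals(perm):
    n = len(perm)
    for i in range(n):
        for j in range(i, n):
            yield perm[:i] + tuple(-v for v in reversed(perm[i : j + 1])) + perm[j + 1 :]


def is_identity(perm):
    ident = tuple(range(1, len(perm) + 1))
    return perm == ident or reflect(perm) == ident


def breakpoints_oracle(perm):
    """Adjacency-set scan: an adjacency (x, y) of ``perm`` (caps L/R added)
    is conserved when the identity contains (x, y) or its reverse-negated
    reading (-y, -x), with negation swapping the caps; everything else is a
    breakpoint."""
    n = len(perm)

    def adjacencies(seq):
        ext = ("L", *seq, "R")
        return list(zip(ext, ext[1:]))

    def negate(x):
        return {"L": "R", "R": "L"}.get(x, None) if isinstance(x, str) else -x

    ident_adj = set(adjacencies(tuple(range(1, n + 1))))
    broken = 0
    for x, y in adjacencies(perm):
        if (x, y) in ident_adj or (negate(y), negate(x)) in ident_adj:
            continue
        broken += 1
    return broken


def iddfs_reversal_distance(perm, max_depth=10):
    """Iterative-deepening DFS to the identity (or its reflection)."""
    if is_identity(perm):
        return 0

    def dfs(p, depth):
        if depth == 0:
            return is_identity(p)
        return any(dfs(q, depth - 1) for q in all_reversals(p))

    for d in range(1, max_depth + 1):
        if dfs(perm, d):
            return d
    raise RuntimeError(f"no sorting found within {max_depth} reversals")


def canon(perm):
    r = reflect(perm)
    return perm if perm <= r else r


def shortest_path_intermediates(perm, distance):
    """All states (canonical forms) interior to at least one minimal
    reversal path from ``perm`` to the identity, by exhaustive path
    enumeration at the known distance."""
    out = set()

    def walk(p, remaining, visited):
        if remaining == 0:
            if is_identity(p):
                out.update(visited)
            return
        for q in all_reversals(p):
            # prune: a state still needs `remaining - 1` steps after q
            try:
                reachable = iddfs_reversal_distance(q, max_depth=remaining - 1) <= remaining - 1
            except RuntimeError:
                reachable = False
            if reachable:
                walk(q, remaining - 1, visited + [canon(q)])

    walk(perm, distance, [])
    out.discard(canon(perm))
    out.discard(canon(tuple(range(1, len(perm) + 1))))
    return out


# ---------------------------------------------------------------------------
# exact-test oracles (rational arithmetic)
# ---------------------------------------------------------------------------


def hw_exact_p_oracle(n11, n12, n22, mid_p=False):
    """Exact conditional Hardy-Weinberg p-value for two alleles by full
    enumeration of the Levene distribution in exact rationals."""
    n1 = 2 * n11 + n12
    n2 = 2 * n22 + n12
    n = n11 + n12 + n22

    def prob(h):
        a, b = (n1 - h) // 2, (n2 - h) // 2
        return Fraction(
            factorial(n) * 2**h * factorial(n1) * factorial(n2),
            factorial(a) * factorial(h) * factorial(b) * factorial(2 * n),
        )

    support = list(range(n1 % 2, min(n1, n2) + 1, 2))
    probs = {h: prob(h) for h in support}
    p_obs = probs[n12]
    total = sum(probs.values())
    if mid_p:
        acc = sum(p for h, p in probs.items() if p < p_obs) + Fraction(1, 2) * sum(
            p for h, p in probs.items() if p == p_obs
        )
    else:
        acc = sum(p for h, p in probs.items() if p <= p_obs)
    return float(acc / total)


def fisher_2x2_p_oracle(a, b, c, d):
    """Two-sided Fisher exact p for a 2x2 table by hypergeometric tail
    summation in exact rationals (sum of tables no more probable than
    the observed one, margins fixed)."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > row2:
            return Fraction(0)
        return Fraction(
            factorial(row1) * factorial(row2) * factorial(col1) * factorial(n - col1),
            factorial(n)
            * factorial(x)
            * factorial(row1 - x)
            * factorial(col1 - x)
            * factorial(row2 - col1 + x),
        )

    p_obs = prob(a)
    total = Fraction(0)
    acc = Fraction(0)
    for x in range(0, min(row1, col1) + 1):
        p = prob(x)
        total += p
        if p <= p_obs:
            acc += p
    return float(acc / total)


# ---------------------------------------------------------------------------
# random additive trees (for neighbor-joining recovery checks)
# ---------------------------------------------------------------------------


def random_additive_tree(rng, n_leaves, min_bl=0.1, max_bl=1.0):
    """Random binary tree by sequential random joins with strictly positive
    branch lengths; returns (newick, leaf names, additive distance matrix
    rows as dict of frozenset pairs)."""
    names = [f"T{i}" for i in range(n_leaves)]
    subs = [(name, {name: 0.0}) for name in names]
    dists = {}
    while len(subs) > 1:
        j, i = sorted(rng.choice(len(subs), 2, replace=False), reverse=True)
        nwk_a, da = subs.pop(j)
        nwk_b, db = subs.pop(i)
        ea, eb = rng.uniform(min_bl, max_bl, 2)
        for la, xa in da.items():
            for lb, xb in db.items():
                dists[frozenset((la, lb))] = xa + ea + xb + eb
        merged_depths = {l: x + ea for l, x in da.items()}
        merged_depths.update({l: x + eb for l, x in db.items()})
        subs.append((f"({nwk_a}:{ea:.6f},{nwk_b}:{eb:.6f})", merged_depths))
    return subs[0][0] + ";", names, dists
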