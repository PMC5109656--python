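"""Independent oracles used by the test suite.

These deliberately avoid the package's own DP/recurrence implementations:
the alignment oracle scores alignments by direct recursion over edit paths,
and the UPGMA oracle recomputes every cluster-average distance from the
original matrix at each step.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")

GAP_OPEN = 11
GAP_EXT = 1


def sub_score(x: str, y: str) -> int:
    if x == "X" or y == "X":
        return 0
    return int(_BLOSUM[x][y])


def best_score_recursive(a: str, b: str) -> int:
    """Optimal global alignment score by memoized recursion over edit paths
    (gap of length k costs GAP_OPEN + k*GAP_EXT, end gaps included)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: str) -> int:
        if i == len(a) and j == len(b):
            return 0
        cands = []
        if i < len(a) and j < len(b):
            cands.append(sub_score(a[i], b[j]) + best(i + 1, j + 1, "M"))
        if i < len(a):
            gap = -GAP_EXT if last == "U" else -(GAP_OPEN + GAP_EXT)
            cands.append(gap + best(i + 1, j, "U"))
        if j < len(b):
            gap = -GAP_EXT if last == "L" else -(GAP_OPEN + GAP_EXT)
            cands.append(gap + best(i, j + 1, "L"))
        return max(cands)

    return best(0, 0, "S")


def enumerate_alignments(a: str, b: str):
    """Yield (score, identity_pct) for every global alignment (small inputs)."""
    n, m = len(a), len(b)

    def rec(i, j, last, score, matches, cols):
        if i == n and j == m:
            yield score, 100.0 * matches / cols if cols else 0.0
            return
        if i < n and j < m:
            yield from rec(
                i + 1, j + 1, "M",
                score + sub_score(a[i], b[j]),
                matches + (1 if a[i] == b[j] else 0),
                cols + 1,
            )
        if i < n:
            gap = -GAP_EXT if last == "U" else -(GAP_OPEN + GAP_EXT)
            yield from rec(i + 1, j, "U", score + gap, matches, cols + 1)
        if j < m:
            gap = -GAP_EXT if last == "L" else -(GAP_OPEN + GAP_EXT)
            yield from rec(i, j + 1, "L", score + gap, matches, cols + 1)

    yield from rec(0, 0, "S", 0, 0, 0)


def rescore_alignment(aligned_a: str, aligned_b: str) -> tuple[int, float]:
    """Independent rescoring of a gapped alignment: (score, identity_pct)."""
    score = 0
    matches = 0
    last = "S"
    for x, y in zip(aligned_a, aligned_b, strict=True):
        if x == "-" and y == "-":
            raise ValueError("double gap column")
        if x == "-":
            score += -GAP_EXT if last == "L" else -(GAP_OPEN + GAP_EXT)
            last = "L"
        elif y == "-":
            score += -GAP_EXT if last == "U" else -(GAP_OPEN + GAP_EXT)
            last = "U"
        else:
            score += sub_score(x.upper(), y.upper())
            if x.upper() == y.upper():
                matches += 1
            last = "M"
    return score, 100.0 * matches / len(aligned_a)


def brute_force_upgma(names: list[str], dist) -> tuple:
    """UPGMA recomputing all cluster averages from the original matrix at
    each step. Returns a nested tuple tree: leaf = name, internal =
    (left, right, height). Mirrors the tie-break (first minimal pair in the
    current cluster list, merged cluster appended at the end)."""
    n = len(names)
    idx = {nm: i for i, nm in enumerate(names)}
    clusters = [frozenset([nm]) for nm in names]
    trees: list = list(names)

    def avg(c1: frozenset, c2: frozenset) -> float:
        total = sum(dist[idx[x]][idx[y]] for x in c1 for y in c2)
        return total / (len(c1) * len(c2))

    while len(clusters) > 1:
        best = None
        bi = bj = -1
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = avg(clusters[i], clusters[j])
                if best is None or d < best:
                    best, bi, bj = d, i, j
        merged = clusters[bi] | clusters[bj]

        def min_leaf(t):
            return t if isinstance(t, str) else min(min_leaf(t[0]), min_leaf(t[1]))

        left, right = sorted((trees[bi], trees[bj]), key=min_leaf)
        tree = (left, right, best / 2.0)
        keep = [t for t in range(len(clusters)) if t not in (bi, bj)]
        clusters = [clusters[t] for t in keep] + [merged]
        trees = [trees[t] for t in keep] + [tree]
    return trees[0]


def node_to_tuple(node) -> tuple | str:
    """Convert an UpgmaNode into the oracle's nested-tuple form."""
    if node.is_leaf:
        return node.name
    left, right = node.children
    return (node_to_tuple(left), node_to_tuple(right), node.height)


def trees_equal(t1, t2, tol: float = 1e-9) -> bool:
    if isinstance(t1, str) or isinstance(t2, str):
        return t1 == t2
    return (
        abs(t1[2] - t2[2]) <= tol
        and trees_equal(t1[0], t2[0], tol)
        and trees_equal(t1[1], t2[1], tol)
    )


def random_protein_pair(rng, max_len: int = 8) -> tuple[str, str]:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    la = int(rng.integers(1, max_len + 1))
    lb = int(rng.integers(1, max_len + 1))
    a = "".join(aa[i] for i in rng.integers(0, 20, la))
    b = "".join(aa[i] for i in rng.integers(0, 20, lb))
    return a, b
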