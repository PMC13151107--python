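"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity from its definition (exact
rational arithmetic, full re-summation at every rank, pair enumeration)
rather than reusing any incremental code path from the package.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations


def brute_force_es(genes, impacts, members, score_type="pos",
                   p_hit_denom="total"):
    """O(N * N_S) enrichment score by re-summing P_Hit and P_Miss from
    scratch at every rank, in exact rationals."""
    members = set(members)
    n = len(genes)
    n_s = sum(1 for g in genes if g in members)
    assert 1 <= n_s < n
    impacts = [Fraction(x).limit_denominator(10**12) if not isinstance(x, Fraction)
               else x for x in impacts]
    if p_hit_denom == "total":
        total = sum(impacts)
    else:
        total = sum(impacts[j] for j, g in enumerate(genes) if g in members)
    if total == 0:  # all-zero members under "set": P_Hit identically 0
        impacts = [Fraction(0)] * n
        total = Fraction(1)
    assert total > 0
    devs = []
    for i in range(1, n + 1):
        p_hit = sum(impacts[j] for j in range(i) if genes[j] in members) / total
        n_miss = sum(1 for j in range(i) if genes[j] not in members)
        p_miss = Fraction(n_miss, n - n_s)
        devs.append(p_hit - p_miss)
    if score_type == "pos":
        return float(max(max(devs), Fraction(0)))
    return float(max(abs(d) for d in devs))


def brute_force_convergence(matrix_rows, genes, members):
    """C(S) by enumerating every sample pair and member gene.

    ``matrix_rows`` is a list of per-sample 0/1 lists aligned to ``genes``.
    """
    members = set(members)
    cols = [j for j, g in enumerate(genes) if g in members]
    count = 0
    for a, b in combinations(range(len(matrix_rows)), 2):
        for j in cols:
            if matrix_rows[a][j] and matrix_rows[b][j]:
                count += 1
    return count


def brute_force_bh(pvals):
    """Step-up BH from the definition: padj_(i) = min_{j >= i} m*p_(j)/j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    out = [0.0] * m
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [m * pvals[order[j - 1]] / j for j in range(rank_pos, m + 1)]
        out[idx] = min(1.0, min(candidates))
    return out


def significant_to_root_nodes(edges, significant, root):
    """All nodes on any directed path from a significant node to the root,
    by exhaustive simple-path enumeration over a child->parent edge list."""
    from itertools import chain

    adj = {}
    for child, parent in edges:
        adj.setdefault(child, set()).add(parent)

    def simple_paths(node, target, seen):
        if node == target:
            yield [node]
            return
        for nxt in adj.get(node, ()):  # noqa: B023
            if nxt not in seen:
                yield from ([node] + rest
                            for rest in simple_paths(nxt, target, seen | {nxt}))

    keep = set(significant) | {root}
    for s in significant:
        for path in simple_paths(s, root, {s}):
            keep.update(path)
    return keep
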