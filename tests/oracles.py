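"""Independent brute-force oracles used by the test suite.

Deliberately naive re-implementations (nested loops, exhaustive enumeration)
kept separate from the package code paths they validate.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


# --- semantic similarity ----------------------------------------------------


def naive_ancestors(dag, term) -> set[str]:
    """Ancestor-or-self closure by repeated edge following."""
    out = {term}
    frontier = [term]
    while frontier:
        node = frontier.pop()
        for _, parent in dag.out_edges(node):
            if parent not in out:
                out.add(parent)
                frontier.append(parent)
    return out


def naive_term_sim(t1, t2, dag, ic) -> float:
    """Lin similarity with the MICA found by exhaustive common-ancestor search."""
    common = naive_ancestors(dag, t1) & naive_ancestors(dag, t2)
    mica = max((ic.get(a, 0.0) for a in common), default=0.0)
    denom = ic[t1] + ic[t2]
    if denom == 0:
        return 1.0 if t1 == t2 else 0.0
    return 2.0 * mica / denom


def naive_gene_its(terms1, terms2, dag, ic) -> float:
    t1 = sorted(terms1)
    t2 = sorted(terms2)
    if not t1 or not t2:
        return float("nan")
    fwd = sum(max(naive_term_sim(a, b, dag, ic) for b in t2) for a in t1)
    rev = sum(max(naive_term_sim(a, b, dag, ic) for a in t1) for b in t2)
    return (fwd + rev) / (len(t1) + len(t2))


def naive_snp_its(genes1, genes2, gene_sim) -> float:
    """Direct transcription of the pair-similarity formula.

    ``gene_sim(gi, gj)`` supplies gene-level similarities; gene sets are
    assumed pre-filtered to annotated genes.
    """
    g1 = sorted(genes1)
    g2 = sorted(genes2)
    if not g1 or not g2:
        return float("nan")
    total = 0.0
    for gi in g1:
        best = max(gene_sim(gi, gj) for gj in g2)
        total += best
    for gj in g2:
        best = max(gene_sim(gi, gj) for gi in g1)
        total += best
    return total / (len(g1) + len(g2))


# --- fixed-margin bipartite enumeration ------------------------------------


def enumerate_fixed_margin_matrices(row_sums, col_sums):
    """All 0/1 matrices with the given row and column sums (small inputs)."""
    n_rows = len(row_sums)
    n_cols = len(col_sums)

    def rec(row, remaining_cols, acc):
        if row == n_rows:
            if all(c == 0 for c in remaining_cols):
                yield np.array(acc, dtype=np.int64)
            return
        k = row_sums[row]
        for cols in itertools.combinations(range(n_cols), k):
            if any(remaining_cols[c] == 0 for c in cols):
                continue
            new_remaining = list(remaining_cols)
            r = [0] * n_cols
            for c in cols:
                new_remaining[c] -= 1
                r[c] = 1
            yield from rec(row + 1, new_remaining, acc + [r])

    yield from rec(0, list(col_sums), [])


# --- Fisher / BH -------------------------------------------------------------


def exact_fisher_greater(table) -> Fraction:
    """One-sided hypergeometric tail by exhaustive enumeration (exact rational)."""
    a, b = table[0]
    c, d = table[1]
    r1 = a + b
    c1 = a + c
    n = a + b + c + d
    denom = comb(n, c1)
    k_min = max(0, c1 - (n - r1))
    k_max = min(r1, c1)
    total = sum(
        comb(r1, k) * comb(n - r1, c1 - k) for k in range(a, k_max + 1) if k >= k_min
    )
    return Fraction(total, denom)


def naive_bh(pvalues) -> np.ndarray:
    """BH step-up q-values straight from the definition."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        q[idx] = running
    return q


# --- entropy -----------------------------------------------------------------


def entropy_bits(counts) -> float:
    counts = np.asarray(counts, dtype=float).ravel()
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def naive_interaction_information(table_3x3x2) -> float:
    """IG from a 3x3x2 count table by direct entropy arithmetic."""
    t = np.asarray(table_3x3x2, dtype=float)
    h_y = entropy_bits(t.sum(axis=(0, 1)))
    h_g1 = entropy_bits(t.sum(axis=(1, 2)))
    h_g2 = entropy_bits(t.sum(axis=(0, 2)))
    h_g1g2 = entropy_bits(t.sum(axis=2))
    h_g1y = entropy_bits(t.sum(axis=1))
    h_g2y = entropy_bits(t.sum(axis=0))
    h_all = entropy_bits(t)
    i_joint = h_g1g2 + h_y - h_all
    i_1 = h_g1 + h_y - h_g1y
    i_2 = h_g2 + h_y - h_g2y
    return i_joint - i_1 - i_2
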