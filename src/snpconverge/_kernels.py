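"""Numba kernels for the permutation null and best-match-average similarity.

These are performance back-ends only: the public single-pair API
(`similarity.snp_its`, `similarity.gene_its`, `permutation.permute_network`)
has pure-Python reference implementations, and the test suite asserts the two
code paths agree to 1e-12.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "swap_chain",
    "fill_sorted_adjacency",
    "all_pairs_bma",
    "pair_statistics",
]


@njit(cache=True)
def swap_chain(edge_snp, edge_mrna, adj, pick_a, pick_b):
    """Run one checkerboard-swap chain segment on a bipartite edge list.

    ``edge_snp``/``edge_mrna`` are parallel int arrays (one entry per edge);
    ``adj`` is a dense boolean SNP x mRNA membership matrix kept in sync.
    ``pick_a``/``pick_b`` hold pre-drawn edge indices, one proposal per entry.
    A proposal (s1,m1),(s2,m2) -> (s1,m2),(s2,m1) is rejected (chain stays)
    whenever it would duplicate an existing edge; rejected moves still count
    as attempts, which keeps the chain's stationary distribution uniform over
    the fixed-margin edge sets.

    Returns the number of accepted swaps.
    """
    accepted = 0
    for t in range(pick_a.size):
        i = pick_a[t]
        j = pick_b[t]
        if i == j:
            continue
        s1 = edge_snp[i]
        m1 = edge_mrna[i]
        s2 = edge_snp[j]
        m2 = edge_mrna[j]
        if s1 == s2 or m1 == m2:
            continue
        if adj[s1, m2] or adj[s2, m1]:
            continue
        adj[s1, m1] = False
        adj[s2, m2] = False
        adj[s1, m2] = True
        adj[s2, m1] = True
        edge_mrna[i] = m2
        edge_mrna[j] = m1
        accepted += 1
    return accepted


@njit(cache=True)
def fill_sorted_adjacency(edge_snp, edge_mrna, offsets, out, cursor):
    """Scatter the edge list into a CSR layout of per-SNP sorted gene indices.

    ``offsets`` (len n_snps+1) is fixed across permutations because node
    degrees are conserved. ``cursor`` is scratch of len n_snps.
    """
    n = offsets.size - 1
    for s in range(n):
        cursor[s] = offsets[s]
    for e in range(edge_snp.size):
        s = edge_snp[e]
        out[cursor[s]] = edge_mrna[e]
        cursor[s] += 1
    # insertion sort per slice; degrees are small under heavy-tailed truncation
    for s in range(n):
        lo = offsets[s]
        hi = offsets[s + 1]
        for i in range(lo + 1, hi):
            v = out[i]
            j = i - 1
            while j >= lo and out[j] > v:
                out[j + 1] = out[j]
                j -= 1
            out[j + 1] = v


@njit(cache=True)
def _bma(items, ai, aj, bi, bj, sim):
    """Best-match average of sim[x, y] over two index slices (no filtering)."""
    total = 0.0
    for u in range(ai, aj):
        best = 0.0
        for v in range(bi, bj):
            s = sim[items[u], items[v]]
            if s > best:
                best = s
        total += best
    for v in range(bi, bj):
        best = 0.0
        for u in range(ai, aj):
            s = sim[items[u], items[v]]
            if s > best:
                best = s
        total += best
    return total / ((aj - ai) + (bj - bi))


@njit(cache=True)
def all_pairs_bma(offsets, items, sim):
    """Symmetric all-pairs best-match-average matrix.

    Entry (i, j) is the BMA similarity of item sets i and j under the base
    similarity matrix ``sim``; rows with empty sets yield NaN.
    """
    n = offsets.size - 1
    out = np.empty((n, n), dtype=np.float64)
    for i in range(n):
        ai = offsets[i]
        aj = offsets[i + 1]
        for j in range(i, n):
            bi = offsets[j]
            bj = offsets[j + 1]
            if aj == ai or bj == bi:
                v = np.nan
            else:
                v = _bma(items, ai, aj, bi, bj, sim)
            out[i, j] = v
            out[j, i] = v
    return out


@njit(cache=True)
def _bma_filtered(genes, ai, aj, bi, bj, sim, annotated):
    """BMA over two gene slices restricted to annotated genes; NaN if a side
    has no annotated gene."""
    na = 0
    nb = 0
    for u in range(ai, aj):
        if annotated[genes[u]]:
            na += 1
    for v in range(bi, bj):
        if annotated[genes[v]]:
            nb += 1
    if na == 0 or nb == 0:
        return np.nan
    total = 0.0
    for u in range(ai, aj):
        gu = genes[u]
        if not annotated[gu]:
            continue
        best = 0.0
        for v in range(bi, bj):
            gv = genes[v]
            if not annotated[gv]:
                continue
            s = sim[gu, gv]
            if s > best:
                best = s
        total += best
    for v in range(bi, bj):
        gv = genes[v]
        if not annotated[gv]:
            continue
        best = 0.0
        for u in range(ai, aj):
            gu = genes[u]
            if not annotated[gu]:
                continue
            s = sim[gu, gv]
            if s > best:
                best = s
        total += best
    return total / (na + nb)


@njit(cache=True)
def pair_statistics(
    offsets,
    genes,
    pair_a,
    pair_b,
    sim_mf,
    ann_mf,
    sim_bp,
    ann_bp,
    do_overlap,
    do_mf,
    do_bp,
    out_overlap,
    out_mf,
    out_bp,
):
    """Per-pair mRNA overlap and GO-MF/GO-BP BMA similarity on one network.

    ``offsets``/``genes`` is the CSR layout from :func:`fill_sorted_adjacency`
    (gene indices sorted within each SNP slice, enabling the two-pointer
    intersection). Pair statistics with no annotated genes on one side are
    NaN (undefined, not zero).
    """
    for p in range(pair_a.size):
        a = pair_a[p]
        b = pair_b[p]
        ai = offsets[a]
        aj = offsets[a + 1]
        bi = offsets[b]
        bj = offsets[b + 1]
        if do_overlap:
            c = 0
            u = ai
            v = bi
            while u < aj and v < bj:
                gu = genes[u]
                gv = genes[v]
                if gu == gv:
                    c += 1
                    u += 1
                    v += 1
                elif gu < gv:
                    u += 1
                else:
                    v += 1
            out_overlap[p] = c
        if do_mf:
            out_mf[p] = _bma_filtered(genes, ai, aj, bi, bj, sim_mf, ann_mf)
        if do_bp:
            out_bp[p] = _bma_filtered(genes, ai, aj, bi, bj, sim_bp, ann_bp)
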