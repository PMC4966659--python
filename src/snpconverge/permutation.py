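"""Degree-conserving permutation null, empirical p-values, FDR, prioritisation.

The null preserves every SNP node degree and every mRNA node degree exactly
by rewiring the bipartite SNP-mRNA network with checkerboard (double-edge)
swaps; all candidate pairs are evaluated on the *same* permuted network at
each iteration, so the null also respects the observed degree heterogeneity
of hub mRNAs. Samples are taken sequentially along one swap chain (Q*E
attempted swaps apart, after a burn-in of ``burn_in_mult``*E swaps) rather
than restarting per sample; mixing is validated against exhaustive
enumeration of fixed-margin edge sets in the test suite.

Empirical p-values count permutations with *equal or greater* statistic than
observed. Two conventions are supported:

- ``p_mode="raw"`` (default): p = x / N, the plain proportion. This can be 0
  for signals never reached by the null, which is what lets strong planted
  or real signals survive BH correction over millions of pairs.
- ``p_mode="add_one"``: p = (1 + x) / (1 + N), never 0 and never above 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from snpconverge import _kernels
from snpconverge.errors import DegreeConservationError
from snpconverge.io import EqtlNetwork
from snpconverge.pairing import SnpPair
from snpconverge.similarity import (
    OntologyCorpus,
    PairScore,
    gene_similarity_matrix,
    mrna_overlap,
)

logger = logging.getLogger(__name__)

STATISTICS = ("overlap", "mf", "bp")
TIE_EPS = 1e-9  # float guard for the "equal or greater" tie rule


class DegreeConservingSampler:
    """Sequential sampler over degree-preserving rewirings of an eQTL network.

    Every draw advances the chain by ``q_mult * n_edges`` attempted swaps and
    re-asserts exact degree conservation (hard failure otherwise).
    """

    def __init__(
        self,
        eqtl: EqtlNetwork,
        rng: np.random.Generator,
        q_mult: int = 10,
        burn_in_mult: int = 20,
    ):
        self.n_snps = len(eqtl.snp_ids)
        self.n_mrnas = len(eqtl.mrna_ids)
        self.edge_snp = eqtl.edge_snp.copy()
        self.edge_mrna = eqtl.edge_mrna.copy()
        self.rng = rng
        self.q_mult = q_mult
        self._snp_deg = np.bincount(self.edge_snp, minlength=self.n_snps)
        self._mrna_deg = np.bincount(self.edge_mrna, minlength=self.n_mrnas)
        self.adj = np.zeros((self.n_snps, self.n_mrnas), dtype=bool)
        self.adj[self.edge_snp, self.edge_mrna] = True
        self.swappable = self._has_valid_swap()
        if not self.swappable:
            logger.warning(
                "network admits no degree-preserving swap (complete bipartite "
                "or trivially small); permutations return the input unchanged"
            )
        elif burn_in_mult > 0:
            self._advance(burn_in_mult * self.edge_snp.size)

    def _has_valid_swap(self) -> bool:
        e = self.edge_snp.size
        if e < 2:
            return False
        if e == self.n_snps * self.n_mrnas:  # complete bipartite graph
            return False
        return True

    def _advance(self, n_attempts: int) -> None:
        picks = self.rng.integers(0, self.edge_snp.size, size=(2, n_attempts))
        _kernels.swap_chain(
            self.edge_snp, self.edge_mrna, self.adj, picks[0], picks[1]
        )

    def draw(self) -> tuple[np.ndarray, np.ndarray]:
        """Advance the chain one sample and return the (snp, mrna) edge arrays."""
        if self.swappable:
            self._advance(self.q_mult * self.edge_snp.size)
        self.assert_degrees()
        return self.edge_snp, self.edge_mrna

    def assert_degrees(self) -> None:
        snp_deg = np.bincount(self.edge_snp, minlength=self.n_snps)
        mrna_deg = np.bincount(self.edge_mrna, minlength=self.n_mrnas)
        if not (
            np.array_equal(snp_deg, self._snp_deg)
            and np.array_equal(mrna_deg, self._mrna_deg)
        ):
            raise DegreeConservationError(
                "permutation sample failed exact degree conservation"
            )


def permute_network(
    eqtl: EqtlNetwork, rng: np.random.Generator, q_mult: int = 10
) -> EqtlNetwork:
    """One degree-preserving rewiring of ``eqtl`` (Q*E attempted swaps).

    Networks admitting no valid swap (complete bipartite, < 2 edges) are
    returned unchanged with a warning.
    """
    sampler = DegreeConservingSampler(eqtl, rng, q_mult=q_mult, burn_in_mult=0)
    edge_snp, edge_mrna = sampler.draw()
    edges = eqtl.edges.copy()
    edges["rsid"] = [eqtl.snp_ids[i] for i in edge_snp]
    edges["mrna_id"] = [eqtl.mrna_ids[i] for i in edge_mrna]
    return EqtlNetwork(
        edges[["rsid", "mrna_id", "p_value"]], p_cutoff=eqtl.p_cutoff
    )


@dataclass
class NullEnsemble:
    """Bookkeeping for one permutation run: seed, chain settings, exceedances."""

    n_permutations: int
    seed: int | None
    q_mult: int
    burn_in_mult: int
    p_mode: str
    exceedance: dict[str, np.ndarray] = field(default_factory=dict)
    observed: dict[str, np.ndarray] = field(default_factory=dict)


def _csr_layout(eqtl: EqtlNetwork, extra_empty: bool):
    n = len(eqtl.snp_ids) + (1 if extra_empty else 0)
    deg = np.bincount(eqtl.edge_snp, minlength=n)
    offsets = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(deg, out=offsets[1:])
    return offsets


def empirical_pvalues(
    pairs: list[SnpPair],
    statistics: tuple[str, ...],
    eqtl: EqtlNetwork,
    corpora: dict[str, OntologyCorpus] | None,
    n_perm: int,
    seed: int | np.random.Generator,
    q_mult: int = 10,
    burn_in_mult: int = 20,
    p_mode: str = "raw",
    return_ensemble: bool = False,
):
    """Empirical permutation p-values for each pair and requested statistic.

    All pairs share each permuted network; ties ("equal or greater") count as
    exceedances. Pairs with an undefined observed statistic get p = NaN for
    that method; permuted draws with an undefined statistic never count as
    exceedances. GENE_ITS values are computed once and cached — the
    gene-level similarity matrix is permutation-invariant, only the SNP ->
    gene-set map is resampled.
    """
    unknown = set(statistics) - set(STATISTICS)
    if unknown:
        raise ValueError(f"unknown statistic(s): {sorted(unknown)}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if p_mode not in {"raw", "add_one"}:
        raise ValueError(f"unknown p_mode: {p_mode}")
    do_ov = "overlap" in statistics
    do_mf = "mf" in statistics
    do_bp = "bp" in statistics
    if (do_mf or do_bp) and not corpora:
        raise ValueError("GO corpora required for similarity statistics")

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_pairs = len(pairs)
    empty_slot = len(eqtl.snp_ids)  # virtual degree-0 slot for absent SNPs
    pair_a = np.array(
        [eqtl.snp_index.get(p.rsid_a, empty_slot) for p in pairs], dtype=np.int64
    )
    pair_b = np.array(
        [eqtl.snp_index.get(p.rsid_b, empty_slot) for p in pairs], dtype=np.int64
    )

    one = np.zeros((1, 1))
    ann_false = np.zeros(1, dtype=bool)
    if do_mf:
        sim_mf, ann_mf = gene_similarity_matrix(corpora["MF"], eqtl.mrna_ids)
    else:
        sim_mf, ann_mf = one, ann_false
    if do_bp:
        sim_bp, ann_bp = gene_similarity_matrix(corpora["BP"], eqtl.mrna_ids)
    else:
        sim_bp, ann_bp = one, ann_false

    offsets = _csr_layout(eqtl, extra_empty=True)
    genes_buf = np.empty(eqtl.n_edges, dtype=np.int64)
    cursor = np.empty(offsets.size - 1, dtype=np.int64)

    def evaluate(edge_snp, edge_mrna, out_ov, out_mf, out_bp):
        _kernels.fill_sorted_adjacency(edge_snp, edge_mrna, offsets, genes_buf, cursor)
        _kernels.pair_statistics(
            offsets, genes_buf, pair_a, pair_b,
            sim_mf, ann_mf, sim_bp, ann_bp,
            do_ov, do_mf, do_bp,
            out_ov, out_mf, out_bp,
        )

    obs_ov = np.zeros(n_pairs, dtype=np.float64)
    obs_mf = np.full(n_pairs, np.nan)
    obs_bp = np.full(n_pairs, np.nan)
    evaluate(eqtl.edge_snp, eqtl.edge_mrna, obs_ov, obs_mf, obs_bp)

    exc_ov = np.zeros(n_pairs, dtype=np.int64)
    exc_mf = np.zeros(n_pairs, dtype=np.int64)
    exc_bp = np.zeros(n_pairs, dtype=np.int64)
    def_mf = np.zeros(n_pairs, dtype=np.int64)
    def_bp = np.zeros(n_pairs, dtype=np.int64)
    perm_ov = np.zeros(n_pairs, dtype=np.float64)
    perm_mf = np.full(n_pairs, np.nan)
    perm_bp = np.full(n_pairs, np.nan)

    sampler = DegreeConservingSampler(
        eqtl, rng, q_mult=q_mult, burn_in_mult=burn_in_mult
    )
    thr_ov = obs_ov - TIE_EPS
    thr_mf = obs_mf - TIE_EPS
    thr_bp = obs_bp - TIE_EPS
    for _ in range(n_perm):
        edge_snp, edge_mrna = sampler.draw()
        evaluate(edge_snp, edge_mrna, perm_ov, perm_mf, perm_bp)
        if do_ov:
            exc_ov += perm_ov >= thr_ov
        if do_mf:
            exc_mf += perm_mf >= thr_mf  # NaN comparisons are False
            def_mf += ~np.isnan(perm_mf)
        if do_bp:
            exc_bp += perm_bp >= thr_bp
            def_bp += ~np.isnan(perm_bp)

    def to_p(exc, n_def, obs_defined):
        # a permuted draw whose statistic is undefined (no annotated genes on
        # one side) carries no evidence either way: the p-value conditions on
        # defined draws, otherwise undefined draws would deflate p
        with np.errstate(invalid="ignore", divide="ignore"):
            if p_mode == "add_one":
                p = (1.0 + exc) / (1.0 + n_def)
            else:
                p = exc / np.asarray(n_def, dtype=np.float64)
        return np.where(obs_defined & (np.asarray(n_def) > 0), p, np.nan)

    full = np.full(n_pairs, n_perm, dtype=np.int64)
    p_ov = to_p(exc_ov, full, np.full(n_pairs, do_ov))
    p_mf = (
        to_p(exc_mf, def_mf, ~np.isnan(obs_mf))
        if do_mf
        else np.full(n_pairs, np.nan)
    )
    p_bp = (
        to_p(exc_bp, def_bp, ~np.isnan(obs_bp))
        if do_bp
        else np.full(n_pairs, np.nan)
    )

    scores: list[PairScore] = []
    for i, pair in enumerate(pairs):
        count, genes = mrna_overlap(pair.rsid_a, pair.rsid_b, eqtl)
        scores.append(
            PairScore(
                pair=pair,
                overlap_count=count,
                overlap_genes=genes,
                mf_its=float(obs_mf[i]),
                bp_its=float(obs_bp[i]),
                p_overlap=float(p_ov[i]),
                p_mf=float(p_mf[i]),
                p_bp=float(p_bp[i]),
            )
        )
    if return_ensemble:
        ensemble = NullEnsemble(
            n_permutations=n_perm,
            seed=None if isinstance(seed, np.random.Generator) else int(seed),
            q_mult=q_mult,
            burn_in_mult=burn_in_mult,
            p_mode=p_mode,
            exceedance={"overlap": exc_ov, "mf": exc_mf, "bp": exc_bp},
            observed={"overlap": obs_ov, "mf": obs_mf, "bp": obs_bp},
        )
        return scores, ensemble
    return scores


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries are excluded from the
    family and returned as NaN."""
    p = np.asarray(pvalues, dtype=np.float64)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return q
    q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def attach_qvalues(scores: list[PairScore]) -> None:
    """Compute BH q-values independently for each of the three methods."""
    for stat, p_attr, q_attr in (
        ("overlap", "p_overlap", "q_overlap"),
        ("mf", "p_mf", "q_mf"),
        ("bp", "p_bp", "q_bp"),
    ):
        q = bh_fdr([getattr(s, p_attr) for s in scores])
        for s, qi in zip(scores, q):
            setattr(s, q_attr, float(qi))


def prioritise(scores: list[PairScore], fdr_max: float = 0.05) -> list[PairScore]:
    """Flag pairs with min(q_overlap, q_mf, q_bp) < fdr_max; keep per-method flags."""
    out = []
    for s in scores:
        methods = set()
        if not np.isnan(s.q_overlap) and s.q_overlap < fdr_max:
            methods.add("overlap")
        if not np.isnan(s.q_mf) and s.q_mf < fdr_max:
            methods.add("mf")
        if not np.isnan(s.q_bp) and s.q_bp < fdr_max:
            methods.add("bp")
        s.methods = frozenset(methods)
        s.prioritised = bool(methods)
        if s.prioritised:
            out.append(s)
    return out
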