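"""Per-pair statistics: mRNA overlap and GO semantic similarity.

The SNP-level information-theoretic similarity (SNP_ITS) of a pair is the
symmetric best-match average (BMA) of gene-level similarities over the two
SNPs' eQTL gene sets:

    SNP_ITS(s1, s2) = [ sum_{gi in G(s1)} max_{gj in G(s2)} GENE_ITS(gi, gj)
                      + sum_{gj in G(s2)} max_{gi in G(s1)} GENE_ITS(gi, gj) ]
                      / (|G(s1)| + |G(s2)|)

GENE_ITS is itself a BMA over the genes' *direct* GO term sets under an
information-content term kernel (Lin by default). Annotation propagation to
ancestors (true-path rule) is used only for IC counting. Genes and SNPs
without annotations yield *undefined* (NaN) rather than 0, so "no signal" is
distinguished from "dissimilar".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from snpconverge import _kernels
from snpconverge.errors import UndefinedSimilarityError

logger = logging.getLogger(__name__)

ONTOLOGY_RELATIONS = ("is_a", "part_of")
NAMESPACE_LONG = {"MF": "molecular_function", "BP": "biological_process"}


@dataclass
class OntologyCorpus:
    """A GO namespace DAG with propagated annotations and term IC.

    ``dag`` holds child -> parent edges (is_a/part_of). ``gene_terms`` holds
    ancestor-propagated annotations; ``gene_direct`` the direct ones used for
    similarity. IC(t) = -ln(n_t / n_root) over the annotation corpus.
    """

    namespace: str
    dag: nx.MultiDiGraph
    gene_direct: dict[str, frozenset[str]]
    gene_terms: dict[str, frozenset[str]]
    ic: dict[str, float]
    ic_max: float
    kernel: str = "lin"
    aggregation: str = "bma"
    skipped_terms: dict[str, int] = field(default_factory=dict)
    ancestors: dict[str, frozenset[str]] = field(default_factory=dict)
    _term_index: dict[str, int] | None = None
    _term_sim: np.ndarray | None = None

    # -- term-level ----------------------------------------------------

    def term_sim_matrix(self) -> tuple[dict[str, int], np.ndarray]:
        """Dense term x term similarity over all IC-bearing terms (cached)."""
        if self._term_sim is not None:
            return self._term_index, self._term_sim
        terms = sorted(self.ic)
        index = {t: i for i, t in enumerate(terms)}
        n = len(terms)
        anc = np.zeros((n, n), dtype=bool)
        ic = np.array([self.ic[t] for t in terms])
        for t, i in index.items():
            for a in self.ancestors[t]:
                j = index.get(a)
                if j is not None:
                    anc[i, j] = True
        mica = np.zeros((n, n))
        for i in range(n):
            both = anc & anc[i]
            masked = np.where(both, ic[np.newaxis, :], -np.inf)
            mica[i] = masked.max(axis=1)
        mica[~np.isfinite(mica)] = 0.0
        if self.kernel == "lin":
            denom = ic[:, None] + ic[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                sim = np.where(denom > 0, 2.0 * mica / np.where(denom > 0, denom, 1.0), 0.0)
            np.fill_diagonal(sim, 1.0)  # self-similarity 1 even at IC 0
        elif self.kernel == "resnik_norm":
            sim = mica / self.ic_max if self.ic_max > 0 else np.zeros((n, n))
        else:
            raise ValueError(f"unknown term kernel: {self.kernel}")
        self._term_index = index
        self._term_sim = sim
        return index, sim


@dataclass
class PairScore:
    """A candidate pair's three statistics with empirical p and FDR q values.

    Similarity scores are NaN when undefined (no annotated eQTL genes on one
    side); undefined statistics are excluded from that method's
    multiple-testing family.
    """

    pair: object  # pairing.SnpPair
    overlap_count: int = 0
    overlap_genes: frozenset[str] = frozenset()
    mf_its: float = float("nan")
    bp_its: float = float("nan")
    p_overlap: float = float("nan")
    p_mf: float = float("nan")
    p_bp: float = float("nan")
    q_overlap: float = float("nan")
    q_mf: float = float("nan")
    q_bp: float = float("nan")
    prioritised: bool = False
    methods: frozenset[str] = frozenset()


def propagate(terms: frozenset[str] | set[str], ancestors: dict[str, frozenset[str]]) -> frozenset[str]:
    """True-path closure of a direct term set."""
    out: set[str] = set()
    for t in terms:
        out |= ancestors.get(t, frozenset({t}))
    return frozenset(out)


def _dag_ancestors(dag: nx.MultiDiGraph) -> dict[str, frozenset[str]]:
    """Ancestor-or-self sets along is_a/part_of edges (child -> parent)."""
    sub = nx.MultiDiGraph()
    sub.add_nodes_from(dag.nodes)
    for u, v, key in dag.edges(keys=True):
        if key in ONTOLOGY_RELATIONS:
            sub.add_edge(u, v, key=key)
    order = list(nx.topological_sort(sub))  # parents after children
    anc: dict[str, set[str]] = {}
    for node in reversed(order):  # roots first
        s = {node}
        for _, parent in sub.out_edges(node):
            s |= anc[parent]
        anc[node] = s
    return {t: frozenset(s) for t, s in anc.items()}


def compute_ic(
    annotations: dict[str, set[str] | frozenset[str]],
    dag: nx.MultiDiGraph,
    namespace: str,
    kernel: str = "lin",
    aggregation: str = "bma",
) -> OntologyCorpus:
    """Build an OntologyCorpus: propagate annotations and compute term IC.

    Terms absent from the DAG are collected in ``skipped_terms`` (not fatal).
    IC(t) = -ln(n_t / n), where n_t counts genes annotated at-or-below t
    after propagation and n is the number of annotated genes; IC(root) = 0.
    """
    ns_long = NAMESPACE_LONG.get(namespace, namespace)
    in_ns = {
        t
        for t in dag.nodes
        if dag.nodes[t].get("namespace", ns_long) == ns_long
    }
    ancestors = _dag_ancestors(dag)
    skipped: dict[str, int] = {}
    direct: dict[str, frozenset[str]] = {}
    propagated: dict[str, frozenset[str]] = {}
    counts: dict[str, int] = {}
    for gene in sorted(annotations):
        kept = frozenset(t for t in annotations[gene] if t in in_ns)
        for t in annotations[gene]:
            if t not in in_ns:
                skipped[t] = skipped.get(t, 0) + 1
        if not kept:
            continue
        direct[gene] = kept
        full = propagate(kept, ancestors)
        propagated[gene] = full
        for t in full:
            counts[t] = counts.get(t, 0) + 1
    if skipped:
        logger.warning(
            "%s: %d annotation term(s) absent from the DAG were skipped",
            namespace,
            len(skipped),
        )
    n_genes = len(direct)
    ic = {
        t: -math.log(c / n_genes) if n_genes else 0.0 for t, c in counts.items()
    }
    ic_max = max(ic.values(), default=0.0)
    return OntologyCorpus(
        namespace=namespace,
        dag=dag,
        gene_direct=direct,
        gene_terms=propagated,
        ic=ic,
        ic_max=ic_max,
        kernel=kernel,
        aggregation=aggregation,
        skipped_terms=skipped,
        ancestors={t: ancestors[t] for t in in_ns if t in ancestors},
    )


def term_similarity(t1: str, t2: str, corpus: OntologyCorpus) -> float:
    """IC-based similarity of two terms (Lin by default).

    Lin: 2*IC(MICA) / (IC(t1)+IC(t2)) with MICA the common ancestor of
    maximal IC; when both ICs are 0 the value is 1 for identical terms and 0
    otherwise. ``resnik_norm``: IC(MICA)/IC_max.
    """
    for t in (t1, t2):
        if t not in corpus.ic:
            raise UndefinedSimilarityError(f"term without information content: {t}")
    common = corpus.ancestors.get(t1, frozenset()) & corpus.ancestors.get(
        t2, frozenset()
    )
    mica_ic = max((corpus.ic.get(a, 0.0) for a in common), default=0.0)
    if corpus.kernel == "resnik_norm":
        return mica_ic / corpus.ic_max if corpus.ic_max > 0 else 0.0
    denom = corpus.ic[t1] + corpus.ic[t2]
    if denom == 0.0:
        return 1.0 if t1 == t2 else 0.0
    return 2.0 * mica_ic / denom


def gene_its(g1: str, g2: str, corpus: OntologyCorpus) -> float:
    """Similarity of two genes over their *direct* term sets.

    Default aggregation is the symmetric best-match average; the all-pairs
    mean is available via ``corpus.aggregation = "mean"``. Returns NaN
    (undefined) when either gene lacks direct annotation in the namespace.
    """
    ta = corpus.gene_direct.get(g1)
    tb = corpus.gene_direct.get(g2)
    if not ta or not tb:
        return float("nan")
    ta_sorted = sorted(ta)
    tb_sorted = sorted(tb)
    if corpus.aggregation == "mean":
        vals = [term_similarity(x, y, corpus) for x in ta_sorted for y in tb_sorted]
        return float(sum(vals) / len(vals))
    fwd = sum(
        max(term_similarity(x, y, corpus) for y in tb_sorted) for x in ta_sorted
    )
    rev = sum(
        max(term_similarity(x, y, corpus) for x in ta_sorted) for y in tb_sorted
    )
    return float((fwd + rev) / (len(ta_sorted) + len(tb_sorted)))


def snp_its(s1: str, s2: str, eqtl, corpus: OntologyCorpus) -> float:
    """SNP-level similarity: BMA of GENE_ITS over the SNPs' annotated gene sets.

    Undefined (NaN) when either SNP has no annotated eQTL gene — a missing
    signal, deliberately distinct from a similarity of 0.
    """
    ga = sorted(g for g in eqtl.genes_of(s1) if g in corpus.gene_direct)
    gb = sorted(g for g in eqtl.genes_of(s2) if g in corpus.gene_direct)
    if not ga or not gb:
        return float("nan")
    fwd = sum(max(gene_its(gi, gj, corpus) for gj in gb) for gi in ga)
    rev = sum(max(gene_its(gi, gj, corpus) for gi in ga) for gj in gb)
    return float((fwd + rev) / (len(ga) + len(gb)))


def mrna_overlap(s1: str, s2: str, eqtl) -> tuple[int, frozenset[str]]:
    """Number (and identity) of mRNAs shared by the two SNPs' eQTL targets."""
    shared = eqtl.genes_of(s1) & eqtl.genes_of(s2)
    return len(shared), frozenset(shared)


def gene_similarity_matrix(
    corpus: OntologyCorpus, gene_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Dense gene x gene GENE_ITS matrix aligned to ``gene_ids``.

    Returns ``(sim, annotated)`` where ``annotated`` is a boolean mask; rows
    and columns of unannotated genes are 0 and must be masked by callers
    (the bulk kernels do). The matrix is permutation-invariant, so the
    permutation null computes it once and reuses it for every resample.
    """
    term_index, term_sim = corpus.term_sim_matrix()
    annotated = np.array([g in corpus.gene_direct for g in gene_ids], dtype=bool)
    if corpus.aggregation != "bma":
        # all-pairs mean path stays in Python; only used at desk scales
        n = len(gene_ids)
        sim = np.zeros((n, n))
        for i, gi in enumerate(gene_ids):
            for j in range(i, n):
                v = gene_its(gi, gene_ids[j], corpus)
                if not math.isnan(v):
                    sim[i, j] = sim[j, i] = v
        return sim, annotated
    offsets = np.zeros(len(gene_ids) + 1, dtype=np.int64)
    items: list[int] = []
    for i, g in enumerate(gene_ids):
        terms = sorted(corpus.gene_direct.get(g, frozenset()))
        items.extend(term_index[t] for t in terms)
        offsets[i + 1] = len(items)
    items_arr = np.asarray(items, dtype=np.int64)
    sim = _kernels.all_pairs_bma(offsets, items_arr, term_sim)
    sim = np.nan_to_num(sim, nan=0.0)
    sim[~annotated, :] = 0.0
    sim[:, ~annotated] = 0.0
    return sim, annotated
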