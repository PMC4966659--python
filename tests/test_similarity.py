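"""Information content, term/gene/SNP similarity and kernel/pure consistency."""

import math

import numpy as np
import pytest

import oracles
from conftest import make_dag, make_network
from snpconverge.errors import UndefinedSimilarityError
from snpconverge.similarity import (
    compute_ic,
    gene_its,
    gene_similarity_matrix,
    mrna_overlap,
    snp_its,
    term_similarity,
)
from snpconverge.synth import random_go_dag


class TestInformationContent:
    def test_root_ic_zero(self, toy_corpus):
        assert toy_corpus.ic["R"] == 0.0

    def test_closed_form(self, toy_corpus):
        # B annotated (directly or below) by g5..g8 -> 4 of 10 genes
        assert toy_corpus.ic["B"] == pytest.approx(-math.log(0.4))
        # A1 annotated by g0, g1, g4 -> 3 of 10
        assert toy_corpus.ic["A1"] == pytest.approx(-math.log(0.3))

    def test_single_gene_term(self):
        dag = make_dag([(f"T{i}", "R") for i in range(3)])
        ann = {f"g{i}": {"T0" if i else "T1"} for i in range(10)}
        ann["g0"] = {"T1"}
        corpus = compute_ic(ann, dag, "MF")
        # T1 annotates exactly 1 of 10 genes
        assert corpus.ic["T1"] == pytest.approx(2.302585, abs=1e-6)

    def test_missing_terms_skipped_not_fatal(self, toy_corpus):
        dag = toy_corpus.dag
        corpus = compute_ic({"g0": {"A1", "NOT_A_TERM"}}, dag, "MF")
        assert "NOT_A_TERM" in corpus.skipped_terms
        assert corpus.gene_direct["g0"] == {"A1"}

    def test_propagated_child_subset_of_parent(self, rng):
        """True-path rule: gene sets at a child are contained in each parent's."""
        for trial in range(60):
            dag, leaves = random_go_dag(
                25, 4, "MF", rng, id_offset=3_000_000 + trial * 100
            )
            ann = {
                f"g{i}": {
                    leaves[j]
                    for j in rng.choice(len(leaves), size=2, replace=False)
                }
                for i in range(12)
            }
            corpus = compute_ic(ann, dag, "MF")
            genes_at = {}
            for g, terms in corpus.gene_terms.items():
                for t in terms:
                    genes_at.setdefault(t, set()).add(g)
            for child, parent, key in dag.edges(keys=True):
                assert genes_at.get(child, set()) <= genes_at.get(parent, set())


class TestTermSimilarity:
    def test_self_similarity_is_one(self, toy_corpus):
        assert term_similarity("A1", "A1", toy_corpus) == 1.0

    def test_root_only_common_ancestor_is_zero(self, toy_corpus):
        assert term_similarity("A1", "B1", toy_corpus) == 0.0

    def test_unknown_term_raises(self, toy_corpus):
        with pytest.raises(UndefinedSimilarityError):
            term_similarity("A1", "NOPE", toy_corpus)

    def test_matches_exhaustive_mica_search(self, rng):
        """Lin similarity equals the brute-force best-common-ancestor search."""
        for trial in range(25):
            dag, leaves = random_go_dag(12, 4, "MF", rng, 4_000_000 + trial * 50)
            terms = sorted(dag.nodes)
            ann = {
                f"g{i}": {terms[j] for j in rng.choice(len(terms), 2, replace=False)}
                for i in range(10)
            }
            corpus = compute_ic(ann, dag, "MF")
            known = sorted(corpus.ic)
            for _ in range(30):
                t1, t2 = (known[j] for j in rng.integers(0, len(known), 2))
                expected = oracles.naive_term_sim(t1, t2, dag, corpus.ic)
                assert term_similarity(t1, t2, corpus) == pytest.approx(
                    expected, abs=1e-12
                )

    def test_resnik_norm_kernel(self, toy_corpus):
        corpus = compute_ic(
            {g: set(t) for g, t in toy_corpus.gene_direct.items()},
            toy_corpus.dag,
            "MF",
            kernel="resnik_norm",
        )
        assert term_similarity("A1", "B1", corpus) == 0.0
        expected = corpus.ic["A1"] / corpus.ic_max
        assert term_similarity("A1", "A1", corpus) == pytest.approx(expected)


class TestGeneIts:
    def test_identical_direct_sets(self, toy_corpus):
        assert gene_its("g0", "g1", toy_corpus) == pytest.approx(1.0)

    def test_root_only_cross_pairs(self, toy_corpus):
        assert gene_its("g0", "g5", toy_corpus) == pytest.approx(0.0)

    def test_unannotated_gene_is_nan(self, toy_corpus):
        assert math.isnan(gene_its("g0", "missing", toy_corpus))

    def test_hand_enumerated_bma(self, toy_corpus):
        # g4={A1,A2}, g0={A1}: forward best matches = 1 (A1) and s(A2,A1);
        # reverse = 1; BMA = (1 + s + 1) / 3
        s = term_similarity("A2", "A1", toy_corpus)
        expected = (1.0 + s + 1.0) / 3.0
        assert gene_its("g4", "g0", toy_corpus) == pytest.approx(expected, abs=1e-12)
        expected_oracle = oracles.naive_gene_its(
            toy_corpus.gene_direct["g4"],
            toy_corpus.gene_direct["g0"],
            toy_corpus.dag,
            toy_corpus.ic,
        )
        assert gene_its("g4", "g0", toy_corpus) == pytest.approx(
            expected_oracle, abs=1e-12
        )

    def test_all_pairs_mean_aggregation(self, toy_corpus):
        corpus = compute_ic(
            {g: set(t) for g, t in toy_corpus.gene_direct.items()},
            toy_corpus.dag,
            "MF",
            aggregation="mean",
        )
        vals = [
            term_similarity(a, b, corpus)
            for a in sorted(corpus.gene_direct["g4"])
            for b in sorted(corpus.gene_direct["g0"])
        ]
        assert gene_its("g4", "g0", corpus) == pytest.approx(np.mean(vals))


class TestSnpIts:
    def test_shared_single_gene_is_one(self, toy_corpus):
        net = make_network([("s1", "g0"), ("s2", "g0")])
        assert snp_its("s1", "s2", net, toy_corpus) == 1.0

    def test_equal_gene_sets_score_one(self, toy_corpus):
        net = make_network(
            [("s1", g) for g in ("g0", "g3", "g5")]
            + [("s2", g) for g in ("g0", "g3", "g5")]
        )
        assert snp_its("s1", "s2", net, toy_corpus) == pytest.approx(1.0)

    def test_singleton_sets_reduce_to_gene_its(self, toy_corpus):
        net = make_network([("s1", "g4"), ("s2", "g0")])
        x = gene_its("g4", "g0", toy_corpus)
        assert snp_its("s1", "s2", net, toy_corpus) == pytest.approx(x, abs=1e-12)

    def test_no_annotated_genes_is_undefined(self, toy_corpus):
        net = make_network([("s1", "u1"), ("s2", "g0")])
        assert math.isnan(snp_its("s1", "s2", net, toy_corpus))

    def test_symmetry_and_range(self, toy_corpus, rng):
        genes = sorted(toy_corpus.gene_direct)
        for _ in range(300):
            ga = [genes[i] for i in rng.choice(len(genes), rng.integers(1, 4), replace=False)]
            gb = [genes[i] for i in rng.choice(len(genes), rng.integers(1, 4), replace=False)]
            net = make_network([("s1", g) for g in ga] + [("s2", g) for g in gb])
            v = snp_its("s1", "s2", net, toy_corpus)
            assert 0.0 <= v <= 1.0 + 1e-12
            assert v == pytest.approx(
                snp_its("s2", "s1", net, toy_corpus), abs=1e-12
            )

    def test_matches_naive_oracle_random_instances(self, rng):
        """Pair score equals an independent naive double-loop evaluation."""
        dag, leaves = random_go_dag(30, 4, "MF", rng, 5_000_000)
        genes = [f"g{i}" for i in range(20)]
        ann = {
            g: {leaves[j] for j in rng.choice(len(leaves), rng.integers(1, 4), replace=False)}
            for g in genes
        }
        corpus = compute_ic(ann, dag, "MF")
        for _ in range(200):
            ga = [genes[i] for i in rng.choice(len(genes), rng.integers(1, 5), replace=False)]
            gb = [genes[i] for i in rng.choice(len(genes), rng.integers(1, 5), replace=False)]
            net = make_network([("s1", g) for g in ga] + [("s2", g) for g in gb])
            expected = oracles.naive_snp_its(
                ga, gb, lambda x, y: oracles.naive_gene_its(ann[x], ann[y], dag, corpus.ic)
            )
            assert snp_its("s1", "s2", net, corpus) == pytest.approx(
                expected, abs=1e-12
            )


class TestOverlap:
    @pytest.mark.parametrize(
        "ga,gb,expected",
        [
            (("A", "B", "C"), ("B", "C", "D"), 2),
            (("A", "B", "C"), ("A", "B", "C"), 3),
            (("A", "B"), ("C", "D"), 0),
        ],
    )
    def test_counts(self, ga, gb, expected):
        net = make_network([("s1", g) for g in ga] + [("s2", g) for g in gb])
        count, genes = mrna_overlap("s1", "s2", net)
        assert count == expected
        assert genes == frozenset(ga) & frozenset(gb)


class TestNamespaceIsolation:
    def test_mf_and_bp_never_share_terms(self, rng):
        """A gene annotated only in BP is undefined in the MF corpus."""
        mf_dag, mf_leaves = random_go_dag(10, 3, "MF", rng, 6_000_000)
        bp_dag, bp_leaves = random_go_dag(10, 3, "BP", rng, 7_000_000)
        ann_mf = {"g1": {mf_leaves[0]}}
        ann_bp = {"g1": {bp_leaves[0]}, "g2": {bp_leaves[0]}}
        mf = compute_ic(ann_mf, mf_dag, "MF")
        bp = compute_ic(ann_bp, bp_dag, "BP")
        assert "g2" not in mf.gene_direct
        assert math.isnan(gene_its("g1", "g2", mf))
        assert gene_its("g1", "g2", bp) == pytest.approx(1.0)

    def test_mixed_namespace_dag_respects_namespace(self, rng):
        """compute_ic on a merged DAG keeps only the requested namespace."""
        mf_dag, mf_leaves = random_go_dag(8, 3, "MF", rng, 8_000_000)
        bp_dag, bp_leaves = random_go_dag(8, 3, "BP", rng, 9_000_000)
        merged = mf_dag.copy()
        merged.update(bp_dag)
        ann = {"g1": {mf_leaves[0], bp_leaves[0]}}
        mf = compute_ic(ann, merged, "MF")
        assert mf.gene_direct["g1"] == {mf_leaves[0]}


class TestBulkKernelConsistency:
    def test_gene_matrix_matches_pure_gene_its(self, toy_corpus, rng):
        genes = sorted(toy_corpus.gene_direct) + ["unannotated"]
        sim, annotated = gene_similarity_matrix(toy_corpus, genes)
        assert not annotated[-1]
        for _ in range(100):
            i, j = rng.integers(0, len(genes) - 1, 2)
            expected = gene_its(genes[i], genes[j], toy_corpus)
            assert sim[i, j] == pytest.approx(expected, abs=1e-12)
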