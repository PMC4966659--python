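"""Degree-conserving null: swap chain, empirical p-values, BH, prioritisation."""

import numpy as np
import pytest

import oracles
from conftest import make_network, make_snp
from snpconverge.pairing import make_pair
from snpconverge.permutation import (
    DegreeConservingSampler,
    attach_qvalues,
    bh_fdr,
    empirical_pvalues,
    permute_network,
    prioritise,
)
from snpconverge.similarity import PairScore, mrna_overlap, snp_its
from snpconverge.synth import SynthConfig, generate_bundle


def pair_of(a, b, same_disease=True):
    da = ("D0",) if same_disease else ("D0",)
    db = ("D0",) if same_disease else ("D1",)
    return make_pair(make_snp(a, diseases=da), make_snp(b, diseases=db), 0.0)


class TestSwapChain:
    def test_two_edge_network_identity_or_swap(self, rng):
        net = make_network([("s1", "a"), ("s2", "b")])
        seen = set()
        for _ in range(50):
            out = permute_network(net, rng)
            edges = frozenset(zip(out.edges["rsid"], out.edges["mrna_id"]))
            seen.add(edges)
            assert out.snp_degree == net.snp_degree
            assert out.mrna_degree == net.mrna_degree
        assert seen == {
            frozenset({("s1", "a"), ("s2", "b")}),
            frozenset({("s1", "b"), ("s2", "a")}),
        }

    def test_degrees_conserved_every_draw(self, rng):
        bundle = generate_bundle(
            SynthConfig(n_diseases=8, snps_per_disease=(3, 10), n_mrnas=200, seed=2)
        )
        net = bundle.eqtl
        sampler = DegreeConservingSampler(net, rng)
        snp_deg = np.bincount(net.edge_snp, minlength=len(net.snp_ids))
        mrna_deg = np.bincount(net.edge_mrna, minlength=len(net.mrna_ids))
        for _ in range(200):
            edge_snp, edge_mrna = sampler.draw()
            assert np.array_equal(
                np.bincount(edge_snp, minlength=len(net.snp_ids)), snp_deg
            )
            assert np.array_equal(
                np.bincount(edge_mrna, minlength=len(net.mrna_ids)), mrna_deg
            )

    def test_complete_bipartite_returns_input_with_warning(self, rng, caplog):
        net = make_network(
            [(f"s{i}", f"m{j}") for i in range(2) for j in range(2)]
        )
        with caplog.at_level("WARNING"):
            out = permute_network(net, rng)
        assert out == net
        assert any("no degree-preserving swap" in r.message for r in caplog.records)

    def test_chain_visits_states_uniformly(self):
        """Long-run visit frequencies match exhaustive enumeration (3x3 toy)."""
        edges = [("s0", "m0"), ("s0", "m1"), ("s1", "m1"), ("s2", "m2")]
        net = make_network(edges)
        row = np.bincount(net.edge_snp, minlength=3)
        col = np.bincount(net.edge_mrna, minlength=3)
        states = list(
            oracles.enumerate_fixed_margin_matrices(row.tolist(), col.tolist())
        )
        n_states = len(states)
        assert n_states > 1
        keys = {m.tobytes(): i for i, m in enumerate(states)}
        sampler = DegreeConservingSampler(
            net, np.random.default_rng(7), q_mult=10
        )
        n_draws = 20_000
        counts = np.zeros(n_states)
        mat = np.zeros((3, 3), dtype=np.int64)
        for _ in range(n_draws):
            edge_snp, edge_mrna = sampler.draw()
            mat[:] = 0
            mat[edge_snp, edge_mrna] = 1
            counts[keys[mat.tobytes()]] += 1
        expected = n_draws / n_states
        sigma = np.sqrt(n_draws * (1 / n_states) * (1 - 1 / n_states))
        assert np.all(np.abs(counts - expected) <= 3 * sigma)


@pytest.fixture(scope="module")
def planted_net():
    """30 background SNPs plus a pair sharing 3 dedicated mRNAs."""
    edges = [(f"s{i:02d}", f"m{2 * i + k}") for i in range(30) for k in range(2)]
    edges += [("sA", f"sh{j}") for j in range(3)]
    edges += [("sB", f"sh{j}") for j in range(3)]
    return make_network(edges)


class TestEmpiricalPvalues:
    def test_add_one_formula_strict_maximum(self, planted_net):
        """A statistic no permutation matches gives p = 1/(N+1)."""
        pairs = [pair_of("sA", "sB")]
        scores = empirical_pvalues(
            pairs, ("overlap",), planted_net, None, n_perm=99, seed=3,
            p_mode="add_one",
        )
        assert scores[0].overlap_count == 3
        assert scores[0].p_overlap == pytest.approx(1 / 100)

    def test_minimum_achievable_statistic_p_one(self):
        net = make_network([("s1", "a"), ("s2", "b")])
        scores = empirical_pvalues(
            [pair_of("s1", "s2")], ("overlap",), net, None, n_perm=50, seed=0,
            p_mode="add_one",
        )
        # observed overlap 0 is the minimum achievable -> every draw ties
        assert scores[0].p_overlap == 1.0

    def test_raw_mode_can_reach_zero(self, planted_net):
        scores = empirical_pvalues(
            [pair_of("sA", "sB")], ("overlap",), planted_net, None,
            n_perm=200, seed=3, p_mode="raw",
        )
        assert scores[0].p_overlap == 0.0

    def test_add_one_p_in_open_unit_interval(self, planted_net, rng):
        ids = sorted(planted_net.snp_ids)
        pairs = [
            pair_of(*sorted((ids[i], ids[j])))
            for i, j in rng.choice(len(ids), size=(40, 2), replace=True)
            if ids[i] != ids[j]
        ][:30]
        scores = empirical_pvalues(
            pairs, ("overlap",), planted_net, None, n_perm=100, seed=1,
            p_mode="add_one",
        )
        for s in scores:
            assert 0.0 < s.p_overlap <= 1.0

    def test_reproducible_bit_for_bit(self, planted_net):
        pairs = [pair_of("sA", "sB"), pair_of("s00", "s01")]
        kw = dict(n_perm=150, seed=11, p_mode="add_one")
        a = empirical_pvalues(pairs, ("overlap",), planted_net, None, **kw)
        b = empirical_pvalues(pairs, ("overlap",), planted_net, None, **kw)
        assert [(s.p_overlap, s.overlap_count) for s in a] == [
            (s.p_overlap, s.overlap_count) for s in b
        ]

    def test_observed_stats_match_pure_functions(self, toy_corpus):
        net = make_network(
            [("s1", g) for g in ("g0", "g4")]
            + [("s2", g) for g in ("g0", "g5", "g8")]
        )
        pairs = [pair_of("s1", "s2")]
        scores = empirical_pvalues(
            pairs, ("overlap", "mf"), net, {"MF": toy_corpus}, n_perm=20, seed=5
        )
        count, genes = mrna_overlap("s1", "s2", net)
        assert scores[0].overlap_count == count
        assert scores[0].overlap_genes == genes
        assert scores[0].mf_its == pytest.approx(
            snp_its("s1", "s2", net, toy_corpus), abs=1e-12
        )

    def test_undefined_similarity_gives_nan_p(self, toy_corpus):
        net = make_network([("s1", "unannotated"), ("s2", "g0")])
        scores = empirical_pvalues(
            [pair_of("s1", "s2")], ("overlap", "mf"), net,
            {"MF": toy_corpus}, n_perm=20, seed=5,
        )
        assert np.isnan(scores[0].mf_its)
        assert np.isnan(scores[0].p_mf)
        assert not np.isnan(scores[0].p_overlap)


class TestBhFdr:
    def test_textbook_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_nan_excluded_from_family(self):
        q = bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert q[0] == pytest.approx(0.02)

    def test_matches_naive_step_up(self, rng):
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 60)))
            assert bh_fdr(p) == pytest.approx(oracles.naive_bh(p), abs=1e-12)


class TestPrioritise:
    def make_score(self, q_ov, q_mf, q_bp):
        s = PairScore(pair=pair_of("s1", "s2"))
        s.q_overlap, s.q_mf, s.q_bp = q_ov, q_mf, q_bp
        return s

    def test_single_method_flag(self):
        s = self.make_score(0.04, np.nan, 0.2)
        out = prioritise([s], fdr_max=0.05)
        assert out == [s] and s.methods == {"overlap"}

    def test_not_prioritised(self):
        s = self.make_score(0.2, 0.2, 0.2)
        assert prioritise([s], fdr_max=0.05) == []
        assert not s.prioritised

    def test_all_methods(self):
        s = self.make_score(0.01, 0.01, 0.01)
        prioritise([s], fdr_max=0.05)
        assert s.methods == {"overlap", "mf", "bp"}

    def test_attach_qvalues_per_method_families(self):
        scores = [self.make_score(np.nan, np.nan, np.nan) for _ in range(3)]
        for s, p in zip(scores, (0.01, 0.02, 0.03)):
            s.p_overlap = p
            s.p_mf = np.nan
            s.p_bp = 0.5
        attach_qvalues(scores)
        assert [s.q_overlap for s in scores] == pytest.approx([0.03] * 3)
        assert all(np.isnan(s.q_mf) for s in scores)
        assert [s.q_bp for s in scores] == pytest.approx([0.5] * 3)
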