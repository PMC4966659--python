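"""Shared fixtures: hand-built toy ontologies, networks and random generators."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from snpconverge.io import EqtlNetwork, LdTable, SnpRecord
from snpconverge.similarity import compute_ic


def make_dag(edges, namespace="molecular_function"):
    """Build a child->parent is_a MultiDiGraph from (child, parent) tuples."""
    dag = nx.MultiDiGraph()
    nodes = {n for e in edges for n in e}
    for n in nodes:
        dag.add_node(n, name=n, namespace=namespace)
    for child, parent in edges:
        dag.add_edge(child, parent, key="is_a")
    return dag


@pytest.fixture(scope="session")
def toy_corpus():
    """Small hand-checkable MF corpus.

    DAG:          R
                 / \
                A   B
               / \   \
              A1  A2  B1

    Ten genes; annotation counts chosen so IC values are simple closed forms.
    """
    dag = make_dag([("A", "R"), ("B", "R"), ("A1", "A"), ("A2", "A"), ("B1", "B")])
    annotations = {
        "g0": {"A1"},
        "g1": {"A1"},
        "g2": {"A2"},
        "g3": {"A2"},
        "g4": {"A1", "A2"},
        "g5": {"B1"},
        "g6": {"B1"},
        "g7": {"B1"},
        "g8": {"B"},
        "g9": {"A"},
    }
    return compute_ic(annotations, dag, "MF")


def make_network(edges, p=1e-6, cutoff=1e-4) -> EqtlNetwork:
    df = pd.DataFrame(
        [(s, m, p) for s, m in edges], columns=["rsid", "mrna_id", "p_value"]
    )
    return EqtlNetwork(df, p_cutoff=cutoff)


def make_snp(rsid, chrom="1", pos=1000, category="intergenic", diseases=("D0",)):
    rec = SnpRecord(rsid=rsid, chrom=chrom, pos=pos)
    rec.category = category
    rec.diseases = set(diseases)
    return rec


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def empty_ld():
    return LdTable()
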