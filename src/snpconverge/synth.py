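"""Seeded synthetic input bundles with the structure the analysis assumes.

The generator emulates the shape of the real inputs — diseases with multiple
lead SNPs, heavy-tailed SNP-mRNA eQTL degrees, a small GO DAG per namespace
with true-path annotation propagation, LD blocks, regulatory annotations and
case/control genotypes — and can plant convergent same-disease SNP pairs
(shared mRNAs, or similar GO profiles with *disjoint* mRNA sets) and
epistatic genotype patterns, recorded in a GroundTruth object. It makes no
attempt to mimic real allele frequencies, real GO term counts or real
chromosome lengths.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from snpconverge import io as sio
from snpconverge.errors import ConfigError
from snpconverge.similarity import NAMESPACE_LONG

MECHANISMS = ("overlap", "mf_sim", "bp_sim")
REG_MECHANISMS = ("shared_tf", "interacting_tfs", "long_range")


@dataclass
class GenotypeConfig:
    """Case/control genotype simulation settings.

    ``planted_interaction``: "none" (phenotype independent of genotypes),
    "xor" (phenotype is the XOR of the dichotomised planted pair, noise-free
    by default) or "multiplicative" (additive logistic model with an
    interaction odds-ratio ratio of ``interaction_ror``).
    """

    n_cases: int = 500
    n_controls: int = 500
    maf: float = 0.3
    planted_interaction: str = "none"
    interaction_ror: float = 1.0
    main_or: float = 1.2
    xor_noise: float = 0.0
    n_extra_snps: int = 4


@dataclass
class SynthConfig:
    """Everything the generator needs; same seed => byte-identical bundle."""

    n_diseases: int = 20
    snps_per_disease: tuple[int, int] = (2, 30)  # log-uniform bounds
    n_mrnas: int = 2000
    intergenic_frac: float = 0.46  # the catalogue is roughly half intergenic
    degree_exponent: float = 2.5
    max_degree_frac: float = 0.1  # truncation keeps permutation mixing feasible
    n_go_terms: int = 150
    dag_depth: int = 5
    terms_per_gene: tuple[int, int] = (2, 5)
    annotated_frac: float = 0.95
    mrna_weight_exponent: float = 0.5  # popularity skew of mRNA targets
    n_planted_overlap_pairs: int = 0
    n_planted_similarity_pairs: int = 0
    planted_overlap_size: int = 4
    planted_similarity_degree: int = 3  # dedicated mRNAs per similarity-planted SNP
    plant_regulatory: bool = True
    ld_block_count: int = 10
    n_chroms: int = 22
    chrom_length: int = 50_000_000
    eqtl_p_cutoff: float = 1e-4
    snp_reuse_prob: float = 0.05  # chance a disease recruits an existing SNP
    genotype: GenotypeConfig = field(default_factory=GenotypeConfig)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_diseases, self.n_mrnas, self.n_go_terms) < 1:
            raise ConfigError("counts must be positive")
        for frac in (self.intergenic_frac, self.annotated_frac):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"fraction out of [0,1]: {frac}")
        kmax = max(1, int(self.n_mrnas * self.max_degree_frac))
        if self.planted_overlap_size < 1:
            raise ConfigError("planted_overlap_size must be >= 1")
        if self.planted_overlap_size > kmax:
            raise ConfigError(
                f"planted_overlap_size {self.planted_overlap_size} exceeds the "
                f"degree truncation {kmax}: infeasible"
            )
        if self.genotype.planted_interaction not in {"none", "xor", "multiplicative"}:
            raise ConfigError(
                f"unknown planted_interaction: {self.genotype.planted_interaction}"
            )


@dataclass
class PlantedPair:
    rsid_a: str
    rsid_b: str
    mechanism: str  # overlap | mf_sim | bp_sim
    disease: str


@dataclass
class GroundTruth:
    """What was planted: convergent pairs and epistasis parameters."""

    pairs: list[PlantedPair] = field(default_factory=list)
    epistasis_snps: tuple[str, str] | None = None
    epistasis_model: str = "none"
    epistasis_ror: float = 1.0
    regulatory: dict[tuple[str, str], str] = field(default_factory=dict)


@dataclass
class SyntheticBundle:
    cfg: SynthConfig
    catalog: sio.DiseaseCatalog
    eqtl: sio.EqtlNetwork
    genes: list[sio.GeneModel]
    ontologies: dict[str, nx.MultiDiGraph]
    annotations: dict[str, dict[str, set[str]]]
    ld: sio.LdTable
    regulatory: sio.RegulatoryAnnotation
    genotypes: sio.GenotypeStudy | None
    truth: GroundTruth

    @property
    def snp_positions(self) -> dict[str, tuple[str, int]]:
        return {r.rsid: (r.chrom, r.pos) for r in self.catalog.snps.values()}


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------


def _truncated_power_law(rng, alpha: float, kmax: int, size: int) -> np.ndarray:
    """Inverse-CDF sampling of P(k) ~ k^-alpha on {1..kmax}."""
    k = np.arange(1, kmax + 1, dtype=float)
    pmf = k**-alpha
    pmf /= pmf.sum()
    cdf = np.cumsum(pmf)
    u = rng.random(size)
    return 1 + np.searchsorted(cdf, u)


def random_go_dag(
    n_terms: int, depth: int, namespace: str, rng, id_offset: int
) -> tuple[nx.MultiDiGraph, list[str]]:
    """A rooted random DAG of GO-style terms; returns (graph, leaf-term pool).

    Terms are spread over ``depth`` levels below one root; each term gets 1-2
    parents from the level above (is_a edges, child -> parent). The leaf pool
    is the deepest two levels, used for direct gene annotation.
    """
    ns_long = NAMESPACE_LONG[namespace]
    ids = [f"GO:{id_offset + i:07d}" for i in range(n_terms)]
    dag = nx.MultiDiGraph()
    for t in ids:
        dag.add_node(t, name=f"{namespace.lower()} term {t[-5:]}", namespace=ns_long)
    # geometric level growth below a narrow top level, echoing the real GO
    # shape (few direct children of the root, most terms deep); multiple
    # inheritance makes root-only common ancestors rare
    n_levels = max(1, depth - 1)
    raw = np.array([4.0 * 2.5**k for k in range(n_levels)])
    sizes = np.maximum(1, np.round(raw * (n_terms - 1) / raw.sum()).astype(int))
    sizes[-1] += (n_terms - 1) - sizes.sum()
    levels: list[list[str]] = [[ids[0]]]
    cursor = 1
    for size in sizes:
        levels.append(ids[cursor : cursor + int(size)])
        cursor += int(size)
    for lvl in range(1, len(levels)):
        parents_pool = levels[lvl - 1]
        for term in levels[lvl]:
            n_par = 1 + int(rng.random() < 0.6)
            chosen = rng.choice(len(parents_pool), size=min(n_par, len(parents_pool)), replace=False)
            for ci in sorted(chosen.tolist()):
                dag.add_edge(term, parents_pool[ci], key="is_a")
    leaf_pool = [t for lvl in levels[-2:] for t in lvl] if len(levels) > 1 else ids
    return dag, leaf_pool


def _place_genes(cfg: SynthConfig, rng) -> list[sio.GeneModel]:
    genes = []
    for i in range(cfg.n_mrnas):
        chrom = str(int(rng.integers(1, cfg.n_chroms + 1)))
        length = int(rng.integers(5_000, 100_000))
        start = int(rng.integers(200_000, cfg.chrom_length - length - 200_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            sio.GeneModel(
                gene_id=f"G{i:05d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=start + length,
            )
        )
    return genes


def _place_snp(cfg, rng, genes, trees, category: str) -> tuple[str, int]:
    if category == "intragenic":
        g = genes[int(rng.integers(0, len(genes)))]
        return g.chrom, int(rng.integers(g.start, g.end + 1))
    for _ in range(1000):
        chrom = str(int(rng.integers(1, cfg.n_chroms + 1)))
        pos = int(rng.integers(1, cfg.chrom_length))
        tree = trees.get(chrom)
        if tree is None or not tree.overlaps_point(pos):
            return chrom, pos
    raise ConfigError("could not place an intergenic SNP; genome too dense")


def _pick_planted_pairs(
    rng,
    catalog: sio.DiseaseCatalog,
    n_pairs: int,
    used: set[str],
    what: str,
) -> list[tuple[str, str, str]]:
    """Same-disease pairs with >= 1 intergenic SNP and disjoint membership."""
    picked: list[tuple[str, str, str]] = []
    diseases = sorted(catalog.disease_to_snps)
    order = rng.permutation(len(diseases))
    for di in order:
        if len(picked) == n_pairs:
            break
        disease = diseases[di]
        members = sorted(catalog.disease_to_snps[disease] - used)
        inter = [s for s in members if catalog.snps[s].category == "intergenic"]
        other = [s for s in members if s not in inter]
        if not inter or len(members) < 2:
            continue
        a = inter[int(rng.integers(0, len(inter)))]
        partners = [s for s in (inter + other) if s != a]
        b = partners[int(rng.integers(0, len(partners)))]
        a, b = sorted((a, b))
        picked.append((a, b, disease))
        used.update({a, b})
    if len(picked) < n_pairs:
        raise ConfigError(
            f"could only place {len(picked)}/{n_pairs} planted {what} pairs; "
            "increase n_diseases or snps_per_disease"
        )
    return picked


def plant_regulatory_convergence(
    bundle: SyntheticBundle,
    pairs: list[tuple[str, str]],
    mechanisms: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticBundle:
    """Give each designated pair one shared regulatory property.

    Cycles through shared-TF, interacting-TFs (edge score >= 0.9) and paired
    long-range anchors unless explicit mechanisms are given.
    """
    rng = rng or np.random.default_rng(bundle.cfg.seed + 7)
    reg = bundle.regulatory
    positions = bundle.snp_positions
    for idx, (a, b) in enumerate(pairs):
        if a not in positions or b not in positions:
            raise KeyError(f"unknown rsid in regulatory planting: {(a, b)}")
        mech = (
            mechanisms[idx]
            if mechanisms is not None
            else REG_MECHANISMS[idx % len(REG_MECHANISMS)]
        )
        if mech == "shared_tf":
            tf = f"TFSHARE{idx:02d}"
            reg.snp_to_tfs.setdefault(a, set()).add(tf)
            reg.snp_to_tfs.setdefault(b, set()).add(tf)
        elif mech == "interacting_tfs":
            ta, tb = f"TFIA{idx:02d}", f"TFIB{idx:02d}"
            reg.snp_to_tfs.setdefault(a, set()).add(ta)
            reg.snp_to_tfs.setdefault(b, set()).add(tb)
            reg.tf_edges[tuple(sorted((ta, tb)))] = 0.95
        elif mech == "long_range":
            ca, pa = positions[a]
            cb, pb = positions[b]
            reg.anchor_pairs.append(
                sio.AnchorPair(
                    interaction_id=f"planted{idx:02d}",
                    chrom_a=ca,
                    start_a=max(1, pa - 500),
                    end_a=pa + 500,
                    chrom_b=cb,
                    start_b=max(1, pb - 500),
                    end_b=pb + 500,
                    mediator="POLR2A",
                )
            )
        else:
            raise ConfigError(f"unknown regulatory mechanism: {mech}")
        bundle.truth.regulatory[(a, b)] = mech
    return bundle


def _simulate_genotypes(
    cfg: SynthConfig, rng, snp_pool: list[str]
) -> tuple[sio.GenotypeStudy | None, tuple[str, str] | None]:
    gc = cfg.genotype
    n = gc.n_cases + gc.n_controls
    if n == 0 or len(snp_pool) < 2:
        return None, None
    pair = (snp_pool[0], snp_pool[1])
    extra = snp_pool[2 : 2 + gc.n_extra_snps]
    snp_ids = list(pair) + list(extra)
    geno = rng.binomial(2, gc.maf, size=(n, len(snp_ids))).astype(np.int8)
    g1 = geno[:, 0].astype(float)
    g2 = geno[:, 1].astype(float)
    if gc.planted_interaction == "xor":
        y = ((g1 > 0).astype(int) ^ (g2 > 0).astype(int)).astype(np.int8)
        if gc.xor_noise > 0:
            flip = rng.random(n) < gc.xor_noise
            y = np.where(flip, 1 - y, y).astype(np.int8)
    elif gc.planted_interaction == "multiplicative":
        prevalence = gc.n_cases / n
        b0 = math.log(prevalence / (1 - prevalence))
        b = math.log(gc.main_or)
        b3 = math.log(gc.interaction_ror)
        eta = b0 + b * g1 + b * g2 + b3 * g1 * g2
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int8)
    else:
        y = np.zeros(n, dtype=np.int8)
        y[: gc.n_cases] = 1
        y = rng.permutation(y)
    if len(np.unique(y)) < 2:  # degenerate draw; force one flip
        y[0] = 1 - y[0]
    study = sio.GenotypeStudy(
        genotypes=geno,
        phenotype=y,
        snp_ids=snp_ids,
        individual_ids=[f"ind{i:05d}" for i in range(n)],
    )
    return study, pair


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def generate_bundle(cfg: SynthConfig) -> SyntheticBundle:
    """Generate a complete synthetic input bundle from a validated config."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = _place_genes(cfg, rng)
    trees = sio.build_interval_trees(genes)
    mrna_ids = [f"M{i:05d}" for i in range(cfg.n_mrnas)]
    hosts = {m: g for m, g in zip(mrna_ids, genes)}

    # --- catalogue -----------------------------------------------------
    lo, hi = cfg.snps_per_disease
    snps: dict[str, sio.SnpRecord] = {}
    counter = 0
    for d in range(cfg.n_diseases):
        disease = f"D{d:03d}"
        size = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        size = max(1, size)
        for _ in range(size):
            existing = sorted(snps)
            if existing and rng.random() < cfg.snp_reuse_prob:
                rsid = existing[int(rng.integers(0, len(existing)))]
                snps[rsid].diseases.add(disease)
                continue
            category = (
                "intergenic" if rng.random() < cfg.intergenic_frac else "intragenic"
            )
            chrom, pos = _place_snp(cfg, rng, genes, trees, category)
            rsid = f"rs{counter:06d}"
            counter += 1
            rec = sio.SnpRecord(rsid=rsid, chrom=chrom, pos=pos)
            rec.category = category
            rec.diseases = {disease}
            snps[rsid] = rec
    catalog = sio.DiseaseCatalog(snps)
    snp_ids = sorted(snps)

    # --- eQTL network with planted structure ---------------------------
    kmax = max(1, int(cfg.n_mrnas * cfg.max_degree_frac))
    n_reserved = (
        cfg.n_planted_overlap_pairs * cfg.planted_overlap_size
        + cfg.n_planted_similarity_pairs * 2 * cfg.planted_similarity_degree
    )
    n_background = cfg.n_mrnas - n_reserved
    if n_background < kmax + 1:
        raise ConfigError("too many reserved planted mRNAs for n_mrnas")
    degrees = _truncated_power_law(rng, cfg.degree_exponent, kmax, len(snp_ids))
    weights = (np.arange(1, n_background + 1, dtype=float)) ** -cfg.mrna_weight_exponent
    weights /= weights.sum()
    edge_map: dict[str, set[int]] = {}
    for rsid, k in zip(snp_ids, degrees):
        targets = rng.choice(n_background, size=int(k), replace=False, p=weights)
        edge_map[rsid] = set(int(t) for t in targets)

    used: set[str] = set()
    truth = GroundTruth()
    reserved_cursor = n_background
    overlap_picks = _pick_planted_pairs(
        rng, catalog, cfg.n_planted_overlap_pairs, used, "overlap"
    )
    for a, b, disease in overlap_picks:
        shared = list(range(reserved_cursor, reserved_cursor + cfg.planted_overlap_size))
        reserved_cursor += cfg.planted_overlap_size
        edge_map[a].update(shared)
        edge_map[b].update(shared)
        truth.pairs.append(PlantedPair(a, b, "overlap", disease))

    sim_picks = _pick_planted_pairs(
        rng, catalog, cfg.n_planted_similarity_pairs, used, "similarity"
    )
    planted_term_sets: dict[str, list[tuple[int, int]]] = {"MF": [], "BP": []}
    for idx, (a, b, disease) in enumerate(sim_picks):
        mech = "mf_sim" if idx % 2 == 0 else "bp_sim"
        k = cfg.planted_similarity_degree
        slots = list(range(reserved_cursor, reserved_cursor + 2 * k))
        reserved_cursor += 2 * k
        # disjoint dedicated gene sets; similarity comes from annotation only:
        # each of a's genes has an identically-annotated twin among b's, so a
        # chance null exceedance would need k simultaneous perfect matches
        edge_map[a] = set(slots[:k])
        edge_map[b] = set(slots[k:])
        ns = "MF" if mech == "mf_sim" else "BP"
        for j in range(k):
            planted_term_sets[ns].append((slots[j], slots[k + j]))
        truth.pairs.append(PlantedPair(a, b, mech, disease))

    rows = []
    for rsid in snp_ids:
        for t in sorted(edge_map[rsid]):
            p = 10.0 ** rng.uniform(-12, math.log10(cfg.eqtl_p_cutoff))
            rows.append((rsid, mrna_ids[t], p))
    eqtl = sio.EqtlNetwork(
        pd.DataFrame(rows, columns=["rsid", "mrna_id", "p_value"]),
        p_cutoff=cfg.eqtl_p_cutoff,
    )
    sio.annotate_cis_trans(eqtl, {r: (s.chrom, s.pos) for r, s in snps.items()}, hosts)

    # --- ontologies + annotations --------------------------------------
    ontologies: dict[str, nx.MultiDiGraph] = {}
    annotations: dict[str, dict[str, set[str]]] = {}
    for ns, offset in (("MF", 1_000_000), ("BP", 2_000_000)):
        dag, leaf_pool = random_go_dag(cfg.n_go_terms, cfg.dag_depth, ns, rng, offset)
        ontologies[ns] = dag
        ann: dict[str, set[str]] = {}
        t_lo, t_hi = cfg.terms_per_gene
        for m in mrna_ids:
            if rng.random() >= cfg.annotated_frac:
                continue
            k = int(rng.integers(t_lo, t_hi + 1))
            chosen = rng.choice(len(leaf_pool), size=min(k, len(leaf_pool)), replace=False)
            ann[m] = {leaf_pool[c] for c in sorted(chosen.tolist())}
        # planted similarity: matched genes share identical direct term sets
        for slot_a, slot_b in planted_term_sets[ns]:
            chosen = rng.choice(len(leaf_pool), size=min(2, len(leaf_pool)), replace=False)
            terms = {leaf_pool[c] for c in sorted(chosen.tolist())}
            ann[mrna_ids[slot_a]] = set(terms)
            ann[mrna_ids[slot_b]] = set(terms)
        annotations[ns] = ann

    # --- LD blocks ------------------------------------------------------
    ld = sio.LdTable()
    planted_snps = {s for p in truth.pairs for s in (p.rsid_a, p.rsid_b)}
    by_chrom: dict[str, list[str]] = {}
    for rsid in snp_ids:
        if rsid in planted_snps:
            continue
        by_chrom.setdefault(snps[rsid].chrom, []).append(rsid)
    eligible_chroms = sorted(c for c, v in by_chrom.items() if len(v) >= 2)
    for _ in range(cfg.ld_block_count):
        if not eligible_chroms:
            break
        chrom = eligible_chroms[int(rng.integers(0, len(eligible_chroms)))]
        members = by_chrom[chrom]
        size = int(rng.integers(2, min(4, len(members)) + 1))
        block_idx = rng.choice(len(members), size=size, replace=False)
        block = sorted(members[i] for i in block_idx)
        for i, a in enumerate(block):
            for b in block[i + 1 :]:
                ld.set(a, b, float(rng.uniform(0.8, 0.99)))
    n_weak = max(1, len(snp_ids) // 10)
    for _ in range(n_weak):
        i, j = rng.choice(len(snp_ids), size=2, replace=False)
        a, b = sorted((snp_ids[i], snp_ids[j]))
        if a in planted_snps and b in planted_snps:
            continue
        if ld.get(a, b) == 0.0:
            ld.set(a, b, float(rng.uniform(0.0, 0.3)))

    # --- regulatory annotations ----------------------------------------
    reg = sio.RegulatoryAnnotation()
    tf_pool = [f"TF{i:02d}" for i in range(25)]
    for rsid in snp_ids:
        if rng.random() < 0.6:
            k = int(rng.integers(1, 4))
            chosen = rng.choice(len(tf_pool), size=k, replace=False)
            reg.snp_to_tfs[rsid] = {tf_pool[c] for c in sorted(chosen.tolist())}
    for _ in range(30):
        i, j = sorted(rng.choice(len(tf_pool), size=2, replace=False).tolist())
        reg.tf_edges[(tf_pool[i], tf_pool[j])] = float(rng.uniform(0.4, 1.0))
    for i in range(10):
        ca = str(int(rng.integers(1, cfg.n_chroms + 1)))
        cb = str(int(rng.integers(1, cfg.n_chroms + 1)))
        sa = int(rng.integers(1, cfg.chrom_length - 10_000))
        sb = int(rng.integers(1, cfg.chrom_length - 10_000))
        reg.anchor_pairs.append(
            sio.AnchorPair(f"bg{i:02d}", ca, sa, sa + 5_000, cb, sb, sb + 5_000, "CTCF")
        )
    proxy_counter = 0
    for rsid in snp_ids:
        if rng.random() < 0.2:
            for _ in range(int(rng.integers(1, 3))):
                proxy = f"rsP{proxy_counter:05d}"
                proxy_counter += 1
                rec = snps[rsid]
                ppos = max(1, rec.pos + int(rng.integers(-50_000, 50_000)))
                reg.ld_proxies.setdefault(rsid, set()).add(proxy)
                reg.proxy_pos[proxy] = (rec.chrom, ppos)
                if rng.random() < 0.5:
                    k = int(rng.integers(1, 3))
                    chosen = rng.choice(len(tf_pool), size=k, replace=False)
                    reg.snp_to_tfs[proxy] = {tf_pool[c] for c in sorted(chosen.tolist())}

    # --- genotypes ------------------------------------------------------
    epi_pool = (
        [truth.pairs[0].rsid_a, truth.pairs[0].rsid_b] if truth.pairs else snp_ids[:2]
    )
    epi_pool = epi_pool + [s for s in snp_ids if s not in epi_pool]
    genotypes, epi_pair = _simulate_genotypes(cfg, rng, epi_pool)
    truth.epistasis_snps = epi_pair
    truth.epistasis_model = cfg.genotype.planted_interaction
    truth.epistasis_ror = cfg.genotype.interaction_ror

    bundle = SyntheticBundle(
        cfg=cfg,
        catalog=catalog,
        eqtl=eqtl,
        genes=genes,
        ontologies=ontologies,
        annotations=annotations,
        ld=ld,
        regulatory=reg,
        genotypes=genotypes,
        truth=truth,
    )
    if cfg.plant_regulatory and truth.pairs:
        plant_regulatory_convergence(
            bundle,
            [(p.rsid_a, p.rsid_b) for p in truth.pairs],
            rng=np.random.default_rng(cfg.seed + 7),
        )
    return bundle


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Emit the exact file formats the readers consume, plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {
        "catalog": outdir / "catalog.tsv",
        "eqtl": outdir / "eqtl.tsv",
        "genes": outdir / "genes.bed",
        "ld": outdir / "ld.tsv",
        "obo_mf": outdir / "ontology_mf.obo",
        "obo_bp": outdir / "ontology_bp.obo",
        "ann_mf": outdir / "annotations_mf.tsv",
        "ann_bp": outdir / "annotations_bp.tsv",
        "manifest": outdir / "manifest.yaml",
        "truth": outdir / "truth.yaml",
    }
    sio.write_catalog(bundle.catalog, paths["catalog"])
    sio.write_eqtl(bundle.eqtl, paths["eqtl"])
    sio.write_gene_models(bundle.genes, paths["genes"])
    sio.write_ld(bundle.ld, paths["ld"])
    sio.write_obo(bundle.ontologies["MF"], paths["obo_mf"], "MF")
    sio.write_obo(bundle.ontologies["BP"], paths["obo_bp"], "BP")
    sio.write_annotations(bundle.annotations["MF"], paths["ann_mf"])
    sio.write_annotations(bundle.annotations["BP"], paths["ann_bp"])
    paths.update(sio.write_regulatory(bundle.regulatory, outdir / "regulatory"))
    if bundle.genotypes is not None:
        paths["genotypes"] = outdir / "genotypes.tsv"
        sio.write_genotypes(bundle.genotypes, paths["genotypes"])
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(
            {
                "pairs": [
                    {
                        "rsid_a": p.rsid_a,
                        "rsid_b": p.rsid_b,
                        "mechanism": p.mechanism,
                        "disease": p.disease,
                    }
                    for p in bundle.truth.pairs
                ],
                "epistasis": {
                    "snps": list(bundle.truth.epistasis_snps or []),
                    "model": bundle.truth.epistasis_model,
                    "ror": bundle.truth.epistasis_ror,
                },
                "regulatory": {
                    f"{a}|{b}": m for (a, b), m in sorted(bundle.truth.regulatory.items())
                },
            },
            fh,
            sort_keys=True,
        )
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(
            {"config": dataclasses.asdict(bundle.cfg), "seed": bundle.cfg.seed},
            fh,
            sort_keys=True,
        )
    return paths
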