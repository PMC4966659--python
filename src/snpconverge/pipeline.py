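"""End-to-end orchestration: load -> pair -> score -> null -> FDR ->
prioritise -> enrich (-> epistasis), from a single validated config.

Reproducibility: one global seed is fanned out deterministically per stage
(child seeds from numpy SeedSequence spawning), so re-running a single stage
from persisted intermediates matches the full run. Every output file carries
the config hash in the run metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from snpconverge import io as sio
from snpconverge.enrichment import (
    ContingencyResult,
    disease_enrichment,
    regulatory_enrichment,
)
from snpconverge.epistasis import InteractionResult, evaluate_pair
from snpconverge.errors import ConfigError
from snpconverge.pairing import (
    SnpPair,
    enumerate_pairs,
    pairs_to_frame,
    stratify_pairs,
)
from snpconverge.permutation import attach_qvalues, empirical_pvalues, prioritise
from snpconverge.similarity import OntologyCorpus, PairScore, compute_ic
from snpconverge.synth import SynthConfig, SyntheticBundle, generate_bundle

logger = logging.getLogger(__name__)

STAGES = (
    "load",
    "pair",
    "score",
    "fdr",
    "prioritise",
    "enrich",
    "epistasis",
)


@dataclass
class RunConfig:
    """All knobs of one analysis run; serialised verbatim into run metadata."""

    # inputs: either file paths ...
    catalog_path: str | None = None
    eqtl_path: str | None = None
    genes_path: str | None = None
    obo_mf_path: str | None = None
    obo_bp_path: str | None = None
    ann_mf_path: str | None = None
    ann_bp_path: str | None = None
    ld_path: str | None = None
    tf_path: str | None = None
    tf_edge_path: str | None = None
    anchor_path: str | None = None
    proxy_path: str | None = None
    genotype_path: str | None = None
    # ... or a synthetic bundle
    synth: SynthConfig | None = None
    # thresholds (documented ranges per the study design)
    eqtl_p_cutoff: float = 1e-4
    min_mrnas: int = 1
    r2_max: float = 0.8
    fdr_max: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    kernel: str = "lin"  # lin | resnik_norm
    aggregation: str = "bma"  # bma | mean
    p_mode: str = "raw"  # raw | add_one
    statistics: tuple[str, ...] = ("overlap", "mf", "bp")
    categories: tuple[str, ...] = ("inter-inter", "inter-intra")
    use_proxies: bool = True
    epistasis_n_perm: int = 1000
    out_dir: str | None = None

    def validate(self) -> None:
        if self.synth is None and (self.catalog_path is None or self.eqtl_path is None):
            raise ConfigError(
                "config needs either a synth block or catalog+eQTL input paths"
            )
        if not 1e-6 <= self.eqtl_p_cutoff <= 1e-4:
            logger.warning(
                "eqtl_p_cutoff %g outside the documented 1e-6..1e-4 range",
                self.eqtl_p_cutoff,
            )
        if self.min_mrnas < 1:
            raise ConfigError("min_mrnas must be >= 1")
        if not 0.0 < self.r2_max <= 1.0:
            raise ConfigError("r2_max must be in (0, 1]")
        if not 0.0 < self.fdr_max < 1.0:
            raise ConfigError("fdr_max must be in (0, 1)")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.p_mode not in {"raw", "add_one"}:
            raise ConfigError(f"unknown p_mode {self.p_mode}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        synth = data.pop("synth", None)
        cfg = cls(**data)
        if synth is not None:
            geno = synth.pop("genotype", None)
            from snpconverge.synth import GenotypeConfig

            sc = SynthConfig(**synth)
            if geno is not None:
                sc.genotype = GenotypeConfig(**geno)
            cfg.synth = sc
        for attr in ("statistics", "categories"):
            setattr(cfg, attr, tuple(getattr(cfg, attr)))
        return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PipelineResult:
    config: RunConfig
    catalog: sio.DiseaseCatalog
    eqtl: sio.EqtlNetwork
    corpora: dict[str, OntologyCorpus]
    pairs: list[SnpPair]
    scores: list[PairScore]
    prioritised: list[PairScore]
    disease_enrichment: ContingencyResult | None = None
    regulatory_enrichment: dict | None = None
    epistasis: dict[tuple[str, str], InteractionResult] = field(default_factory=dict)
    bundle: SyntheticBundle | None = None
    stage_log: list[str] = field(default_factory=list)


def _load_inputs(config: RunConfig):
    if config.synth is not None:
        bundle = generate_bundle(config.synth)
        corpora = {
            ns: compute_ic(
                bundle.annotations[ns],
                bundle.ontologies[ns],
                ns,
                kernel=config.kernel,
                aggregation=config.aggregation,
            )
            for ns in ("MF", "BP")
        }
        return (
            bundle.catalog,
            bundle.eqtl,
            corpora,
            bundle.ld,
            bundle.regulatory,
            bundle.genotypes,
            bundle,
        )
    catalog = sio.load_catalog(config.catalog_path)
    eqtl = sio.load_eqtl(config.eqtl_path, p_cutoff=config.eqtl_p_cutoff)
    genes = sio.load_gene_models(config.genes_path) if config.genes_path else []
    if genes:
        sio.classify_catalog(catalog, genes)
        # host lookup by mRNA id: gene ids directly, plus the M<idx> <-> G<idx>
        # naming convention of synthetic bundles
        hosts = {g.gene_id: g for g in genes}
        hosts.update(
            {
                f"M{g.gene_id[1:]}": g
                for g in genes
                if g.gene_id.startswith("G") and g.gene_id[1:].isdigit()
            }
        )
        sio.annotate_cis_trans(
            eqtl, {r: (s.chrom, s.pos) for r, s in catalog.snps.items()}, hosts
        )
    else:
        for rec in catalog.snps.values():
            rec.category = "intergenic"
        logger.warning("no gene models supplied; all SNPs treated as intergenic")
    corpora = {}
    for ns, obo_path, ann_path in (
        ("MF", config.obo_mf_path, config.ann_mf_path),
        ("BP", config.obo_bp_path, config.ann_bp_path),
    ):
        if obo_path and ann_path:
            dag = sio.load_obo(obo_path)
            ann = sio.load_annotations(ann_path, namespace=ns)
            corpora[ns] = compute_ic(
                dag=dag,
                annotations=ann,
                namespace=ns,
                kernel=config.kernel,
                aggregation=config.aggregation,
            )
    ld = sio.load_ld(config.ld_path) if config.ld_path else sio.LdTable()
    reg = sio.load_regulatory(
        tf_path=config.tf_path,
        tf_edge_path=config.tf_edge_path,
        anchor_path=config.anchor_path,
        proxy_path=config.proxy_path,
    )
    genotypes = (
        sio.load_genotypes(config.genotype_path) if config.genotype_path else None
    )
    return catalog, eqtl, corpora, ld, reg, genotypes, None


def run(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline; stage failures abort with the stage name."""
    config.validate()
    log: list[str] = []

    def record(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        log.append(line)
        logger.info(line)

    stage = "load"
    try:
        catalog, eqtl, corpora, ld, reg, genotypes, bundle = _load_inputs(config)
        record(
            stage,
            f"{len(catalog)} SNPs, {len(catalog.disease_to_snps)} diseases, "
            f"{eqtl.n_edges} eQTL edges",
        )

        stage = "pair"
        statistics = tuple(config.statistics)
        wanted = {s for s in catalog.snps if eqtl.snp_degree.get(s, 0) >= 1}
        candidates = {s: catalog.snps[s] for s in wanted}
        pairs = enumerate_pairs(
            candidates, ld, r2_max=config.r2_max, keep=set(config.categories)
        )
        pairs = stratify_pairs(pairs, eqtl, min_mrnas=config.min_mrnas)
        record(stage, f"{len(pairs)} candidate pairs after LD/category/degree filters")

        stage = "score"
        need_corpora = {"mf", "bp"} & set(statistics)
        scores = empirical_pvalues(
            pairs,
            statistics,
            eqtl,
            corpora if need_corpora else None,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, "null"),
            p_mode=config.p_mode,
        )
        record(stage, f"{len(scores)} pairs scored, n_perm={config.n_perm}")

        stage = "fdr"
        attach_qvalues(scores)
        record(stage, "BH q-values attached per method")

        stage = "prioritise"
        prioritised = prioritise(scores, fdr_max=config.fdr_max)
        record(stage, f"{len(prioritised)} prioritised pairs at FDR<{config.fdr_max}")

        stage = "enrich"
        dis = disease_enrichment(pairs, prioritised)
        record(
            stage,
            f"disease enrichment OR={dis.odds_ratio:.3g} p={dis.p_value:.3g}",
        )
        reg_enrich = None
        if reg and (reg.snp_to_tfs or reg.anchor_pairs):
            positions = {r: (s.chrom, s.pos) for r, s in catalog.snps.items()}
            reg_enrich = regulatory_enrichment(
                pairs, prioritised, reg, positions, use_proxies=config.use_proxies
            )
            record(stage, "regulatory enrichment computed for 3 predicates")

        stage = "epistasis"
        epistasis: dict[tuple[str, str], InteractionResult] = {}
        if genotypes is not None:
            genotyped = set(genotypes.snp_ids)
            targets = [
                p for p in prioritised
                if p.pair.rsid_a in genotyped and p.pair.rsid_b in genotyped
            ]
            if not targets and bundle is not None and bundle.truth.epistasis_snps:
                a, b = bundle.truth.epistasis_snps
                targets = [s for s in scores if {s.pair.rsid_a, s.pair.rsid_b} == {a, b}]
            rng = np.random.default_rng(stage_seed(config.seed, "epistasis"))
            for s in targets:
                epistasis[s.pair.key] = evaluate_pair(
                    genotypes.column(s.pair.rsid_a),
                    genotypes.column(s.pair.rsid_b),
                    genotypes.phenotype,
                    n_perm=config.epistasis_n_perm,
                    seed=rng,
                )
            record(stage, f"epistasis evaluated for {len(epistasis)} pair(s)")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    result = PipelineResult(
        config=config,
        catalog=catalog,
        eqtl=eqtl,
        corpora=corpora,
        pairs=pairs,
        scores=scores,
        prioritised=prioritised,
        disease_enrichment=dis,
        regulatory_enrichment=reg_enrich,
        epistasis=epistasis,
        bundle=bundle,
        stage_log=log,
    )
    if config.out_dir:
        write_results(result, config.out_dir)
    return result


# ---------------------------------------------------------------------------
# result serialisation
# ---------------------------------------------------------------------------


def scores_to_frame(scores: list[PairScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rsid_a": [s.pair.rsid_a for s in scores],
            "rsid_b": [s.pair.rsid_b for s in scores],
            "category": [s.pair.category for s in scores],
            "same_disease": [s.pair.same_disease for s in scores],
            "overlap_count": [s.overlap_count for s in scores],
            "overlap_genes": [";".join(sorted(s.overlap_genes)) for s in scores],
            "mf_its": [s.mf_its for s in scores],
            "bp_its": [s.bp_its for s in scores],
            "p_overlap": [s.p_overlap for s in scores],
            "p_mf": [s.p_mf for s in scores],
            "p_bp": [s.p_bp for s in scores],
            "q_overlap": [s.q_overlap for s in scores],
            "q_mf": [s.q_mf for s in scores],
            "q_bp": [s.q_bp for s in scores],
            "prioritised": [s.prioritised for s in scores],
            "methods": [";".join(sorted(s.methods)) for s in scores],
        }
    )


def write_results(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    paths = {
        "pairs": out / "pairs.tsv",
        "scores": out / "scores.tsv",
        "prioritised": out / "prioritised.tsv",
        "enrichment": out / "enrichment.tsv",
        "metadata": out / "run_metadata.yaml",
        "log": out / "stages.log",
    }
    pairs_to_frame(result.pairs).to_csv(paths["pairs"], sep="\t", index=False)
    frame = scores_to_frame(result.scores)
    frame.to_csv(paths["scores"], sep="\t", index=False)
    frame[frame["prioritised"]].to_csv(paths["prioritised"], sep="\t", index=False)

    rows = []
    if result.disease_enrichment is not None:
        d = result.disease_enrichment
        rows.append(
            {
                "family": "disease",
                "predicate": "same_disease",
                "a": d.table[0, 0], "b": d.table[0, 1],
                "c": d.table[1, 0], "d": d.table[1, 1],
                "odds_ratio": d.odds_ratio,
                "sample_odds_ratio": d.sample_odds_ratio,
                "p_value": d.p_value,
                "degenerate": d.degenerate,
            }
        )
    if result.regulatory_enrichment:
        for pred, fams in result.regulatory_enrichment.items():
            for fam, r in fams.items():
                rows.append(
                    {
                        "family": fam,
                        "predicate": pred,
                        "a": r.table[0, 0], "b": r.table[0, 1],
                        "c": r.table[1, 0], "d": r.table[1, 1],
                        "odds_ratio": r.odds_ratio,
                        "sample_odds_ratio": r.sample_odds_ratio,
                        "p_value": r.p_value,
                        "degenerate": r.degenerate,
                    }
                )
    pd.DataFrame(rows).to_csv(paths["enrichment"], sep="\t", index=False)

    if result.epistasis:
        paths["epistasis"] = out / "epistasis.tsv"
        erows = []
        for (a, b), r in sorted(result.epistasis.items()):
            erows.append(
                {
                    "rsid_a": a, "rsid_b": b,
                    "ig_bits": r.ig_bits, "ig_perm_p": r.ig_perm_p,
                    "mdr_balanced_accuracy": r.mdr_balanced_accuracy,
                    "mdr_perm_p": r.mdr_perm_p,
                    "ror_i": r.ror_i, "ror_i_p": r.ror_i_p,
                    "converged": r.converged,
                    "extreme_or": r.extreme_or, "extreme_p": r.extreme_p,
                    "n_used": r.n_used, "n_dropped": r.n_dropped,
                }
            )
        pd.DataFrame(erows).to_csv(paths["epistasis"], sep="\t", index=False)

    with open(paths["metadata"], "w") as fh:
        yaml.safe_dump(
            {"config": cfg.to_dict(), "config_hash": cfg.config_hash},
            fh,
            sort_keys=True,
            default_flow_style=False,
        )
    with open(paths["log"], "w") as fh:
        fh.write("\n".join(result.stage_log) + "\n")
    return paths
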