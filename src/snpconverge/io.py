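"""Readers, writers and genomic classification for all pipeline inputs.

Coordinate convention: 1-based inclusive throughout (dbSNP/RefSeq style).
BED inputs (0-based half-open) are converted on read and back on write.
All tabular readers accept gzip-compressed files transparently (pandas
infers compression from the ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import obonet
import pandas as pd
from intervaltree import IntervalTree

from snpconverge.errors import EmptyCatalogError, RowParseError, SchemaError

logger = logging.getLogger(__name__)

HLA_CHROM = "6"
HLA_START = 29_000_000
HLA_END = 34_000_000

UPSTREAM_EXT = 2_000  # bp 5' of the TSS
DOWNSTREAM_EXT = 500  # bp 3' of the terminator
TRANS_DISTANCE = 4_000_000  # bp; at or beyond => trans


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SnpRecord:
    """A catalogued SNP with genomic classification and disease links."""

    rsid: str
    chrom: str
    pos: int
    category: str | None = None  # "intergenic" | "intragenic"
    diseases: set[str] = field(default_factory=set)
    hla_flag: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1, got {self.pos}")
        self.hla_flag = (
            str(self.chrom) == HLA_CHROM and HLA_START <= self.pos <= HLA_END
        )


@dataclass
class GeneModel:
    """A gene span with strand-aware promoter/terminator extension.

    The extension is 2,000 bp 5' of the transcription start site and 500 bp
    3' of the terminator; for minus-strand genes the TSS is the *end*
    coordinate, so "upstream" extends past ``end``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    ext_start: int = 0
    ext_end: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+":
            self.ext_start = max(1, self.start - UPSTREAM_EXT)
            self.ext_end = self.end + DOWNSTREAM_EXT
        else:
            self.ext_start = max(1, self.start - DOWNSTREAM_EXT)
            self.ext_end = self.end + UPSTREAM_EXT

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


class DiseaseCatalog:
    """Many-to-many disease <-> SNP map built from a GWAS-catalogue-like table."""

    def __init__(self, snps: dict[str, SnpRecord]):
        self.snps = snps
        self.disease_to_snps: dict[str, set[str]] = {}
        for rec in snps.values():
            for d in rec.diseases:
                self.disease_to_snps.setdefault(d, set()).add(rec.rsid)

    @property
    def n_associations(self) -> int:
        return sum(len(r.diseases) for r in self.snps.values())

    def __len__(self) -> int:
        return len(self.snps)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiseaseCatalog):
            return NotImplemented
        if set(self.snps) != set(other.snps):
            return False
        for rsid, rec in self.snps.items():
            o = other.snps[rsid]
            if (rec.chrom, rec.pos, rec.diseases) != (o.chrom, o.pos, o.diseases):
                return False
        return True


class EqtlNetwork:
    """Bipartite SNP <-> mRNA association network with per-node degrees.

    Edges are unique ``(rsid, mrna_id)`` pairs carrying the association
    p-value and an optional cis/trans label. Integer index arrays are built
    once and shared with the permutation machinery.
    """

    def __init__(self, edges: pd.DataFrame, p_cutoff: float = 1e-4):
        required = {"rsid", "mrna_id", "p_value"}
        missing = required - set(edges.columns)
        if missing:
            raise SchemaError(f"eQTL edge table missing column(s): {sorted(missing)}")
        if "cis_trans" not in edges.columns:
            edges = edges.assign(cis_trans=pd.NA)
        edges = edges.sort_values(["rsid", "mrna_id"], kind="mergesort").reset_index(
            drop=True
        )
        if edges.duplicated(["rsid", "mrna_id"]).any():
            raise ValueError("duplicate (rsid, mrna_id) edges")
        self.edges = edges
        self.p_cutoff = p_cutoff
        self.snp_ids: list[str] = sorted(edges["rsid"].unique())
        self.mrna_ids: list[str] = sorted(edges["mrna_id"].unique())
        self.snp_index = {s: i for i, s in enumerate(self.snp_ids)}
        self.mrna_index = {m: i for i, m in enumerate(self.mrna_ids)}
        self.edge_snp = edges["rsid"].map(self.snp_index).to_numpy(np.int64)
        self.edge_mrna = edges["mrna_id"].map(self.mrna_index).to_numpy(np.int64)
        self._gene_sets: dict[str, frozenset[str]] | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def snp_degree(self) -> dict[str, int]:
        counts = np.bincount(self.edge_snp, minlength=len(self.snp_ids))
        return {s: int(counts[i]) for s, i in self.snp_index.items()}

    @property
    def mrna_degree(self) -> dict[str, int]:
        counts = np.bincount(self.edge_mrna, minlength=len(self.mrna_ids))
        return {m: int(counts[i]) for m, i in self.mrna_index.items()}

    def genes_of(self, rsid: str) -> frozenset[str]:
        if self._gene_sets is None:
            sets: dict[str, set[str]] = {}
            for r, m in zip(self.edges["rsid"], self.edges["mrna_id"]):
                sets.setdefault(r, set()).add(m)
            self._gene_sets = {r: frozenset(v) for r, v in sets.items()}
        return self._gene_sets.get(rsid, frozenset())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EqtlNetwork):
            return NotImplemented
        a = self.edges[["rsid", "mrna_id", "p_value"]]
        b = other.edges[["rsid", "mrna_id", "p_value"]]
        return a.equals(b)


class LdTable:
    """Symmetric pairwise r-squared lookup; missing pairs read as 0 (unlinked)."""

    def __init__(self, entries: dict[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if entries:
            for (a, b), r2 in entries.items():
                self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 out of [0,1]: {r2}")
        self._r2[self._key(a, b)] = float(r2)

    def get(self, a: str, b: str) -> float:
        return self._r2.get(self._key(a, b), 0.0)

    def items(self):
        return self._r2.items()

    def __len__(self) -> int:
        return len(self._r2)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LdTable):
            return NotImplemented
        return self._r2 == other._r2


@dataclass
class AnchorPair:
    """One paired-anchor (ChIA-PET-like) long-range interaction record."""

    interaction_id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    mediator: str = "."


@dataclass
class RegulatoryAnnotation:
    """SNP-level regulatory context: TF binding, TF-TF edges, anchors, proxies."""

    snp_to_tfs: dict[str, set[str]] = field(default_factory=dict)
    tf_edges: dict[tuple[str, str], float] = field(default_factory=dict)
    anchor_pairs: list[AnchorPair] = field(default_factory=list)
    ld_proxies: dict[str, set[str]] = field(default_factory=dict)
    proxy_pos: dict[str, tuple[str, int]] = field(default_factory=dict)

    def tf_edge_score(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        return self.tf_edges.get(key, 0.0)


@dataclass
class GenotypeStudy:
    """Individuals x SNPs genotype codes {0,1,2; -1 missing} + binary phenotype."""

    genotypes: np.ndarray  # int8/int16, shape (n_individuals, n_snps)
    phenotype: np.ndarray  # 0/1 per individual
    snp_ids: list[str]
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.phenotype = np.asarray(self.phenotype)
        if self.genotypes.shape[0] != self.phenotype.size:
            raise ValueError("genotype/phenotype length mismatch")
        classes = set(np.unique(self.phenotype).tolist())
        if not classes == {0, 1}:
            raise ValueError("phenotype must contain both classes {0, 1}")

    def column(self, rsid: str) -> np.ndarray:
        return self.genotypes[:, self.snp_ids.index(rsid)]


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: set[str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=sorted(required))
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{what} table missing column(s): {sorted(missing)}")
    return df


def load_catalog(path: str | Path) -> DiseaseCatalog:
    """Read a disease <-> SNP catalogue TSV (columns rsid, chrom, pos, disease).

    Duplicate (rsid, disease) rows collapse to one association; rows with
    unparseable coordinates are reported and dropped.
    """
    df = _read_tsv(path, {"rsid", "chrom", "pos", "disease"}, "catalogue")
    if df.empty:
        raise EmptyCatalogError(f"catalogue {path} contains no associations")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos.isna() | (pos < 1)
    if bad.any():
        logger.warning(
            "dropping %d catalogue row(s) with unparseable coordinates", int(bad.sum())
        )
        df = df[~bad]
        pos = pos[~bad]
    if df.empty:
        raise EmptyCatalogError(f"catalogue {path}: no rows with valid coordinates")
    df = df.assign(pos=pos.astype(int)).drop_duplicates(["rsid", "disease"])
    snps: dict[str, SnpRecord] = {}
    for row in df.itertuples(index=False):
        rec = snps.get(row.rsid)
        if rec is None:
            rec = SnpRecord(rsid=row.rsid, chrom=str(row.chrom), pos=int(row.pos))
            snps[row.rsid] = rec
        rec.diseases.add(row.disease)
    return DiseaseCatalog(snps)


def load_eqtl(path: str | Path, p_cutoff: float = 1e-4) -> EqtlNetwork:
    """Read a SNP -> mRNA eQTL table (columns rsid, mrna_id, p_value).

    Edges with p <= ``p_cutoff`` are retained; duplicate edges keep the most
    significant (smallest) p-value.
    """
    df = _read_tsv(path, {"rsid", "mrna_id", "p_value"}, "eQTL")
    # Python's float() round-trips repr exactly (pandas' fast parser can be
    # off by one ulp), keeping write/load round-trips bit-identical
    vals = np.empty(len(df))
    for i, s in enumerate(df["p_value"].astype(str)):
        try:
            vals[i] = float(s)
        except ValueError:
            raise RowParseError(
                f"{path}: non-numeric p_value at line {i + 2}"  # header = line 1
            ) from None
    df = df.assign(p_value=vals)
    df = df[df["p_value"] <= p_cutoff]
    if df.empty:
        logger.warning("eQTL network empty after filtering at p <= %g", p_cutoff)
    keep_cols = ["rsid", "mrna_id", "p_value"] + (
        ["cis_trans"] if "cis_trans" in df.columns else []
    )
    df = (
        df[keep_cols]
        .sort_values(["rsid", "mrna_id", "p_value"], kind="mergesort")
        .drop_duplicates(["rsid", "mrna_id"], keep="first")
        .reset_index(drop=True)
    )
    return EqtlNetwork(df, p_cutoff=p_cutoff)


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (0-based half-open) or GFF3 (1-based)."""
    path = Path(path)
    suffixes = {s.lower() for s in path.suffixes}
    if ".bed" in suffixes:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str},
        )
        return [
            GeneModel(
                gene_id=str(r.name),
                chrom=str(r.chrom),
                strand=str(r.strand),
                start=int(r.start) + 1,  # BED -> 1-based inclusive
                end=int(r.end),
            )
            for r in df.itertuples(index=False)
        ]
    if ".gff" in suffixes or ".gff3" in suffixes:
        genes: list[GeneModel] = []
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9 or fields[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID") or attrs.get("gene_id") or fields[8]
                genes.append(
                    GeneModel(
                        gene_id=gene_id,
                        chrom=fields[0],
                        strand=fields[6],
                        start=int(fields[3]),
                        end=int(fields[4]),
                    )
                )
        return genes
    raise ValueError(f"unrecognised gene-model format: {path}")


def build_interval_trees(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees over *extended* gene spans."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.ext_start, g.ext_end + 1, g.gene_id
        )
    return trees


def classify_snp(
    snp: SnpRecord, trees: dict[str, IntervalTree]
) -> str:
    """Classify a SNP as intragenic iff it falls within >= 1 extended gene span."""
    tree = trees.get(snp.chrom)
    if tree is None:
        logger.warning(
            "SNP %s on chromosome %s absent from gene set; calling intergenic",
            snp.rsid,
            snp.chrom,
        )
        return "intergenic"
    return "intragenic" if tree.overlaps_point(snp.pos) else "intergenic"


def classify_catalog(catalog: DiseaseCatalog, genes: list[GeneModel]) -> None:
    """Assign the intergenic/intragenic category to every catalogue SNP in place."""
    trees = build_interval_trees(genes)
    for rec in catalog.snps.values():
        rec.category = classify_snp(rec, trees)


def label_cis_trans(snp_pos: int, mrna_tss: int, same_chrom: bool) -> str:
    """A SNP-mRNA link is trans iff on different chromosomes or >= 4 Mb apart."""
    if not same_chrom:
        return "trans"
    return "trans" if abs(snp_pos - mrna_tss) >= TRANS_DISTANCE else "cis"


def annotate_cis_trans(
    network: EqtlNetwork,
    snp_positions: dict[str, tuple[str, int]],
    mrna_hosts: dict[str, GeneModel],
) -> None:
    """Fill the cis/trans column from SNP positions and host-gene TSSs.

    Distance is measured to the extended-model TSS of the gene hosting the
    mRNA; mRNAs without a model are labelled trans with a warning.
    """
    labels = []
    warned = 0
    for row in network.edges.itertuples(index=False):
        chrom_pos = snp_positions.get(row.rsid)
        host = mrna_hosts.get(row.mrna_id)
        if chrom_pos is None or host is None:
            warned += 1
            labels.append("trans")
            continue
        chrom, pos = chrom_pos
        labels.append(label_cis_trans(pos, host.tss, str(chrom) == str(host.chrom)))
    if warned:
        logger.warning("no host gene model for %d edge(s); labelled trans", warned)
    network.edges["cis_trans"] = labels


def load_ld(path: str | Path) -> LdTable:
    """Read a pairwise LD table (columns rsid_a, rsid_b, r2)."""
    df = _read_tsv(path, {"rsid_a", "rsid_b", "r2"}, "LD")
    table = LdTable()
    for row in df.itertuples(index=False):
        table.set(row.rsid_a, row.rsid_b, float(row.r2))
    return table


def load_obo(path: str | Path):
    """Read an OBO 1.2 ontology into a networkx graph (edges child -> parent)."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return obonet.read_obo(fh)
    return obonet.read_obo(str(path))


def load_annotations(
    path: str | Path, namespace: str | None = None
) -> dict[str, set[str]]:
    """Read gene -> GO-term annotations from a 2-column TSV or a GAF 2.x file.

    For GAF input the aspect column is respected: ``namespace`` "MF" keeps
    aspect F, "BP" keeps aspect P.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.readline()
    is_gaf = first.startswith("!") or len(first.split("\t")) >= 15
    annotations: dict[str, set[str]] = {}
    if is_gaf:
        aspect_wanted = {"MF": "F", "BP": "P"}.get(namespace or "", None)
        df = pd.read_csv(path, sep="\t", comment="!", header=None, dtype=str)
        for row in df.itertuples(index=False):
            gene, term, aspect = row[2], row[4], row[8]
            if aspect_wanted is not None and aspect != aspect_wanted:
                continue
            annotations.setdefault(str(gene), set()).add(str(term))
    else:
        df = _read_tsv(path, {"gene_id", "term"}, "annotation")
        for row in df.itertuples(index=False):
            annotations.setdefault(row.gene_id, set()).add(row.term)
    return annotations


def load_anchors(path: str | Path) -> list[AnchorPair]:
    """Read paired-anchor interval records from BEDPE (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    anchors = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = row[6] if len(row) > 6 else f"ix{i}"
        mediator = row[7] if len(row) > 7 else "."
        anchors.append(
            AnchorPair(
                interaction_id=str(name),
                chrom_a=str(row[0]),
                start_a=int(row[1]) + 1,
                end_a=int(row[2]),
                chrom_b=str(row[3]),
                start_b=int(row[4]) + 1,
                end_b=int(row[5]),
                mediator=str(mediator),
            )
        )
    return anchors


def load_regulatory(
    tf_path: str | Path | None = None,
    tf_edge_path: str | Path | None = None,
    anchor_path: str | Path | None = None,
    proxy_path: str | Path | None = None,
) -> RegulatoryAnnotation:
    """Assemble a RegulatoryAnnotation from its four optional component tables."""
    reg = RegulatoryAnnotation()
    if tf_path is not None:
        df = _read_tsv(tf_path, {"rsid", "tf"}, "SNP-TF")
        for row in df.itertuples(index=False):
            reg.snp_to_tfs.setdefault(row.rsid, set()).add(row.tf)
    if tf_edge_path is not None:
        df = _read_tsv(tf_edge_path, {"tf_a", "tf_b", "score"}, "TF-edge")
        for row in df.itertuples(index=False):
            a, b = sorted((row.tf_a, row.tf_b))
            if a == b:
                continue
            reg.tf_edges[(a, b)] = float(row.score)
    if anchor_path is not None:
        reg.anchor_pairs = load_anchors(anchor_path)
    if proxy_path is not None:
        df = _read_tsv(
            proxy_path, {"rsid", "proxy_rsid", "proxy_chrom", "proxy_pos"}, "LD-proxy"
        )
        for row in df.itertuples(index=False):
            reg.ld_proxies.setdefault(row.rsid, set()).add(row.proxy_rsid)
            reg.proxy_pos[row.proxy_rsid] = (str(row.proxy_chrom), int(row.proxy_pos))
    return reg


def load_genotypes(path: str | Path) -> GenotypeStudy:
    """Read a transposed genotype TSV: columns individual_id, phenotype, rsID...

    Genotype codes 0/1/2; anything unparseable becomes -1 (missing).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual_id", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"genotype table missing column(s): {sorted(missing)}")
    snp_ids = [c for c in df.columns if c not in required]
    geno = (
        df[snp_ids]
        .apply(pd.to_numeric, errors="coerce")
        .fillna(-1)
        .to_numpy(np.int8)
    )
    pheno = pd.to_numeric(df["phenotype"]).to_numpy(np.int8)
    return GenotypeStudy(
        genotypes=geno,
        phenotype=pheno,
        snp_ids=snp_ids,
        individual_ids=df["individual_id"].tolist(),
    )


def load_genotypes_vcf(
    vcf_path: str | Path, phenotype: dict[str, int]
) -> GenotypeStudy:
    """Read biallelic GT calls from a VCF; ``phenotype`` maps sample -> 0/1."""
    from cyvcf2 import VCF  # optional heavy import

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        gt = np.asarray(variant.gt_types, dtype=np.int8)  # 0,1,3=hom-alt,2=unknown
        col = np.where(gt == 3, 2, np.where(gt == 2, -1, gt))
        columns.append(col.astype(np.int8))
    geno = np.column_stack(columns)
    pheno = np.array([phenotype[s] for s in samples], dtype=np.int8)
    return GenotypeStudy(
        genotypes=geno, phenotype=pheno, snp_ids=snp_ids, individual_ids=samples
    )


# ---------------------------------------------------------------------------
# writers (canonical round-trip formats)
# ---------------------------------------------------------------------------


def write_catalog(catalog: DiseaseCatalog, path: str | Path) -> None:
    rows = [
        {"rsid": r.rsid, "chrom": r.chrom, "pos": r.pos, "disease": d}
        for r in sorted(catalog.snps.values(), key=lambda r: r.rsid)
        for d in sorted(r.diseases)
    ]
    pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "disease"]).to_csv(
        path, sep="\t", index=False
    )


def write_eqtl(network: EqtlNetwork, path: str | Path) -> None:
    network.edges.to_csv(path, sep="\t", index=False)


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    """Write BED6 (converting back to 0-based half-open)."""
    rows = [
        (g.chrom, g.start - 1, g.end, g.gene_id, 0, g.strand)
        for g in sorted(genes, key=lambda g: g.gene_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_ld(table: LdTable, path: str | Path) -> None:
    rows = [
        {"rsid_a": a, "rsid_b": b, "r2": r2}
        for (a, b), r2 in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"]).to_csv(
        path, sep="\t", index=False
    )


def write_annotations(annotations: dict[str, set[str]], path: str | Path) -> None:
    rows = [
        {"gene_id": g, "term": t}
        for g in sorted(annotations)
        for t in sorted(annotations[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term"]).to_csv(path, sep="\t", index=False)


def write_obo(graph, path: str | Path, namespace: str) -> None:
    """Write a minimal OBO 1.2 file (id/name/namespace/is_a stanzas)."""
    ns_long = {"MF": "molecular_function", "BP": "biological_process"}.get(
        namespace, namespace
    )
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(graph.nodes):
            data = graph.nodes[term]
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {data.get('name', term)}\n")
            fh.write(f"namespace: {data.get('namespace', ns_long)}\n")
            for _, parent, key in sorted(graph.out_edges(term, keys=True)):
                if key == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {key} {parent}\n")
            fh.write("\n")


def write_anchors(anchors: list[AnchorPair], path: str | Path) -> None:
    rows = [
        (
            a.chrom_a,
            a.start_a - 1,
            a.end_a,
            a.chrom_b,
            a.start_b - 1,
            a.end_b,
            a.interaction_id,
            a.mediator,
        )
        for a in anchors
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_regulatory(reg: RegulatoryAnnotation, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tf": outdir / "snp_tfs.tsv",
        "tf_edges": outdir / "tf_edges.tsv",
        "anchors": outdir / "anchors.bedpe",
        "proxies": outdir / "ld_proxies.tsv",
    }
    pd.DataFrame(
        [
            {"rsid": s, "tf": t}
            for s in sorted(reg.snp_to_tfs)
            for t in sorted(reg.snp_to_tfs[s])
        ],
        columns=["rsid", "tf"],
    ).to_csv(paths["tf"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"tf_a": a, "tf_b": b, "score": s}
            for (a, b), s in sorted(reg.tf_edges.items())
        ],
        columns=["tf_a", "tf_b", "score"],
    ).to_csv(paths["tf_edges"], sep="\t", index=False)
    write_anchors(reg.anchor_pairs, paths["anchors"])
    pd.DataFrame(
        [
            {
                "rsid": s,
                "proxy_rsid": p,
                "proxy_chrom": reg.proxy_pos[p][0],
                "proxy_pos": reg.proxy_pos[p][1],
            }
            for s in sorted(reg.ld_proxies)
            for p in sorted(reg.ld_proxies[s])
        ],
        columns=["rsid", "proxy_rsid", "proxy_chrom", "proxy_pos"],
    ).to_csv(paths["proxies"], sep="\t", index=False)
    return paths


def write_genotypes(study: GenotypeStudy, path: str | Path) -> None:
    ids = study.individual_ids or [f"ind{i}" for i in range(study.phenotype.size)]
    df = pd.DataFrame(study.genotypes, columns=study.snp_ids)
    df.insert(0, "phenotype", study.phenotype)
    df.insert(0, "individual_id", ids)
    df.to_csv(path, sep="\t", index=False)
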