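"""Candidate SNP-pair enumeration, LD exclusion and categorisation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from snpconverge.io import DiseaseCatalog, EqtlNetwork, LdTable, SnpRecord

logger = logging.getLogger(__name__)

CATEGORIES = ("inter-inter", "inter-intra", "intra-intra")
DEFAULT_R2_MAX = 0.8


def pair_category(cat_a: str, cat_b: str) -> str:
    n_inter = (cat_a == "intergenic") + (cat_b == "intergenic")
    return ("intra-intra", "inter-intra", "inter-inter")[n_inter]


@dataclass(frozen=True)
class SnpPair:
    """An unordered candidate pair; identity is the sorted rsID tuple."""

    rsid_a: str
    rsid_b: str
    category: str
    r2: float
    same_disease: bool
    shared_diseases: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.rsid_a < self.rsid_b:
            raise ValueError("pair members must be lexicographically ordered")

    @property
    def key(self) -> tuple[str, str]:
        return (self.rsid_a, self.rsid_b)


def make_pair(a: SnpRecord, b: SnpRecord, r2: float) -> SnpPair:
    if a.rsid > b.rsid:
        a, b = b, a
    shared = frozenset(a.diseases & b.diseases)
    return SnpPair(
        rsid_a=a.rsid,
        rsid_b=b.rsid,
        category=pair_category(a.category, b.category),
        r2=r2,
        same_disease=bool(shared),
        shared_diseases=shared,
    )


def enumerate_pairs(
    snps: dict[str, SnpRecord] | DiseaseCatalog,
    ld: LdTable,
    r2_max: float = DEFAULT_R2_MAX,
    keep: set[str] | None = None,
) -> list[SnpPair]:
    """All unordered SNP pairs with r2 < ``r2_max`` and category in ``keep``.

    SNPs are deduplicated by rsID before pairing; a pair is same-disease when
    the members' disease sets intersect (any shared disease counts).
    """
    if isinstance(snps, DiseaseCatalog):
        snps = snps.snps
    keep_set = set(keep) if keep is not None else set(CATEGORIES)
    records = sorted(snps.values(), key=lambda r: r.rsid)
    for rec in records:
        if rec.category is None:
            raise ValueError(f"SNP {rec.rsid} has no genomic category assigned")
    pairs: list[SnpPair] = []
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            r2 = ld.get(a.rsid, b.rsid)
            if r2 >= r2_max:
                continue
            pair = make_pair(a, b, r2)
            if pair.category in keep_set:
                pairs.append(pair)
    logger.info(
        "enumerated %d pairs from %d SNPs (r2 < %g, categories %s)",
        len(pairs),
        len(records),
        r2_max,
        sorted(keep_set),
    )
    return pairs


def stratify_pairs(
    pairs: list[SnpPair], eqtl: EqtlNetwork, min_mrnas: int = 1
) -> list[SnpPair]:
    """Retain pairs where both SNPs have eQTL degree >= ``min_mrnas``."""
    if min_mrnas < 1:
        raise ValueError("min_mrnas must be >= 1")
    degree = eqtl.snp_degree
    kept = [
        p
        for p in pairs
        if degree.get(p.rsid_a, 0) >= min_mrnas
        and degree.get(p.rsid_b, 0) >= min_mrnas
    ]
    logger.info(
        "stratified %d -> %d pairs at >= %d mRNA(s) per SNP",
        len(pairs),
        len(kept),
        min_mrnas,
    )
    return kept


def pairs_to_frame(pairs: list[SnpPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rsid_a": [p.rsid_a for p in pairs],
            "rsid_b": [p.rsid_b for p in pairs],
            "category": [p.category for p in pairs],
            "r2": [p.r2 for p in pairs],
            "same_disease": [p.same_disease for p in pairs],
            "shared_diseases": [
                ";".join(sorted(p.shared_diseases)) for p in pairs
            ],
        }
    )


def write_pairs(pairs: list[SnpPair], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[SnpPair]:
    df = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str})
    out = []
    for row in df.itertuples(index=False):
        shared = (
            frozenset(str(row.shared_diseases).split(";"))
            if isinstance(row.shared_diseases, str) and row.shared_diseases
            else frozenset()
        )
        out.append(
            SnpPair(
                rsid_a=row.rsid_a,
                rsid_b=row.rsid_b,
                category=row.category,
                r2=float(row.r2),
                same_disease=bool(row.same_disease),
                shared_diseases=shared,
            )
        )
    return out
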