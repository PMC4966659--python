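"""Disease-specificity and regulatory-property enrichment (one-sided Fisher).

Each enrichment builds a 2x2 table of pair counts — e.g. (same-disease vs
across-disease) x (prioritised vs non-prioritised) — and tests the "greater"
alternative with Fisher's exact test. The reported odds ratio is the
conditional maximum-likelihood estimate (the convention of R's fisher.test);
the sample cross-product OR with a Haldane 0.5 correction on zero cells is
kept as a secondary value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

from snpconverge.io import RegulatoryAnnotation
from snpconverge.pairing import SnpPair
from snpconverge.similarity import PairScore

logger = logging.getLogger(__name__)

TF_EDGE_MIN_SCORE = 0.9
PREDICATES = ("shared_tf", "interacting_tfs", "long_range")


@dataclass
class ContingencyResult:
    """A 2x2 count table with one-sided ("greater") Fisher results."""

    table: np.ndarray
    odds_ratio: float  # conditional MLE; inf when a zero cell forces it
    sample_odds_ratio: float  # cross-product with Haldane correction on zeros
    p_value: float
    sidedness: str = "greater"
    degenerate: bool = False  # a zero margin made the test uninformative (p=1)


def fisher_one_sided(table) -> ContingencyResult:
    """One-sided (greater) Fisher's exact test on a 2x2 table of counts."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer cells")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise ValueError(f"zero margin in {t.tolist()}: Fisher's test undefined")
    _, p = fisher_exact(t, alternative="greater")
    a, b, c, d = t.ravel()
    if b * c == 0 and a * d != 0:
        cmle = float("inf")
    else:
        cmle = float(_cmle_odds_ratio(t, kind="conditional").statistic)
    if b == 0 or c == 0 or a == 0 or d == 0:
        ah, bh, ch, dh = (x + 0.5 for x in (a, b, c, d))
        sample = float(ah * dh / (bh * ch))
    else:
        sample = float(a * d / (b * c))
    return ContingencyResult(
        table=t,
        odds_ratio=cmle,
        sample_odds_ratio=sample,
        p_value=float(p),
    )


def _pair_table(
    pairs: list[SnpPair],
    row_flags: dict[tuple[str, str], bool],
    prioritised: set[tuple[str, str]],
) -> np.ndarray:
    a = b = c = d = 0
    for p in pairs:
        in_row = row_flags[p.key]
        in_col = p.key in prioritised
        if in_row and in_col:
            a += 1
        elif in_row:
            b += 1
        elif in_col:
            c += 1
        else:
            d += 1
    return np.array([[a, b], [c, d]], dtype=np.int64)


def disease_enrichment(
    pairs: list[SnpPair], prioritised: set[tuple[str, str]] | list[PairScore]
) -> ContingencyResult:
    """(same-disease vs across-disease) x (prioritised vs non-prioritised).

    Degenerate tables (e.g. no prioritised pairs) return p = 1 with a warning
    instead of failing.
    """
    prioritised_keys = _as_keys(prioritised)
    table = _pair_table(
        pairs, {p.key: p.same_disease for p in pairs}, prioritised_keys
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("degenerate disease-enrichment table %s; p = 1", table.tolist())
        return ContingencyResult(
            table=table,
            odds_ratio=float("nan"),
            sample_odds_ratio=float("nan"),
            p_value=1.0,
            degenerate=True,
        )
    return fisher_one_sided(table)


def _as_keys(prioritised) -> set[tuple[str, str]]:
    keys = set()
    for item in prioritised:
        if isinstance(item, PairScore):
            keys.add(item.pair.key)
        elif isinstance(item, SnpPair):
            keys.add(item.key)
        else:
            keys.add(tuple(item))
    return keys


def _expanded(
    rsid: str,
    reg: RegulatoryAnnotation,
    positions: dict[str, tuple[str, int]],
    use_proxies: bool,
) -> tuple[set[str], set[str], list[tuple[str, int]]]:
    """(contributing rsids, TF union, positions) for a SNP and its LD proxies."""
    members = {rsid}
    if use_proxies:
        members |= reg.ld_proxies.get(rsid, set())
    tfs: set[str] = set()
    locs: list[tuple[str, int]] = []
    for m in sorted(members):
        tfs |= reg.snp_to_tfs.get(m, set())
        loc = positions.get(m) or reg.proxy_pos.get(m)
        if loc is not None:
            locs.append((str(loc[0]), int(loc[1])))
    return members, tfs, locs


def _in_interval(loc: tuple[str, int], chrom: str, start: int, end: int) -> bool:
    return loc[0] == str(chrom) and start <= loc[1] <= end


def regulatory_predicates(
    pair: SnpPair,
    reg: RegulatoryAnnotation,
    positions: dict[str, tuple[str, int]],
    use_proxies: bool = True,
) -> dict[str, bool]:
    """Evaluate the three shared-regulatory-property predicates for one pair.

    - ``shared_tf``: the two sides' TF sets intersect.
    - ``interacting_tfs``: two *distinct* TFs, one per side, joined by a
      TF-TF edge scoring >= 0.9.
    - ``long_range``: one side falls in anchor A and the other in anchor B
      of a single paired-anchor record (closed intervals, same chromosome);
      one contributing SNP (or proxy) is required per side.

    With ``use_proxies`` each side's TF and position sets are unioned over
    its strong-LD proxies (r2 >= 0.8).
    """
    _, tfs_a, locs_a = _expanded(pair.rsid_a, reg, positions, use_proxies)
    _, tfs_b, locs_b = _expanded(pair.rsid_b, reg, positions, use_proxies)
    if not (tfs_a or locs_a) and pair.rsid_a not in reg.snp_to_tfs:
        logger.debug("SNP %s absent from regulatory annotation", pair.rsid_a)
    if not (tfs_b or locs_b) and pair.rsid_b not in reg.snp_to_tfs:
        logger.debug("SNP %s absent from regulatory annotation", pair.rsid_b)
    shared_tf = bool(tfs_a & tfs_b)
    interacting = any(
        ta != tb and reg.tf_edge_score(ta, tb) >= TF_EDGE_MIN_SCORE
        for ta in tfs_a
        for tb in tfs_b
    )
    long_range = False
    for rec in reg.anchor_pairs:
        a_in_first = any(
            _in_interval(l, rec.chrom_a, rec.start_a, rec.end_a) for l in locs_a
        )
        b_in_second = any(
            _in_interval(l, rec.chrom_b, rec.start_b, rec.end_b) for l in locs_b
        )
        if a_in_first and b_in_second:
            long_range = True
            break
        a_in_second = any(
            _in_interval(l, rec.chrom_b, rec.start_b, rec.end_b) for l in locs_a
        )
        b_in_first = any(
            _in_interval(l, rec.chrom_a, rec.start_a, rec.end_a) for l in locs_b
        )
        if a_in_second and b_in_first:
            long_range = True
            break
    return {
        "shared_tf": shared_tf,
        "interacting_tfs": interacting,
        "long_range": long_range,
    }


def regulatory_enrichment(
    pairs: list[SnpPair],
    prioritised,
    reg: RegulatoryAnnotation,
    positions: dict[str, tuple[str, int]],
    use_proxies: bool = True,
) -> dict[str, dict[str, ContingencyResult]]:
    """Two enrichment families per predicate.

    Family I: (property shared vs not) x (prioritised vs non-prioritised).
    Family II: (same disease AND property shared vs rest) x (prioritised vs
    non-prioritised).
    """
    prioritised_keys = _as_keys(prioritised)
    flags = {
        p.key: regulatory_predicates(p, reg, positions, use_proxies) for p in pairs
    }
    out: dict[str, dict[str, ContingencyResult]] = {}
    for pred in PREDICATES:
        fam: dict[str, ContingencyResult] = {}
        for family, row_fn in (
            ("prioritised_vs_rest", lambda p: flags[p.key][pred]),
            (
                "same_disease_prioritised_vs_rest",
                lambda p: flags[p.key][pred] and p.same_disease,
            ),
        ):
            table = _pair_table(pairs, {p.key: row_fn(p) for p in pairs}, prioritised_keys)
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                logger.warning(
                    "degenerate regulatory table for %s/%s; p = 1", pred, family
                )
                fam[family] = ContingencyResult(
                    table=table,
                    odds_ratio=float("nan"),
                    sample_odds_ratio=float("nan"),
                    p_value=1.0,
                    degenerate=True,
                )
            else:
                fam[family] = fisher_one_sided(table)
        out[pred] = fam
    return out
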