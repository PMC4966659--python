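"""Genotype-level validation of prioritised pairs.

Four complementary views of SNP-SNP interaction on case/control data:

- interaction information (entropy, bits): I(g1,g2; y) - I(g1; y) - I(g2; y);
  positive values indicate synergy, negative antagonism.
- minimal MDR: the 3x3 genotype-combination grid is binned high/low risk by
  the training case:control ratio, generalisability estimated by stratified
  cross-validation and significance by phenotype-permutation testing.
- ROR_i: the exponentiated SNP x SNP interaction coefficient of an additive
  logistic model (optionally covariate-adjusted); > 1 synergy, < 1 antagonism.
- diametric allelic extremes: the case/control odds ratio contrasting the two
  opposite homozygote combinations, plus the full 3x3 allelic-combination OR
  grid.

Missing genotypes (< 0 codes) are dropped listwise per pair, PLINK-style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold

from snpconverge.enrichment import ContingencyResult, fisher_one_sided
from snpconverge.errors import ConvergenceError

logger = logging.getLogger(__name__)


@dataclass
class InteractionResult:
    """Joint summary of the genotype-level interaction statistics for a pair."""

    ig_bits: float = float("nan")
    ig_perm_p: float = float("nan")
    mdr_balanced_accuracy: float = float("nan")
    mdr_perm_p: float = float("nan")
    ror_i: float = float("nan")
    ror_i_p: float = float("nan")
    converged: bool = True
    extreme_or: float = float("nan")
    extreme_p: float = float("nan")
    or_grid: np.ndarray | None = None
    n_used: int = 0
    n_dropped: int = 0
    notes: list[str] = field(default_factory=list)


def _listwise(g1, g2, y):
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    y = np.asarray(y)
    keep = (g1 >= 0) & (g2 >= 0) & (y >= 0)
    return g1[keep], g2[keep], y[keep], int((~keep).sum())


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """I(X; Y) in bits from empirical joint frequencies of coded variables."""
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xv.size, yv.size))
    np.add.at(joint, (xi, yi), 1.0)
    return (
        _entropy(joint.sum(axis=1))
        + _entropy(joint.sum(axis=0))
        - _entropy(joint.ravel())
    )


def interaction_information(g1, g2, y) -> float:
    """IG = I(g1,g2; y) - I(g1; y) - I(g2; y), in bits.

    A constant genotype contributes 0 to every term (no error). Symmetric in
    its genotype arguments.
    """
    g1, g2, y, _ = _listwise(g1, g2, y)
    joint = g1.astype(np.int64) * 3 + g2.astype(np.int64)
    return (
        _mutual_information(joint, y)
        - _mutual_information(g1, y)
        - _mutual_information(g2, y)
    )


def explicit_epistasis_test(
    g1, g2, y, n_perm: int = 1000, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Permutation test of interaction information holding main effects fixed.

    Experimental. One locus's genotypes are shuffled *within phenotype
    strata*, preserving both marginal genotype-phenotype tables while
    breaking the three-way dependence. Returns (IG bits, add-one p).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g1, g2, y, _ = _listwise(g1, g2, y)
    observed = interaction_information(g1, g2, y)
    idx_case = np.flatnonzero(y == 1)
    idx_ctrl = np.flatnonzero(y == 0)
    exceed = 0
    g2p = g2.copy()
    for _ in range(n_perm):
        g2p[idx_case] = g2[idx_case][rng.permutation(idx_case.size)]
        g2p[idx_ctrl] = g2[idx_ctrl][rng.permutation(idx_ctrl.size)]
        if interaction_information(g1, g2p, y) >= observed - 1e-12:
            exceed += 1
    return observed, (1.0 + exceed) / (1.0 + n_perm)


def _mdr_cv_accuracy(
    combo: np.ndarray, y: np.ndarray, k_folds: int, rng_fold: int
) -> float:
    """Mean held-out balanced accuracy of the high/low-risk MDR grid."""
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=rng_fold)
    accs = []
    for train, test in skf.split(combo.reshape(-1, 1), y):
        ct, yt = combo[train], y[train]
        cases = np.bincount(ct[yt == 1], minlength=9).astype(float)
        ctrls = np.bincount(ct[yt == 0], minlength=9).astype(float)
        total_ratio = cases.sum() / max(ctrls.sum(), 1.0)
        # a cell is high-risk iff its case:control ratio strictly exceeds the
        # overall training ratio; ties and empty cells are low-risk
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ctrls > 0, cases / np.maximum(ctrls, 1e-300), np.inf)
        ratio = np.where((ctrls == 0) & (cases == 0), 0.0, ratio)
        high = ratio > total_ratio
        pred = high[combo[test]]
        yv = y[test]
        tp = np.count_nonzero(pred & (yv == 1))
        tn = np.count_nonzero(~pred & (yv == 0))
        n1 = np.count_nonzero(yv == 1)
        n0 = np.count_nonzero(yv == 0)
        sens = tp / n1 if n1 else 0.0
        spec = tn / n0 if n0 else 0.0
        accs.append(0.5 * (sens + spec))
    return float(np.mean(accs))


def mdr_test(
    g1,
    g2,
    y,
    k_folds: int = 10,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Minimal two-locus MDR with cross-validated permutation testing.

    Returns (balanced accuracy, permutation p). The permutation test repeats
    the full cross-validation on phenotype-shuffled copies; p uses the
    add-one convention (1+x)/(1+N).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g1, g2, y, _ = _listwise(g1, g2, y)
    combo = (np.asarray(g1, dtype=np.int64) * 3 + np.asarray(g2, dtype=np.int64))
    fold_seed = int(rng.integers(0, 2**31 - 1))
    observed = _mdr_cv_accuracy(combo, y, k_folds, fold_seed)
    exceed = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        if _mdr_cv_accuracy(combo, yp, k_folds, fold_seed) >= observed - 1e-12:
            exceed += 1
    return observed, (1.0 + exceed) / (1.0 + n_perm)


def ror_i(g1, g2, y, covariates=None) -> tuple[float, float, bool]:
    """Interaction odds-ratio ratio from additive logistic regression.

    Fits logit(y) = b0 + b1*g1 + b2*g2 + b3*g1*g2 (+ covariates) with
    genotypes coded 0/1/2 and returns (exp(b3), Wald p for b3, converged).
    Separation or non-convergence is flagged, never silently estimated.
    """
    g1, g2, y, _ = _listwise(g1, g2, y)
    cols = [np.asarray(g1, float), np.asarray(g2, float), np.asarray(g1, float) * np.asarray(g2, float)]
    names = ["g1", "g2", "g1xg2"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != len(y):
            cov = cov.T
        for k in range(cov.shape[1]):
            cols.append(cov[:, k])
            names.append(f"cov{k}")
    X = sm.add_constant(np.column_stack(cols))
    try:
        fit = sm.Logit(np.asarray(y, float), X).fit(disp=False, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and friends
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    beta3 = fit.params[3]
    p3 = fit.pvalues[3]
    converged = bool(fit.mle_retvals.get("converged", False)) and np.isfinite(
        fit.bse
    ).all()
    if not converged:
        logger.warning("ROR_i fit flagged non-converged (possible separation)")
    return float(np.exp(beta3)), float(p3), converged


def allelic_or_grid(g1, g2, y, haldane: bool = True) -> np.ndarray:
    """3x3 grid of allelic-combination ORs relative to the (0,0) reference.

    Entry (i, j) is the case/control odds of combination (g1=i, g2=j) over
    the odds of (0, 0); empty cells give NaN (or Haldane-corrected values
    when ``haldane``).
    """
    g1, g2, y, _ = _listwise(g1, g2, y)
    cases = np.zeros((3, 3))
    ctrls = np.zeros((3, 3))
    np.add.at(cases, (g1[y == 1], g2[y == 1]), 1.0)
    np.add.at(ctrls, (g1[y == 0], g2[y == 0]), 1.0)
    if haldane and ((cases == 0).any() or (ctrls == 0).any()):
        cases = cases + 0.5
        ctrls = ctrls + 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = cases / ctrls
        grid = odds / odds[0, 0]
    return grid


def allelic_extreme_or(
    g1, g2, y, extremes=((0, 0), (2, 2))
) -> ContingencyResult:
    """Fisher test contrasting the two diametric homozygote combinations.

    Builds the case/control 2x2 from the combinations in ``extremes``
    (default (0,0) vs (2,2)) and applies the one-sided test, with the second
    extreme as the exposed row.
    """
    g1, g2, y, _ = _listwise(g1, g2, y)
    (a1, a2), (b1, b2) = extremes
    ref = (g1 == a1) & (g2 == a2)
    alt = (g1 == b1) & (g2 == b2)
    table = np.array(
        [
            [np.count_nonzero(alt & (y == 1)), np.count_nonzero(alt & (y == 0))],
            [np.count_nonzero(ref & (y == 1)), np.count_nonzero(ref & (y == 0))],
        ],
        dtype=np.int64,
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        logger.warning("empty extreme homozygote cell; OR undefined")
        return ContingencyResult(
            table=table,
            odds_ratio=float("nan"),
            sample_odds_ratio=float("nan"),
            p_value=float("nan"),
            degenerate=True,
        )
    return fisher_one_sided(table)


def evaluate_pair(
    g1,
    g2,
    y,
    k_folds: int = 10,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    covariates=None,
) -> InteractionResult:
    """Run all four interaction analyses for one genotyped pair."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g1c, g2c, yc, dropped = _listwise(g1, g2, y)
    result = InteractionResult(n_used=len(yc), n_dropped=dropped)
    ig, ig_p = explicit_epistasis_test(g1c, g2c, yc, n_perm=n_perm, seed=rng)
    result.ig_bits = ig
    result.ig_perm_p = ig_p
    result.mdr_balanced_accuracy, result.mdr_perm_p = mdr_test(
        g1c, g2c, yc, k_folds=k_folds, n_perm=n_perm, seed=rng
    )
    try:
        result.ror_i, result.ror_i_p, result.converged = ror_i(
            g1c, g2c, yc, covariates=covariates
        )
    except ConvergenceError as exc:
        result.converged = False
        result.notes.append(str(exc))
    extreme = allelic_extreme_or(g1c, g2c, yc)
    result.extreme_or = extreme.sample_odds_ratio
    result.extreme_p = extreme.p_value
    result.or_grid = allelic_or_grid(g1c, g2c, yc)
    return result
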