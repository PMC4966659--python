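# Methods

## The statistical problem

Two GWAS lead SNPs may act through a common downstream mechanism even when
neither falls inside a gene: both may perturb the expression of the same
mRNAs, or of different mRNAs with the same molecular function or biological
process. The package quantifies this convergence per SNP pair and asks
whether it exceeds what the topology of the eQTL network alone would
produce.

The null model matters more than the statistic. SNP–mRNA networks are
heavy-tailed: a few hub mRNAs are associated with many SNPs, so two SNPs
share a hub target far more often than independence would suggest. A naive
resampling null is therefore anticonservative. The null used here rewires
the *entire* bipartite network while preserving every SNP degree and every
mRNA degree exactly, so each pair is judged against networks with identical
connectivity load everywhere.

## Pair statistics

**mRNA overlap** is |G(s₁) ∩ G(s₂)| over the eQTL edges at the configured
p-value cutoff (1e-4 by default; 1e-4…1e-6 is the documented range).

**GO similarity** is computed per namespace (MF and BP strictly separated):

- Term information content: annotations are propagated to all ancestors
  (true-path rule, is_a and part_of edges), and IC(t) = −ln(n_t / n), with
  n_t the number of genes annotated at or below t and n the number of
  annotated genes. IC(root) = 0.
- Term kernel: Lin, 2·IC(MICA)/(IC(t₁)+IC(t₂)), where MICA is the common
  ancestor with maximal IC. Lin is the default because the pair score must
  equal 1 for identical annotation profiles; normalised Resnik
  (IC(MICA)/IC_max) violates self-similarity = 1 and is available only as a
  config option. When both ICs are zero the similarity is 1 for identical
  terms and 0 otherwise.
- Gene similarity (GENE_ITS): symmetric best-match average over the two
  genes' *direct* term sets (propagation is used only for IC counting, the
  standard practice for IC-based measures). An all-pairs mean is available
  via config.
- SNP similarity (SNP_ITS): the same best-match average applied one level
  up, over the SNPs' annotated eQTL gene sets. Genes without annotation in
  a namespace cannot contribute a defined GENE_ITS and are excluded from
  G(s) for that namespace; if either side becomes empty the pair score is
  *undefined* (NA), not 0 — an absent signal must not masquerade as
  dissimilarity, and NA pairs are excluded from that method's
  multiple-testing family.

## Permutation null

The sampler runs one checkerboard-swap chain on the edge list: propose two
random edges (s₁,m₁),(s₂,m₂), swap to (s₁,m₂),(s₂,m₁) unless a duplicate
edge would arise. Rejected proposals count as attempts, making the chain a
symmetric Metropolis walk whose stationary distribution is uniform over the
fixed-margin 0/1 matrices (the state space is connected under such swaps).
Defaults: burn-in 20·E attempted swaps, then one sample every Q·E = 10·E
swaps, sequentially along one chain rather than restarting — the test suite
validates the resulting sampling distribution against exhaustive enumeration
of all degree-preserving edge sets on small networks. Degree conservation is
re-asserted after every draw and any violation is a hard failure.

All candidate pairs are evaluated on the *same* permuted network at each
iteration (the global-network reading of the resampling scheme); per-pair
independent resampling would be quadratically more expensive and would
discard the shared-topology control. The gene-level similarity matrix is
permutation-invariant and computed once; only the SNP→gene-set map is
resampled.

Empirical p-values count permutations with an equal-or-greater statistic
(ties are exceedances; a 1e-9 float guard covers summation-order noise).
Two conventions are provided:

- `raw` (default): p = x/N, the plain proportion. This is the convention the
  prioritisation needs in practice: a signal the null never reaches gets
  p = 0 and survives BH correction over tens of thousands (or millions) of
  pairs. With N = 2,000 permutations and m ≈ 10⁴ pairs, a p-value floor of
  1/(N+1) would make the smallest attainable q ≈ 0.5, and no planted signal
  could ever be declared.
- `add_one`: p = (1+x)/(1+N), never 0 and never above 1, for users who want
  a strictly valid p-value at the cost of the above.

A permuted draw whose similarity statistic is undefined (an unannotated gene
landed in a SNP's permuted set) is excluded from both numerator and
denominator for that pair. Counting such draws as non-exceedances while
dividing by the full N deflates p by the undefinedness rate (~5–10% under
the default 95% annotation coverage) and measurably breaks null calibration;
conditioning on defined draws restores uniformity.

BH FDR is applied independently per method (overlap, MF, BP) over the pairs
with defined p-values; a pair is prioritised when min(q) < fdr_max
(default 0.05), with per-method flags retained.

## Enrichment

2×2 tables of pair counts are tested one-sided ("greater") with Fisher's
exact test. The reported odds ratio is the conditional maximum-likelihood
estimate (the convention of R's `fisher.test`); the sample cross-product OR
with a Haldane 0.5 correction on zero cells is kept as a secondary value.
Degenerate tables (e.g. no prioritised pairs) return p = 1 with a warning.
Regulatory predicates: shared TF (TF-set intersection), interacting TFs
(distinct TFs joined by an edge scoring ≥ 0.9), and long-range anchors (one
side per anchor of a single paired record, closed intervals on the same
chromosome; a SNP covering both anchors alone does not count). With proxy
expansion each side's TF and position sets are unioned over its r² ≥ 0.8
proxies, and one contributing SNP-or-proxy is required per side.

## Epistasis

Genotypes are coded 0/1/2 with listwise deletion per pair. Interaction
information IG = I(g₁,g₂;y) − I(g₁;y) − I(g₂;y) in bits; positive values
indicate synergy. The MDR classifier labels each of the ≤9 genotype cells
high-risk iff its training case:control ratio strictly exceeds the overall
training ratio (ties and empty cells low-risk — the conservative,
deterministic convention; empty cells at test time predict low-risk);
generalisability is the mean held-out balanced accuracy over stratified
k-fold CV (balanced accuracy chosen because case:control ratios are rarely
1:1; configurable), and significance comes from phenotype-permutation with
the full CV repeated per permutation, p = (1+x)/(1+N). ROR_i is exp(β₃)
from logit(y) = β₀ + β₁g₁ + β₂g₂ + β₃g₁g₂ (+ covariates), with the Wald p
for β₃; separation or non-convergence is flagged, never silently estimated.
The "explicit test" holding main effects constant is implemented as
shuffling one locus within phenotype strata (this preserves both marginal
genotype–phenotype tables while breaking the three-way dependence) and is
flagged experimental. Diametric-extreme ORs contrast the (0,0) and (2,2)
homozygote combinations (configurable), alongside the full 3×3 grid of
allelic-combination ORs relative to (0,0).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical shape* of the inputs:

- Disease sizes log-uniform on 2–30 SNPs (mirroring catalogue skew without
  copying it); ~46% intergenic SNPs; SNPs occasionally shared between
  diseases (5%).
- SNP eQTL degrees from a truncated power law (exponent 2.5, max degree
  n_mrnas/10 — truncation keeps permutation mixing feasible); mRNA targets
  drawn with a mild popularity skew (weight ∝ rank^−0.5), giving the mRNA
  side its own heavy tail without letting a single hub dominate.
- GO DAGs per namespace with geometric level growth below a narrow top
  level and frequent multiple inheritance, echoing the real GO shape; genes
  carry 2–5 direct leaf terms and 95% of genes are annotated. These choices
  make the gene-similarity distribution effectively continuous (the mass at
  exactly 0 — root-only common ancestors — is negligible), as in real
  corpora.
- LD blocks of 2–4 same-chromosome SNPs at r² 0.8–0.99, plus sparse weak
  entries; missing pairs read as r² = 0, as in real LD tables that list
  only correlated pairs.
- Planted signals: overlap pairs share `planted_overlap_size` (default 4)
  dedicated low-degree mRNAs — large enough that a degree-conserving null
  essentially never reproduces the count by chance; similarity pairs get
  `planted_similarity_degree` (default 3) dedicated mRNAs per SNP with
  identically-annotated twins on the other side, so SNP_ITS = 1.0 with zero
  overlap, and a chance null exceedance would require three simultaneous
  perfect matches (a single chance-shared mRNA yields similarity 1 for that
  gene but not for the set). Planted pairs are always same-disease, include
  an intergenic SNP, and are kept out of LD blocks.
- Genotypes: binomial(2, MAF) with phenotype independent ("none"), the
  noise-free XOR of the dichotomised planted pair ("xor"), or an additive
  logistic model with interaction odds-ratio ratio `interaction_ror`
  ("multiplicative").

Not emulated: real allele frequencies, chromosome lengths, GO term counts,
genotype missingness patterns, and population structure. Passing tests on
synthetic bundles therefore demonstrate the *statistical machinery* —
calibration, exactness, recovery — not biological validity on any real
cohort.

## Numerical conventions and problem sizes

- Coordinates 1-based inclusive everywhere; BED is converted on read/write.
- cis/trans boundary: distance ≥ 4 Mb (or different chromosome) is trans;
  distance is measured to the host gene's TSS (the transcript-edge
  alternative is noted in the code; TSS was chosen and is flagged in the
  reader docs).
- Seed fan-out: one global seed, per-stage child seeds derived by hashing
  (`stage_seed`), so single-stage re-runs reproduce full-run outputs
  bit-for-bit.
- Desk-scale defaults: n_perm = 10,000 for real analyses, 1,000–2,000 in
  the test suite; the calibration checks use ~550-SNP bundles with ~900
  scored pairs, and the recovery check ~190 SNPs / ~14,000 candidate pairs.
  Hot loops (swap chain, CSR fill, best-match averages) are numba kernels;
  pure-Python reference implementations remain the public single-pair API
  and the two paths are asserted equal to 1e-12 in the tests.

## Known limitations

- Under the global-null scheme all pairs share each permuted network, so
  p-values are correlated across pairs; uniformity holds marginally but a
  KS test over many pairs sharing SNPs will overstate deviations. The
  calibration tests cap per-SNP pair multiplicity for this reason.
- The overlap statistic is a small integer: under sparse networks most
  observed values are 0 and the equal-or-greater tie rule sends them to
  p = 1. Overlap p-values are therefore valid (super-uniform) but far from
  uniform; only the two similarity statistics admit a two-sided uniformity
  check.
- `raw` p-values can be 0 and are not strictly valid test statistics; they
  trade validity at the floor for BH-survivable prioritisation, matching
  the resampling-proportion convention. Use `add_one` when strict validity
  matters more than detection.
- MDR permutation p-values inherit the discreteness of (1+x)/(1+N).
- The explicit-epistasis permutation scheme is one of several published
  readings of "holding main effects constant" and is marked experimental.
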