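# Methods

## Scope and data model

The package reimplements, as a tested pipeline, the analysis design of a
case-control HLA association study in Behçet's disease: 56 cases and 192
unmatched controls, typed at three-field ("6-digit") resolution across
*HLA-A, -B, -C, -DPB1, -DQB1, -DRB1*. Subject-level genotypes for that
cohort are not public; what is public — and shipped here as TSV
fixtures — are the per-allele carrier counts and the printed statistics.
Everything downstream of those counts (odds ratios, CIs, p-values, Pc) is
therefore an exact-reproduction surface; everything upstream (reads,
calls, haplotype phase) is exercised on synthetic data with planted
truth.

Allele names are stored as a gene symbol plus 1–4 string fields
(preserving leading zeros and expression-suffix letters); resolution
truncation keeps a prefix of fields. Carrier status of a subject for an
allele at resolution r means: either called allele truncates to the
target at r. Homozygous carriers count once — carrier (phenotype)
frequencies, not 2N allele frequencies, are the unit throughout, which is
what makes 7/56-vs-8/192 reproduce OR 3.285.

## Genotype calling

"Fully mapped" is operationalised as an end-to-end (global) alignment of
the read against a reference allele with identity ≥ `min_identity`,
where identity = matching columns / alignment columns, both strands
checked, computed with edlib. A read may count toward every allele it
maps to; no unique assignment or rescaling is attempted, because
same-gene alleles share most of their sequence and the per-allele
ranking carries the signal. Candidate selection keeps at most
`max_candidates = 4` alleles with ≥ `min_reads = 50` mapped reads,
sorted by count with a lexicographic tie-break (total, hence
deterministic). The top candidate is always called; the second is added
(heterozygote) when its count ≥ `het_ratio = 0.25` of the top; a third
candidate passing that bar flags the call `ambiguous` rather than
forcing a diploid guess. Reads shorter than 50 bases never map. An
empty candidate list is a no-call, not an error.

Parameter rationale:

- `min_identity = 0.995` (default): consensus reads are ~99.9%
  accurate, so ~1 error/kb is expected; 0.995 tolerates 5/kb. For
  stress tests at 0.5% per-base error the threshold must sit below
  1 − 2·(error rate) and is set to 0.98; synthetic same-gene alleles
  diverge ≥ 4%, so 0.98 still rejects wrong-allele mappings (~0.96
  identity).
- `het_ratio = 0.25`: the simplest monotone rule consistent with "the
  two top alleles have much higher counts"; exposed as configuration.
- Verification (`verify_assignment`) reports substitution/indel counts
  of a consensus against its assigned reference via global alignment;
  any mismatch flags a potential novel allele.

## Association statistics

For carrier table (a, b; c, d):

- OR = ad/bc, undefined when any cell is zero (no Haldane–Anscombe
  correction; the published tables print dashes, and so do we).
- Woolf logit CI: exp(ln OR ± z·SE), SE = √(1/a+1/b+1/c+1/d),
  z = Φ⁻¹((1+level)/2) = 1.959964 at 95%.
- Wald p: two-sided normal tail of ln OR / SE.
- Fisher exact p: two-sided sum of hypergeometric outcomes no more
  probable than observed (scipy); an independent `math.comb` enumeration
  oracle backs it in the tests to 1e-12.
- Bonferroni: Pc = p × m per locus, uncapped; m = number of distinct
  alleles observed at the locus in the combined cohort.

Two reporting conventions were established numerically before being
frozen into code and tests: the published tables truncate OR and CI
bounds at 3 decimals (3.28571 → 3.285, CI low 1.32376 → 1.323) while
rounding p-values (0.02687 → 0.027), and the published Pc values are
products of the *rounded* p with m (0.027 × 49 = 1.323). The reporting
layer mirrors both; `pc_exact` (from the unrounded p) is also exposed.
The tables are not perfectly consistent in the last printed digit
(identical counts print 0.995 in one row and 0.994 in another), so the
whole-table reproduction check allows one unit in the last place for the
OR; highlighted-allele checks are exact.

The printed p-values are reproduced by the Wald test, not by Fisher's
exact test, despite the captions: verified for all nine highlighted
alleles (largest discrepancy A\*26:01:01, Fisher 0.049 vs printed
0.028). Both p-values are always computed; Wald is the default for
reporting and Pc so that published values reproduce.

Three fixture rows are flagged as misprints because their printed
statistics contradict their own carrier counts (one CI upper bound of
1.803 where identical counts elsewhere print 7.803; one of 9.086 where
the counts force 3.086; one whole statistics triplet belonging to a
different count pattern); one row prints dashes despite nonzero counts
in both groups. Flagged rows are excluded from exact matching and the
recomputed values asserted instead.

Phenotype associations (ocular, vascular, skin, CNS, GI, pathergy flags
on cases) build the same 2×2 either between phenotype-positive cases and
controls or within cases. The case/control sex comparison uses the
Pearson chi-square without continuity correction, which reproduces the
published demographic p = 0.027.

## Haplotype analysis

EM under HWE: a subject heterozygous at h of the analysed loci has
2^(h−1) phase-consistent haplotype pairs; the E-step weights pairs by
c·f(h1)f(h2) (c = 2 for heterozygous pairs), the M-step re-estimates f
from posterior-weighted counts / 2n. Log-likelihood is asserted
non-decreasing at every iteration; convergence when the gain < 1e-8
(default), cap 1000 iterations. Haplotypes with mass < 1e-6 are pruned
between iterations and mass renormalised, keeping multi-locus state
spaces small. Initialisation defaults to allele-frequency products;
uniform is available; 2 additional seeded Dirichlet restarts guard
against local optima (best log-likelihood wins). With fully homozygous
data EM reduces to direct counting in one step.

LD for a focal two-locus haplotype AB: D = p_AB − p_A·p_B;
D′ = D / D_max with D_max = min(p_A(1−p_B), (1−p_A)p_B) for D > 0 and
min(p_A p_B, (1−p_A)(1−p_B)) for D < 0; r² = D²/(p_A(1−p_A)p_B(1−p_B));
undefined at monomorphic loci.

The case-control test uses the likelihood-ratio heterogeneity statistic
2(LL_cases + LL_controls − LL_pooled) at the EM optima, calibrated by
permuting group labels over a single precomputed phase-pair expansion
(the pooled fit is permutation-invariant and computed once). p uses the
add-one rule (1 + #{perm ≥ obs})/(1 + n_perm), so p > 0 always. The
pairwise scan corrects by the number of pairs (capped at 1 in the scan
report). The published haplotype p-values cannot be reproduced without
subject-level data; this stage is validated by properties instead:
recovery of known pool frequencies (±0.02 at n = 500), null-p
uniformity, and detection power against a planted D′ = 0.8 coupling.
The EM inner loop is vectorised (numpy segment sums over the
expansion), which is what makes 40k+ EM fits in the permutation studies
affordable; it is tested to agree with an independent direct
likelihood maximiser.

## Synthetic data

The generator mirrors the study's design quantities: group sizes 56/192,
HWE diplotypes, per-locus spectra loosely shaped on common Thai class I
alleles, a B\*51:01:01–C\*14:02:01 coupling at D′ = 0.8 (the study's
strong-LD pair), and planted carrier odds ratios (default 3.033, the
B\*51:01:01 point estimate). Cases are generated by drawing carrier
status Bernoulli at odds⁻¹(OR × odds(p_control)) — the retrospective
sampling identity — then rejection-sampling a matching diplotype; an
unattainable OR (degenerate pool) raises. LD induction moves joint mass
into the focal 2×2 cell and rescales the complementary cells
proportionally, preserving marginals exactly; infeasible targets raise.

Reference sequences are synthetic 1 kb alleles: same-gene alleles share
a seeded random core and each mutates its own disjoint 25-base block, so
any same-gene pair differs at 50 positions (5%) — enough that the
calling thresholds separate alleles, while remaining deliberately
unrealistic in content. Reads are Poisson(depth) copies per true allele
with iid substitutions and random strand; indel errors are omitted
(consensus reads are near-perfect; a documented limitation). All
generators are pure functions of (parameters, seed).

What passing synthetic tests does not show: performance on real IMGT
sequences (exon/intron structure, paralogous genes, G/P groups), indel
robustness, allelic dropout from amplification bias, or behaviour of the
EM under population substructure (HWE is assumed).

## Problem sizes in the shipped studies

Simulation studies run at: caller recovery 200 samples × Poisson(100)
depth over a six-allele registry (error-free and 0.5% error); EM
recovery n = 500 subjects; null uniformity 200 replicates of 40/40
subjects at 99 permutations; planted-LD power 20 replicates of 100/100
at 199 permutations. These sizes give stable pass/fail behaviour across
seeds while keeping the full suite around a minute.

## Known limitations

- The caller is a counting method over full-length alignments; it does
  not model chimeric consensus reads, does not phase across genes, and
  leaves 3+-candidate calls as `ambiguous` by design.
- Association is single-allele carrier-based; no covariate adjustment,
  no HWE testing of controls, no experiment-wide correction beyond the
  per-locus m.
- Bonferroni Pc uses the rounded-p convention to match the published
  values; `pc_exact` differs in the third decimal for some alleles.
- The permutation p is exact only conditional on the observed genotype
  multiset; with very small groups its grid is coarse (a warning fires
  below 100 permutations).
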