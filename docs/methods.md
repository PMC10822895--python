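# Methods

## Data model

A study is a set of diploid individuals genotyped at two biallelic
loci. Genotypes are unordered allele pairs — input order never carries
phase; phase enters only through EM estimation. Each locus is a
`LocusDef` (name, rsid, allele labels, and the restriction-fragment
signature of each genotype for PCR-RFLP calling). Individuals carry
case/control status, sex, and — cases only — an optional Mandard
tumor-regression grade (TRG), dichotomised as responders (TRG 1–2) vs
non-responders (TRG 3–5); individuals without a TRG stay in the risk
analyses and are dropped from response analyses.

The sample TSV dialect is `sample_id, group, sex, trg`, then one column
per locus named by the locus name; tab-separated, `NA` = missing,
`#` comments. VCF input is matched by record ID against each locus
rsid; phased separators are collapsed to unphased genotype classes and
multiallelic records are rejected (only two biallelic loci are in
scope).

### RFLP calling

A band pattern is decoded by exact set matching: the observed fragment
set must pair one-to-one (sorted order) with a genotype's nominal
fragment set, every fragment within ±`tolerance` bp (default 2 bp —
on-chip electrophoresis sizes are approximate while the published
fragment lengths are nominal). Extra or missing bands make the pattern
uninterpretable rather than forcing a nearest call; a pattern matching
two genotypes under a generous tolerance is an ambiguity error.

## Single-locus statistics

- Allele frequency: $p = (2 n_{\text{hom-ref}} + n_{\text{het}})/2n$.
- HWE: Pearson chi-square against $n(p^2, 2pq, q^2)$, df 1. No exact
  HWE test is provided; the chi-square is the test the analysis is
  built around.
- Odds ratios: cross-product with the Woolf log-interval,
  $z = 1.959964$. Zero cells yield an explicit "NA" result by default;
  the Haldane-Anscombe +0.5 correction (applied to every cell, for
  both OR and CI) is available by flag. The Woolf interval reproduces
  the bundled cohort's published intervals at two decimals, which is
  why no exact or score interval is offered.
- 2×2 p-values: Yates-corrected chi-square
  $N(|ad-bc| - N/2)^2/(R_1 R_2 C_1 C_2)$ with the continuity term
  clamped at zero so a nearly proportional table cannot overshoot the
  null. Fisher's exact test (two-sided, by summing hypergeometric
  probabilities ≤ that of the observed table; delegated to
  `scipy.stats.fisher_exact` and cross-checked in the tests against a
  full-enumeration oracle) is used automatically when a margin is zero
  and suggested by warning when an expected cell is below 5.
- Genetic models: codominant (each non-reference genotype vs the
  reference homozygote; one joint Pearson chi-square on the 2×3 table,
  df 2, with genotype classes absent from both groups dropped),
  dominant, recessive, overdominant.

### Odds-ratio orientation

Every 2×2 is laid out with the exposed genotype class as row 1 and
cases as column 1. `risk_allele` selects the exposed side of each
model's split: `"ref"` places the reference-allele class first (the
appropriate orientation for the bundled cohort's risk analysis, where
the wild-type C/A alleles carry the risk), `"alt"` the conventional
variant-carrier exposure (used for the response-to-therapy analysis).
The orientation is explicit in each result's `risk_class`/`contrast`
fields rather than being inferred from which OR exceeds 1.

## Two-locus analyses

Combined genotypes are counted directly (all nine cells, percentages
of the group total) and each combination can be tested against all
others pooled; both OR orientations are retained because risk and
protective combinations are conventionally both reported above 1.

### EM haplotype estimation

With two biallelic loci, eight of the nine genotype cells resolve into
haplotypes by counting; only the double heterozygote is ambiguous
between the cis (ref-ref + alt-alt) and trans (ref-alt + alt-ref)
resolutions. EM therefore reduces to one scalar: the cis fraction
$f$, updated as $f \leftarrow \hat p_{rr}\hat p_{aa} /
(\hat p_{rr}\hat p_{aa} + \hat p_{ra}\hat p_{ar})$.

- Initialisation: $f = 0.5$. Deterministic, no seed; in this
  one-parameter family the likelihood is unimodal in practice, and the
  test suite guards against edge cases with an independent dense
  grid-search maximiser of the multinomial genotype likelihood.
- Convergence: $|\Delta f| <$ `tol` (default 1e-10), cap `max_iter`
  (default 1000); non-convergence raises an error carrying the
  log-likelihood trace. A table with no double heterozygotes is exact
  direct counting in one iteration.
- Invariants: haplotype-frequency margins equal the observed allele
  frequencies exactly at every iteration (conservation, asserted in
  tests per iteration), and the log-likelihood trace is
  non-decreasing.

Haplotype-vs-rest odds ratios accept fractional (EM expected) counts
as-is in the OR and Woolf formulas. The bundled dataset also carries
the study's own printed haplotype chromosome counts, kept separate
from the genotype grids: those printed counts are not derivable from
the printed genotype data (their totals do not even match the number
of chromosomes), so the pipeline estimates haplotypes from genotypes
via EM by default and uses externally supplied haplotype counts only
when explicitly provided. Of the published haplotype table, only the
odds ratios computed from its own counts are treated as reproducible.

### Linkage disequilibrium

$D = p_{rr} - p_1 p_2$ for the ref-ref haplotype;
$D_\max = \min(p_1 p_2,\; q_1 q_2)$ when $D<0$ and
$\min(p_1 q_2,\; q_1 p_2)$ when $D>0$; $D' = |D|/D_\max$ reported
unsigned with the sign carried separately (the bundled cohort's
published D′ values are unsigned although the underlying D is
negative); $r^2 = D^2/(p_1 q_1 p_2 q_2)$. LD is undefined at a
monomorphic locus. Display convention: D′ to 2 decimals, r² to 5.

## Synthetic cohorts

The generator emulates the sampling scheme the estimators assume:
haplotypes drawn i.i.d. from a four-haplotype distribution (random
union of gametes ⇒ HWE at each locus), a genotype effect on disease
odds at locus 1, and retrospective case-control ascertainment by
rejection sampling until both quotas fill — to which the OR is
invariant. `haplotype_freqs_from_ld(p1, p2, D')` inverts the LD
summary; with the sign-matched $D_\max$ every $|D'| \le 1$ is
feasible, $|D'| = 1$ giving a boundary distribution with one absent
haplotype.

Defaults are the bundled cohort's control-population conditions:
$p_1 = 0.60$, $p_2 = 0.65$, signed $D' = -0.12$ (the EM estimate from
the control grid is −0.1232), a dominant effect of OR 2.27 on the
reference-allele class, baseline disease probability 0.10, 97 cases,
119 controls, 60% male. The exposed class mirrors the estimator's
model splits exactly, so fitting the matching model recovers
`effect_or` in the same orientation.

Randomness is a single `numpy.random.default_rng(seed)` stream
consumed in batches in the fixed order (haplotype 1, haplotype 2, sex,
disease); cohorts are byte-identical per seed. What the generator does
*not* model: population stratification, relatedness, genotyping error,
missingness, two-locus interaction effects, and response-to-therapy
labels (simulated cases carry no TRG). Passing calibration tests on
these cohorts therefore demonstrates estimator correctness under the
idealised sampling model, not robustness to real-data artefacts.

## Problem sizes used in the test and acceptance runs

All published-value checks run on the bundled count tables
(desk-scale, milliseconds). Stochastic calibration checks use: null
type-I error at 4,000 simulated tables of the cohort's group sizes;
EM parameter recovery at n = 5,000 individuals (3 binomial SEs);
dominant-OR CI coverage over 100 seeded replicates of 400 + 400
individuals (≥ 90% coverage at nominal 95%, leaving Monte-Carlo
slack); HWE pass-rate over 40 replicates of 800. The full suite runs
in well under a minute on one CPU.

## Known limitations

- Exactly two biallelic loci; no multiallelic variants, no >2-locus
  haplotypes, no per-individual phasing (population frequencies only).
- No covariate-adjusted regression and no multiple-testing correction
  — the pipeline reproduces a direct-counting analysis style.
- The published p-values of the bundled cohort are not all
  reproducible because the original test choice per table (Yates
  chi-square vs Fisher) is ambiguous; the package exposes both and the
  tests only assert the dominant-model significance directionally.
- Woolf intervals are poor for very sparse tables; the Haldane
  correction is a pragmatic, not principled, fix.
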