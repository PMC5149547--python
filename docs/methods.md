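# Methods

## The two-site disease model

Two linked biallelic loci are tracked: a causal site *A* with alleles
A₁/A₂ and a marker *B* with alleles B₁/B₂. The general population is
described by the four haplotype frequencies P₁₁…P₂₂ (P₁₁ = P(A₁B₁)),
with marginals p = P₁₁+P₁₂ and q = P₁₁+P₂₁ and LD coefficient
D = P₁₁P₂₂ − P₁₂P₂₁. Disease risk enters only through the causal
genotype: f_ij = P(Case | AᵢAⱼ), each strictly inside (0,1), with no
ordering imposed — the model covers every mode of inheritance.

Assumptions baked in:

- Hardy–Weinberg proportions at the causal site (random mating, no
  inbreeding parameter);
- a monogenic prevalence, K = f₁₁p² + 2f₁₂p(1−p) + f₂₂(1−p)² — the total
  probability of disease attributable to this locus. For a complex
  disease this is best read as the prevalence of the sub-phenotype driven
  by the locus, not of the disease as a whole; the package computes the
  monogenic formula and leaves that interpretation to the user;
- every individual is either a case or a control, so population
  frequencies are the K-weighted mixture of case and control frequencies
  (law of total probability).

Case haplotype frequencies follow by Bayes' theorem,
V_ij = P_ij·[fᵢ₁p + fᵢ₂(1−p)]/K (the partner chromosome carries A₁ with
probability p), controls by U_ij = (P_ij − K·V_ij)/(1−K). The expected
case/control chi-square at either site is the squared case–control allele
frequency contrast scaled by sample sizes over the population-frequency
variance term. Algebraic cancellation of the penetrance terms gives the
exact identity χ²_M = r²·χ²_D; the package computes both sides
independently (`theorem_ratio`) so tests of the identity are genuine
checks, verified to |ratio − r²| < 1e-10 over randomly drawn valid
parameter sets.

## Statistic scale conventions

Two scales circulate for the 1-df allelic chi-square: the *traditional*
statistic (upper-tail chi-square with 1 df under the null) and the
*doubled* form, twice that, which is what the expected-statistic formula
used here produces when sample sizes are counted as diploid individuals.
Every statistic in the package is an `AssociationStat` carrying its
convention tag; p-values are always computed on the traditional scale, so
conversion never changes a p-value and round-trips exactly.

## Recombination dynamics

The per-generation recursion P₁₁,ₜ = P₁₁,ₜ₋₁(1−c) + c·p·q (and analogues)
is iterated explicitly, mirroring the generative process; the closed form
D_t = D₀(1−c)ᵗ is kept as an independent oracle and verified to 1e-10 out
to t = 10,000. Marginal allele frequencies are conserved by construction
(the equilibrium targets use the input marginals), so
r²_t = r²₀(1−c)²ᵗ. A guard renormalises the simplex after long
iterations to absorb accumulated rounding; the correction is below 1e-12
per coordinate in all tested regimes. Drift, mutation and selection are
deliberately out of scope.

## Monte Carlo simulator

Case and control haplotype counts are two independent multinomial draws
from V and U. Each diploid individual contributes two chromosomes, so an
arm of n individuals yields 2n haploid draws; `chrom_per_diploid=1` gives
the literal one-draw-per-individual reading. Replicate statistics are the
standard 1-df allelic chi-square on the drawn chromosome counts — under a
null model its mean is 1, and its noncentrality equals the expected
(doubled-tagged) parameter-level statistic, which is why the doubled
bookkeeping depends on whether sample sizes count individuals or
chromosomes.

The denominator frequency is *pooled* (case+control sample frequency) by
default, matching what an analyst computes from data. Note a subtlety
verified by the tests: with cases heavily oversampled relative to K, the
pooled frequency sits near the midpoint of the case and control
frequencies rather than the population value, deflating both statistics
slightly and displacing the ratio χ²_M/χ²_D from r² by a few percent at
strong effects; with `freq_denominator="population"` the ratio converges
to r² exactly. Replicates where a denominator frequency fixes are flagged
and carried as missing, never silently dropped.

Default dispersion-study scenario: parental haplotype frequencies 0.28
(causal) and 0.70 (non-causal) with recombinants at 0.01 each (causal
allele A₁ in coupling with marker allele B₁ — the assignment is
configurable via the haplotype inputs), additive penetrances
0.05/0.03/0.01 with A₁ the risk allele, c = 0.01, generations sampled at
t = 0, 20, 50, 100 to spread r² from ≈0.91 down to ≈0.12. The test suite
runs this at 1,000 cases / 4,000 controls with 1,000 replicates per time
point, a scale at which the origin-through regression of χ²_M on r²·χ²_D
estimates its slope to a couple of percent.

## Effect-size inversion

Given a marker statistic χ²_M, its r² with a non-interrogated site, and
that site's population allele frequency p, the implied case allele
frequency is p + Δ with Δ = √(2p(1−p)·χ²_M,doubled/(m·r²)), and the
allelic odds ratio is R = ((1−p)/p)·(p+Δ)/(1−p−Δ). The rare-disease
approximation p_C ≅ p is built in. Two conventions for the effective
sample size m are exposed because the quantity is defined ambiguously in
common usage:

- `worked_example` (default): m = 2n_D n_C/(n_D+n_C) applied to the
  doubled statistic — the convention under which the canonical worked
  example (χ²=20 doubled, 500/500, p=0.03, r²=0.2) yields R = 5.17;
- `eq_literal`: m = 4n_D n_C/(n_D+n_C), the algebraically exact inverse
  of the expected-statistic formula under p_C = p, yielding R = 3.85 on
  the same inputs (the two differ by √2 in Δ).

`marker_chi2_from_causal_or` is the exact forward counterpart on either
convention; the pair round-trips to machine precision, which the tests
exercise over random feasible configurations. The negative root of the
quadratic (`protective=True`) returns the R < 1 solution. Feasibility is
enforced: Δ ≥ 1−p means no allele frequency in (0,1) can produce the
signal, and the error message says so.

## Decay screening

All markers in a region are regressed on their r² with the index variant
through the origin. The decay line is *anchored*: its slope is the index
variant's own chi-square, so the prediction at r² = 1 is the index
statistic and the index residual is exactly 0. Alongside the anchored
slope the unanchored least-squares slope through the origin
(Σxy/Σx², x = r²) is reported; it averages over all markers' noise and is
the better slope estimate when the statistics are noisy. Pearson and
Spearman correlations of observed statistic against r² are both reported;
Spearman's rho carries the test p-value, being the rank-based choice for
the visibly non-normal residuals.

The 95% band treats the fitted values as the expected response and
resamples the observed residuals with replacement (B resamples, seeded).
Two constructions are provided:

- `quantile` (default): the band at each marker is the pointwise
  0.025/0.975 quantile range of its bootstrap replicate responses
  (fitted + resampled residual). Because every marker's residual is a
  member of the resampling pool, roughly 95% of markers fall inside this
  band by construction, which is the property an outlier screen needs.
- `refit`: each replicate is refit by origin-through least squares and
  the band is the quantile range of the refitted lines. This is a
  confidence band for the line itself; its width shrinks like
  s/√(Σr⁴) and it will legitimately exclude a large fraction of
  individual observations. It is retained for inference about the slope,
  not for flagging.

Flagged variants are those observed above the upper band, reported with
their exceedance and sorted by it. Converting all inputs between the
doubled and traditional scales rescales slope, band and exceedances by
exactly 2 and changes no flag decision. B below 100 is refused (tail
quantiles are unstable); the default is 100,000, and tests use 10,000, at
which band endpoints are stable to well under 2% of the slope across
seeds.

## Synthetic regions

The region generator emulates the data shape of a dense fine-mapping
study: one summary-statistics row per marker and a PLINK-style `.ld`
table of pairwise r² with the index. Non-index r² values default to
Beta(1,3) — many weakly linked markers, few tightly linked — matching the
long-tailed point clouds of real regions; a uniform option and explicit
lists are available. Exactly one marker (the index) has r² = 1.

Under multinomial noise every marker's statistic is one sampling
replicate of the two-site model at that marker's r². Marker allele
frequencies are set equal to the causal allele frequency so that any
r² ∈ [0,1] is feasible with a single coupling-phase convention, and the
generator uses the population-frequency denominator so each marker's
expected statistic sits on the decay line (see the pooled-frequency
subtlety above). The injected second signal is an additive chi-square
offset at one marker — sufficient to test flagging; a genuine
two-causal-site haplotype model is out of scope.

The end-to-end screening check runs 100 seeded regions of 120 markers at
783 cases / 783 controls with additive penetrances 0.05/0.03/0.01 and
causal frequency 0.3 (index statistic ≈ 142, the scale of a strong GWAS
hit), injecting an offset of 61.62 at a marker with r² = 0.087 — an
observed ≈ 74 where the line predicts ≈ 12.4 — and requires detection in
at least 95 of 100 runs with at most 10% of null markers flagged. These
sizes were chosen to make each band computation (B = 10,000) and the full
100-seed sweep comfortable on a single CPU.

### What the generator does not emulate

Real regions have blockwise LD with correlated r² among markers,
heterogeneous marker allele frequencies, imputation noise, and
winner's-curse inflation at the index. Passing the synthetic checks
demonstrates the statistical machinery (exactness, calibration of the
band, detectability of a programmed exceedance) — not robustness to
those features of real data. In particular, correlated markers make
flagged sets clump: neighbours of a true secondary signal will often be
flagged with it.

## Numerical choices

- Analytic identities tested at 1e-10; probability-conservation
  invariants at 1e-12.
- Haplotype constructors snap values within 1e-12 of the [0,1] boundary
  back onto it (Lewontin-bound arithmetic can leave ~1e-17 overshoots).
- `theorem_ratio` refuses χ²_D < 1e-15: an exactly-null model leaves
  float dust in pD − pC and the ratio would be garbage.
- Chi-square/p-value conversion uses the scipy survival function and its
  inverse; round-trip error is below 1e-9 in the statistic across the
  tested range (p down to 1e-33).
- Empirical quantiles use numpy's default (linear interpolation); with
  all residuals equal the band has exactly zero width.

## Known limitations

- Biallelic sites, one causal locus, no epistasis, no covariates, no
  genotype-level (as opposed to allele-level) tests.
- The monogenic prevalence interpretation discussed above.
- The effect-size inversion inherits p_C ≅ p; for common diseases with
  strong effects the implied R is biased accordingly (no exact-p_C
  variant is provided).
- The screen assumes the index variant is, or perfectly tags, the causal
  site; if the true causal site is imperfectly tagged by the index, the
  anchored slope underestimates the causal statistic and the band is
  anchored too low.
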