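# Methods

## Model

`asekit` detects allele-specific expression (ASE) from allelic read counts at
heterozygous exonic SNVs, aggregated into genes (or any other "ASE unit").
The observation model at one SNV with total RNA coverage `n` is

    X_hap1 ~ Beta-Binomial(n, mu = f_hap1(p), rho),

where `p` is the transcript-scale frequency of haplotype 1, `rho` is a global
overdispersion (intra-class correlation) inflating the binomial variance by
`rho (n - 1) + 1`, and `f_hap1(·)` maps transcript frequency to the
probability of *observing* the haplotype-1 allele.  Pre-existing allelic bias
(reference-mapping bias and similar artifacts) is modelled by a single global
parameter `f = f_ref(0.5)`, the probability of observing the reference allele
under balanced expression, through the odds weighting

    mu_A = p f_A / (p f_A + (1 - p)(1 - f_A)),   f_A ∈ {f, 1 - f}.

The gene-level quantity of interest is the major haplotype frequency (MAF):
0.5 means balanced expression, 1.0 monoallelic.

### One-sample analysis

Per SNV, major-haplotype counts are variance-stabilized with the
Freeman–Tukey double-arcsine transform

    z = asin√(x/(n+1)) + asin√((x+1)/(n+1)),   Var(z) ≈ (rho(n-1)+1)/(n+0.5),

combined across the SNVs of a gene by fixed-effects inverse-variance
weighting, and backtransformed (`p = sin²(z/2)`, the exact inverse of the
mean map `2 asin√p`) to an observed-scale frequency; inverting the bias map
yields the transcript-scale estimate `T_FT`.  Cochran's Q of the per-SNV
scores measures between-SNV heterogeneity; large Q flags possible
isoform-specific ASE.  The DerSimonian–Laird between-SNV variance τ² is
reported as a diagnostic but never feeds the point estimate: the printed
estimator is fixed-effects, and all inference is calibrated by simulation, so
the random-effects refinement would change nothing downstream.

When true haplotypes are unknown, SNVs are pseudo-phased by *voting*: the
higher-count allele at each SNV goes to the "major" haplotype (count ties go
to the reference allele, deterministically).  Voting makes `T_FT` a maximum
statistic, biased above 0.5 under the null, so nominal normal-theory p-values
would be anti-conservative.  Instead, the null distribution of `(T_FT, Q)` is
estimated by Monte Carlo: holding each SNV's total fixed, reference counts
are redrawn from Beta-Binomial(n, f, rho), the *identical* phasing and
estimation pipeline is re-applied, and

    p_ase = #(T_sim ≥ T_obs) / N_sim,    p_het = #(Q_sim ≥ Q_obs) / N_sim.

For a single-SNV gene this construction converges to the two-sided exact
binomial test as `N_sim` grows.  When phase labels are supplied, no voting is
done — the gene-level haplotype with the larger combined frequency is
reported as major — but p-values still come from simulation, for consistency
across genes.

### Two-sample analysis

For sample-specific ASE (e.g. tumor vs. normal) the target is
`D = p_hap1,tumor − p_hap1,normal`.  Only SNVs heterozygous and covered in
both samples are used.  Phasing is anchored on the sample of interest alone
and imposed on the other sample.  Each SNV contributes the proportion
difference `z = x_t/n_t − x_n/n_n` with null variance
`p(1−p)/n_t + p(1−p)/n_n` (each term inflated by `rho(n−1)+1`), evaluated at
a pooled estimate of the common haplotype frequency `p` under H0 — total
major counts over both samples divided by total coverage, clipped to
`[1/(N+2), 1−1/(N+2)]` so monoallelic observations cannot produce a
zero-variance null.  The combined statistic `T_PD` is already a frequency
difference, so no backtransform is applied; nor is any variance-stabilizing
transform, which makes `T_PD` more sensitive to single outlier SNVs than
`T_FT` — heterogeneity flags matter correspondingly more here.  The null
simulation draws both samples' counts at the pooled frequency (pushed through
the bias map per major allele), re-votes on the simulated sample of interest,
and recomputes `(T_PD, Q)`.

### Calling

Within one sample's batch, `p_ase` is Benjamini–Hochberg adjusted and a gene
is called ASE when the adjusted p-value is ≤ 0.05 *and* it clears an
effect-size gate: estimated MAF ≥ 0.7 (one-sample) or MAF difference ≥ 0.2
(two-sample) — deep coverage otherwise makes trivial departures from 1:1
significant.  Two-sample calls can additionally require one-sample ASE
evidence in the sample of interest.  Heterogeneity p-values are BH-adjusted
over multi-SNV genes only (single-SNV genes have no Q test and would dilute
the family); genes at adjusted `p_het` ≤ 0.05 are flagged isoform-specific.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `rho` | beta-binomial overdispersion | 0 | 0.004 is a typical RNA-seq value and is the benchmark setting |
| `f_ref_null` | P(observe ref allele) under balanced expression | 0.5 | estimable from data (`estimate_global_bias`) |
| `n_sim` | Monte-Carlo null size | 100,000 | the benchmark uses 10,000; 10⁶ available where the p-value floor matters |
| `fdr_level` | BH level for calls | 0.05 | |
| `maf_cutoff` / `maf_diff_cutoff` | effect-size gates | 0.7 / 0.2 | `None` disables |

Empirical p-values are floored at `1/(N_sim + 1)` rather than reported as 0,
so BH adjustment never divides by zero-significance artifacts.  Null
distributions depend on a gene only through the multiset of its per-SNV
totals (plus `rho`, `f`, phase mode), so they are cached and shared across
genes; the cache is seeded by `(seed, shape)` and therefore independent of
gene order.  The cache is size-capped (3,000 shapes) to bound memory in
large stratified studies.

## Numerical choices and degenerate inputs

- Count ties in voting go to the reference allele; the null simulation applies
  the same rule, so calibration absorbs the convention.
- Backtransform clips the combined score to `[0, π]`; bias inversion clips its
  argument away from {0, 1} by 1e-12 (monoallelic genes otherwise hit the
  boundary of the odds map).
- With mixed ref-major/alt-major SNVs under bias, the gene-level inversion
  uses the inverse-variance-weighted mean of the per-SNV major-allele `f`
  values.  This composition of variance inflation and odds mapping is a
  first-order treatment of bias + overdispersion jointly; because observed and
  simulated data traverse the identical code path, p-value calibration does
  not depend on its accuracy, only effect-size estimates do (and only when
  `f ≠ 0.5`).
- Tail comparisons use a 1e-12 tolerance so discrete-statistic ties between
  the scalar (observed) and vectorized (simulated) code paths never
  undercount.
- A gene that fails validation yields a flagged record with NaN estimates; the
  batch continues.

## Synthetic data and what the benchmark shows

The generator (`asekit.simulation`) reproduces the model's assumed structure:
25 strata crossing SNVs/gene (1, 2, 3, 4, 5+) with mean reads/SNV (10–20,
…, 50+), a fixed fraction (default 25%) of true-positive genes per stratum
whose randomly chosen major-haplotype allele is drawn at a constant signal
MAF (default 0.8), true negatives at `mu_ref = f`, all counts beta-binomial
with `rho = 0.004`.  Per-SNV totals are uniform within the coverage bin, the
open-ended bins resolving to 50–100 reads and 5–8 SNVs; real datasets have
heavier-tailed coverage, so only within-stratum performance — not a
dataset-weighted overall rate — transfers.  The generator also does not
emulate alignment artifacts, correlated reads across nearby SNVs (the
read-sharing filter exists precisely because the model assumes independence),
copy-number alterations, or per-SNV bias variation; passing benchmarks show
the statistics are calibrated and powerful *under the model*, not that these
upstream artifacts are handled.

Default study profile: 10 replicates of 40 genes/stratum (200 genes for the
single-stratum power check) at `N_sim = 10⁴`, chosen as the package's
desk-scale default; the replicate and gene counts are flags on
`SimConfig`/the `simulate` subcommand for larger runs.

## Known limitations

- Exactly two haplotypes are assumed; regions of copy-number alteration or
  admixture violate this silently.
- A single global `rho` and `f`; per-SNV values are accepted by the low-level
  API only through the global parameter, not estimated per locus.
- The method-of-moments `rho`/`f` estimators treat all input SNVs as null;
  datasets rich in strong ASE inflate both.
- The two-sample test is asymmetric by design (phasing anchored on the sample
  of interest); to find normal-specific ASE, swap the roles.
- Pseudo-phasing caps the achievable specificity of effect-size estimates
  near MAF 0.5: under the null the estimate is biased upward by construction
  and only the calibrated p-value corrects for it.
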