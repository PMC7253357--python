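# Methods

## Data model

The unit of input is a study record: genotype counts (Val/Val, Val/Met,
Met/Met) for each smoking-status arm, plus label, publication year and
ancestry. Counts are stored per arm rather than pre-collapsed so that any
genetic model can be derived downstream. Three phenotype contrasts are
defined — persistence (current vs never smokers, the default), initiation
(ever vs never) and cessation (current vs former) — with the case arm
always listed first. The packaged eight-cohort table carries only the
persistence arms; the `ever`/`former` arms are optional record fields.

Two invariant conventions fix all signs: exposure is always the
Val-containing genotype category, and cases are always the first arm, so
OR > 1 uniformly means Val carriers have higher odds of the case phenotype.

## Genetic models

* dominant (default): a = case Val/Val + Val/Met, b = case Met/Met, and
  mirrored for controls;
* recessive: Val/Val vs Val/Met + Met/Met;
* allelic: each subject contributes two alleles, so arm totals double;
* additive: deliberately *not* collapsed to a 2×2 — there is no unique
  collapse — and realised instead as a Cochran–Armitage trend test with
  Val-dose scores 0/1/2 (N·r² against chi-square, 1 df). Requesting an
  additive 2×2 raises an error that points at the trend test.

Hardy–Weinberg equilibrium is tested per arm by the 1-df Pearson
goodness-of-fit chi-square against (p², 2pq, q²) expected counts, with
p̂ = (2·vv + vm)/(2n). The control (never-smoker) arm is the conventional
arm to test, since HWE violation there flags genotyping error; monomorphic
arms return chi2 = 0, p = 1 with an explicit flag rather than an error.
Which arm the original analysts tested is not recoverable from the source,
so no test encodes their per-study HWE verdicts; all eight packaged control
arms pass at the 0.05 level under this implementation.

## Effect estimation and pooling

Per-study effects are Woolf log odds ratios, var = 1/a + 1/b + 1/c + 1/d.
The continuity-correction default is `add_half_if_zero` (0.5 added to all
four cells of any table containing a zero, before both the estimate and the
variance); `always_half` and `none` are available. The packaged table has
no zero cells, so its results are correction-free.

Three pooling models:

* `fixed_iv` — inverse-variance weighting. This is the package default,
  although the originating analysis names Mantel–Haenszel: the
  inverse-variance results reproduce the published subgroup CI bounds and
  cumulative points to their printed precision, indicating the software
  that produced them used IV weighting in those outputs. Both are always
  computed by the pipeline.
* `fixed_mh` — Mantel–Haenszel pooled OR with the Robins–Breslow–Greenland
  variance. On the packaged table it agrees with IV within 0.2%.
* `random_dl` — DerSimonian–Laird, the only τ² estimator offered (no REML
  or Paule–Mandel), with τ² truncated at zero. Whenever Q ≤ df the random
  model therefore equals the fixed IV model exactly — which is the case for
  the all-cohorts analysis (Q = 6.70, df = 7).

CIs use the multiplier 1.959964; P values are two-sided normal tails of
Z = θ̂/SE. I² is reported in percent, truncated at zero — the truncation is
what produces an exact 0.0 on the all-cohorts analysis. The known residual
gap between this package's all-cohorts P (0.019) and the published 0.021 is
attributed to the originating software's internals; both round to
"significant at 0.05" and the package reports its own computed value.

## Publication bias

Egger's test is the classical unweighted OLS of the standardized effect
tᵢ = θ̂ᵢ/SEᵢ on precision 1/SEᵢ; only the intercept's two-sided t test
(k − 2 df) is consumed. A perfect fit (zero residuals) with zero intercept
is reported as p = 1 rather than 0/0. Funnel coordinates are (log OR, SE)
with pseudo-95% guide lines around the fixed-IV centre; rendering inverts
the SE axis.

Trim-and-fill runs fixed-IV pooling inside the trimming loop (Duval &
Tweedie's recommendation), defaults to the L0 estimator, and reports the
adjusted estimate under both fixed and random models. `side=auto` picks the
heavy funnel side from the Egger intercept sign, falling back to the sign
of the summed deviations from the pooled centre when all precisions are
equal (where the Egger design is singular). Imputed studies are mirror
images: θ̂ = 2·(trimmed pooled) − (trimmed extreme), variance copied. The
R0 estimator is the rightmost positive-deviation run length minus one;
note that appending m extreme studies to a symmetric set yields k0 = m − 1
under R0 (the run cannot extend into the symmetric base), a behaviour
cross-checked against an independent implementation during development.

## Robustness analyses

Leave-one-out re-pools each k−1 subset (k ≥ 3 required). Cumulative
meta-analysis sorts studies by (year, label) and emits one row per distinct
year pooling all studies published by then; ties share a row because the
cumulative trajectory is indexed by publication year, and the packaged
table's 2007 point (OR 1.422) is reproduced only by pooling both 2007
cohorts together. The final cumulative row equals the all-studies pooling
exactly, by construction.

On the packaged table, one leave-one-out row (omitting the 2012 cohort, the
largest single-study OR) has p = 0.062 and is not significant at 0.05,
although its OR (1.208) stays inside the published sensitivity range. The
published claim that every row is significant rests on a sample-size
accounting (N = 10,490) that the genotype table itself (N = 10,160) does
not reproduce; the package reports what the counts give.

## Synthetic data

The generator parameterises the dominant-model OR directly: control
genotypes are multinomial draws from HWE proportions at a configurable
Val-allele frequency; each study draws a log OR from
Normal(ln(true_or), τ²); case genotype probabilities are the control
probabilities with the two Val-carrier categories tilted by that study's OR
and renormalised. This makes the dominant-model population OR equal the
drawn OR *exactly*, so parameter recovery is a sharp test of the analysis
chain rather than of an approximation. It deliberately does not simulate a
per-allele logistic model, linkage disequilibrium, covariates or
interactions — passing recovery tests therefore shows the pipeline's
algebra is right, not that real cohorts satisfy the dominant model.

Defaults: k = 8 studies, 500 cases / 500 controls, true OR 1.25 (the
magnitude of association the package's worked example estimates), τ = 0,
and allele-frequency presets `asian_like` (0.515) and `caucasian_like`
(0.784) matching the two ancestries' typical Val frequencies. One seeded
`numpy` Generator drives a whole simulated meta-analysis, so a single seed
reproduces every count. The recovery experiment (default 200 replicates,
k = 20) reports bias, empirical SE, CI coverage and fixed-model rejection
rate; under the null it recovers a type-I error near 0.05, and at
true OR = 1.25 the bias of the mean pooled OR is below 0.03.

## Numerical choices and degenerate inputs

* Empty arms, zero-total tables and monomorphic HWE inputs raise typed
  errors (or return flagged results) rather than NaNs.
* k-minimums: pooling 1, random effects and heterogeneity 2, Egger and
  trim-and-fill 3; subgroups below 2 cohorts are skipped with a logged
  notice (the packaged table's single African cohort).
* Trim-and-fill caps at 20 iterations and raises on non-convergence; k0 is
  capped so at least two studies remain untrimmed.
* Reports serialise at full double precision; rounding (2 decimals for
  ORs, 1 for I², 3 for P) is display-only.
* Problem sizes in the test suite (200-replicate recovery runs at
  k = 20, 1,000 subjects per study; 30-replicate heterogeneity contrasts)
  were chosen as the smallest giving stable Monte-Carlo verdicts for the
  properties checked.

## Known limitations

No Hartung–Knapp adjustment, prediction intervals, meta-regression,
Begg–Mazumdar test or selection models; no genotype imputation or
multi-SNP haplotype handling; the Egger variant is fixed (unweighted), so
published intercept P values produced by other variants are matched only
qualitatively.
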