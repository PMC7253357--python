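# genemeta

Genotype-count meta-analysis for candidate-gene case-control association
studies.

Many candidate-gene association papers publish, for each cohort, nothing
more than a table of genotype counts split by phenotype arm. `genemeta`
turns such tables into a complete meta-analysis: per-study odds ratios under
a chosen genetic model, fixed- and random-effects pooling, heterogeneity
statistics, publication-bias diagnostics, and robustness (leave-one-out and
cumulative-by-year) analyses. It ships an eight-cohort table for the BDNF
Val66Met (rs6265) polymorphism and smoking persistence (current vs never
smokers; 10,160 participants) as a worked, validated example, plus a
synthetic cohort generator so every pipeline stage can be tested against
known true parameters.

It is written for epidemiologists and statistical geneticists who want the
standard meta-analytic toolkit operating directly on genotype counts, with
every intermediate quantity exposed and testable.

## The statistics

For each study a 2×2 table (a, b; c, d) is built under a genetic model —
by default the **dominant model**, Val/\* carriers (Val/Val + Val/Met) vs
Met/Met — with cases in the first phenotype arm and the Val-containing
category as exposure. The per-study effect is the log odds ratio with
Woolf's variance:

```
θ̂ᵢ = ln(aᵢdᵢ / bᵢcᵢ),   v̂ᵢ = 1/aᵢ + 1/bᵢ + 1/cᵢ + 1/dᵢ
```

Pooling:

* **Fixed effects, inverse variance**: weights wᵢ = 1/v̂ᵢ,
  θ̂ = Σwᵢθ̂ᵢ / Σwᵢ, SE = (Σwᵢ)^(−1/2).
* **Fixed effects, Mantel–Haenszel**: OR_MH = Σ(aᵢdᵢ/nᵢ) / Σ(bᵢcᵢ/nᵢ),
  with the Robins–Breslow–Greenland variance for ln OR_MH.
* **Random effects, DerSimonian–Laird**:
  τ̂² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)), re-weighting with
  wᵢ\* = 1/(v̂ᵢ + τ̂²).

Heterogeneity is Cochran's Q = Σwᵢ(θ̂ᵢ − θ̂)² with df = k − 1 and
I² = max(0, 100·(Q − df)/Q). Significance of a pooled estimate uses the
Z test θ̂/SE against the standard normal; 95% CIs use the multiplier
1.959964. Publication bias is assessed by funnel coordinates, Egger's
regression of the standardized effect on precision (intercept t test,
k − 2 df), and Duval–Tweedie trim-and-fill (L0/R0 rank estimators,
mirror-image imputation).

## Worked example

```sh
genemeta run --fixture --out results/
```

prints (abridged):

```
[overall] k=8 N=10160
  fixed_iv  OR=1.23 (95% CI 1.04-1.47) Z=2.35 P=0.019
  fixed_mh  OR=1.23 (95% CI 1.04-1.47) Z=2.36 P=0.018
  random_dl OR=1.23 (95% CI 1.04-1.47) Z=2.35 P=0.019 tau2=0.0000
  heterogeneity Q=6.70 df=7 P_Q=0.46 I2=0.0
  Egger intercept=0.057 P=0.94

[Asian] k=3 N=2095
  fixed_iv  OR=1.24 (95% CI 1.01-1.54) Z=2.02 P=0.044
  random_dl OR=1.25 (95% CI 1.00-1.56) Z=1.97 P=0.049 tau2=0.0026
  heterogeneity Q=2.12 df=2 P_Q=0.35 I2=5.6

skipped subgroups (below minimum cohorts): African
```

Reading: across all eight cohorts, Val/\* carriers have 1.23 times the odds
of persisting in smoking (P = 0.019), with no detectable between-study
heterogeneity (I² = 0), so fixed and random models coincide. The Asian
stratum alone remains significant; the single African cohort is skipped
because one study cannot be meta-analysed. `results/` receives
`report.json` (full precision), `report.txt`, forest and funnel plots per
analysis, and `sensitivity.csv` / `cumulative.csv`.

Simulation and recovery from the same CLI:

```sh
genemeta simulate --preset asian_like --k 20 --true-or 1.25 --seed 7 --out sim/
genemeta recover --replicates 200 --true-or 1.25 --seed 7
```

Everything is also available as a library:

```python
from genemeta import load_fixture, build_contingency, study_effect, pool_fixed_iv

effects = [study_effect(build_contingency(s)) for s in load_fixture()]
print(pool_fixed_iv(effects).odds_ratio)   # 1.2335520872100196
```

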