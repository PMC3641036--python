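# Methods

## The model of the experiment

`regenscreen` analyses a paired two-condition expression time course.
Each biological replicate contributes a complete amputation series and a
complete lateral-wound series over the 13 sampling times 0–528 h, with
the two conditions at a given (time, replicate) taken from contralateral
limbs. Three limb-bud samples and three mature-proximal samples anchor
the developmental and baseline ends of the comparison. All statistics
assume a balanced, complete design with no missing cells; a missing cell
is a hard error rather than an imputation case, because every
downstream F statistic relies on the balanced decomposition.

Signals are modelled as multiplicative log-normal: analysis runs on
log₂ of normalized intensities. The scale is a config switch
(`log_transform`), but log₂ is the default everywhere because the
fold-change logic of the pairwise pipeline is ratio-based and the
generator's noise model is additive on the log scale.

## Statistical tests

* **One-way ANOVA** (time effect within a condition): classical
  fixed-effects F with df (k−1, N−k), computed vectorised across probes
  from the between/within sum-of-squares decomposition.
* **Two-way ANOVA** (time × condition over 3–528 h, 12 × 2 × 3): the
  standard balanced decomposition; the interaction family (df 11, 48)
  is the screen for amputation-specific regulation. The 0 h sample is
  excluded here (both limbs are uninjured, so no condition contrast
  exists); the one-way amputation ANOVA of the pairwise pipeline keeps
  0 h as its 13th group.
* **FDR**: Benjamini–Hochberg step-up, applied per family (interaction
  p-values; one-way amputation p-values). BH was chosen because the
  analysis only specifies "5% FDR" and step-up is the standard,
  monotone, reproducible choice.
* **Paired t per time point**: one-sample t on the log₂ contralateral
  differences, df = n−1.
* **Fisher LSD** between consecutive time points: pooled error mean
  square and residual df from the per-condition one-way fit across the
  3–72 h window; the canonical window yields 7 pairs per condition.

Degenerate inputs follow pinned conventions: zero residual variance
with a real effect ⇒ p = 0 with a warning; fully constant ⇒ F = 0,
p = 1; constant non-zero paired difference ⇒ p = 0 with a warning.
Ties at thresholds are pinned too: interaction q ≤ 0.05 (inclusive),
wound p > 0.05 (strict), paired-t p < 0.05 (strict), fold change ≥ 2
(inclusive).

## Normalization conventions

Pipeline A uses quantile normalization (every sample mapped onto the
mean of order statistics); pipeline B uses floor-at-5.0 followed by
division by each sample's 75th percentile. Percentiles use the
nearest-rank convention — the smallest value whose cumulative fraction
reaches p — because it is deterministic and exactly testable. Row
standardization uses the population (divide-by-n) standard deviation.
"Standard scores of log₂ signals" is the implemented order of
operations: standard scores of negative values have no logarithm, so
log first, then centre and scale.

A caveat worth knowing: quantile normalization assumes the majority of
probes are unchanged across samples. When a large fraction of the
transcriptome responds to injury, rank shifts imprint a systematic
wobble on genuinely flat probes, which both inflates the null
interaction rate and makes truly wound-flat probes look wound-
responsive — the wound-insignificance filter then becomes very lossy.
The probe-pair concordance QC therefore runs on log₂ raw signals, where
the closed-form prediction (below) is exact; and the generator's
default conditions keep the responding fraction modest (~30%) so the
normalization assumption holds.

## The synthetic generator

The generator emulates the statistical structure of the experiment, not
its biology in detail. Per target: log₂ baseline ~ N(8, 1.5²); per
probe: an affinity offset ~ N(0, 0.5²) (two non-overlapping probes on
90% of targets); per sample: an animal-pool effect ~ N(0, 0.05²) shared
by the two probes of a target, and measurement noise ~ N(0, 0.25²) per
probe. Raw intensity is 2^x clipped below at 1. Pooling of several
limbs per sample is represented only as this small pool variance; pool
effects are independent across samples because each time point uses a
different pool of animals (the clutch-level component shared within a
replicate is neglected as small against measurement noise — a
simplification that keeps the two-way ANOVA exactly calibrated, at the
cost of understating long-range within-replicate correlation).

Nine planted classes define the truth (all effects in units of the
4-fold default, e = 2 on log₂):

| class | amputation course | wound course | limb bud |
|---|---|---|---|
| null | flat | flat | low |
| wound_common_early | strong early wave, 0.5-log₂ remodelling tail | identical to amputation | low |
| amp_transient | +e at 24–120 h | flat | low |
| amp_persistent | +e from 24 h onward | flat | high |
| amp_short_heterogeneous | +e at 24–52 h | flat | low |
| down_sudden | −e from 24 h | flat | low |
| down_continuous | linear decline to −e | flat | low |
| limb_dev_late | +e from 120 h | flat | high |
| cell_cycle_bimodal | +e from 24 h, sustained | +e at 24–120 h only | high |

`wound_common_early` and `cell_cycle_bimodal` are planted hard
negatives for the interaction screen: both respond in the wound course,
so the wound-insignificance filter must reject them even though the
cell-cycle class has a strong late interaction. Default proportions are
null-dominant (70% null, each planted class at 3–5%), keeping the
responding fraction compatible with quantile normalization while
leaving every per-class recall estimate enough probes.

The mature-proximal samples carry a small distinct tissue signature (2%
of targets, drawn from the null class, elevated only in the proximal
columns). Without it the proximal columns would be statistically
identical to the 0 h columns and the t = 0 sibling structure of the
condition tree would be decided by noise ties; with it, the proximal
samples still join the mature cluster, as they should.

What the generator does **not** emulate: probe sequences and
cross-hybridization, spatial expression, scanner-level artefacts,
missing values, unbalanced designs, and within-class profile
heterogeneity beyond noise. Passing the planted-recovery tests
therefore shows the pipelines are correct and calibrated under the
stated error model — not that they would achieve the same precision on
arrays whose noise violates it.

Closed-form concordance: two probes of one target share the class
profile and pool effects and differ by independent noise, so their
expected correlation is r = σ²_profile / (σ²_profile + σ²_noise) with
σ²_profile the variance of the shared offsets across the 84 columns
plus the pool variance. Empirical per-class medians match this within
0.01 on log₂ raw signals; predicted summary fractions use the Fisher-z
sampling distribution of r̂ around the class value.

## Clustering choices

* **Condition tree**: Pearson-correlation distance (d = 1 − r) on
  replicate-averaged log₂ profiles, UPGMA merging. scipy's
  implementation is verified exactly against a naive O(n³) oracle.
* **Profile clustering** (pipeline A): spherical-covariance Gaussian
  mixture fitted by EM on standardized median amputation profiles,
  component count selected by BIC over 1–8, ten seeded restarts. This
  is a transparent stand-in for HMM-based time-course clustering tools:
  it preserves their contract (≤ 8 components, data-driven count,
  profile-shape clusters) without re-implementing their internals. A
  cluster is *down* when its centroid's mean after 24 h falls below its
  mean before 12 h — a cluster-level rule, matching the discard of
  whole down-regulated clusters rather than per-probe thresholds.
* **LSD p-value clustering**: −log₁₀ p capped at 300 (keeps
  standardization finite under underflow), row-standardized, K-means
  with K by Davies–Bouldin minimization over 2–15. The early-switch
  cluster must have its amputation (12,24)-pair centroid above +1
  standardized unit with wound features within ±0.5 of the null mean;
  when no cluster qualifies the flag is absent.
* **Limb-bud partition**: K-means with K fixed at 3 over standardized
  profiles including the limb-bud columns (injury and limb-bud features
  jointly); a cluster is limb-bud-high when its centroid's limb-bud
  mean exceeds its injury-course mean. The call is centroid-relative
  because the standardized scale has no absolute expression units.
* Determinism: every stochastic stage takes the config seed; K-means
  uses seeded k-means++ initialisation; identical inputs and seed give
  byte-identical outputs.

## Evaluation conventions

Planted-truth scoring evaluates pipeline A at its carry-forward product
(the up-classified clusters), with positives the four up-regulated
amputation-specific classes; recall is additionally reported for the
persistent ∪ transient classes. Pipeline B positives are derived by
applying the pipeline's own defining rule (≥ 2-fold true difference at
≥ 3 consecutive time points) to the noise-free class templates, so the
positive set is exactly what the method is designed to find. An empty
selection scores precision 1.0 with a warning; empty positives are an
error.

Problem sizes: the default generator uses 5000 probes; the null
calibration uses 2000 probes per simulation with 100 (acceptance
script) to 400 (test suite) simulations; clustering K-recovery uses 50–
100 seeds for Davies–Bouldin and 10 seeds for the mixture. These sizes
give per-class estimates stable to a few percent while keeping a full
run of the suite around half a minute.

## Known limitations

* The classical equal-variance F is used throughout (no Welch variant,
  no moderated/shrunken variances, no mixed effects or permutation
  nulls).
* Balanced complete designs only; no missing-value support.
* Quantile normalization's unchanged-majority assumption is the
  pipeline's main fragility on heavily responding transcriptomes (see
  above).
* The GCT reader/writer supports version 1.2 only, without description
  metadata.
* Heat-map rendering is out of scope; the package exports
  clustering-ready standardized matrices and Newick trees instead.
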