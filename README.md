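# regenscreen

Comparative time-course expression analysis for identifying
**regeneration-specific genes** in the axolotl limb. After amputation, a
salamander limb forms a blastema and regrows; a deep lateral wound on the
contralateral limb heals without regenerating. Contrasting the two
matched time courses separates the genes that drive blastema formation
from the generic wound-healing program. `regenscreen` is a tested,
reusable implementation of that analysis for anyone working with paired
two-condition expression time courses: probe-level QC, both selection
pipelines, the clustering stages, and a synthetic-data generator with
planted gene classes so that every stage can be validated against a
known truth.

## The analysis

The design is a paired time course: 13 time points (0, 3, 6, 9, 12, 24,
36, 52, 72, 120, 168, 288, 528 h after injury) × two conditions
(amputation, lateral wound) × three biological replicates, where the two
conditions at each (time, replicate) are contralateral limbs, plus
developing limb-bud and mature-proximal reference samples. Two selection
pipelines run in parallel:

**Pipeline A — amputation-specific (interaction screen).** On
quantile-normalized log₂ signals, a balanced two-way ANOVA over the
3–528 h course tests the time × condition interaction per probe;
Benjamini–Hochberg control at 5% FDR defines the interaction-significant
set. Probes whose wound course alone is insignificant (one-way ANOVA
p > 0.05) form the amputation-specific set. Their replicate-median
amputation profiles are standardized (mean 0, sd 1) and clustered with a
BIC-selected spherical Gaussian mixture (≤ 8 components); down-regulated
clusters (centroid falls after 24 h) are discarded. The up-regulated
carry-forward set is sub-categorized by K-means over standardized
−log₁₀ Fisher-LSD p-values between consecutive time points in the 3–72 h
window (K chosen by Davies–Bouldin minimization), flagging the
*early-switch* cluster that jumps between 12 and 24 h in amputation only
— candidate triggers of blastema formation.

**Pipeline B — amputation-enriched (pairwise screen).** Raw signals are
floored at 5.0, each sample is divided by its 75th percentile
(nearest-rank), and marginally expressed probes (below 50 in > 80% of
samples) are rejected. A probe is selected when its amputation course
changes (one-way ANOVA, 5% FDR) and amputation differs from the paired
wound sample by ≥ 2-fold with paired-t p < 0.05 at ≥ 3 consecutive time
points. The up-regulated subset rises relative to the uninjured 0 h
sample.

Around the screens: probe-pair concordance QC (Pearson r between the two
probes of each target), the Pearson/average-linkage sample condition
tree that exposes the three phases of regeneration (early wound healing
→ divergence → re-established limb development), probe → target →
human-homolog collapsing, and a K = 3 partition relating selected genes
to limb-bud expression (redeployed development genes vs
regeneration-restricted ones).

## Worked example

```sh
python examples/02_amputation_specific_screen.py
```

```
interaction-significant probes (5% FDR): 1466
wound-insignificant (amputation-specific): 1094
profile clusters: 8 (up: [2, 4, 5, 6], down: [1, 3, 7, 8])
up-regulated carry-forward set: 705
LSD p-value clusters: K = 3 (Davies-Bouldin estimate)
early-switch cluster: 1 (497 probes)

against the planted truth: precision 1.000, recall 0.909
```

Of 5000 synthetic probes, 1466 show a significant time × condition
interaction; 1094 of those have a quiet wound course; after discarding
the down-regulated clusters, 705 up-regulated probes carry forward, and
the LSD profiling isolates the early-switch group. Because the data are
synthetic, the selection can be scored against the planted truth: every
carried-forward probe is a genuinely amputation-specific class
(precision 1.0) and 91% of the planted persistently/transiently
up-regulated genes are recovered. The other examples cover QC and
concordance, the pairwise screen, the condition tree, and the limb-bud
partition; `regenscreen demo --seed 1 --out-dir out/` runs everything
from the shell in one process.

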