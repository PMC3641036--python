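"""The pairwise screen for amputation-enriched genes (pipeline B).

Raw signals are floored at 5.0, divided by each sample's 75th
percentile, and marginally expressed probes are rejected.  A probe is
selected when its amputation time course changes (one-way ANOVA, 5%
FDR) and it differs from the contralateral wound sample by >= 2-fold
with paired-t p < 0.05 at three or more consecutive time points; the
up-regulated subset rises relative to the uninjured 0 h sample.
"""

from regenscreen import AnalysisConfig, SyntheticConfig, generate_dataset
from regenscreen.selection import pipeline_b_tests, select_amp_enriched, collapse_probes
from regenscreen.synthetic import evaluate_selection

matrix, design, annotation, truth = generate_dataset(SyntheticConfig(rng_seed=1))
config = AnalysisConfig(rng_seed=1)

tests = pipeline_b_tests(matrix, design, config)
print(f"probes kept by the marginal filter: {len(tests.kept_probes)}")
print(f"one-way significant (5% FDR): {int((tests.anova['q'] <= 0.05).sum())}")

result = select_amp_enriched(tests, design, config)
print(f"selected (2-fold + paired t at >=3 consecutive points): {len(result.selected)}")
print(f"up-regulated relative to 0 h: {len(result.up_regulated)}")

collapse = collapse_probes(result.up_regulated, annotation, tests.normalized)
print(f"collapsed: {collapse.n_probes} probes -> {collapse.n_targets} targets, "
      f"{collapse.n_targets_without_homolog} without homolog, "
      f"{collapse.n_homologs} distinct human homologs")

score = evaluate_selection(
    truth, result.selected, positive_probes=truth.pipeline_b_positive_probes()
)
print(f"\nagainst the planted truth: precision {score.precision:.3f}, "
      f"recall {score.recall:.3f}")
print("The positives here are probes whose true profiles satisfy the")
print("pipeline's own rule: a >=2-fold true difference at >=3 consecutive points.")
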