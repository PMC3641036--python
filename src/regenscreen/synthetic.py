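"""Synthetic two-condition injury time courses with planted gene classes.

The generator emulates the statistical structure of the comparative
regeneration experiment: 13 time points (0-528 h after injury) x two
injury conditions (limb amputation vs deep lateral wound) x three
biological replicates, where the amputation and wound sample at the same
(time, replicate) are contralateral limbs of the same animal pool, plus
three developing limb-bud samples and three mature-proximal reference
samples.  Most targets carry two independent non-overlapping probes that
share the target's true profile but have independent affinities and
measurement noise.

Each target is assigned one of nine expression classes.  ``null`` probes
are flat in both conditions.  ``wound_common_early`` is the shared injury
response: a strong early wave, identical in both conditions, decaying to
a low persistent remodelling tail.  The amputation-specific classes keep
a flat wound course while the amputation course departs from baseline at
24 h (transient or persistent up-regulation, a short heterogeneous pulse,
sudden or continuous down-regulation) or at 120 h (re-activated limb
development).  ``cell_cycle_bimodal`` rises in both conditions during the
proliferative phase but only the amputation course sustains it - a hard
negative for the amputation-specific screen, because its wound course is
not flat.

Signals are multiplicative log-normal: on the log2 scale a probe's value
is baseline + probe affinity + class offset + animal-pool effect + noise,
and the raw intensity is 2**x clipped below at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import (
    TIMEPOINTS,
    ExpressionMatrix,
    ProbeAnnotation,
    SampleDesign,
    make_sample_id,
)

CLASS_NAMES = (
    "null",
    "wound_common_early",
    "amp_transient",
    "amp_persistent",
    "amp_short_heterogeneous",
    "down_sudden",
    "down_continuous",
    "limb_dev_late",
    "cell_cycle_bimodal",
)

#: Classes whose limb-bud expression is high (re-used in limb development
#: or in the proliferating bud), the remainder are limb-bud low.
LIMB_BUD_HIGH_CLASSES = frozenset(
    {"amp_persistent", "limb_dev_late", "cell_cycle_bimodal"}
)

#: Classes with a flat wound course and a non-flat amputation course: the
#: ground-truth positives of the interaction (amputation-specific) screen.
AMP_SPECIFIC_CLASSES = frozenset(
    {
        "amp_transient",
        "amp_persistent",
        "amp_short_heterogeneous",
        "down_sudden",
        "down_continuous",
        "limb_dev_late",
    }
)

#: Common-response classes planted as hard negatives for the
#: amputation-specific screen (their wound course is significant).
WOUND_RESPONSIVE_CLASSES = frozenset({"wound_common_early", "cell_cycle_bimodal"})

# Shared early injury wave, as a fraction of the class effect size, at the
# canonical 13 time points.  Large distinct early steps give each early
# time point its own transcriptional state; the 0.25 tail is the residual
# remodelling signature that keeps late wound samples off baseline.
_WCE_FACTORS = np.array(
    [0.0, 0.6, 1.1, 1.5, 0.75, 0.45, 0.35, 0.3, 0.28, 0.25, 0.25, 0.25, 0.25]
)

# Null-dominant default proportions with every planted class present at a
# few percent.  Quantile normalization assumes most probes are unchanged;
# keeping the responding fraction modest (~30%) respects that assumption
# while still planting enough probes per class for stable per-class
# recall estimates.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "null": 0.70,
    "wound_common_early": 0.05,
    "cell_cycle_bimodal": 0.03,
    "amp_transient": 0.05,
    "amp_persistent": 0.05,
    "amp_short_heterogeneous": 0.03,
    "down_sudden": 0.03,
    "down_continuous": 0.03,
    "limb_dev_late": 0.03,
}


def template_profile(
    class_name: str,
    timepoints: Sequence[int] = TIMEPOINTS,
    effect_size: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-condition mean log2 offsets (amputation, wound) for a class.

    Offsets are relative to the probe's flat baseline; deterministic for
    fixed arguments.
    """
    t = np.asarray(timepoints, dtype=float)
    e = float(effect_size)
    zero = np.zeros_like(t)
    if class_name == "null":
        return zero.copy(), zero.copy()
    if class_name == "wound_common_early":
        common = e * np.interp(t, TIMEPOINTS, _WCE_FACTORS)
        return common.copy(), common.copy()
    if class_name == "amp_transient":
        return e * ((t >= 24) & (t <= 120)), zero.copy()
    if class_name == "amp_persistent":
        return e * (t >= 24), zero.copy()
    if class_name == "amp_short_heterogeneous":
        return e * ((t >= 24) & (t <= 52)), zero.copy()
    if class_name == "down_sudden":
        return -e * (t >= 24), zero.copy()
    if class_name == "down_continuous":
        late = t >= 24
        ramp = np.zeros_like(t)
        m = int(late.sum())
        if m:
            ramp[late] = -e * (np.arange(1, m + 1) / m)
        return ramp, zero.copy()
    if class_name == "limb_dev_late":
        return e * (t >= 120), zero.copy()
    if class_name == "cell_cycle_bimodal":
        # proliferation rises in both conditions, but only the regenerating
        # limb sustains it after the wound program extinguishes at ~120 h
        amp = e * (t >= 24)
        wound = e * ((t >= 24) & (t <= 120))
        return amp, wound
    raise ValueError(f"unknown expression class {class_name!r}")


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the generator."""

    n_probes: int = 5000
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    effect_size_log2: float = 2.0
    noise_sd_log2: float = 0.25
    replicate_effect_sd: float = 0.05
    paired_probe_fraction: float = 0.9
    probe_affinity_sd: float = 0.5
    proximal_signature_fraction: float = 0.02
    n_replicates: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        props = dict(self.class_proportions)
        unknown = set(props) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown classes in proportions: {sorted(unknown)}")
        total = sum(props.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class proportions sum to {total}, expected 1")
        for name in (
            "baseline_log2_sd",
            "noise_sd_log2",
            "replicate_effect_sd",
            "probe_affinity_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.paired_probe_fraction <= 1:
            raise ValueError("paired_probe_fraction must lie in [0, 1]")
        self.class_proportions = props


@dataclass
class GroundTruth:
    """Planted per-probe truth emitted alongside every synthetic dataset."""

    table: pd.DataFrame  # index probe_id: target_id, class_name, limb_bud_level
    effect_size_log2: float
    replicate_effect_sd: float
    noise_sd_log2: float

    def class_of(self) -> pd.Series:
        return self.table["class_name"]

    def probes_of(self, classes: Iterable[str]) -> set[str]:
        classes = set(classes)
        mask = self.table["class_name"].isin(classes)
        return set(self.table.index[mask])

    def amp_specific_probes(self) -> set[str]:
        return self.probes_of(AMP_SPECIFIC_CLASSES)

    def true_profiles(self, class_name: str) -> tuple[np.ndarray, np.ndarray]:
        return template_profile(class_name, TIMEPOINTS, self.effect_size_log2)

    def pipeline_b_positive_probes(
        self, fold_cutoff: float = 2.0, min_run: int = 3
    ) -> set[str]:
        """Probes whose *true* profiles satisfy the pairwise selection rule.

        A class is positive when its noise-free amputation and wound mean
        profiles differ by at least ``log2(fold_cutoff)`` at ``min_run``
        consecutive injury time points - the pairwise pipeline's own
        defining criterion applied to the planted truth.
        """
        cut = np.log2(fold_cutoff)
        positive_classes = []
        for cls in CLASS_NAMES:
            amp, wound = self.true_profiles(cls)
            diff = np.abs(amp - wound)[1:]  # injury time points, 0 h excluded
            if _longest_run(diff >= cut - 1e-12) >= min_run:
                positive_classes.append(cls)
        return self.probes_of(positive_classes)


def _longest_run(flags: np.ndarray) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def _build_design(n_replicates: int) -> SampleDesign:
    rows = []
    for cond in ("amputation", "lateral_wound"):
        for t in TIMEPOINTS:
            for r in range(1, n_replicates + 1):
                rows.append((make_sample_id(cond, t, r), cond, t, r))
    for r in range(1, n_replicates + 1):
        rows.append((make_sample_id("limb_bud", None, r), "limb_bud", np.nan, r))
    for r in range(1, n_replicates + 1):
        rows.append((make_sample_id("mature_proximal", 0, r), "mature_proximal", 0, r))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "condition", "time_hours", "replicate_id"]
    )
    return SampleDesign(frame)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleDesign, ProbeAnnotation, GroundTruth]:
    """Generate a complete raw-scale dataset with known planted truth.

    Identical config (including seed) yields an identical dataset.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_probes = config.n_probes
    active = [c for c, p in config.class_proportions.items() if p > 0]
    if n_probes < len(active):
        raise ValueError("n_probes smaller than the number of active classes")

    # --- targets and probes ------------------------------------------------
    n_targets = max(1, round(n_probes / (1 + config.paired_probe_fraction)))
    n_paired = n_probes - n_targets  # targets carrying a second probe
    if n_paired < 0 or n_paired > n_targets:
        raise ValueError("paired_probe_fraction inconsistent with n_probes")
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    target_class = rng.choice(classes, size=n_targets, p=probs)
    paired_flags = np.zeros(n_targets, dtype=bool)
    paired_flags[rng.choice(n_targets, size=n_paired, replace=False)] = True

    probe_target = np.concatenate(
        [np.arange(n_targets), np.flatnonzero(paired_flags)]
    )
    order = np.argsort(probe_target, kind="stable")
    probe_target = probe_target[order]
    # strand-qualified target names; one contig per target here
    target_ids = np.array([f"s.contig{i:05d}" for i in range(n_targets)])
    contig_ids = np.array([f"contig{i:05d}" for i in range(n_targets)])
    probe_ids = []
    seen: dict[int, int] = {}
    for tgt in probe_target:
        k = seen.get(tgt, 0) + 1
        seen[tgt] = k
        probe_ids.append(f"probe{tgt:05d}_{k}")

    # --- per-target / per-probe random effects ----------------------------
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_targets)
    affinity = rng.normal(0.0, config.probe_affinity_sd, n_probes)
    n_rep = config.n_replicates
    n_tp = len(TIMEPOINTS)
    # animal-pool sampling effect, independent per sample: each time point
    # uses a different pool of animals, so pool effects do not persist
    # along the time course (clutch-level sharing is neglected as small)
    pool_injury = rng.normal(
        0.0, config.replicate_effect_sd, (n_targets, 2, n_tp, n_rep)
    )
    pool_bud = rng.normal(0.0, config.replicate_effect_sd, (n_targets, n_rep))
    pool_prox = rng.normal(0.0, config.replicate_effect_sd, (n_targets, n_rep))

    # mature-proximal tissue signature on a subset of null targets
    prox_sig = np.zeros(n_targets, dtype=bool)
    null_targets = np.flatnonzero(target_class == "null")
    n_sig = min(len(null_targets), round(config.proximal_signature_fraction * n_targets))
    if n_sig:
        prox_sig[rng.choice(null_targets, size=n_sig, replace=False)] = True

    # --- class offsets per target ------------------------------------------
    e = config.effect_size_log2
    amp_off = np.zeros((n_targets, n_tp))
    wound_off = np.zeros((n_targets, n_tp))
    bud_off = np.zeros(n_targets)
    for cls in classes:
        mask = target_class == cls
        if not mask.any():
            continue
        amp, wound = template_profile(cls, TIMEPOINTS, e)
        amp_off[mask] = amp
        wound_off[mask] = wound
        if cls in LIMB_BUD_HIGH_CLASSES:
            bud_off[mask] = e
    prox_off = np.where(prox_sig, e, 0.0)

    # --- assemble log2 signal ----------------------------------------------
    design = _build_design(n_rep)
    sample_ids = design.sample_ids
    n_samples = len(sample_ids)
    log2 = np.empty((n_probes, n_samples))
    col = 0
    cond_off = {"amputation": amp_off, "lateral_wound": wound_off}
    for ci, cond in enumerate(("amputation", "lateral_wound")):
        off = cond_off[cond]
        for ti in range(n_tp):
            for r in range(n_rep):
                log2[:, col] = (
                    baseline[probe_target]
                    + off[probe_target, ti]
                    + pool_injury[probe_target, ci, ti, r]
                )
                col += 1
    for r in range(n_rep):
        log2[:, col] = baseline[probe_target] + bud_off[probe_target] + pool_bud[
            probe_target, r
        ]
        col += 1
    for r in range(n_rep):
        log2[:, col] = baseline[probe_target] + prox_off[probe_target] + pool_prox[
            probe_target, r
        ]
        col += 1
    log2 += affinity[:, None]
    log2 += rng.normal(0.0, config.noise_sd_log2, (n_probes, n_samples))
    raw = np.clip(np.exp2(log2), 1.0, None)

    matrix = ExpressionMatrix(
        pd.DataFrame(raw, index=probe_ids, columns=sample_ids), scale_tag="raw"
    )
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "target_id": target_ids[probe_target],
                "contig_id": contig_ids[probe_target],
                "homolog_id": [
                    f"NP_{(tgt % 900) + 100:06d}" if tgt % 3 else pd.NA
                    for tgt in probe_target
                ],
                "homology_evalue": [
                    1e-6 if tgt % 3 else np.nan for tgt in probe_target
                ],
            }
        )
    )
    truth_table = pd.DataFrame(
        {
            "target_id": target_ids[probe_target],
            "class_name": target_class[probe_target],
            "limb_bud_level": np.where(
                np.isin(target_class[probe_target], list(LIMB_BUD_HIGH_CLASSES)),
                "high",
                "low",
            ),
            "proximal_signature": prox_sig[probe_target],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    truth = GroundTruth(
        table=truth_table,
        effect_size_log2=e,
        replicate_effect_sd=config.replicate_effect_sd,
        noise_sd_log2=config.noise_sd_log2,
    )
    return matrix, design, annotation, truth


# ---------------------------------------------------------------------------
# Evaluation against the planted truth


@dataclass
class SelectionScore:
    precision: float
    recall: float
    n_selected: int
    n_positives: int
    n_true_positives: int


def evaluate_selection(
    truth: GroundTruth,
    selected: Iterable[str],
    positive_classes: Iterable[str] | None = None,
    positive_probes: Iterable[str] | None = None,
) -> SelectionScore:
    """Precision / recall of a selected probe set against planted truth.

    Positives are given either as class names or as an explicit probe set.
    An empty selection scores precision 1.0 (with a warning); empty
    positives are an error because recall is undefined.
    """
    selected = set(selected)
    unknown = selected - set(truth.table.index)
    if unknown:
        raise ValueError(f"selected probes absent from truth: {sorted(unknown)[:5]}")
    if positive_probes is not None:
        positives = set(positive_probes)
    elif positive_classes is not None:
        positives = truth.probes_of(positive_classes)
    else:
        raise ValueError("provide positive_classes or positive_probes")
    if not positives:
        raise ValueError("positive set is empty; recall undefined")
    tp = len(selected & positives)
    if selected:
        precision = tp / len(selected)
    else:
        warnings.warn("empty selection: precision reported as 1.0", stacklevel=2)
        precision = 1.0
    recall = tp / len(positives)
    return SelectionScore(precision, recall, len(selected), len(positives), tp)


# ---------------------------------------------------------------------------
# Closed-form probe-pair concordance prediction


def predicted_pair_correlation(truth: GroundTruth, class_name: str) -> float:
    """Expected Pearson r between two probes of one target of this class.

    Both probes share the target's class offsets and animal-pool effects
    (profile variance) and differ by independent log2 noise, so
    r = sigma2_profile / (sigma2_profile + sigma2_noise), with the profile
    variance taken across the study's sample columns.
    """
    amp, wound = truth.true_profiles(class_name)
    bud = truth.effect_size_log2 if class_name in LIMB_BUD_HIGH_CLASSES else 0.0
    n_rep = 3
    cols = np.concatenate(
        [np.repeat(amp, n_rep), np.repeat(wound, n_rep), [bud] * n_rep, [0.0] * n_rep]
    )
    var_profile = cols.var() + truth.replicate_effect_sd**2
    return var_profile / (var_profile + truth.noise_sd_log2**2)


def predicted_concordance_fractions(
    truth: GroundTruth,
    eligible_probes: Iterable[str] | None = None,
    thresholds: Sequence[float] = (0.8, 0.9),
    n_samples: int = 84,
) -> dict[float, float]:
    """Predicted fraction of probe pairs with empirical r above thresholds.

    Pairs are the doubly-probed targets whose probes are both eligible
    (default: all non-null probes); each contributes its class's expected
    correlation, with sampling noise of the empirical coefficient handled
    through the Fisher z approximation atanh(r_hat) ~ N(atanh(r), 1/(n-3)).
    """
    t = truth.table
    if eligible_probes is None:
        eligible = set(t.index[t["class_name"] != "null"])
    else:
        eligible = set(eligible_probes)
    sub = t.loc[t.index.isin(eligible)]
    pair_sizes = sub.groupby("target_id").size()
    paired_targets = pair_sizes.index[pair_sizes == 2]
    classes = (
        sub.drop_duplicates("target_id")
        .set_index("target_id")
        .loc[paired_targets, "class_name"]
    )
    counts = classes.value_counts()
    if counts.sum() == 0:
        raise ValueError("no eligible probe pairs to predict over")
    w = counts / counts.sum()
    out = {}
    scale = 1.0 / np.sqrt(n_samples - 3)
    for thr in thresholds:
        probs = []
        for cls in w.index:
            r = predicted_pair_correlation(truth, cls)
            z = np.arctanh(min(r, 1 - 1e-12))
            probs.append(sps.norm.sf(np.arctanh(thr), loc=z, scale=scale))
        out[thr] = float(np.dot(w.to_numpy(), probs))
    return out


# ---------------------------------------------------------------------------
# Deterministic 12-probe toy dataset for the pairwise pipeline


#: The probes the pairwise pipeline is designed to select from the toy set.
TOY_EXPECTED_SELECTED = frozenset(
    {"toy_run_mid", "toy_down_run", "toy_run_end", "toy_run_early"}
)
#: ... and the up-regulated subset among them.
TOY_EXPECTED_UP = frozenset({"toy_run_mid", "toy_run_end", "toy_run_early"})


def toy_pipeline_b_dataset() -> tuple[ExpressionMatrix, SampleDesign, ProbeAnnotation]:
    """A fully deterministic 12-probe fixture for the pairwise pipeline.

    Four "anchor" probes hold constant values 1e4..4e4 so that every
    sample's nearest-rank 75th percentile equals 10000 exactly, making the
    percentile shift a uniform rescaling and fold changes exact.  The
    eight dynamic probes exercise each selection rule:

    - ``toy_run_mid``    2.8-fold up at 24/36/52 h        -> selected, up
    - ``toy_down_run``   2.8-fold down at 24..72 h        -> selected, down
    - ``toy_run_end``    4-fold up at 168/288/528 h       -> selected, up
    - ``toy_run_early``  exactly 2-fold up at 3..12 h     -> selected, up
                         (pins the inclusive FC >= 2 tie rule)
    - ``toy_run_broken`` passes at 24, 52, 72 h only      -> run of 2, rejected
    - ``toy_small_fc``   1.74-fold with significant t     -> rejected
    - ``toy_marginal``   below background almost always   -> filtered out
    - ``toy_both``       same response in both conditions -> paired t fails

    Replicate structure is a deterministic multiplicative jitter, opposite
    in the two conditions, so every statistic is well defined and the
    selected set is exact, with no randomness anywhere.
    """
    design = _build_design(3)
    # 31/32 and 33/32 are exact binary fractions summing exactly to 2, so
    # replicate means (and hence fold changes) are exact in float arithmetic
    amp_jit = np.array([31 / 32, 1.0, 33 / 32])
    lw_jit = amp_jit[::-1]
    tp = np.array(TIMEPOINTS)

    def profiles(base, amp_log2, lw_log2):
        """Raw values over the design's 84 columns from log2 offsets."""
        row = {}
        for ti, t in enumerate(TIMEPOINTS):
            for r in range(1, 4):
                row[make_sample_id("amputation", t, r)] = (
                    base * 2.0 ** amp_log2[ti] * amp_jit[r - 1]
                )
                row[make_sample_id("lateral_wound", t, r)] = (
                    base * 2.0 ** lw_log2[ti] * lw_jit[r - 1]
                )
        for r in range(1, 4):
            row[make_sample_id("limb_bud", None, r)] = base * amp_jit[r - 1]
            row[make_sample_id("mature_proximal", 0, r)] = base * lw_jit[r - 1]
        return row

    zeros = np.zeros(len(tp))
    rows = {}
    rows["toy_run_mid"] = profiles(
        400, 1.5 * ((tp >= 24) & (tp <= 52)), zeros
    )
    rows["toy_down_run"] = profiles(
        400, -1.5 * ((tp >= 24) & (tp <= 72)), zeros
    )
    rows["toy_run_end"] = profiles(200, 2.0 * (tp >= 168), zeros)
    rows["toy_run_early"] = profiles(
        800, 1.0 * ((tp >= 3) & (tp <= 12)), zeros
    )
    rows["toy_run_broken"] = profiles(
        300, 1.5 * np.isin(tp, [24, 52, 72]), zeros
    )
    rows["toy_small_fc"] = profiles(
        500, 0.8 * ((tp >= 24) & (tp <= 72)), zeros
    )
    marginal = profiles(10, zeros, zeros)
    # above background in exactly two samples (2% of columns)
    marginal[make_sample_id("amputation", 0, 1)] = 60.0
    marginal[make_sample_id("lateral_wound", 0, 1)] = 60.0
    rows["toy_marginal"] = marginal
    both = 2.0 * ((tp >= 24) & (tp <= 120))
    rows["toy_both"] = profiles(600, both, both)
    for k, value in enumerate((10000.0, 20000.0, 30000.0, 40000.0), start=1):
        rows[f"toy_anchor{k}"] = {s: value for s in design.sample_ids}

    frame = pd.DataFrame.from_dict(rows, orient="index")[design.sample_ids]
    matrix = ExpressionMatrix(frame, scale_tag="raw")
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": list(rows),
                "target_id": [f"s.toy{c}" for c in range(len(rows))],
                "contig_id": [f"toyc{c}" for c in range(len(rows))],
            }
        )
    )
    return matrix, design, annotation
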