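"""The two gene-selection pipelines and probe-to-target collapsing.

Pipeline A (amputation-specific): quantile-normalised signals, two-way
ANOVA over the 3-528 h injury course, Benjamini-Hochberg 5% FDR on the
time x condition interaction, then a wound-course insignificance filter
(one-way wound ANOVA p > 0.05).  The survivors are profile-clustered on
their replicate-median amputation course; down-regulated clusters are
discarded, and the up-regulated carry-forward set is sub-categorised by
K-means over standardized -log10 Fisher-LSD p-values (K by Davies-
Bouldin), looking for the early-switch cluster that jumps between 12 and
24 h in amputation while staying silent in the wound course.

Pipeline B (amputation-enriched): floor + 75th-percentile shift +
marginal-probe rejection, one-way amputation ANOVA at 5% FDR, then a
paired t (p < 0.05) combined with a 2-fold change at >= 3 consecutive
injury time points; the up-regulated subset rises relative to the
uninjured 0 h sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    AnalysisConfig,
    ExpressionMatrix,
    ProbeAnnotation,
    SampleDesign,
)
from . import preprocess, stats
from .clustering import ClusterResult, kmeans_with_db, mixture_profile_cluster


# ---------------------------------------------------------------------------
# Test tables per pipeline


@dataclass
class PipelineATests:
    """Interaction-screen statistics on quantile-normalised signals."""

    table: pd.DataFrame  # F/p/q interaction + wound one-way F/p
    normalized: ExpressionMatrix
    expressed_probes: list[str]


def pipeline_a_tests(
    matrix: ExpressionMatrix, design: SampleDesign, config: AnalysisConfig
) -> PipelineATests:
    expressed = preprocess.filter_expressed(
        matrix, background=config.background, min_samples=config.min_expressed_samples
    )
    sub = matrix.subset_probes(expressed)
    normalized = preprocess.quantile_normalize(sub)
    times = [t for t in design.times("amputation") if t > 0]
    two_way = stats.two_way_time_condition_anova(normalized, design, times=times)
    q_int, _ = stats.bh_fdr(two_way["p_interaction"].to_numpy(), config.fdr_level)
    wound = stats.one_way_time_anova(normalized, design, "lateral_wound", times=times)
    table = pd.DataFrame(
        {
            "F_interaction": two_way["F_interaction"],
            "p_interaction": two_way["p_interaction"],
            "q_interaction": q_int,
            "F_wound": wound["F"],
            "p_wound": wound["p"],
        },
        index=two_way.index,
    )
    return PipelineATests(table=table, normalized=normalized, expressed_probes=expressed)


def select_amp_specific(tests: PipelineATests, config: AnalysisConfig) -> set[str]:
    """Interaction q <= FDR level AND wound one-way p > the wound floor."""
    t = tests.table
    for col in ("q_interaction", "p_wound"):
        if col not in t.columns:
            raise ValueError(f"missing test column {col!r}")
    mask = (t["q_interaction"] <= config.fdr_level) & (
        t["p_wound"] > config.wound_pvalue_floor
    )
    return set(t.index[mask])


# ---------------------------------------------------------------------------
# Pipeline A clustering stages


@dataclass
class ProfileClusters:
    result: ClusterResult
    up_clusters: list[int]
    down_clusters: list[int]
    carry_forward: set[str]  # probes in up-classified clusters
    profiles: pd.DataFrame  # standardized median amputation profiles


def profile_cluster(
    selected: set[str],
    matrix: ExpressionMatrix,
    design: SampleDesign,
    config: AnalysisConfig,
) -> ProfileClusters:
    """Mixture-cluster the replicate-median amputation profiles of the
    selected probes and keep only up-classified clusters.

    A cluster is *down* when its centroid's mean over t >= 24 h falls
    below its mean over t <= 12 h (on the standardized scale), else *up*.
    """
    median = preprocess.summarize_replicates(
        matrix.subset_probes(sorted(selected)), design, statistic="median"
    )
    amp_cols = [c for c in median.data.columns if c.startswith("amputation")]
    amp = ExpressionMatrix(median.data[amp_cols], scale_tag=median.scale_tag)
    std = preprocess.standardize_rows(amp, log_first=True)
    result = mixture_profile_cluster(
        std.data,
        max_components=config.mixture_max_components,
        restarts=config.mixture_iterations,
        seed=config.rng_seed,
    )
    times = np.array([int(c.rsplit("_", 1)[1]) for c in amp_cols])
    early = times <= 12
    late = times >= 24
    up, down = [], []
    for label in range(1, result.k + 1):
        centroid = result.centroids[label - 1]
        (down if centroid[late].mean() < centroid[early].mean() else up).append(label)
    carry = set(result.labels.index[result.labels.isin(up)])
    return ProfileClusters(
        result=result,
        up_clusters=up,
        down_clusters=down,
        carry_forward=carry,
        profiles=std.data,
    )


@dataclass
class PValueClusters:
    result: ClusterResult
    features: pd.DataFrame  # row-standardized -log10 LSD p-values
    early_switch_cluster: int | None


def pvalue_profile_cluster(
    probes: set[str],
    matrix: ExpressionMatrix,
    design: SampleDesign,
    config: AnalysisConfig,
) -> PValueClusters:
    """K-means over standardized -log10 LSD p-value patterns (3-72 h).

    K is chosen by Davies-Bouldin minimisation over 2..kmeans_kmax.  The
    early-switch cluster is the one whose amputation (12,24)-pair feature
    centroid is maximal, provided that centroid clearly exceeds the null
    feature mean while its wound features stay near it; when no cluster
    qualifies the flag is absent.
    """
    sub = matrix.subset_probes(sorted(probes))
    pvals = stats.lsd_feature_table(sub, design, window=config.lsd_window)
    neglog = -np.log10(np.clip(pvals.to_numpy(), 10.0**-config.neglog10_cap, None))
    neglog = np.minimum(neglog, config.neglog10_cap)
    mean = neglog.mean(axis=1, keepdims=True)
    sd = neglog.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # featureless probes sit at the null mean
    features = pd.DataFrame(
        (neglog - mean) / sd, index=pvals.index, columns=pvals.columns
    )
    kmax = min(config.kmeans_kmax, max(2, len(features) - 1))
    result = kmeans_with_db(
        features,
        k_range=range(2, kmax + 1),
        seed=config.rng_seed,
        restarts=config.kmeans_restarts,
    )
    switch_col = features.columns.get_loc("amputation_12_24")
    wound_cols = [i for i, c in enumerate(features.columns) if "lateral_wound" in c]
    best_label, best_score = None, -np.inf
    for label in range(1, result.k + 1):
        centroid = result.centroids[label - 1]
        if centroid[switch_col] > best_score:
            best_label, best_score = label, centroid[switch_col]
    early = None
    if best_label is not None and best_score > 1.0:
        wound_mean = np.abs(result.centroids[best_label - 1][wound_cols]).mean()
        if wound_mean < 0.5:
            early = best_label
    return PValueClusters(result=result, features=features, early_switch_cluster=early)


# ---------------------------------------------------------------------------
# Pipeline B


def consecutive_run(flags: np.ndarray, min_run: int = 3) -> bool:
    """True iff >= min_run consecutive true flags exist (time-ordered)."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("empty flag vector")
    run = best = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best >= min_run


@dataclass
class PipelineBTests:
    """Pairwise-comparison statistics on floored, percentile-shifted signals."""

    anova: pd.DataFrame  # F, p, q for the amputation one-way course (incl. 0 h)
    t_pvalues: pd.DataFrame  # probes x injury time points
    fold_changes: pd.DataFrame  # probes x injury time points
    normalized: ExpressionMatrix
    kept_probes: list[str]


def pipeline_b_tests(
    matrix: ExpressionMatrix, design: SampleDesign, config: AnalysisConfig
) -> PipelineBTests:
    kept = preprocess.filter_marginal(
        matrix, background=config.background, marginal_fraction=config.marginal_fraction
    )
    sub = matrix.subset_probes(kept)
    floored = preprocess.floor_signals(sub, floor=config.signal_floor)
    shifted = preprocess.percentile_shift_normalize(
        floored, percentile=config.shift_percentile
    )
    anova = stats.one_way_time_anova(shifted, design, "amputation")
    q, _ = stats.bh_fdr(anova["p"].to_numpy(), config.fdr_level)
    anova = anova.assign(q=q)
    times = [t for t in design.times("amputation") if t > 0]
    t_cols, fc_cols = {}, {}
    for t in times:
        t_cols[t] = stats.paired_t_per_timepoint(shifted, design, t)["p"]
        fc_cols[t] = stats.fold_change(shifted, design, t)
    return PipelineBTests(
        anova=anova,
        t_pvalues=pd.DataFrame(t_cols),
        fold_changes=pd.DataFrame(fc_cols),
        normalized=shifted,
        kept_probes=kept,
    )


@dataclass
class PipelineBSelection:
    selected: set[str]
    up_regulated: set[str]
    table: pd.DataFrame  # per-probe pass/fail bookkeeping


def select_amp_enriched(
    tests: PipelineBTests,
    design: SampleDesign,
    config: AnalysisConfig,
) -> PipelineBSelection:
    """ANOVA q <= FDR level plus a >= min_consecutive run of time points
    where the paired t is significant (p < 0.05, strict) and the fold
    change passes the inclusive 2-fold rule.

    The up-regulated subset contains probes whose mean log2 amputation
    signal over the passing time points exceeds their 0 h amputation mean.
    """
    times = list(tests.t_pvalues.columns)
    t_pass = tests.t_pvalues.to_numpy() < config.wound_pvalue_floor  # strict p < 0.05
    fc_pass = stats.two_fold_rule(tests.fold_changes.to_numpy(), config.fold_cutoff)
    flags = t_pass & fc_pass
    anova_pass = (tests.anova["q"] <= config.fdr_level).to_numpy()
    has_run = np.array(
        [consecutive_run(row, config.min_consecutive) for row in flags]
    )
    selected_mask = anova_pass & has_run
    probes = tests.anova.index
    selected = set(probes[selected_mask])

    log2 = stats.log2_signals(tests.normalized)
    amp0 = log2.data[design.samples("amputation", 0)].to_numpy().mean(axis=1)
    amp_means = {
        t: log2.data[design.samples("amputation", t)].to_numpy().mean(axis=1)
        for t in times
    }
    up = set()
    for i, probe in enumerate(probes):
        if not selected_mask[i]:
            continue
        passing = [t for j, t in enumerate(times) if flags[i, j]]
        run_mean = np.mean([amp_means[t][i] for t in passing])
        if run_mean > amp0[i]:
            up.add(probe)
    table = pd.DataFrame(
        {
            "anova_q": tests.anova["q"],
            "anova_pass": anova_pass,
            "consecutive_run_pass": has_run,
            "selected": selected_mask,
            "up_regulated": [p in up for p in probes],
        },
        index=probes,
    )
    return PipelineBSelection(selected=selected, up_regulated=up, table=table)


# ---------------------------------------------------------------------------
# Probe -> target -> homolog collapse


@dataclass
class CollapseResult:
    n_probes: int
    n_targets: int
    n_targets_without_homolog: int
    n_homologs: int
    per_target: pd.DataFrame  # target_id, probes, homolog_id, pair_r

    def counts(self) -> dict[str, int]:
        return {
            "n_probes": self.n_probes,
            "n_targets": self.n_targets,
            "n_targets_without_homolog": self.n_targets_without_homolog,
            "n_homologs": self.n_homologs,
        }


def collapse_probes(
    probes: set[str],
    annotation: ProbeAnnotation,
    matrix: ExpressionMatrix | None = None,
) -> CollapseResult:
    """Collapse a selected probe set to distinct targets and homologs.

    Where two selected probes share a target and a matrix is given, the
    probe-pair Pearson correlation is attached to that target.
    """
    annot = annotation.table.set_index("probe_id")
    missing = probes - set(annot.index)
    if missing:
        raise ValueError(f"probes missing from annotation: {sorted(missing)[:5]}")
    sub = annot.loc[sorted(probes)]
    rows = []
    for target, grp in sub.groupby("target_id"):
        homolog = grp["homolog_id"].dropna()
        homolog_id = homolog.iloc[0] if len(homolog) else None
        pair_r = np.nan
        members = list(grp.index)
        if matrix is not None and len(members) == 2:
            a = matrix.data.loc[members[0]].to_numpy()
            b = matrix.data.loc[members[1]].to_numpy()
            if a.std() > 0 and b.std() > 0:
                pair_r = float(np.corrcoef(a, b)[0, 1])
        rows.append(
            {
                "target_id": target,
                "contig_id": grp["contig_id"].iloc[0],
                "n_probes": len(members),
                "probes": ";".join(members),
                "homolog_id": homolog_id,
                "pair_r": pair_r,
            }
        )
    per_target = pd.DataFrame(
        rows,
        columns=["target_id", "contig_id", "n_probes", "probes", "homolog_id", "pair_r"],
    )
    n_targets = len(per_target)
    with_homolog = per_target["homolog_id"].notna().sum() if n_targets else 0
    homologs = per_target["homolog_id"].dropna().nunique() if n_targets else 0
    return CollapseResult(
        n_probes=len(probes),
        n_targets=n_targets,
        n_targets_without_homolog=int(n_targets - with_homolog),
        n_homologs=int(homologs),
        per_target=per_target,
    )
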