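"""End-to-end orchestration: QC, both selection pipelines, clustering
stages, the limb-bud partition, and a machine-readable run manifest.

``run_full`` executes every stage on a validated dataset (or a freshly
generated synthetic one) and writes TSV/JSON outputs; the manifest
records the per-stage probe-count funnel, which must be monotone
non-increasing along each pipeline.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, preprocess, selection, stats
from .core_io import (
    AnalysisConfig,
    ExpressionMatrix,
    ProbeAnnotation,
    SampleDesign,
    validate_dataset,
)

logger = logging.getLogger("regenscreen")


@dataclass
class RunManifest:
    config: dict
    seed: int
    counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    input_hashes: dict[str, str] = field(default_factory=dict)

    FUNNEL_A = (
        "expressed",
        "interaction_significant",
        "wound_insignificant",
        "up_carry_forward",
    )
    FUNNEL_B = ("marginal_kept", "one_way_significant", "consecutive_run", "up_subset")

    def check_funnels(self) -> None:
        for chain in (self.FUNNEL_A, self.FUNNEL_B):
            present = [self.counts[k] for k in chain if k in self.counts]
            if any(a < b for a, b in zip(present, present[1:])):
                raise AssertionError(f"funnel counts not monotone: {chain} {present}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "counts": self.counts,
                "outputs": self.outputs,
                "input_hashes": self.input_hashes,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class RunResult:
    manifest: RunManifest
    qc: dict
    pipeline_a: selection.PipelineATests | None
    amp_specific: set[str]
    profile_clusters: selection.ProfileClusters | None
    pvalue_clusters: selection.PValueClusters | None
    pipeline_b: selection.PipelineBTests | None
    amp_enriched: selection.PipelineBSelection | None
    collapse_a: selection.CollapseResult | None
    collapse_b: selection.CollapseResult | None
    tree: clustering.Dendrogram | None
    limb_bud: clustering.LimbBudPartition | None


def _hash_frame(frame: pd.DataFrame) -> str:
    digest = hashlib.sha256(
        pd.util.hash_pandas_object(frame, index=True).to_numpy().tobytes()
    )
    return digest.hexdigest()[:16]


def qc_report(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    annotation: ProbeAnnotation,
    config: AnalysisConfig | None = None,
) -> dict:
    """Expression-call counts, probe-pair concordance on the significant
    set, and per-sample signal summaries."""
    config = config or AnalysisConfig()
    expressed = preprocess.filter_expressed(
        matrix, background=config.background, min_samples=config.min_expressed_samples
    )
    marginal_kept = preprocess.filter_marginal(
        matrix, background=config.background, marginal_fraction=config.marginal_fraction
    )
    # concordance QC runs on log2 raw signals: quantile normalization
    # compresses the distribution tails and biases pair correlations low
    log2 = stats.log2_signals(matrix.subset_probes(expressed))
    anova = stats.one_way_time_anova(log2, design, "amputation")
    _, reject = stats.bh_fdr(anova["p"].to_numpy(), config.fdr_level)
    significant = list(anova.index[reject])
    concordance = preprocess.probe_pair_concordance(
        log2, annotation, eligible_probes=significant
    )
    values = matrix.values
    per_sample = {
        s: {
            "median": float(np.median(values[:, j])),
            "p75": float(np.percentile(values[:, j], 75)),
        }
        for j, s in enumerate(matrix.sample_ids)
    }
    return {
        "n_probes": matrix.shape[0],
        "n_expressed": len(expressed),
        "n_marginal_kept": len(marginal_kept),
        "n_significant_time_course": len(significant),
        "concordance": concordance.to_summary_dict(),
        "per_sample": per_sample,
        "_concordance_report": concordance,
    }


def run_full(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    annotation: ProbeAnnotation,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
    run_pipeline_a: bool = True,
    run_pipeline_b: bool = True,
) -> RunResult:
    """Execute QC, normalisations, both selections, clustering and the
    limb-bud partition; identical inputs and seed give identical outputs."""
    config = config or AnalysisConfig()
    t0 = time.perf_counter()
    report = validate_dataset(matrix, design, annotation)
    if not report.ok:
        raise ValueError(f"dataset validation failed: {report.problems}")

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.rng_seed,
        input_hashes={"matrix": _hash_frame(matrix.data)},
    )
    qc = qc_report(matrix, design, annotation, config)
    manifest.counts["total_probes"] = matrix.shape[0]
    logger.info("qc done (%.1fs)", time.perf_counter() - t0)

    tree = clustering.condition_tree(
        matrix.subset_probes(
            preprocess.filter_expressed(
                matrix,
                background=config.background,
                min_samples=config.min_expressed_samples,
            )
        ),
        design,
    )

    pa = amp_specific = profile_clusters = pvalue_clusters = None
    collapse_a = None
    if run_pipeline_a:
        pa = selection.pipeline_a_tests(matrix, design, config)
        manifest.counts["expressed"] = len(pa.expressed_probes)
        manifest.counts["interaction_significant"] = int(
            (pa.table["q_interaction"] <= config.fdr_level).sum()
        )
        amp_specific = selection.select_amp_specific(pa, config)
        manifest.counts["wound_insignificant"] = len(amp_specific)
        logger.info(
            "pipeline A screen: %d interaction-significant, %d wound-insignificant",
            manifest.counts["interaction_significant"],
            manifest.counts["wound_insignificant"],
        )
        if len(amp_specific) >= 2:
            profile_clusters = selection.profile_cluster(
                amp_specific, pa.normalized, design, config
            )
            manifest.counts["up_carry_forward"] = len(profile_clusters.carry_forward)
            if len(profile_clusters.carry_forward) >= 3:
                pvalue_clusters = selection.pvalue_profile_cluster(
                    profile_clusters.carry_forward, pa.normalized, design, config
                )
            collapse_a = selection.collapse_probes(
                profile_clusters.carry_forward, annotation, pa.normalized
            )
            manifest.counts["targets_a"] = collapse_a.n_targets
            manifest.counts["homologs_a"] = collapse_a.n_homologs

    pb = amp_enriched = None
    collapse_b = None
    if run_pipeline_b:
        pb = selection.pipeline_b_tests(matrix, design, config)
        manifest.counts["marginal_kept"] = len(pb.kept_probes)
        manifest.counts["one_way_significant"] = int(
            (pb.anova["q"] <= config.fdr_level).sum()
        )
        amp_enriched = selection.select_amp_enriched(pb, design, config)
        manifest.counts["consecutive_run"] = len(amp_enriched.selected)
        manifest.counts["up_subset"] = len(amp_enriched.up_regulated)
        logger.info(
            "pipeline B: %d one-way significant, %d selected, %d up",
            manifest.counts["one_way_significant"],
            manifest.counts["consecutive_run"],
            manifest.counts["up_subset"],
        )
        collapse_b = selection.collapse_probes(
            amp_enriched.selected, annotation, pb.normalized
        )
        manifest.counts["targets_b"] = collapse_b.n_targets
        manifest.counts["homologs_b"] = collapse_b.n_homologs

    limb_bud = None
    union = set()
    if amp_specific is not None and profile_clusters is not None:
        union |= profile_clusters.carry_forward
    if amp_enriched is not None:
        union |= amp_enriched.selected
    if union:
        limb_bud = _limb_bud_stage(union, matrix, design, config)
        manifest.counts["union_selected"] = len(union)

    manifest.check_funnels()
    result = RunResult(
        manifest=manifest,
        qc=qc,
        pipeline_a=pa,
        amp_specific=amp_specific or set(),
        profile_clusters=profile_clusters,
        pvalue_clusters=pvalue_clusters,
        pipeline_b=pb,
        amp_enriched=amp_enriched,
        collapse_a=collapse_a,
        collapse_b=collapse_b,
        tree=tree,
        limb_bud=limb_bud,
    )
    if out_dir is not None:
        _write_outputs(result, matrix, design, Path(out_dir))
    logger.info("run complete (%.1fs)", time.perf_counter() - t0)
    return result


def _limb_bud_stage(
    union: set[str],
    matrix: ExpressionMatrix,
    design: SampleDesign,
    config: AnalysisConfig,
) -> clustering.LimbBudPartition:
    normalized = preprocess.quantile_normalize(matrix.subset_probes(sorted(union)))
    mean = preprocess.summarize_replicates(normalized, design, statistic="mean")
    std = preprocess.standardize_rows(mean, log_first=True)
    injury_cols = [
        c
        for c in std.data.columns
        if c.startswith("amputation") or c.startswith("lateral_wound")
    ]
    bud_cols = [c for c in std.data.columns if c.startswith("limb_bud")]
    return clustering.limb_bud_partition(
        std.data,
        injury_columns=injury_cols,
        bud_columns=bud_cols,
        seed=config.rng_seed,
        restarts=config.kmeans_restarts,
    )


def _write_outputs(
    result: RunResult,
    matrix: ExpressionMatrix,
    design: SampleDesign,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = result.manifest

    def register(name: str, path: Path) -> None:
        manifest.outputs[name] = str(path)

    if result.pipeline_a is not None:
        path = out_dir / "pipeline_a_tests.tsv"
        result.pipeline_a.table.to_csv(path, sep="\t", index_label="probe_id")
        register("pipeline_a_tests", path)
    if result.profile_clusters is not None:
        table = pd.DataFrame(
            {
                "profile_cluster": result.profile_clusters.result.labels,
                "direction": [
                    "up" if l in result.profile_clusters.up_clusters else "down"
                    for l in result.profile_clusters.result.labels
                ],
            }
        )
        if result.pvalue_clusters is not None:
            table["pvalue_cluster"] = result.pvalue_clusters.result.labels
        path = out_dir / "pipeline_a_clusters.tsv"
        table.to_csv(path, sep="\t", index_label="probe_id")
        register("pipeline_a_clusters", path)
    if result.amp_enriched is not None:
        path = out_dir / "pipeline_b_selection.tsv"
        result.amp_enriched.table.to_csv(path, sep="\t", index_label="probe_id")
        register("pipeline_b_selection", path)
    for name, collapse in (("a", result.collapse_a), ("b", result.collapse_b)):
        if collapse is not None:
            path = out_dir / f"collapse_{name}.tsv"
            collapse.per_target.to_csv(path, sep="\t", index=False)
            register(f"collapse_{name}", path)
    if result.tree is not None:
        path = out_dir / "condition_tree.nwk"
        path.write_text(result.tree.to_newick() + "\n")
        register("condition_tree", path)
    if result.limb_bud is not None:
        path = out_dir / "limb_bud_clusters.tsv"
        frame = pd.DataFrame(
            {
                "limb_bud_cluster": result.limb_bud.result.labels,
                "limb_bud_call": [
                    "high" if l in result.limb_bud.high_clusters else "low"
                    for l in result.limb_bud.result.labels
                ],
            }
        )
        frame.to_csv(path, sep="\t", index_label="probe_id")
        register("limb_bud_clusters", path)
    qc_path = out_dir / "qc_report.json"
    qc = {k: v for k, v in result.qc.items() if not k.startswith("_")}
    qc_path.write_text(json.dumps(qc, indent=2, sort_keys=True))
    register("qc_report", qc_path)
    concordance = result.qc.get("_concordance_report")
    if concordance is not None and len(concordance.pairs):
        path = out_dir / "probe_pair_concordance.tsv"
        concordance.pairs.to_csv(path, sep="\t", index=False)
        register("probe_pair_concordance", path)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(manifest.to_json())


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
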