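"""Normalization, expression filtering, replicate summarization and
probe-pair concordance QC.

Two normalization routes coexist, mirroring the two selection pipelines:
the interaction (ANOVA) pipeline quantile-normalizes the raw signals,
while the pairwise pipeline floors raw signals at 5.0, divides each
sample by its own 75th percentile, and rejects marginally expressed
probes.  Percentiles use the nearest-rank convention (smallest value with
cumulative fraction >= p), which is deterministic and exactly invertible
in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DatasetError, ExpressionMatrix, ProbeAnnotation, SampleDesign


def floor_signals(matrix: ExpressionMatrix, floor: float = 5.0) -> ExpressionMatrix:
    """Clip raw signals below ``floor`` up to ``floor``.  Idempotent."""
    if floor < 0:
        raise ValueError("floor must be non-negative")
    if matrix.scale_tag not in ("raw", "floored"):
        raise ValueError(f"floor_signals expects raw signals, got {matrix.scale_tag}")
    return matrix.with_values(np.maximum(matrix.values, floor), "floored")


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Smallest value whose cumulative fraction reaches ``percentile``/100."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    rank = int(np.ceil(percentile / 100.0 * v.size)) - 1
    return float(v[max(rank, 0)])


def percentile_shift_normalize(
    matrix: ExpressionMatrix, percentile: float = 75.0
) -> ExpressionMatrix:
    """Divide each sample by that sample's nearest-rank percentile."""
    if matrix.scale_tag not in ("raw", "floored"):
        raise ValueError(
            f"percentile shift expects raw/floored signals, got {matrix.scale_tag}"
        )
    values = matrix.values
    divisors = np.array(
        [nearest_rank_percentile(values[:, j], percentile) for j in range(values.shape[1])]
    )
    if (divisors <= 0).any():
        bad = [matrix.sample_ids[j] for j in np.flatnonzero(divisors <= 0)]
        raise DatasetError(f"non-positive {percentile:g}th percentile in samples {bad}")
    return matrix.with_values(values / divisors, "percentile_shifted")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean-of-order-statistics distribution.

    After the transform all samples share one sorted value vector and each
    sample's within-column rank order is preserved.  Idempotent.
    """
    values = matrix.values
    order = np.argsort(values, axis=0, kind="stable")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    np.put_along_axis(
        out, order, np.broadcast_to(reference[:, None], values.shape), axis=0
    )
    return matrix.with_values(out, "quantile_normalized")


def filter_expressed(
    matrix: ExpressionMatrix, background: float = 50.0, min_samples: int = 6
) -> list[str]:
    """Probes with raw signal strictly above ``background`` in >= ``min_samples``."""
    if min_samples > matrix.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    if matrix.scale_tag not in ("raw", "floored"):
        raise ValueError("expression call is defined on raw signals")
    n_above = (matrix.values > background).sum(axis=1)
    keep = n_above >= min_samples
    return [p for p, k in zip(matrix.probe_ids, keep) if k]


def filter_marginal(
    matrix: ExpressionMatrix, background: float = 50.0, marginal_fraction: float = 0.8
) -> list[str]:
    """Drop probes below ``background`` in strictly more than the given fraction."""
    if not 0 < marginal_fraction <= 1:
        raise ValueError("marginal_fraction must lie in (0, 1]")
    if matrix.scale_tag not in ("raw", "floored"):
        raise ValueError("marginal call is defined on raw signals")
    frac_below = (matrix.values < background).mean(axis=1)
    keep = ~(frac_below > marginal_fraction)
    return [p for p, k in zip(matrix.probe_ids, keep) if k]


def summarize_replicates(
    matrix: ExpressionMatrix, design: SampleDesign, statistic: str = "mean"
) -> ExpressionMatrix:
    """Collapse replicates to one column per (condition, time) group."""
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    groups = design.table.groupby(["condition", "time_hours"], dropna=False)
    columns = {}
    for (cond, t), sub in groups:
        ids = [s for s in sub["sample_id"] if s in matrix.data.columns]
        if not ids:
            raise DatasetError(f"group ({cond}, {t}) has no samples in matrix")
        block = matrix.data[ids].to_numpy()
        agg = np.mean(block, axis=1) if statistic == "mean" else np.median(block, axis=1)
        label = cond if pd.isna(t) else f"{cond}_{int(t):03d}"
        columns[label] = agg
    frame = pd.DataFrame(columns, index=matrix.data.index)
    return ExpressionMatrix(frame, scale_tag=matrix.scale_tag)


def standardize_rows(
    matrix: ExpressionMatrix, log_first: bool = True
) -> ExpressionMatrix:
    """Per-probe standard scores (mean 0, population sd 1), log2 first by default.

    Constant rows cannot be standardized; they are excluded with a warning
    rather than propagating NaN.
    """
    values = matrix.values.astype(float)
    if log_first and matrix.scale_tag != "log2" and matrix.scale_tag != "standardized":
        if (values <= 0).any():
            raise ValueError("log2 requires strictly positive signals")
        values = np.log2(values)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population sd
    constant = sd[:, 0] == 0
    if constant.any():
        dropped = [p for p, c in zip(matrix.probe_ids, constant) if c]
        warnings.warn(
            f"excluding {len(dropped)} constant probes from standardization",
            stacklevel=2,
        )
        values = values[~constant]
        frame = pd.DataFrame(
            (values - mean[~constant]) / sd[~constant],
            index=[p for p in matrix.probe_ids if p not in set(dropped)],
            columns=matrix.sample_ids,
        )
        return ExpressionMatrix(frame, scale_tag="standardized")
    out = (values - mean) / sd
    return matrix.with_values(out, "standardized")


@dataclass
class ConcordanceReport:
    """Per-target probe-pair Pearson correlations and summary fractions."""

    pairs: pd.DataFrame  # target_id, probe_a, probe_b, r
    frac_r_gt_08: float
    frac_r_gt_09: float
    n_pairs: int

    def to_summary_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "frac_r_gt_08": self.frac_r_gt_08,
            "frac_r_gt_09": self.frac_r_gt_09,
        }


def probe_pair_concordance(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    eligible_probes: list[str] | None = None,
) -> ConcordanceReport:
    """Pearson r between the two probes of each doubly-probed target.

    ``eligible_probes`` restricts the computation, typically to probes
    with statistically significant expression changes over the time
    course; targets contribute only when exactly two eligible probes map
    to them.
    """
    if matrix.shape[1] < 3:
        raise ValueError("concordance requires at least 3 samples")
    eligible = set(eligible_probes) if eligible_probes is not None else set(
        matrix.probe_ids
    )
    annot = annotation.table
    annot = annot[annot["probe_id"].isin(eligible & set(matrix.probe_ids))]
    rows = []
    data = matrix.data
    for target, sub in annot.groupby("target_id"):
        if len(sub) != 2:
            continue
        pa, pb = sub["probe_id"].tolist()
        a = data.loc[pa].to_numpy()
        b = data.loc[pb].to_numpy()
        if a.std() == 0 or b.std() == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        rows.append((target, pa, pb, r))
    pairs = pd.DataFrame(rows, columns=["target_id", "probe_a", "probe_b", "r"])
    n = len(pairs)
    f08 = float((pairs["r"] > 0.8).mean()) if n else 0.0
    f09 = float((pairs["r"] > 0.9).mean()) if n else 0.0
    return ConcordanceReport(pairs=pairs, frac_r_gt_08=f08, frac_r_gt_09=f09, n_pairs=n)
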