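"""Data model, file readers/writers, and dataset validation.

The central objects are a probe x sample :class:`ExpressionMatrix`, a
:class:`SampleDesign` describing the paired two-condition injury time
course (amputated limb vs contralateral lateral wound, plus limb-bud and
mature-proximal reference samples), and a :class:`ProbeAnnotation` mapping
each probe to its strand-qualified target, source contig and optional
human RefSeq homolog.

Expression tables are read and written as plain TSV (first column
``probe_id``, one column per sample) or GCT 1.2.  Signals live on a named
scale (``scale_tag``) so that each pipeline stage can assert it receives
data on the scale it expects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: Hours after injury at which samples were collected, 0 h = uninjured.
TIMEPOINTS: tuple[int, ...] = (0, 3, 6, 9, 12, 24, 36, 52, 72, 120, 168, 288, 528)

#: Injury time points entering the two-condition comparisons (0 h excluded).
INJURY_TIMEPOINTS: tuple[int, ...] = TIMEPOINTS[1:]

CONDITIONS = ("amputation", "lateral_wound", "limb_bud", "mature_proximal")
INJURY_CONDITIONS = ("amputation", "lateral_wound")

SCALE_TAGS = (
    "raw",
    "floored",
    "percentile_shifted",
    "quantile_normalized",
    "log2",
    "standardized",
)

#: Scales on which signals must be non-negative.
_NONNEG_SCALES = ("raw", "floored", "percentile_shifted", "quantile_normalized")

#: BLAST E-value cut-off above which a claimed homolog is not trusted.
HOMOLOGY_EVALUE_CUTOFF = 1e-3


class DatasetError(ValueError):
    """Hard dataset integrity failure (duplicates, broken pairing, ...)."""


# ---------------------------------------------------------------------------
# ExpressionMatrix


@dataclass
class ExpressionMatrix:
    """Probe x sample signal table on a named scale."""

    data: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate probe identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate sample identifiers: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DatasetError(
                "non-finite value at probe "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )
        if self.scale_tag in _NONNEG_SCALES and values.size and (values < 0).any():
            raise DatasetError(f"negative values on scale {self.scale_tag!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, data=self.data.loc[list(probes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, data=self.data[list(samples)])

    def with_values(self, values: np.ndarray, scale_tag: str) -> "ExpressionMatrix":
        frame = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return ExpressionMatrix(frame, scale_tag=scale_tag)


# ---------------------------------------------------------------------------
# SampleDesign


@dataclass
class SampleDesign:
    """Per-sample condition / time / replicate metadata.

    Amputation and lateral-wound samples at the same (time, replicate) are
    contralateral limbs of the same animals, which is what licenses the
    paired t-test stage; the pairing invariant is enforced on construction.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "condition", "time_hours", "replicate_id")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise DatasetError(f"design table missing columns {missing}")
        if t["sample_id"].duplicated().any():
            raise DatasetError("duplicate sample_id in design")
        unknown = set(t["condition"]) - set(CONDITIONS)
        if unknown:
            raise DatasetError(f"unknown condition labels {sorted(unknown)}")
        key = t[["condition", "time_hours", "replicate_id"]]
        if key.duplicated().any():
            raise DatasetError("duplicate (condition, time_hours, replicate_id)")
        self._check_pairing()
        self.table = t.reset_index(drop=True)

    def _check_pairing(self) -> None:
        t = self.table
        amp = t[(t.condition == "amputation") & (t.time_hours > 0)]
        lw = t[t.condition == "lateral_wound"]
        lw_keys = set(zip(lw.time_hours, lw.replicate_id))
        unmatched = [
            row.sample_id
            for row in amp.itertuples()
            if (row.time_hours, row.replicate_id) not in lw_keys
        ]
        if unmatched:
            raise DatasetError(
                f"amputation samples without contralateral wound match: {unmatched}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples(
        self,
        condition: str | None = None,
        time_hours: int | None = None,
        replicate_id: int | None = None,
    ) -> list[str]:
        t = self.table
        mask = np.ones(len(t), dtype=bool)
        if condition is not None:
            mask &= (t.condition == condition).to_numpy()
        if time_hours is not None:
            mask &= (t.time_hours == time_hours).to_numpy()
        if replicate_id is not None:
            mask &= (t.replicate_id == replicate_id).to_numpy()
        return list(t.loc[mask, "sample_id"])

    def times(self, condition: str) -> list[int]:
        t = self.table
        vals = t.loc[(t.condition == condition) & t.time_hours.notna(), "time_hours"]
        return sorted(int(v) for v in vals.unique())

    def replicates(self, condition: str, time_hours: int) -> list[int]:
        t = self.table
        mask = (t.condition == condition) & (t.time_hours == time_hours)
        return sorted(int(r) for r in t.loc[mask, "replicate_id"])

    def paired_samples(self, time_hours: int) -> tuple[list[str], list[str]]:
        """Amputation and wound sample ids at ``time_hours``, replicate-aligned."""
        reps = self.replicates("amputation", time_hours)
        amp = [self.samples("amputation", time_hours, r)[0] for r in reps]
        lw = [self.samples("lateral_wound", time_hours, r)[0] for r in reps]
        return amp, lw


# ---------------------------------------------------------------------------
# ProbeAnnotation


@dataclass
class ProbeAnnotation:
    """probe -> strand-qualified target -> contig -> optional human homolog.

    Target identifiers carry an ``s.``/``a.`` prefix distinguishing the two
    strands of a contig whose coding strand is unknown.  A homolog is kept
    only when its E-value clears :data:`HOMOLOGY_EVALUE_CUTOFF`.
    """

    table: pd.DataFrame

    REQUIRED = ("probe_id", "target_id", "contig_id")

    def __post_init__(self) -> None:
        t = self.table.copy()
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise DatasetError(f"annotation table missing columns {missing}")
        if t["probe_id"].duplicated().any():
            raise DatasetError("probe mapped to more than one target")
        per_target = t.groupby("target_id")["contig_id"].nunique()
        conflicted = per_target[per_target > 1]
        if len(conflicted):
            raise DatasetError(
                f"targets mapped to multiple contigs: {list(conflicted.index[:5])}"
            )
        if "homolog_id" not in t.columns:
            t["homolog_id"] = pd.NA
        if "homology_evalue" not in t.columns:
            t["homology_evalue"] = np.nan
        has_homolog = t["homolog_id"].notna() & (t["homolog_id"] != "")
        weak = has_homolog & ~(t["homology_evalue"] <= HOMOLOGY_EVALUE_CUTOFF)
        if weak.any():
            warnings.warn(
                f"dropping {int(weak.sum())} homolog assignments with "
                f"E-value > {HOMOLOGY_EVALUE_CUTOFF:g}",
                stacklevel=2,
            )
            t.loc[weak, ["homolog_id", "homology_evalue"]] = [pd.NA, np.nan]
        self.table = t.reset_index(drop=True)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])

    def target_of(self) -> pd.Series:
        return self.table.set_index("probe_id")["target_id"]

    def probes_per_target(self) -> pd.Series:
        return self.table.groupby("target_id")["probe_id"].size()

    def homolog_of_target(self) -> pd.Series:
        sub = self.table.drop_duplicates("target_id").set_index("target_id")
        return sub["homolog_id"]


# ---------------------------------------------------------------------------
# AnalysisConfig


@dataclass
class AnalysisConfig:
    """All thresholds of both selection pipelines, in one place.

    Defaults are the constants of the published analysis: 5% FDR for every
    ANOVA family, wound-course insignificance at p > 0.05, a 2-fold change
    with paired-t p < 0.05 at >= 3 consecutive time points, a raw-signal
    floor of 5.0 and 75th-percentile shift for the pairwise pipeline,
    expression calls against a background of 50, and the 3-72 h window for
    the LSD post-hoc profiling.
    """

    fdr_level: float = 0.05
    wound_pvalue_floor: float = 0.05
    fold_cutoff: float = 2.0
    min_consecutive: int = 3
    signal_floor: float = 5.0
    shift_percentile: float = 75.0
    background: float = 50.0
    min_expressed_samples: int = 6
    marginal_fraction: float = 0.8
    lsd_window: tuple[int, int] = (3, 72)
    kmeans_kmax: int = 15
    kmeans_restarts: int = 10
    mixture_max_components: int = 8
    mixture_iterations: int = 10
    neglog10_cap: float = 300.0
    log_transform: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "fold_cutoff signal_floor shift_percentile background "
            "min_consecutive min_expressed_samples kmeans_kmax "
            "mixture_max_components mixture_iterations neglog10_cap"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("fdr_level", "wound_pvalue_floor"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0 < self.marginal_fraction <= 1:
            raise ValueError("marginal_fraction must lie in (0, 1]")
        self.lsd_window = tuple(self.lsd_window)  # type: ignore[assignment]

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**(payload or {}))

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["lsd_window"] = list(self.lsd_window)
        return d


# ---------------------------------------------------------------------------
# Readers / writers


def read_expression_table(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a probe x sample table from TSV or GCT 1.2; values tagged ``raw``."""
    path = Path(path)
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
    elif dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise DatasetError(f"unsupported GCT version line {version!r}")
            n_rows, n_cols = (int(x) for x in fh.readline().split("\t")[:2])
            frame = pd.read_csv(fh, sep="\t", index_col=0)
        frame = frame.drop(columns=["Description"], errors="ignore")
        if frame.shape != (n_rows, n_cols):
            raise DatasetError(
                f"GCT dimension line {n_rows}x{n_cols} does not match data {frame.shape}"
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    frame.index = frame.index.astype(str)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise DatasetError(f"duplicate probe identifiers in {path.name}: {dups[:5]}")
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            raise DatasetError(
                f"non-numeric value at probe {frame.index[bad.argmax()]!r}, "
                f"sample {col!r}"
            )
        if coerced.isna().any():
            raise DatasetError(f"missing value in sample {col!r}")
        frame[col] = coerced.astype(float)
    return ExpressionMatrix(frame, scale_tag="raw")


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> Path:
    path = Path(path)
    frame = matrix.data
    if dialect == "tsv":
        frame.to_csv(path, sep="\t", index_label="probe_id", float_format="%.10g")
    elif dialect == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{frame.shape[0]}\t{frame.shape[1]}\n")
            out = frame.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name", float_format="%.10g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_design_and_annotation(
    design_path: str | Path, annot_path: str | Path
) -> tuple[SampleDesign, ProbeAnnotation]:
    design = pd.read_csv(design_path, sep="\t")
    design["time_hours"] = pd.to_numeric(design["time_hours"], errors="coerce")
    annot = pd.read_csv(annot_path, sep="\t")
    return SampleDesign(design), ProbeAnnotation(annot)


def write_design_and_annotation(
    design: SampleDesign,
    annotation: ProbeAnnotation,
    design_path: str | Path,
    annot_path: str | Path,
) -> None:
    design.table.to_csv(design_path, sep="\t", index=False)
    annotation.table.to_csv(annot_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    """Report-only dataset check; the caller decides whether to proceed."""

    unknown_samples: list[str] = field(default_factory=list)
    unannotated_probes: list[str] = field(default_factory=list)
    missing_samples: list[str] = field(default_factory=list)
    replicate_counts: dict[tuple, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def problems(self) -> list[str]:
        out = []
        if self.unknown_samples:
            out.append(f"samples absent from design: {self.unknown_samples[:10]}")
        if self.missing_samples:
            out.append(f"design samples absent from matrix: {self.missing_samples[:10]}")
        return out

    @property
    def ok(self) -> bool:
        return not self.problems


def validate_dataset(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    annotation: ProbeAnnotation | None = None,
) -> ValidationReport:
    report = ValidationReport()
    design_ids = set(design.sample_ids)
    matrix_ids = set(matrix.sample_ids)
    report.unknown_samples = sorted(matrix_ids - design_ids)
    report.missing_samples = sorted(design_ids - matrix_ids)
    if annotation is not None:
        annotated = set(annotation.probe_ids)
        report.unannotated_probes = sorted(set(matrix.probe_ids) - annotated)
        if report.unannotated_probes:
            report.warnings.append(
                f"{len(report.unannotated_probes)} probes lack annotation"
            )
    counts = design.table.groupby(["condition", "time_hours"], dropna=False)[
        "sample_id"
    ].size()
    report.replicate_counts = {
        (cond, None if pd.isna(t) else int(t)): int(n)
        for (cond, t), n in counts.items()
    }
    full = max(report.replicate_counts.values(), default=0)
    for key, n in report.replicate_counts.items():
        if n < full:
            report.warnings.append(f"group {key} has {n} replicates (others have {full})")
    return report


def make_sample_id(condition: str, time_hours: int | None, replicate_id: int) -> str:
    """Human-readable ``amp_024_r1``-style sample identifier.

    Identifiers are never parsed back; the design table is authoritative.
    """
    short = {
        "amputation": "amp",
        "lateral_wound": "lw",
        "limb_bud": "bud",
        "mature_proximal": "prox",
    }[condition]
    if time_hours is None:
        return f"{short}_r{replicate_id}"
    return f"{short}_{int(time_hours):03d}_r{replicate_id}"
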