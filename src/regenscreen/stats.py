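"""Per-probe test statistics for the balanced paired time course.

All tests run vectorised across probes on log2 signals: classical
fixed-effects one-way ANOVA over time within a condition, balanced
two-way ANOVA (time x condition) whose interaction term defines the
amputation-specific screen, Benjamini-Hochberg step-up FDR, paired t per
time point exploiting the contralateral replicate pairing, fold changes
on the normalised (linear) scale, and Fisher LSD p-values between
consecutive time points, sharing the one-way fit's pooled error.

Degenerate inputs follow fixed conventions: a group structure with zero
residual variance but a real effect yields p = 0 (with a warning), and a
completely constant probe yields F = 0, p = 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import ExpressionMatrix, SampleDesign


def log2_signals(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform positive signals; no-op if already on log2 scale."""
    if matrix.scale_tag == "log2":
        return matrix
    values = matrix.values
    if (values <= 0).any():
        raise ValueError("log2 requires strictly positive signals")
    return matrix.with_values(np.log2(values), "log2")


# ---------------------------------------------------------------------------
# ANOVA


def one_way_anova(
    values: np.ndarray, groups: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Classical fixed-effects one-way F test, vectorised over rows.

    ``values`` is (n_rows, n_samples); ``groups`` lists column indices per
    group.  Returns F and p with df (k-1, N-k).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    k = len(groups)
    if k < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    sizes = np.array([len(g) for g in groups])
    if (sizes < 2).any():
        raise ValueError("each group needs at least 2 observations")
    n_total = sizes.sum()
    grand = values[:, np.concatenate(groups)].mean(axis=1)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for g in groups:
        block = values[:, g]
        m = block.mean(axis=1)
        ssb += len(g) * (m - grand) ** 2
        ssw += ((block - m[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = sps.f.sf(f, df_b, df_w)
    zero_resid = ssw == 0
    if zero_resid.any():
        effect = zero_resid & (ssb > 0)
        if effect.any():
            warnings.warn(
                f"{int(effect.sum())} probes with zero residual variance; p set to 0",
                stacklevel=2,
            )
        f = np.where(zero_resid, np.where(ssb > 0, np.inf, 0.0), f)
        p = np.where(zero_resid, np.where(ssb > 0, 0.0, 1.0), p)
    return f, p


def one_way_time_anova(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    condition: str,
    times: list[int] | None = None,
) -> pd.DataFrame:
    """Per-probe one-way ANOVA over the time groups of one condition."""
    log2 = log2_signals(matrix)
    if times is None:
        times = design.times(condition)
    col_index = {s: j for j, s in enumerate(log2.sample_ids)}
    groups = [
        np.array([col_index[s] for s in design.samples(condition, t)]) for t in times
    ]
    f, p = one_way_anova(log2.values, groups)
    return pd.DataFrame({"F": f, "p": p}, index=log2.data.index)


def two_way_anova(cells: np.ndarray) -> dict[str, np.ndarray]:
    """Balanced two-way fixed-effects decomposition, vectorised over rows.

    ``cells`` has shape (n_rows, a, b, n): a time levels x b condition
    levels x n replicates per cell.  Returns F and p for the time (A),
    condition (B) and interaction effects.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 4:
        raise ValueError("expected (rows, a, b, n) array of balanced cells")
    _, a, b, n = cells.shape
    if n < 2:
        raise ValueError("need at least 2 replicates per cell")
    grand = cells.mean(axis=(1, 2, 3))
    mean_a = cells.mean(axis=(2, 3))
    mean_b = cells.mean(axis=(1, 3))
    mean_cell = cells.mean(axis=3)
    ss_a = b * n * ((mean_a - grand[:, None]) ** 2).sum(axis=1)
    ss_b = a * n * ((mean_b - grand[:, None]) ** 2).sum(axis=1)
    interaction = (
        mean_cell - mean_a[:, :, None] - mean_b[:, None, :] + grand[:, None, None]
    )
    ss_int = n * (interaction**2).sum(axis=(1, 2))
    ss_err = ((cells - mean_cell[..., None]) ** 2).sum(axis=(1, 2, 3))
    df = {"time": a - 1, "condition": b - 1, "interaction": (a - 1) * (b - 1)}
    df_err = a * b * (n - 1)
    out: dict[str, np.ndarray] = {}
    zero_resid = ss_err == 0
    for name, ss in (("time", ss_a), ("condition", ss_b), ("interaction", ss_int)):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / df[name]) / (ss_err / df_err)
        p = sps.f.sf(f, df[name], df_err)
        if zero_resid.any():
            if (zero_resid & (ss > 0)).any():
                warnings.warn(
                    "zero residual variance in two-way ANOVA; p set to 0",
                    stacklevel=2,
                )
            f = np.where(zero_resid, np.where(ss > 0, np.inf, 0.0), f)
            p = np.where(zero_resid, np.where(ss > 0, 0.0, 1.0), p)
        out[f"F_{name}"] = f
        out[f"p_{name}"] = p
    return out


def two_way_time_condition_anova(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    times: list[int] | None = None,
    conditions: tuple[str, str] = ("amputation", "lateral_wound"),
) -> pd.DataFrame:
    """Two-way ANOVA over time x condition on the injury course (0 h excluded).

    The design must be balanced and complete over the requested cells; an
    unbalanced design is a hard error because the decomposition assumes it.
    """
    log2 = log2_signals(matrix)
    if times is None:
        times = [t for t in design.times(conditions[0]) if t > 0]
    col_index = {s: j for j, s in enumerate(log2.sample_ids)}
    reps = design.replicates(conditions[0], times[0])
    n = len(reps)
    cols = np.empty((len(times), len(conditions), n), dtype=int)
    for i, t in enumerate(times):
        for j, cond in enumerate(conditions):
            ids = [design.samples(cond, t, r) for r in reps]
            if any(len(s) != 1 for s in ids):
                raise ValueError(f"unbalanced cell ({cond}, {t})")
            cols[i, j] = [col_index[s[0]] for s in ids]
    cells = log2.values[:, cols]
    result = two_way_anova(cells)
    return pd.DataFrame(result, index=log2.data.index)


# ---------------------------------------------------------------------------
# FDR


def bh_fdr(
    p_values: np.ndarray, q_level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags.

    adjusted_i = min over j >= rank(i) of m * p_(j) / j, capped at 1;
    reject iff adjusted <= q_level.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted, adjusted <= q_level


# ---------------------------------------------------------------------------
# Paired comparisons per time point


def paired_t_per_timepoint(
    matrix: ExpressionMatrix, design: SampleDesign, time_hours: int
) -> pd.DataFrame:
    """Two-sided paired t (amputation vs contralateral wound) per probe.

    Differences are taken on the log2 scale between replicate-matched
    contralateral samples; df = n_pairs - 1.
    """
    log2 = log2_signals(matrix)
    amp_ids, lw_ids = design.paired_samples(time_hours)
    if len(amp_ids) < 2:
        raise ValueError("need at least 2 contralateral pairs")
    diffs = log2.data[amp_ids].to_numpy() - log2.data[lw_ids].to_numpy()
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(np.abs(t), n - 1)
    zero_sd = sd == 0
    if zero_sd.any():
        nonzero_mean = zero_sd & (mean != 0)
        if nonzero_mean.any():
            warnings.warn(
                f"{int(nonzero_mean.sum())} probes with constant nonzero paired "
                "difference; p set to 0",
                stacklevel=2,
            )
        signed_inf = np.where(mean > 0, np.inf, -np.inf)
        t = np.where(zero_sd, np.where(mean != 0, signed_inf, 0.0), t)
        p = np.where(zero_sd, np.where(mean != 0, 0.0, 1.0), p)
    return pd.DataFrame({"t": t, "p": p}, index=log2.data.index)


def fold_change(
    matrix: ExpressionMatrix, design: SampleDesign, time_hours: int
) -> pd.Series:
    """FC = mean(amputation replicates) / mean(wound replicates), linear scale.

    The "2-fold difference" rule is satisfied when FC >= cutoff or
    FC <= 1/cutoff (see :func:`two_fold_rule`).
    """
    if matrix.scale_tag in ("log2", "standardized"):
        raise ValueError("fold change is defined on linear-scale signals")
    amp_ids, lw_ids = design.paired_samples(time_hours)
    amp_mean = matrix.data[amp_ids].to_numpy().mean(axis=1)
    lw_mean = matrix.data[lw_ids].to_numpy().mean(axis=1)
    if (lw_mean <= 0).any():
        raise ValueError("non-positive wound mean; fold change undefined")
    return pd.Series(amp_mean / lw_mean, index=matrix.data.index, name="FC")


def two_fold_rule(fc: np.ndarray | pd.Series, cutoff: float = 2.0) -> np.ndarray:
    fc = np.asarray(fc, dtype=float)
    return (fc >= cutoff) | (fc <= 1.0 / cutoff)


# ---------------------------------------------------------------------------
# Fisher LSD between consecutive time points


def lsd_consecutive(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    condition: str,
    window: tuple[int, int] = (3, 72),
) -> pd.DataFrame:
    """Fisher LSD p-values for consecutive time-point pairs in a window.

    A one-way ANOVA is fitted per probe over the window's time groups of
    the given condition; each consecutive pair (t_i, t_{i+1}) is then
    compared with t = (m_i - m_{i+1}) / sqrt(MSE * (1/n_i + 1/n_{i+1}))
    on the fit's residual degrees of freedom.  Columns are labelled
    ``{condition}_{t_i}_{t_i+1}``.
    """
    log2 = log2_signals(matrix)
    times = [t for t in design.times(condition) if window[0] <= t <= window[1]]
    if len(times) < 2:
        raise ValueError("LSD window must contain at least 2 time points")
    col_index = {s: j for j, s in enumerate(log2.sample_ids)}
    groups = [
        np.array([col_index[s] for s in design.samples(condition, t)]) for t in times
    ]
    values = log2.values
    sizes = np.array([len(g) for g in groups])
    n_total = sizes.sum()
    k = len(groups)
    means = np.stack([values[:, g].mean(axis=1) for g in groups], axis=1)
    ssw = np.zeros(values.shape[0])
    for g, m in zip(groups, means.T):
        ssw += ((values[:, g] - m[:, None]) ** 2).sum(axis=1)
    df_err = n_total - k
    mse = ssw / df_err
    out = {}
    zero_mse = mse == 0
    for i in range(k - 1):
        se = np.sqrt(mse * (1.0 / sizes[i] + 1.0 / sizes[i + 1]))
        delta = means[:, i] - means[:, i + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta / se
        p = 2 * sps.t.sf(np.abs(t), df_err)
        if zero_mse.any():
            p = np.where(zero_mse, np.where(delta != 0, 0.0, 1.0), p)
        out[f"{condition}_{times[i]}_{times[i + 1]}"] = p
    return pd.DataFrame(out, index=log2.data.index)


def lsd_feature_table(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    window: tuple[int, int] = (3, 72),
) -> pd.DataFrame:
    """LSD p-values for both injury conditions side by side (7 + 7 columns
    for the canonical 3-72 h window)."""
    amp = lsd_consecutive(matrix, design, "amputation", window)
    lw = lsd_consecutive(matrix, design, "lateral_wound", window)
    return pd.concat([amp, lw], axis=1)
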