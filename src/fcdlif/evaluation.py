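"""Comparison, robustness and feature-exploration machinery.

Predicted and measured input functions are compared frame by frame:
unweighted MSE, Pearson correlation, Deming (orthogonal) regression of
predicted on measured values, and — across a dataset — per-frame paired
t-tests at alpha = 0.05 with quantile-quantile data for normality
inspection.  Robustness checks exercise the model's fully convolutional
temporal behavior by prepending a frame (time shift) or removing the first
4 and last 6 frames (truncation).  t-SNE embeds the per-frame 32-feature
vectors of the spatial feature extractor for qualitative inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE

from .formats_io import BloodCurve, DynamicPETImage, FrameSchedule
from .network import Network, predict_aif
from .training import segment_labels

SEGMENT_NAMES = ("peak", "intermediate", "tail")


@dataclass(frozen=True)
class CurveComparison:
    """Frame-by-frame comparison of one predicted curve with its reference."""

    mse: float
    differences: np.ndarray          # predicted - measured, per frame
    pearson_r: float                 # NaN (flagged) when either curve is constant
    r_squared: float
    deming_slope: float
    deming_intercept: float
    segments: np.ndarray             # 'peak' | 'intermediate' | 'tail' per frame


def deming_regression(x: np.ndarray, y: np.ndarray, variance_ratio: float = 1.0) -> tuple[float, float]:
    """Closed-form Deming (errors-in-both-variables) regression of y on x.

    ``variance_ratio`` is delta = var(y-errors)/var(x-errors); delta = 1 is
    orthogonal regression, minimizing perpendicular distances.  As
    delta -> infinity the estimate approaches ordinary least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two matching 1-D arrays with at least 2 points")
    sxx = np.var(x)
    syy = np.var(y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    if sxx == 0 and syy == 0:
        raise ValueError("all points identical: regression undefined")
    d = variance_ratio
    if sxy == 0:
        slope = 0.0 if syy < d * sxx else np.inf
    else:
        slope = (syy - d * sxx + np.sqrt((syy - d * sxx) ** 2 + 4 * d * sxy**2)) / (2 * sxy)
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


def _segment_names(schedule: FrameSchedule | None, n: int) -> np.ndarray:
    if schedule is not None:
        return np.array([SEGMENT_NAMES[s] for s in segment_labels(schedule)])
    return np.array(["unknown"] * n)


def compare_curves(
    predicted: BloodCurve,
    measured: BloodCurve,
    schedule: FrameSchedule | None = None,
) -> CurveComparison:
    """All per-pair comparison metrics; curves must share one time grid."""
    if len(predicted) != len(measured) or not np.allclose(predicted.times, measured.times):
        raise ValueError("curves must share one time grid")
    p = np.asarray(predicted.values, dtype=float)
    m = np.asarray(measured.values, dtype=float)
    diff = p - m
    mse = float(np.mean(diff**2))
    if np.ptp(p) == 0 or np.ptp(m) == 0:
        r = float("nan")  # correlation undefined for a constant curve
        slope, intercept = (1.0, float(np.mean(p - m))) if np.array_equal(p, m + (p - m).mean()) else (float("nan"), float("nan"))
    else:
        r = float(stats.pearsonr(m, p).statistic)
        slope, intercept = deming_regression(m, p, variance_ratio=1.0)
    return CurveComparison(
        mse=mse,
        differences=diff,
        pearson_r=r,
        r_squared=r * r if np.isfinite(r) else float("nan"),
        deming_slope=slope,
        deming_intercept=intercept,
        segments=_segment_names(schedule, len(predicted)),
    )


def compare_dataset(
    predicted: list[BloodCurve],
    measured: list[BloodCurve],
    schedule: FrameSchedule | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> dict:
    """Dataset-level statistics over paired (predicted, measured) curves.

    Returns per-sample :class:`CurveComparison` objects, pooled pointwise
    Pearson r / r^2 and Deming line, per-frame paired t-tests across
    samples (unadjusted at ``alpha`` unless ``bonferroni``), and
    quantile-quantile pairs of the pooled differences for normality
    inspection.
    """
    if len(predicted) != len(measured) or len(predicted) == 0:
        raise ValueError("need matching, non-empty lists of curves")
    comparisons = [compare_curves(p, m, schedule) for p, m in zip(predicted, measured)]
    pred_all = np.concatenate([c.values for c in predicted])
    meas_all = np.concatenate([c.values for c in measured])
    r = float(stats.pearsonr(meas_all, pred_all).statistic)
    slope, intercept = deming_regression(meas_all, pred_all, variance_ratio=1.0)
    # r^2 about the Deming line's predictions
    line = slope * meas_all + intercept
    r_line = float(stats.pearsonr(line, pred_all).statistic) if np.ptp(line) > 0 else float("nan")

    diffs = np.stack([c.differences for c in comparisons])  # (n_samples, T)
    tstat, pval = stats.ttest_rel(
        np.stack([np.asarray(p.values) for p in predicted]),
        np.stack([np.asarray(m.values) for m in measured]),
        axis=0,
    )
    threshold = alpha / diffs.shape[1] if bonferroni else alpha
    pooled = np.sort(diffs.ravel())
    theoretical = stats.norm.ppf((np.arange(1, pooled.size + 1) - 0.5) / pooled.size)
    return {
        "comparisons": comparisons,
        "pearson_r": r,
        "r_squared": r_line * r_line if np.isfinite(r_line) else float("nan"),
        "deming_slope": slope,
        "deming_intercept": intercept,
        "t_statistics": tstat,
        "p_values": pval,
        "significant_frames": np.flatnonzero(pval < threshold),
        "alpha": threshold,
        "qq_pairs": np.column_stack([theoretical, pooled]),
    }


def rank_samples(comparisons: list[CurveComparison]) -> tuple[int, int, int]:
    """(best, median, worst) indices by ascending unweighted MSE; ties by index."""
    if len(comparisons) == 0:
        raise ValueError("empty comparison list")
    order = np.argsort([c.mse for c in comparisons], kind="stable")
    return int(order[0]), int(order[len(order) // 2]), int(order[-1])


# ---------------------------------------------------------------------------
# Robustness operations
# ---------------------------------------------------------------------------

def shift_test(
    network: Network, image: DynamicPETImage, mode: str = "empty"
) -> tuple[BloodCurve, BloodCurve, float]:
    """Prepend one 30-s frame (zeros or a copy of the first frame) and re-predict.

    Returns the original prediction, the prediction on the shifted input
    (length T + 1) and an alignment score: the MSE between the original
    curve and the shifted prediction with its first frame dropped.
    """
    if mode not in ("empty", "copy"):
        raise ValueError("mode must be 'empty' or 'copy'")
    extra = np.zeros_like(image.values[:1]) if mode == "empty" else image.values[:1].copy()
    values = np.concatenate([extra, image.values], axis=0)
    sched = image.schedule
    new_sched = FrameSchedule(
        np.concatenate([[0.0], sched.starts + 30.0]),
        np.concatenate([[30.0], sched.durations]),
    )
    shifted = DynamicPETImage(values=values, schedule=new_sched, spacing=image.spacing)
    original_curve = predict_aif(network, image)
    shifted_curve = predict_aif(network, shifted)
    score = float(np.mean((shifted_curve.values[1:] - original_curve.values) ** 2))
    return original_curve, shifted_curve, score


def truncate_test(
    network: Network, image: DynamicPETImage, drop_start: int = 4, drop_end: int = 6
) -> BloodCurve:
    """Remove the first ``drop_start`` and last ``drop_end`` frames and predict.

    Emulates a protocol that starts imaging with the infusion already
    running and stops early; the schedule is re-anchored to t = 0.
    """
    T = image.n_frames
    if T < drop_start + drop_end + 1:
        raise ValueError(f"need more than {drop_start + drop_end} frames, got {T}")
    sel = slice(drop_start, T - drop_end)
    truncated = DynamicPETImage(
        values=image.values[sel],
        schedule=image.schedule.subset(sel),
        spacing=image.spacing,
    )
    return predict_aif(network, truncated)


# ---------------------------------------------------------------------------
# Feature exploration
# ---------------------------------------------------------------------------

def tsne_features(
    feature_matrices: list[np.ndarray],
    group_labels: list[str],
    seed: int = 0,
    schedule: FrameSchedule | None = None,
    perplexity: float | None = None,
) -> pd.DataFrame:
    """2-D t-SNE embedding of stacked per-frame SFE features.

    One row per frame with columns x, y, segment (peak/intermediate/tail
    when a schedule is given), group and frame index.  Deterministic per
    seed.
    """
    if len(feature_matrices) != len(group_labels):
        raise ValueError("one group label per feature matrix is required")
    rows = np.concatenate(feature_matrices, axis=0)
    if rows.shape[0] < 5:
        raise ValueError("need at least 5 feature rows for t-SNE")
    if perplexity is None:
        perplexity = min(30.0, (rows.shape[0] - 1) / 3.0)
    emb = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(rows)
    segments: list[str] = []
    groups: list[str] = []
    frames: list[int] = []
    for mat, label in zip(feature_matrices, group_labels):
        names = _segment_names(schedule, mat.shape[0]) if (
            schedule is None or schedule.n_frames == mat.shape[0]
        ) else np.array(["unknown"] * mat.shape[0])
        segments.extend(names)
        groups.extend([label] * mat.shape[0])
        frames.extend(range(mat.shape[0]))
    return pd.DataFrame(
        {"x": emb[:, 0], "y": emb[:, 1], "segment": segments, "group": groups, "frame": frames}
    )
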