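"""Time-course and drug-screen statistics for infiltration counts.

The endpoint assay yields one infiltrated-cell count per well per day.
This module implements the downstream statistics:

* per-well baseline correction (subtract each well's day-0 count);
* condition × day summaries (mean, sample SD, n);
* Z-factor assay windowing to pick the day that best separates a
  positive (invasive) from a negative (control) condition;
* a two-way repeated-measures ANOVA on log10(y + 1)-transformed
  corrected counts, with Geisser–Greenhouse sphericity correction and
  Tukey-adjusted pairwise condition contrasts per day;
* nonparametric screen testing (Kruskal–Wallis omnibus plus Dunn's
  post-hoc comparisons against vehicle);
* morphology counter-screen summaries (roundness, width-to-length)
  that rule out cytotoxicity as the cause of reduced infiltration.

The Z-factor is ``Z = 1 − 3(σ_pos + σ_neg)/|µ_pos − µ_neg|``; values
≥ 0.5 conventionally indicate an excellent assay window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssayWindow",
    "ScreenResult",
    "DesignError",
    "baseline_correct",
    "summarize",
    "cv_percent",
    "zfactor",
    "assay_window",
    "timecourse_test",
    "screen_test",
    "dunn_test",
    "morphology_counterscreen",
]

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """The records do not form the design a procedure requires."""


@dataclass(frozen=True)
class AssayWindow:
    """Per-day Z-factors for one (positive, negative) condition pair."""

    positive: str
    negative: str
    z_by_day: dict[int, float]
    selected_day: int
    excellent_days: tuple[int, ...]  # days with Z >= 0.5


@dataclass(frozen=True)
class ScreenResult:
    """Kruskal–Wallis omnibus plus Dunn comparisons vs. vehicle for
    one cell line at the readout day."""

    condition: str
    day: int
    kw_stat: float
    kw_p: float
    comparisons: pd.DataFrame  # compound, z, p_unadj, p_adj, n


# ---------------------------------------------------------------------------
# Baseline correction and summaries
# ---------------------------------------------------------------------------


def baseline_correct(records: pd.DataFrame) -> pd.DataFrame:
    """Subtract each well's day-0 raw count from all of its days.

    Adds a ``corrected_count`` column; day-0 corrected values are 0 by
    construction and negatives are retained.  A well without a day-0
    record is an error naming the well.
    """
    required = {"well", "day", "raw_count"}
    missing = required - set(records.columns)
    if missing:
        raise DesignError(f"missing column(s): {', '.join(sorted(missing))}")
    out = records.copy()
    day0 = out[out["day"] == 0].set_index("well")["raw_count"]
    absent = sorted(set(out["well"]) - set(day0.index))
    if absent:
        raise DesignError(f"well(s) without a day-0 record: {', '.join(map(str, absent))}")
    out["corrected_count"] = out["raw_count"] - out["well"].map(day0).to_numpy()
    return out


def summarize(
    records: pd.DataFrame, value: str = "corrected_count"
) -> pd.DataFrame:
    """Mean, sample SD (n−1) and n per condition × day."""
    if value not in records.columns:
        raise DesignError(f"no column {value!r} to summarize")
    g = records.groupby(["condition", "day"])[value]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)  # n = 1 groups
    return out


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100·sd/|mean|, rounded to one decimal."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return round(100.0 * sd / abs(mean), 1)


# ---------------------------------------------------------------------------
# Z-factor and assay window
# ---------------------------------------------------------------------------


def zfactor(mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float) -> float:
    """Z-factor: 1 − 3(σ_pos + σ_neg)/|µ_pos − µ_neg| (≤ 1 always)."""
    if sd_pos < 0 or sd_neg < 0:
        raise ValueError("standard deviations must be non-negative")
    delta = abs(mean_pos - mean_neg)
    if delta == 0:
        raise ValueError("Z-factor undefined for equal means")
    return 1.0 - 3.0 * (sd_pos + sd_neg) / delta


def assay_window(summaries: pd.DataFrame, positive: str, negative: str) -> AssayWindow:
    """Per-day Z-factor for a condition pair and the best readout day.

    The selected day is the argmax of Z (earliest day on ties); days
    with Z ≥ 0.5 are flagged as giving an excellent window.  Day 0 —
    where baseline-corrected means coincide at zero — and any day with
    equal means are skipped.
    """
    wide = summaries.set_index(["condition", "day"])
    days = sorted(set(summaries["day"]))
    z_by_day: dict[int, float] = {}
    for day in days:
        try:
            p = wide.loc[(positive, day)]
            n = wide.loc[(negative, day)]
        except KeyError:
            continue
        if p["mean"] == n["mean"]:
            continue
        z_by_day[int(day)] = zfactor(p["mean"], p["sd"], n["mean"], n["sd"])
    if not z_by_day:
        raise DesignError(
            f"no day has both conditions {positive!r} and {negative!r} "
            "with distinct means"
        )
    best = max(z_by_day, key=lambda d: (z_by_day[d], -d))
    excellent = tuple(d for d in sorted(z_by_day) if z_by_day[d] >= 0.5)
    return AssayWindow(
        positive=positive,
        negative=negative,
        z_by_day=z_by_day,
        selected_day=best,
        excellent_days=excellent,
    )


# ---------------------------------------------------------------------------
# Time-course testing
# ---------------------------------------------------------------------------


def log_transform(y: np.ndarray | pd.Series) -> np.ndarray:
    """log10(y + 1) with negatives floored at 0 first (count logged).

    Baseline correction can produce small negative values; flooring
    only at the transform step keeps the raw corrected data intact
    while making the log transform well-defined.
    """
    arr = np.asarray(y, dtype=float)
    n_neg = int((arr < 0).sum())
    if n_neg:
        logger.warning("floored %d negative corrected counts at 0 before log", n_neg)
    return np.log10(np.maximum(arr, 0.0) + 1.0)


def timecourse_test(
    records: pd.DataFrame, value: str = "corrected_count"
) -> dict[str, pd.DataFrame]:
    """Two-way repeated-measures ANOVA on log10(y + 1) counts.

    Condition is a between-subject factor (each well tracks one cell
    line), day a within-subject factor (wells are re-imaged daily).
    Sphericity is handled by the Geisser–Greenhouse epsilon, applied
    to the day main effect and the condition × day interaction.
    Pairwise condition contrasts per day are Tukey-adjusted.

    Returns ``{"anova": ..., "pairwise": ...}``.  An unbalanced design
    (any well missing any day) is an explicit error listing the holes.
    """
    needed = {"well", "condition", "day", value}
    missing = needed - set(records.columns)
    if missing:
        raise DesignError(f"missing column(s): {', '.join(sorted(missing))}")
    df = records.copy()
    days = sorted(df["day"].unique())
    holes = []
    for well, g in df.groupby("well"):
        absent = sorted(set(days) - set(g["day"]))
        if absent:
            holes.append(f"{well}: day(s) {absent}")
    if holes:
        raise DesignError("unbalanced design; missing cells — " + "; ".join(holes))
    if len(days) < 2 or df["condition"].nunique() < 2:
        raise DesignError("need >= 2 days and >= 2 conditions")

    df["y_log"] = log_transform(df[value])
    aov = pg.mixed_anova(
        data=df,
        dv="y_log",
        within="day",
        subject="well",
        between="condition",
        correction=True,
    )
    # apply the within-factor epsilon to the interaction too (the
    # interaction shares the within-subject error term)
    eps_row = aov.loc[aov["Source"] == "day", "eps"]
    eps = float(eps_row.iloc[0]) if len(eps_row) and not math.isnan(eps_row.iloc[0]) else 1.0
    out = aov.copy()
    out["p_GG"] = out["p_unc"]
    for src in ("day", "Interaction"):
        row = out["Source"] == src
        f = float(out.loc[row, "F"].iloc[0])
        df1 = float(out.loc[row, "DF1"].iloc[0]) * eps
        df2 = float(out.loc[row, "DF2"].iloc[0]) * eps
        out.loc[row, "p_GG"] = float(stats.f.sf(f, df1, df2))

    pairwise_frames = []
    for day in days:
        sub = df[df["day"] == day]
        if sub["condition"].nunique() < 2 or sub["y_log"].nunique() <= 1:
            continue  # day 0 is identically zero after baseline correction
        tk = pg.pairwise_tukey(data=sub, dv="y_log", between="condition")
        tk.insert(0, "day", day)
        pairwise_frames.append(tk)
    pairwise = pd.concat(pairwise_frames, ignore_index=True)
    return {"anova": out, "pairwise": pairwise}


# ---------------------------------------------------------------------------
# Drug-screen testing
# ---------------------------------------------------------------------------


def dunn_test(
    groups: dict[str, np.ndarray],
    control: str,
    *,
    adjust: str = "holm",
) -> pd.DataFrame:
    """Dunn's rank-based post-hoc comparisons against a control group.

    Uses the pooled-rank z statistic with tie correction; p-values are
    adjusted over the compounds-vs-control family (Holm by default).
    """
    if control not in groups:
        raise DesignError(f"control group {control!r} absent")
    labels = list(groups)
    values = np.concatenate([np.asarray(groups[k], dtype=float) for k in labels])
    sizes = {k: len(groups[k]) for k in labels}
    n = len(values)
    ranks = stats.rankdata(values)
    mean_ranks = {}
    start = 0
    for k in labels:
        mean_ranks[k] = ranks[start : start + sizes[k]].mean()
        start += sizes[k]
    # tie correction for the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term

    rows = []
    others = [k for k in labels if k != control]
    for k in others:
        se = math.sqrt(var_base * (1.0 / sizes[k] + 1.0 / sizes[control]))
        z = (mean_ranks[k] - mean_ranks[control]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"compound": k, "z": z, "p_unadj": p, "n": sizes[k]})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = multipletests(table["p_unadj"], method=adjust)[1]
    else:
        table["p_adj"] = []
    return table[["compound", "z", "p_unadj", "p_adj", "n"]]


def screen_test(
    records: pd.DataFrame,
    *,
    day: int = 3,
    vehicle: str = "vehicle",
    value: str = "corrected_count",
    adjust: str = "holm",
) -> list[ScreenResult]:
    """Per-cell-line screen analysis at the readout day.

    For each condition (cell line): Kruskal–Wallis omnibus across all
    compounds plus vehicle, then Dunn's post-hoc comparisons against
    vehicle with family-wise adjustment across compounds.
    """
    needed = {"condition", "compound", "day", value}
    missing = needed - set(records.columns)
    if missing:
        raise DesignError(f"missing column(s): {', '.join(sorted(missing))}")
    sub = records[records["day"] == day]
    if sub.empty:
        raise DesignError(f"no records at day {day}")
    results = []
    for cond, g in sub.groupby("condition"):
        groups = {
            comp: gg[value].to_numpy(dtype=float)
            for comp, gg in g.groupby("compound")
        }
        if vehicle not in groups:
            raise DesignError(f"condition {cond!r}: vehicle group {vehicle!r} missing")
        if len(groups) < 2:
            raise DesignError(
                f"condition {cond!r}: need at least one compound besides "
                f"{vehicle!r}"
            )
        small = [k for k, v in groups.items() if len(v) < 3]
        if small:
            raise DesignError(
                f"condition {cond!r}: groups with < 3 replicates: {small}"
            )
        samples = list(groups.values())
        if np.ptp(np.concatenate(samples)) == 0:
            kw_stat, kw_p = 0.0, 1.0  # all observations identical
        else:
            kw_stat, kw_p = stats.kruskal(*samples)
        comparisons = dunn_test(groups, vehicle, adjust=adjust)
        results.append(
            ScreenResult(
                condition=str(cond),
                day=day,
                kw_stat=float(kw_stat),
                kw_p=float(kw_p),
                comparisons=comparisons,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Morphology counter-screen
# ---------------------------------------------------------------------------


def morphology_counterscreen(
    cells: pd.DataFrame,
    *,
    control: str = "vehicle",
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group roundness and width-to-length summaries.

    Input: one row per cell with ``roundness`` and either
    ``width_to_length`` or ``aspect_ratio`` (width-to-length = 1/AR)
    plus a group label (and optionally ``day``).  Output: mean ± SD
    and n per group (× day), with each group's mean difference from
    the control group alongside.
    """
    df = cells.copy()
    if group_col not in df.columns or "roundness" not in df.columns:
        raise DesignError(f"need columns {group_col!r} and 'roundness'")
    if "width_to_length" not in df.columns:
        if "aspect_ratio" not in df.columns:
            raise DesignError("need 'width_to_length' or 'aspect_ratio'")
        df["width_to_length"] = 1.0 / df["aspect_ratio"]
    keys = [group_col] + (["day"] if "day" in df.columns else [])
    if df.groupby(keys).size().min() < 1:
        raise DesignError("empty group")
    agg = df.groupby(keys)[["roundness", "width_to_length"]].agg(["mean", "std", "count"])
    agg.columns = ["_".join(c) for c in agg.columns]
    agg = agg.reset_index().rename(
        columns={"roundness_count": "n", "width_to_length_count": "n_wl"}
    )
    agg = agg.drop(columns=["n_wl"])
    for metric in ("roundness", "width_to_length"):
        agg[f"{metric}_std"] = agg[f"{metric}_std"].fillna(0.0)
    ctrl_keys = ["day"] if "day" in df.columns else []
    ctrl = agg[agg[group_col] == control]
    if ctrl.empty:
        raise DesignError(f"control group {control!r} absent")
    if ctrl_keys:
        ctrl_map_r = ctrl.set_index("day")["roundness_mean"]
        ctrl_map_w = ctrl.set_index("day")["width_to_length_mean"]
        agg["roundness_diff_vs_control"] = (
            agg["roundness_mean"] - agg["day"].map(ctrl_map_r).to_numpy()
        )
        agg["width_to_length_diff_vs_control"] = (
            agg["width_to_length_mean"] - agg["day"].map(ctrl_map_w).to_numpy()
        )
    else:
        agg["roundness_diff_vs_control"] = (
            agg["roundness_mean"] - float(ctrl["roundness_mean"].iloc[0])
        )
        agg["width_to_length_diff_vs_control"] = (
            agg["width_to_length_mean"] - float(ctrl["width_to_length_mean"].iloc[0])
        )
    return agg
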