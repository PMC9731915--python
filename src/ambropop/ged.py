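"""Gene expression diversity (GED) analysis.

GED of a transcript within a sample group is the coefficient of variation
(sample s.d. / mean) of its TPM across the group's samples. High GED means
variable expression among plants; the study's central observation is that
wild populations show higher GED than weedy ones. This module computes GED
tables, compares group CV distributions with rank tests, extracts transcripts
under shifted density peaks, applies the pairwise more-than-twofold filter
with seeded downsampling, and provides a rank-test differential-expression
caller with exclusive (UpSet-style) DEG set overlaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelextrema
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, SamplePanel

log = logging.getLogger(__name__)

Grouping = Literal["by_population", "by_habitat_within_region"]


def _groups(panel: SamplePanel, grouping: Grouping) -> dict[str, list[str]]:
    t = panel.table
    if grouping == "by_population":
        return {p: list(sub["sample_id"])
                for p, sub in t.groupby("population_id", sort=False)}
    if grouping == "by_habitat_within_region":
        return {f"{r}:{h}": list(sub["sample_id"])
                for (r, h), sub in t.groupby(["region", "habitat"], sort=False)}
    raise ValueError(f"unknown grouping {grouping!r}")


def cv_vector(values: pd.DataFrame) -> pd.Series:
    """Per-transcript CV (n-1 s.d. / mean) across columns; NaN where the
    mean is 0 (CV undefined) or fewer than 2 samples."""
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    if arr.shape[1] < 2:
        return pd.Series(np.nan, index=values.index)
    sd = arr.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.Series(cv, index=values.index)


def ged_cv(expr: ExpressionMatrix, panel: SamplePanel,
           grouping: Grouping = "by_population") -> pd.DataFrame:
    """GED table: one row per (transcript, group) with CV, n and mean TPM.

    Transcripts whose group mean TPM is 0 are omitted for that group;
    groups with a single sample are skipped with a warning.
    """
    rows = []
    for group, samples in _groups(panel, grouping).items():
        if len(samples) < 2:
            log.warning("ged_cv: group %s has 1 sample; skipped", group)
            continue
        sub = expr.values[samples]
        cv = cv_vector(sub)
        mean = sub.mean(axis=1)
        keep = cv.notna()
        rows.append(pd.DataFrame({
            "transcript_id": sub.index[keep],
            "group_id": group,
            "cv": cv[keep].to_numpy(),
            "n_samples": len(samples),
            "mean_tpm": mean[keep].to_numpy(),
        }))
    return (pd.concat(rows, ignore_index=True) if rows
            else pd.DataFrame(columns=["transcript_id", "group_id", "cv",
                                       "n_samples", "mean_tpm"]))


def compare_ged_groups(ged_weedy: np.ndarray | pd.Series,
                       ged_wild: np.ndarray | pd.Series,
                       test: str = "kruskal_wallis"
                       ) -> tuple[float, float, str]:
    """Rank-based comparison of two CV distributions.

    Returns (statistic, p, higher_median_group) with group names
    "weedy"/"wild" ("tie" when medians are equal).
    """
    x = np.asarray(ged_weedy, dtype=float)
    y = np.asarray(ged_wild, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both CV vectors must be non-empty")
    med_w, med_x = float(np.median(x)), float(np.median(y))
    higher = "wild" if med_x > med_w else ("weedy" if med_w > med_x else "tie")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0, higher
    if test == "kruskal_wallis":
        stat, p = stats.kruskal(x, y)
    elif test == "wilcoxon_rank_sum":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(stat), float(p), higher


@dataclass
class PeakShift:
    weedy_peak: float
    wild_peak: float
    interval: tuple[float, float]
    weedy_transcripts: list[str]
    wild_transcripts: list[str]


@dataclass
class PeakShiftResult:
    weedy_peaks: list[float]
    wild_peaks: list[float]
    shifts: list[PeakShift]


def _density_peaks(values: np.ndarray, grid: np.ndarray,
                   bw_method: str = "silverman") -> tuple[list[float], float]:
    kde = stats.gaussian_kde(values, bw_method=bw_method)
    dens = kde(grid)
    idx = argrelextrema(dens, np.greater)[0]
    if dens[0] > dens[1]:
        idx = np.append(0, idx)
    if dens[-1] > dens[-2]:
        idx = np.append(idx, len(grid) - 1)
    bandwidth = float(np.sqrt(kde.covariance[0, 0]))
    return [float(grid[i]) for i in idx], bandwidth


def peak_shift_transcripts(ged_weedy: pd.DataFrame, ged_wild: pd.DataFrame,
                           bw_method: str = "silverman",
                           shift_threshold: float = 0.05,
                           grid_points: int = 512) -> PeakShiftResult:
    """Locate CV-density peaks that moved between habitats.

    Gaussian KDE (Silverman bandwidth) on each CV vector; local maxima are
    paired greedily by proximity; a pair whose locations differ by more than
    ``shift_threshold`` CV units defines the interval
    [min(loc) - h, max(loc) + h] (h = mean bandwidth), and transcripts with
    CV inside the interval are listed per habitat.

    Inputs are GED tables (or any frames with transcript_id + cv columns)
    with >= 50 CV values each.
    """
    w = ged_weedy.dropna(subset=["cv"])
    x = ged_wild.dropna(subset=["cv"])
    if len(w) < 50 or len(x) < 50:
        raise ValueError("need >= 50 CV values per group for density estimation")
    lo = min(w["cv"].min(), x["cv"].min())
    hi = max(w["cv"].max(), x["cv"].max())
    grid = np.linspace(lo, hi, grid_points)
    peaks_w, h_w = _density_peaks(w["cv"].to_numpy(), grid, bw_method)
    peaks_x, h_x = _density_peaks(x["cv"].to_numpy(), grid, bw_method)
    result = PeakShiftResult(peaks_w, peaks_x, [])
    if not peaks_w or not peaks_x:
        return result
    h = (h_w + h_x) / 2
    # greedy pairing by proximity
    cand = sorted(((abs(a - b), i, j) for i, a in enumerate(peaks_w)
                   for j, b in enumerate(peaks_x)))
    used_w: set[int] = set()
    used_x: set[int] = set()
    for dist, i, j in cand:
        if i in used_w or j in used_x:
            continue
        used_w.add(i)
        used_x.add(j)
        if dist > shift_threshold:
            a, b = peaks_w[i], peaks_x[j]
            interval = (min(a, b) - h, max(a, b) + h)
            in_w = w[(w["cv"] >= interval[0]) & (w["cv"] <= interval[1])]
            in_x = x[(x["cv"] >= interval[0]) & (x["cv"] <= interval[1])]
            result.shifts.append(PeakShift(
                a, b, interval,
                list(in_w["transcript_id"]), list(in_x["transcript_id"])))
    return result


def pairwise_twofold_ged(expr: ExpressionMatrix, panel: SamplePanel,
                         pair: tuple[str, str], seed: int = 0,
                         n_draws: int = 1) -> dict[str, list[str]]:
    """More-than-twofold GED differences between a weedy/wild population pair.

    The larger population is downsampled (without replacement, seeded) to the
    smaller's size before computing CVs; with n_draws > 1 the median CV over
    draws is used. Strictly-greater-than-twofold ratios are flagged, only
    where both CVs are defined.

    Returns {"weedy_higher": [...], "wild_higher": [...]}.
    """
    weedy_pop, wild_pop = pair
    s_w = panel.samples_of(weedy_pop)
    s_x = panel.samples_of(wild_pop)
    if len(s_w) < 2 or len(s_x) < 2:
        raise ValueError("both populations need >= 2 samples")
    n = min(len(s_w), len(s_x))
    rng = np.random.default_rng(seed)

    def median_cv(samples: list[str]) -> pd.Series:
        if len(samples) == n:
            return cv_vector(expr.values[samples])
        draws = []
        for _ in range(n_draws):
            pick = list(rng.choice(samples, size=n, replace=False))
            draws.append(cv_vector(expr.values[pick]))
        return pd.concat(draws, axis=1).median(axis=1)

    cv_w = median_cv(s_w)
    cv_x = median_cv(s_x)
    both = cv_w.notna() & cv_x.notna()
    weedy_higher = cv_w[both & (cv_w > 2 * cv_x)].index
    wild_higher = cv_x[both & (cv_x > 2 * cv_w)].index
    return {"weedy_higher": list(weedy_higher), "wild_higher": list(wild_higher)}


def de_rank_test(expr: ExpressionMatrix, panel: SamplePanel,
                 pair: tuple[str, str], alpha: float = 0.05
                 ) -> dict[str, list[str]]:
    """Rank-sum DE between a population pair on log2(TPM+1), BH-corrected.

    Returns {"up": [...], "down": [...]} — up means higher in the first
    (weedy) population. Constant transcripts get p = 1.
    """
    g1 = panel.samples_of(pair[0])
    g2 = panel.samples_of(pair[1])
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both populations need >= 2 samples")
    x = np.log2(expr.values[g1].to_numpy() + 1)
    y = np.log2(expr.values[g2].to_numpy() + 1)
    pvals = np.ones(x.shape[0])
    const = np.array([np.all(row == row[0]) for row in
                      np.hstack([x, y])])
    if (~const).any():
        res = stats.mannwhitneyu(x[~const], y[~const], axis=1,
                                 alternative="two-sided")
        pvals[~const] = res.pvalue
    adj = multipletests(pvals, method="fdr_bh")[1]
    diff = np.median(x, axis=1) - np.median(y, axis=1)
    ids = np.asarray(expr.transcript_ids)
    sig = adj <= alpha
    return {"up": list(ids[sig & (diff > 0)]),
            "down": list(ids[sig & (diff < 0)])}


def deg_overlap(sets: Mapping[str, tuple[set[str], set[str]]]) -> pd.DataFrame:
    """Exclusive (UpSet-style) intersection counts of up/down DEG sets.

    For every non-empty combination of populations, counts transcripts
    present in all member sets and absent from every other population's set.
    The exclusive counts partition each union.
    """
    pops = list(sets)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    rows = []
    for which, idx in (("up", 0), ("down", 1)):
        per_pop = {p: set(sets[p][idx]) for p in pops}
        for r in range(1, len(pops) + 1):
            for combo in combinations(pops, r):
                inside = set.intersection(*(per_pop[p] for p in combo))
                outside = set().union(*(per_pop[p] for p in pops
                                        if p not in combo)) if r < len(pops) \
                    else set()
                rows.append(("+".join(combo), which, len(inside - outside)))
    return pd.DataFrame(rows, columns=["combination", "direction", "count"])
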