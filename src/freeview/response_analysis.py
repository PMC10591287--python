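"""Fixation-aligned firing-rate analysis.

Builds perifixation time histograms (PFTHs: 1-ms binned spike counts,
smoothed per fixation with a 10-ms-SD Gaussian kernel, then averaged
across fixations), compares rate time courses between fixation-order
categories, locates the two fixation-order-dependent response (FODR)
windows from the time course of the count of units with significant
first-vs-later rate decreases, and tabulates per-fixation rates inside
the FODR windows for the population analyses downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PFTH",
    "FODRWindows",
    "DEFAULT_FODR",
    "compute_pfth",
    "rate_comparison_timecourse",
    "determine_fodr",
    "build_rate_table",
    "per_object_change_counts",
]

logger = logging.getLogger(__name__)

BIN_MS = 1.0
SMOOTH_SD_MS = 10.0

# per-area defaults for the two 50-ms FODR windows, ms after fixation onset
DEFAULT_FODR: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "V1": ((40.0, 90.0), (110.0, 160.0)),
    "V2": ((40.0, 90.0), (110.0, 160.0)),
    "IT": ((100.0, 150.0), (150.0, 200.0)),
}


@dataclass(frozen=True)
class PFTH:
    """Mean fixation-aligned spike density with its SEM."""

    time_ms: np.ndarray
    rate: np.ndarray  # spikes/s
    sem: np.ndarray
    n_fixations: int
    smoothing_sd_ms: float = SMOOTH_SD_MS


@dataclass(frozen=True)
class FODRWindows:
    area: str
    fodr1: tuple[float, float]  # ms
    fodr2: tuple[float, float]

    def __post_init__(self):
        for w in (self.fodr1, self.fodr2):
            if not (0 <= w[0] < w[1] <= 200):
                raise ValueError("FODR windows must lie within [0, 200] ms")
        if self.fodr1[0] >= self.fodr2[0]:
            raise ValueError("fodr1 must precede fodr2")


def _binned_density(spikes: np.ndarray, onset: float,
                    window_ms: tuple[float, float]) -> np.ndarray:
    """1-ms binned spike density (spikes/s) around one fixation onset."""
    lo, hi = window_ms
    edges = np.arange(lo, hi + BIN_MS, BIN_MS) * 1e-3 + onset
    counts, _ = np.histogram(spikes, bins=edges)
    return counts * (1000.0 / BIN_MS)


def compute_pfth(spikes: np.ndarray, onsets: Sequence[float],
                 window_ms: tuple[float, float] = (-100.0, 300.0),
                 smoothing_sd_ms: float = SMOOTH_SD_MS) -> PFTH:
    """Smooth-then-average perifixation time histogram.

    Each fixation's 1-ms binned counts are smoothed with a Gaussian
    kernel (SD ``smoothing_sd_ms``) to a spike density, and the
    densities are averaged across fixations (mean +/- SEM).  The kernel
    conserves spike mass for spikes away from the window edges.
    """
    onsets = np.asarray(onsets, dtype=float)
    if len(onsets) == 0:
        raise ValueError("need at least one fixation onset")
    spikes = np.asarray(spikes, dtype=float)
    sigma_bins = smoothing_sd_ms / BIN_MS
    dens = np.stack([
        gaussian_filter1d(_binned_density(spikes, on, window_ms), sigma_bins,
                          mode="constant")
        for on in onsets])
    lo, hi = window_ms
    centers = np.arange(lo, hi, BIN_MS) + BIN_MS / 2
    sem = (dens.std(axis=0, ddof=1) / np.sqrt(len(onsets))
           if len(onsets) > 1 else np.zeros(dens.shape[1]))
    return PFTH(time_ms=centers, rate=dens.mean(axis=0), sem=sem,
                n_fixations=len(onsets), smoothing_sd_ms=smoothing_sd_ms)


def rate_comparison_timecourse(per_unit_pfths: Mapping[object, Mapping[str, PFTH]],
                               baseline: str = "first",
                               others: Sequence[str] = ("secondplus", "revisit"),
                               alpha: float = 0.01,
                               range_ms: tuple[float, float] = (0.0, 200.0),
                               ) -> pd.DataFrame:
    """Per-bin paired signed-rank comparison of category PFTHs across units.

    For every 1-ms bin in ``range_ms``, the baseline-category rate is
    compared against each other category across units (two-sided
    signed-rank), Bonferroni-corrected over the bins tested.  Units
    missing a category are dropped pairwise.  Returns a long table of
    (category, time_ms, p, significant).
    """
    rows = []
    for other in others:
        units = [u for u, d in per_unit_pfths.items()
                 if baseline in d and other in d]
        if len(units) < 2:
            warnings.warn(f"fewer than 2 units with both {baseline!r} and "
                          f"{other!r}; skipping")
            continue
        t = per_unit_pfths[units[0]][baseline].time_ms
        sel = (t >= range_ms[0]) & (t < range_ms[1])
        a = np.stack([per_unit_pfths[u][baseline].rate[sel] for u in units])
        b = np.stack([per_unit_pfths[u][other].rate[sel] for u in units])
        n_bins = sel.sum()
        for k, tm in enumerate(t[sel]):
            diff = a[:, k] - b[:, k]
            if np.allclose(diff, 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(a[:, k], b[:, k],
                                         zero_method="zsplit").pvalue)
            p_corr = min(p * n_bins, 1.0)
            rows.append({"category": other, "time_ms": float(tm), "p": p,
                         "p_bonferroni": p_corr,
                         "significant": p_corr < alpha})
    return pd.DataFrame(rows)


def _window_rates(spikes: np.ndarray, onsets: np.ndarray,
                  start_ms: float, width_ms: float) -> np.ndarray:
    """Per-fixation rates (spikes/s) in one post-onset window."""
    lo = onsets + start_ms * 1e-3
    hi = lo + width_ms * 1e-3
    counts = (np.searchsorted(spikes, hi) - np.searchsorted(spikes, lo))
    return counts / (width_ms * 1e-3)


def determine_fodr(unit_fixations: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
                   area: str = "IT", *, window_ms: float = 50.0,
                   step_ms: float = 5.0, range_ms: tuple[float, float] = (0.0, 200.0),
                   alpha: float = 0.01,
                   ) -> tuple[FODRWindows, pd.DataFrame]:
    """Locate the two FODR windows from first-vs-later rate decreases.

    ``unit_fixations`` holds, per unit, (spike_times, first_onsets,
    later_onsets).  For each 50-ms window slid in 5-ms steps over
    [0, 200] ms, every unit's first-fixation rates are tested against
    its later-fixation rates (one-sided Mann-Whitney U for a decrease,
    p < 0.01) and the significant units are counted.  The two highest
    local maxima of the count curve give the window centers; if fewer
    than two local maxima emerge, the per-area default windows are
    returned (with a log entry).  Also returns the count curve.
    """
    if len(unit_fixations) < 10:
        raise ValueError("need at least 10 units to determine FODR windows")
    starts = np.arange(range_ms[0], range_ms[1] - window_ms + step_ms / 2, step_ms)
    counts = np.zeros(len(starts), dtype=int)
    for spikes, first_on, later_on in unit_fixations:
        spikes = np.sort(np.asarray(spikes, dtype=float))
        if len(first_on) == 0 or len(later_on) == 0:
            continue
        for k, s in enumerate(starts):
            rf = _window_rates(spikes, np.asarray(first_on), s, window_ms)
            rl = _window_rates(spikes, np.asarray(later_on), s, window_ms)
            if np.ptp(rf) == 0 and np.ptp(rl) == 0 and rf[0] == rl[0]:
                continue
            p = stats.mannwhitneyu(rf, rl, alternative="greater").pvalue
            counts[k] += p < alpha
    curve = pd.DataFrame({"center_ms": starts + window_ms / 2, "n_significant": counts})
    # local maxima (plateaus count once, at their midpoint)
    peaks = []
    k = 0
    while k < len(counts):
        j = k
        while j + 1 < len(counts) and counts[j + 1] == counts[k]:
            j += 1
        left = counts[k - 1] if k > 0 else -1
        right = counts[j + 1] if j + 1 < len(counts) else -1
        if counts[k] > left and counts[k] > right and counts[k] > 0:
            peaks.append(((k + j) // 2, counts[k]))
        k = j + 1
    if len(peaks) < 2:
        logger.info("fewer than two local maxima in the significant-unit "
                    "curve; falling back to %s defaults", area)
        d1, d2 = DEFAULT_FODR[area]
        return FODRWindows(area=area, fodr1=d1, fodr2=d2), curve
    top = sorted(sorted(peaks, key=lambda p: -p[1])[:2])
    wins = []
    for idx, _ in top:
        c = starts[idx] + window_ms / 2
        lo = float(np.clip(c - window_ms / 2, range_ms[0], range_ms[1] - window_ms))
        wins.append((lo, lo + window_ms))
    return FODRWindows(area=area, fodr1=wins[0], fodr2=wins[1]), curve


def build_rate_table(session_spikes: Sequence[Sequence[np.ndarray]],
                     labeled_fixations: Sequence[Sequence],
                     windows: FODRWindows,
                     unit_ids: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-(unit, object fixation, window) firing rates during the FODRs.

    ``session_spikes[trial][unit]`` are spike times on the trial clock;
    ``labeled_fixations[trial]`` the LabeledFixations of that trial.
    Background fixations are excluded.  Fixations that end before the
    window does are kept but flagged (``short``) so users can filter.
    """
    if unit_ids is None:
        unit_ids = range(len(session_spikes[0])) if session_spikes else []
    rows = []
    for trial_fix, trial_spikes in zip(labeled_fixations, session_spikes):
        for u, spikes in zip(unit_ids, trial_spikes):
            spikes = np.asarray(spikes, dtype=float)
            for fid, lf in enumerate(trial_fix):
                if lf.category == "background":
                    continue
                for name, (lo, hi) in (("FODR1", windows.fodr1),
                                       ("FODR2", windows.fodr2)):
                    t0 = lf.t_on + lo * 1e-3
                    t1 = lf.t_on + hi * 1e-3
                    n = int(np.searchsorted(spikes, t1) - np.searchsorted(spikes, t0))
                    rows.append({
                        "unit_id": u, "trial_id": lf.trial_id, "fixation_id": fid,
                        "object_id": lf.target, "category": lf.category,
                        "sub_order": lf.sub_order, "mix_index": lf.mix_index,
                        "window": name, "n_spikes": n,
                        "rate": n / ((hi - lo) * 1e-3),
                        "short": lf.t_off < t1})
    return pd.DataFrame(rows, columns=["unit_id", "trial_id", "fixation_id",
                                       "object_id", "category", "sub_order",
                                       "mix_index", "window", "n_spikes",
                                       "rate", "short"])


def per_object_change_counts(rate_table: pd.DataFrame, *, window: str = "FODR1",
                             baseline: str = "first",
                             other: str = "secondplus",
                             fdr_alpha: float = 0.05,
                             min_samples: int = 2) -> pd.DataFrame:
    """Per-unit counts of objects with increased/decreased later-fixation rates.

    For each (unit, object), the baseline-category rates are compared to
    the other category's (two-sided Mann-Whitney U); p-values are
    corrected across objects within each unit by Benjamini-Hochberg FDR.
    Returns one row per unit with total and significant up/down counts.
    """
    sub = rate_table[rate_table["window"] == window]
    rows = []
    for unit, grp in sub.groupby("unit_id"):
        ps, dirs = [], []
        for obj, og in grp.groupby("object_id"):
            a = og.loc[og["category"] == baseline, "rate"].to_numpy()
            b = og.loc[og["category"] == other, "rate"].to_numpy()
            if len(a) < min_samples or len(b) < min_samples:
                logger.debug("unit %s object %s skipped: too few samples",
                             unit, obj)
                continue
            d = b.mean() - a.mean()
            if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            ps.append(p)
            dirs.append(np.sign(d))
        ps = np.asarray(ps)
        dirs = np.asarray(dirs)
        sig = (multipletests(ps, alpha=fdr_alpha, method="fdr_bh")[0]
               if len(ps) else np.zeros(0, dtype=bool))
        rows.append({"unit_id": unit, "n_objects": len(ps),
                     "n_up": int(np.sum(dirs > 0)),
                     "n_down": int(np.sum(dirs < 0)),
                     "n_sig_up": int(np.sum(sig & (dirs > 0))),
                     "n_sig_down": int(np.sum(sig & (dirs < 0)))})
    return pd.DataFrame(rows)
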