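"""End-to-end session analysis: traces to labeled rates and order effects.

Glue between the modules: runs event detection on every trial of a
session, assigns fixation targets and order categories, tabulates FODR
rates, and summarizes the fixation-order modulation of rates,
sparseness, and population similarity.  This is the path the synthetic
parameter-recovery studies exercise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eye_events import DetectionParams, detect_events
from .fixation_context import label_fixations
from .population_metrics import ResponsePool, resampled_similarity, sparseness
from .response_analysis import DEFAULT_FODR, FODRWindows, build_rate_table
from .synthdata import SessionBundle

__all__ = ["analyze_session", "order_modulation_summary", "OrderModulation"]

CATEGORIES = ("first", "secondplus", "revisit")


def analyze_session(bundle: SessionBundle,
                    windows: FODRWindows | None = None,
                    params: DetectionParams | None = None,
                    use_truth: bool = False,
                    ) -> tuple[list, pd.DataFrame]:
    """Detect, label, and tabulate a whole session.

    Returns (labeled fixations per trial, rate table).  ``windows``
    defaults to the per-area defaults for the session's area.  With
    ``use_truth`` the generator's ground-truth events replace detection
    (useful to isolate spike-level behavior from detector behavior).
    """
    area = bundle.units[0].area if bundle.units else "IT"
    if windows is None:
        d1, d2 = DEFAULT_FODR[area]
        windows = FODRWindows(area=area, fodr1=d1, fodr2=d2)
    scene_by_id = {s.scene_id: s for s in bundle.scenes}
    labeled = []
    for trial in bundle.trials:
        scene = scene_by_id[trial["scene_id"]]
        if use_truth:
            from .eye_events import FixationEvent, SaccadeEvent
            fixations = [FixationEvent(e.t_on, e.t_off, e.x_land, e.y_land, 0.0)
                         for e in trial["truth"].events if e.kind == "fixation"]
            saccades = [SaccadeEvent(e.t_on, e.t_off,
                                     float(np.hypot(e.x_land, e.y_land)),
                                     0.0, 0.0)
                        for e in trial["truth"].events if e.kind == "saccade"]
        else:
            saccades, fixations, _ = detect_events(trial["trace"], params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labeled.append(label_fixations(fixations, scene,
                                           trial["trial_id"], saccades))
    table = build_rate_table(bundle.spikes, labeled, windows,
                             unit_ids=[u.unit_id for u in bundle.units])
    return labeled, table


@dataclass(frozen=True)
class OrderModulation:
    """Session-level fixation-order effects on rate, sparseness, similarity."""

    rate_ratio: float            # mean over units of later/first rate
    sparseness_diff: float       # median over units, later minus first
    similarity_diff: float       # mean over object pairs, later minus first
    n_units: int
    n_pairs: int


def _unit_sparseness(table: pd.DataFrame, window: str) -> pd.DataFrame:
    """Per-(unit, category) sparseness over reduced object vectors.

    For each unit only objects with a valid mean rate in *all three*
    categories enter the rate vector, so categories are compared on the
    same objects.
    """
    sub = table[table["window"] == window]
    means = (sub.groupby(["unit_id", "object_id", "category"])["rate"]
             .mean().unstack("category"))
    rows = []
    for unit, grp in means.groupby(level="unit_id"):
        valid = grp.dropna(subset=[c for c in CATEGORIES if c in grp.columns])
        if len(valid) < 2 or any(c not in valid.columns for c in CATEGORIES):
            continue
        for cat in CATEGORIES:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = sparseness(valid[cat].to_numpy())
            rows.append({"unit_id": unit, "category": cat, "sparseness": s})
    return pd.DataFrame(rows)


def order_modulation_summary(table: pd.DataFrame, *, window: str = "FODR1",
                             rng: np.random.Generator | int | None = None,
                             n_resamples: int = 100) -> OrderModulation:
    """Later-versus-first modulation of rate, sparseness, and similarity.

    "Later" pools secondplus and revisit fixations.  Rate ratio is the
    across-unit mean of (later mean rate / first mean rate); sparseness
    and similarity differences are later minus first (medians over
    units, means over object pairs).
    """
    rng = np.random.default_rng(rng)
    sub = table[table["window"] == window]
    per_unit = (sub.assign(later=sub["category"] != "first")
                .groupby(["unit_id", "later"])["rate"].mean().unstack())
    per_unit = per_unit.dropna()
    per_unit = per_unit[per_unit[False] > 0]
    ratios = (per_unit[True] / per_unit[False]).to_numpy()

    sp = _unit_sparseness(table, window)
    sp_diff = np.nan
    if len(sp):
        wide = sp.pivot_table(index="unit_id", columns="category",
                              values="sparseness").dropna()
        later = wide[["secondplus", "revisit"]].mean(axis=1)
        sp_diff = float((later - wide["first"]).median())

    pool = ResponsePool.from_rate_table(table)
    sims = {}
    for cat in CATEGORIES:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = resampled_similarity(pool, cat, window,
                                       all_categories=CATEGORIES,
                                       n_resamples=n_resamples, rng=rng)
        sims[cat] = pd.DataFrame(
            [{"pair": (r.object_a, r.object_b), "sim": r.similarity}
             for r in res]).set_index("pair") if res else pd.DataFrame()
    sim_diff = np.nan
    n_pairs = 0
    if all(len(sims[c]) for c in CATEGORIES):
        joined = sims["first"].join(sims["secondplus"], rsuffix="_s").join(
            sims["revisit"], rsuffix="_r").dropna()
        n_pairs = len(joined)
        if n_pairs:
            later = (joined["sim_s"] + joined["sim_r"]) / 2
            sim_diff = float((later - joined["sim"]).mean())
    return OrderModulation(rate_ratio=float(np.mean(ratios)),
                           sparseness_diff=sp_diff,
                           similarity_diff=sim_diff,
                           n_units=len(ratios), n_pairs=n_pairs)
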