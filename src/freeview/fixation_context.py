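"""Behavioral context of fixations: target assignment, order taxonomy,
and fixation-position overlap.

Each fixation in a free-viewing trial is assigned to the object whose
center lies within 1.5 deg of the mean gaze position (otherwise it is a
background fixation), then categorized by its order on that object
within the trial:

* ``first``       — the first fixation on the object;
* ``secondplus``  — a consecutive re-fixation of the same object
                    (the preceding fixation was on the same object);
* ``revisit``     — a return to an already-fixated object after
                    fixating elsewhere (another object or background).

Sub-orders refine the taxonomy (second1/second2, revisit1/revisit2) and
the "mix" index counts fixations on the object cumulatively, ignoring
the secondplus/revisit distinction.

Overlap of fixation-position scatter between two categories is measured
by summing isotropic 2-D Gaussians (variance 0.2 deg^2) at the per-
fixation offsets from the object center, normalizing each map to a
maximum of 1, and taking 2*sum(min)/(sum A + sum B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .population_metrics import cliffs_delta

__all__ = [
    "BACKGROUND",
    "LabeledFixation",
    "FixationProbabilityMap",
    "assign_targets",
    "categorize_orders",
    "label_fixations",
    "build_probability_map",
    "overlap",
    "overlap_comparison",
]

BACKGROUND = -1
ASSIGN_RADIUS = 1.5  # deg


@dataclass
class LabeledFixation:
    """A fixation annotated with its target object and order category."""

    t_on: float
    t_off: float
    x: float
    y: float
    trial_id: int
    target: int  # object id or BACKGROUND
    category: str  # first | secondplus | revisit | background
    sub_order: str  # second1 | second2 | revisit1 | revisit2 | other | none
    mix_index: int | None  # cumulative fixation count on the target, or None
    preceding_saccade_amplitude: float = float("nan")


def assign_targets(positions: Sequence[tuple[float, float]],
                   scene, radius: float = ASSIGN_RADIUS) -> list[int]:
    """Nearest object id within ``radius`` of each position, else BACKGROUND.

    The boundary is inclusive; a distance tie is broken by the lowest
    object id.  ``scene`` needs an ``objects`` attribute of
    (object_id, x, y) triples.
    """
    objs = sorted(scene.objects, key=lambda o: o[0])
    ids = np.array([o[0] for o in objs])
    centers = np.array([[o[1], o[2]] for o in objs], dtype=float)
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) < 2 * radius:
                warnings.warn(
                    f"objects {ids[i]} and {ids[j]} are closer than twice the "
                    f"assignment radius; assignment may be ambiguous")
    out = []
    for x, y in positions:
        d = np.hypot(centers[:, 0] - x, centers[:, 1] - y)
        k = int(np.argmin(d))  # argmin takes the first = lowest id on ties
        out.append(int(ids[k]) if d[k] <= radius else BACKGROUND)
    return out


def categorize_orders(targets: Sequence[int]) -> list[tuple[str, str, int | None]]:
    """Order category, sub-order, and mix index for one trial's target sequence.

    Rules, applied per object, in time order:

    * first occurrence of an object -> ``first`` (mix 1);
    * same object as the immediately preceding fixation -> ``secondplus``,
      with the consecutive-run counter restarting after every first or
      revisit (second1, second2, then other);
    * return to a previously fixated object from another object or from
      background -> ``revisit`` (revisit1 = first revisit on that object
      in the trial, revisit2 = second, then other);
    * background fixations carry no order.
    """
    mix_count: dict[int, int] = {}
    revisit_count: dict[int, int] = {}
    chain_pos = 0  # position within the current consecutive same-object run
    prev_target: int | None = None
    out: list[tuple[str, str, int | None]] = []
    for tgt in targets:
        if tgt == BACKGROUND:
            out.append(("background", "none", None))
            prev_target = BACKGROUND
            continue
        mix_count[tgt] = mix_count.get(tgt, 0) + 1
        if mix_count[tgt] == 1:
            out.append(("first", "none", 1))
            chain_pos = 0
        elif tgt == prev_target:
            chain_pos += 1
            sub = {1: "second1", 2: "second2"}.get(chain_pos, "other")
            out.append(("secondplus", sub, mix_count[tgt]))
        else:
            revisit_count[tgt] = revisit_count.get(tgt, 0) + 1
            sub = {1: "revisit1", 2: "revisit2"}.get(revisit_count[tgt], "other")
            out.append(("revisit", sub, mix_count[tgt]))
            chain_pos = 0
        prev_target = tgt
    return out


def label_fixations(fixations, scene, trial_id: int,
                    saccades=None, radius: float = ASSIGN_RADIUS,
                    ) -> list[LabeledFixation]:
    """Assign targets and order categories to detected fixations of one trial.

    ``fixations`` are FixationEvents in time order; ``saccades``
    (optional, time-ordered) provide each fixation's preceding saccade
    amplitude.
    """
    positions = [(f.x_mean, f.y_mean) for f in fixations]
    targets = assign_targets(positions, scene, radius)
    cats = categorize_orders(targets)
    out = []
    for f, tgt, (cat, sub, mix) in zip(fixations, targets, cats):
        amp = float("nan")
        if saccades:
            prior = [s for s in saccades if s.t_off <= f.t_on]
            if prior:
                amp = prior[-1].amplitude
        out.append(LabeledFixation(
            t_on=f.t_on, t_off=f.t_off, x=f.x_mean, y=f.y_mean,
            trial_id=trial_id, target=tgt, category=cat, sub_order=sub,
            mix_index=mix, preceding_saccade_amplitude=amp))
    return out


@dataclass(frozen=True)
class FixationProbabilityMap:
    """Gaussian-sum fixation-occurrence map in object-centered coordinates."""

    grid: np.ndarray
    xs: np.ndarray  # cell-center x coordinates, deg
    ys: np.ndarray


def build_probability_map(offsets: Sequence[tuple[float, float]],
                          variance: float = 0.2, resolution: float = 0.05,
                          extent: float = 3.0) -> FixationProbabilityMap:
    """Sum of isotropic 2-D Gaussians at fixation offsets, peak-normalized.

    ``variance`` is in deg^2 (the literal reading; sigma ~ 0.447 deg for
    the 0.2 default).  The grid spans +/- ``extent`` deg around the
    object center at ``resolution`` deg per cell.
    """
    offsets = np.asarray(offsets, dtype=float).reshape(-1, 2)
    if len(offsets) == 0:
        raise ValueError("need at least one fixation offset")
    xs = np.arange(-extent, extent + resolution / 2, resolution)
    ys = xs.copy()
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    grid = np.zeros_like(gx)
    for ox, oy in offsets:
        grid += np.exp(-((gx - ox) ** 2 + (gy - oy) ** 2) / (2 * variance))
    grid /= grid.max()
    return FixationProbabilityMap(grid=grid, xs=xs, ys=ys)


def overlap(map_a: FixationProbabilityMap, map_b: FixationProbabilityMap) -> float:
    """Overlap of two fixation probability maps: 2*sum(min) / (sum A + sum B).

    Symmetric, in [0, 1], and exactly 1 for identical maps.
    """
    if map_a.grid.shape != map_b.grid.shape or not (
            np.array_equal(map_a.xs, map_b.xs) and np.array_equal(map_a.ys, map_b.ys)):
        raise ValueError("maps must share an identical grid")
    a, b = map_a.grid, map_b.grid
    return float(2.0 * np.minimum(a, b).sum() / (a.sum() + b.sum()))


def overlap_comparison(labeled: Sequence[LabeledFixation], scenes: dict,
                       categories: tuple[str, str, str] = ("first", "revisit",
                                                           "secondplus"),
                       **map_kwargs) -> pd.DataFrame:
    """Per-object overlaps between fixation-category position maps.

    For every object with at least one fixation in each category, builds
    the three per-category maps from the fixation offsets relative to
    the object center and computes the three pairwise overlaps; paired
    signed-rank tests with Cliff's delta across objects follow in the
    ``attrs['tests']`` table.  ``scenes`` maps trial_id -> scene.
    """
    offsets: dict[tuple[int, str], list[tuple[float, float]]] = {}
    for lf in labeled:
        if lf.category not in categories:
            continue
        scene = scenes[lf.trial_id]
        center = next((o[1], o[2]) for o in scene.objects if o[0] == lf.target)
        offsets.setdefault((lf.target, lf.category), []).append(
            (lf.x - center[0], lf.y - center[1]))
    objects = sorted({k[0] for k in offsets})
    rows = []
    for obj in objects:
        if not all((obj, c) in offsets for c in categories):
            warnings.warn(f"object {obj} missing a category; excluded from overlap")
            continue
        maps = {c: build_probability_map(offsets[(obj, c)], **map_kwargs)
                for c in categories}
        row = {"object_id": obj}
        for i, a in enumerate(categories):
            for b in categories[i + 1:]:
                row[f"{a}_vs_{b}"] = overlap(maps[a], maps[b])
        rows.append(row)
    df = pd.DataFrame(rows)
    tests = []
    if len(df) >= 2:
        cols = [c for c in df.columns if c != "object_id"]
        for i, ca in enumerate(cols):
            for cb in cols[i + 1:]:
                d = df[ca] - df[cb]
                if np.allclose(d, 0):
                    p = 1.0
                else:
                    p = float(stats.wilcoxon(df[ca], df[cb],
                                             zero_method="zsplit").pvalue)
                tests.append({"pair": f"{ca} vs {cb}", "p": p,
                              "cliffs_delta": cliffs_delta(df[ca], df[cb])})
    df.attrs["tests"] = pd.DataFrame(tests)
    return df
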