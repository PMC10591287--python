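"""Object-identity decoding from simultaneously recorded populations.

Population spike-count vectors from single fixations are classified by
object identity with a linear discriminant, separately for three
fixation-order categories: first fixations, mix2-3 (second and third
fixations of an object, pooled), and mix4-6.  Sample counts are
equalized across categories, scores come from stratified 10-fold
cross-validation averaged over 10 random equalized draws, and a chance
level is estimated identically with object labels permuted within each
category.  Reported scores are chance-subtracted per session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .population_metrics import cliffs_delta

__all__ = [
    "MIX_GROUPS",
    "DiscriminationDataset",
    "DiscriminationResult",
    "build_dataset",
    "run_lda",
    "compare_categories",
]

MIN_UNITS = 5
MIN_OBJECTS = 10          # sessions need more than this many fixated objects
MIN_FIX_PER_CATEGORY = 10

MIX_GROUPS: dict[str, tuple[int, ...]] = {
    "first": (1,),
    "mix2-3": (2, 3),
    "mix4-6": (4, 5, 6),  # orders beyond mix6 are excluded
}


@dataclass
class DiscriminationDataset:
    """Equalizable decoding samples per fixation-order category.

    ``samples[category]`` is (X, y): population rate vectors
    (n_fixations x n_units) and object labels.  Draws are equalized at
    run time; ``n_equalized`` is the common per-category sample count.
    """

    samples: dict[str, tuple[np.ndarray, np.ndarray]]
    unit_ids: list
    object_ids: list
    window: str
    session_id: object = None

    @property
    def n_equalized(self) -> int:
        return min(len(y) for _, y in self.samples.values())


def build_dataset(rate_table: pd.DataFrame, *, window: str = "FODR1",
                  session_id=None) -> DiscriminationDataset:
    """Assemble the decoding dataset for one session and window.

    Eligibility: at least 5 simultaneously recorded units and more than
    10 fixated objects, each with at least 10 fixations in every one of
    the three categories (first, mix2-3, mix4-6).  Violations raise with
    the failed criteria listed.
    """
    sub = rate_table[(rate_table["window"] == window)
                     & rate_table["mix_index"].notna()].copy()
    unit_ids = sorted(sub["unit_id"].unique())
    failures = []
    if len(unit_ids) < MIN_UNITS:
        failures.append(f"{len(unit_ids)} units < {MIN_UNITS}")
    sub["mix_group"] = sub["mix_index"].map(
        {k: g for g, ks in MIX_GROUPS.items() for k in ks})
    sub = sub[sub["mix_group"].notna()]
    # one population vector per fixation: pivot to (trial, fixation) x unit
    counts = (sub.drop_duplicates(["trial_id", "fixation_id", "unit_id"])
              .pivot_table(index=["trial_id", "fixation_id", "object_id",
                                  "mix_group"],
                           columns="unit_id", values="rate"))
    counts = counts.dropna()
    per_obj = (counts.reset_index()
               .groupby(["object_id", "mix_group"]).size().unstack(fill_value=0))
    ok_objects = [o for o in per_obj.index
                  if all(per_obj.loc[o].get(g, 0) >= MIN_FIX_PER_CATEGORY
                         for g in MIX_GROUPS)]
    if len(ok_objects) <= MIN_OBJECTS:
        failures.append(f"{len(ok_objects)} eligible objects <= {MIN_OBJECTS}")
    if failures:
        raise ValueError("session ineligible for discrimination: "
                         + "; ".join(failures))
    samples: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    idx = counts.index.to_frame(index=False)
    X_all = counts.to_numpy()
    for g in MIX_GROUPS:
        m = (idx["mix_group"] == g) & idx["object_id"].isin(ok_objects)
        samples[g] = (X_all[m.to_numpy()], idx.loc[m, "object_id"].to_numpy())
    return DiscriminationDataset(samples=samples, unit_ids=unit_ids,
                                 object_ids=ok_objects, window=window,
                                 session_id=session_id)


@dataclass
class DiscriminationResult:
    scores: dict[str, float]          # mean CV score per category
    chance: dict[str, float]          # mean label-permuted score
    chance_subtracted: dict[str, float] = field(default_factory=dict)
    window: str = ""
    session_id: object = None

    def __post_init__(self):
        if not self.chance_subtracted:
            self.chance_subtracted = {c: self.scores[c] - self.chance[c]
                                      for c in self.scores}


def _cv_score(X: np.ndarray, y: np.ndarray, n_folds: int,
              rng: np.random.Generator) -> float:
    classes, counts = np.unique(y, return_counts=True)
    folds = min(n_folds, int(counts.min()))
    if folds < n_folds:
        warnings.warn(f"reducing folds to {folds}: smallest class has "
                      f"{counts.min()} samples")
    if folds < 2:
        raise ValueError("cannot cross-validate: a class has < 2 samples")
    cv = StratifiedKFold(n_splits=folds, shuffle=True,
                         random_state=int(rng.integers(2 ** 31)))
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    pred = cross_val_predict(clf, X, y, cv=cv)
    return float(np.mean(pred == y))


def run_lda(dataset: DiscriminationDataset, n_repeats: int = 10,
            n_folds: int = 10,
            rng: np.random.Generator | int | None = None) -> DiscriminationResult:
    """Equalized, repeated, cross-validated linear-discriminant decoding.

    Per repeat: a fresh equalized draw (without replacement, the same
    sample count per category), stratified ``n_folds``-fold CV with a
    shrinkage-regularized linear discriminant, score = proportion of
    fixations whose object is predicted correctly.  Chance scores use an
    identical procedure with the object labels permuted within the
    category.  Scores and chance levels are means over repeats.
    """
    rng = np.random.default_rng(rng)
    n = dataset.n_equalized
    scores = {c: [] for c in dataset.samples}
    chance = {c: [] for c in dataset.samples}
    for _ in range(n_repeats):
        for cat, (X, y) in dataset.samples.items():
            take = rng.choice(len(y), size=n, replace=False)
            Xs, ys = X[take], y[take]
            scores[cat].append(_cv_score(Xs, ys, n_folds, rng))
            chance[cat].append(_cv_score(Xs, rng.permutation(ys), n_folds, rng))
    return DiscriminationResult(
        scores={c: float(np.mean(v)) for c, v in scores.items()},
        chance={c: float(np.mean(v)) for c, v in chance.items()},
        window=dataset.window, session_id=dataset.session_id)


def compare_categories(results: list[DiscriminationResult],
                       baseline: str = "first") -> pd.DataFrame:
    """Paired signed-rank comparison of chance-subtracted scores across sessions.

    One row per (window, category vs baseline); with a single session
    only descriptive output (no p-value) is produced.
    """
    rows = []
    frames = pd.DataFrame([
        {"session": r.session_id, "window": r.window, "category": c,
         "score": r.chance_subtracted[c]}
        for r in results for c in r.chance_subtracted])
    for window, wgrp in frames.groupby("window"):
        wide = wgrp.pivot_table(index="session", columns="category",
                                values="score")
        for cat in wide.columns:
            if cat == baseline:
                continue
            paired = wide[[baseline, cat]].dropna()
            row = {"window": window, "comparison": f"{baseline} vs {cat}",
                   "n_sessions": len(paired),
                   "mean_diff": float((paired[cat] - paired[baseline]).mean())
                   if len(paired) else np.nan,
                   "p": np.nan, "cliffs_delta": np.nan}
            if len(paired) >= 2:
                d = (paired[cat] - paired[baseline]).to_numpy()
                row["p"] = 1.0 if np.allclose(d, 0) else float(
                    stats.wilcoxon(paired[cat], paired[baseline],
                                   zero_method="zsplit").pvalue)
                row["cliffs_delta"] = cliffs_delta(paired[cat], paired[baseline])
            rows.append(row)
    return pd.DataFrame(rows)
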