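"""Population-level response metrics.

Four measures of how a neural population represents a set of objects:

* lifetime sparseness ``S_life`` of a single neuron's mean rates across
  objects (0 = dense/uniform, 1 = responds to a single object);
* cosine similarity between per-object population response vectors,
  estimated by repeated random draws of single-fixation counts from
  response pools;
* area under the normalized cumulative singular-value curve of the
  object x unit rate matrix (0.5 = uniform spectrum, 1 = rank one);
* Cliff's delta nonparametric effect size.

All rates are nonnegative, so cosine similarity lies in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "sparseness",
    "cosine_similarity",
    "ResponsePool",
    "SimilarityResult",
    "resampled_similarity",
    "SVDResult",
    "svd_auc",
    "cliffs_delta",
    "category_contrast",
]

MIN_SAMPLES_PER_CATEGORY = 10
MIN_UNITS = 5


def sparseness(rates: Sequence[float]) -> float:
    """Normalized lifetime sparseness of a rate vector across N objects.

    S_life = (1 - a) / (1 - 1/N)  with  a = ((sum r_i)/N)^2 / (sum r_i^2/N).

    Returns NaN (with a warning) for an all-zero vector, for which the
    measure is undefined.
    """
    r = np.asarray(rates, dtype=float)
    if r.ndim != 1 or len(r) < 2:
        raise ValueError("need a 1-D vector of at least 2 rates")
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    n = len(r)
    if r.max() == 0:
        warnings.warn("all-zero rate vector: sparseness undefined")
        return float("nan")
    r = r / r.max()  # scale-invariant; guards against under/overflow
    a = (np.sum(r) / n) ** 2 / (np.sum(r ** 2) / n)
    return float((1.0 - a) / (1.0 - 1.0 / n))


def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """cos of the angle between two population response vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        warnings.warn("zero vector in cosine similarity")
        return float("nan")
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class ResponsePool:
    """Single-fixation responses pooled per (unit, object, category, window).

    ``samples[(unit, object, category, window)]`` is the list of
    single-fixation rates (or counts) from which population vectors are
    resampled.  Objects enter the similarity analysis only when every
    compared category holds at least ``MIN_SAMPLES_PER_CATEGORY`` samples
    for a unit, and at least ``MIN_UNITS`` such units exist.
    """

    samples: dict[tuple, list[float]]

    @classmethod
    def from_rate_table(cls, table: pd.DataFrame,
                        category_col: str = "category") -> "ResponsePool":
        pools: dict[tuple, list[float]] = {}
        for key, grp in table.groupby(["unit_id", "object_id", category_col,
                                       "window"]):
            pools[tuple(key)] = grp["rate"].tolist()
        return cls(pools)

    def categories(self) -> list:
        return sorted({k[2] for k in self.samples})

    def eligible_units(self, obj, categories: Sequence, window) -> list:
        """Units holding >= MIN_SAMPLES_PER_CATEGORY samples of obj in every category."""
        units = {k[0] for k in self.samples if k[1] == obj and k[3] == window}
        out = []
        for u in sorted(units):
            if all(len(self.samples.get((u, obj, c, window), []))
                   >= MIN_SAMPLES_PER_CATEGORY for c in categories):
                out.append(u)
        return out


@dataclass(frozen=True)
class SimilarityResult:
    object_a: object
    object_b: object
    category: object
    window: object
    similarity: float  # mean over resamples
    n_resamples: int
    n_units: int


def resampled_similarity(pool: ResponsePool, category, window,
                         *, all_categories: Sequence | None = None,
                         n_resamples: int = 100,
                         rng: np.random.Generator | int | None = None,
                         ) -> list[SimilarityResult]:
    """Mean cosine similarity per object pair from resampled population vectors.

    For each resample, one single-fixation rate is drawn (with
    replacement) per (unit, object) from the pool for the requested
    category; the cosine similarity of the two resulting population
    vectors is averaged over ``n_resamples`` draws.  Only units with at
    least 10 samples for *every* category (so the same units back each
    category's estimate) and object pairs with at least 5 common units
    are used.
    """
    rng = np.random.default_rng(rng)
    cats = list(all_categories) if all_categories is not None else pool.categories()
    objs = sorted({k[1] for k in pool.samples if k[3] == window})
    unit_sets = {o: set(pool.eligible_units(o, cats, window)) for o in objs}
    results: list[SimilarityResult] = []
    for i, oa in enumerate(objs):
        for ob in objs[i + 1:]:
            units = sorted(unit_sets[oa] & unit_sets[ob])
            if len(units) < MIN_UNITS:
                continue
            # draw matrices (n_units x n_resamples): one sample per
            # (unit, object) per resample, with replacement
            A = np.stack([
                np.asarray(pool.samples[(u, oa, category, window)])[
                    rng.integers(len(pool.samples[(u, oa, category, window)]),
                                 size=n_resamples)]
                for u in units])
            B = np.stack([
                np.asarray(pool.samples[(u, ob, category, window)])[
                    rng.integers(len(pool.samples[(u, ob, category, window)]),
                                 size=n_resamples)]
                for u in units])
            na = np.linalg.norm(A, axis=0)
            nb = np.linalg.norm(B, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sims = np.einsum("ur,ur->r", A, B) / (na * nb)
            results.append(SimilarityResult(oa, ob, category, window,
                                            float(np.nanmean(sims)),
                                            n_resamples, len(units)))
    if not results:
        warnings.warn("no eligible object pair for resampled similarity")
    return results


@dataclass(frozen=True)
class SVDResult:
    singular_values: np.ndarray  # descending
    cumulative: np.ndarray       # normalized, nondecreasing, ends at 1
    auc: float
    object_profiles: np.ndarray   # left factors, one column per component
    unit_profiles: np.ndarray     # right factors


def svd_auc(R: np.ndarray, *, check_eligibility: bool = False) -> SVDResult:
    """Area under the normalized cumulative singular-value curve of R.

    Singular values are normalized to sum 1 and accumulated; the AUC is
    the rectangle-rule mean of the cumulative curve sampled at
    k = 1..K.  A uniform spectrum gives (K+1)/(2K) -> 0.5 for large K;
    a rank-one matrix gives exactly 1.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2:
        raise ValueError("R must be a 2-D object x unit matrix")
    if check_eligibility and (R.shape[1] < MIN_UNITS or R.shape[0] <= 10):
        raise ValueError(
            f"session ineligible: needs >= {MIN_UNITS} units and > 10 objects, "
            f"got {R.shape[1]} units, {R.shape[0]} objects")
    u, d, vt = np.linalg.svd(R, full_matrices=False)
    total = d.sum()
    if total == 0:
        raise ValueError("rank-0 matrix: singular values all zero")
    cum = np.cumsum(d / total)
    return SVDResult(singular_values=d, cumulative=cum, auc=float(cum.mean()),
                     object_profiles=u, unit_profiles=vt.T)


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta: P(x > y) - P(x < y) over all sample pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    diff = x[:, None] - y[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (len(x) * len(y)))


_TESTS = {
    "signed-rank": lambda a, b: stats.wilcoxon(a, b, zero_method="zsplit"),
    "ks": lambda a, b: stats.ks_2samp(a, b),
    "mann-whitney": lambda a, b: stats.mannwhitneyu(a, b, alternative="two-sided"),
}


def category_contrast(values: pd.DataFrame, *, baseline: str = "first",
                      test: str = "signed-rank",
                      value_col: str = "value",
                      category_col: str = "category",
                      item_col: str = "item") -> pd.DataFrame:
    """Later-minus-baseline paired differences of a metric per item.

    ``values`` holds one metric value per (item, category); items missing
    either member of a comparison are dropped.  Returns one row per
    non-baseline category with the median difference, the chosen test's
    p-value on the paired values, and Cliff's delta.
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}")
    wide = values.pivot_table(index=item_col, columns=category_col,
                              values=value_col, aggfunc="mean")
    if baseline not in wide.columns:
        raise ValueError(f"baseline category {baseline!r} absent")
    rows = []
    for cat in wide.columns:
        if cat == baseline:
            continue
        paired = wide[[baseline, cat]].dropna()
        n = len(paired)
        diffs = (paired[cat] - paired[baseline]).to_numpy()
        row = {"category": cat, "n": n,
               "median_diff": float(np.median(diffs)) if n else np.nan,
               "p": np.nan, "cliffs_delta": np.nan, "flag": ""}
        if n < 2:
            row["flag"] = "insufficient-pairs"
        elif np.allclose(diffs, 0) and test == "signed-rank":
            row["p"] = 1.0
            row["cliffs_delta"] = 0.0
        else:
            a = paired[cat].to_numpy()
            b = paired[baseline].to_numpy()
            res = _TESTS[test](a, b)
            row["p"] = float(res.pvalue)
            row["cliffs_delta"] = cliffs_delta(a, b)
        rows.append(row)
    return pd.DataFrame(rows)
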