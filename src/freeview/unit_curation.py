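"""Spike-train postprocessing for sorted units.

Three curation steps applied to the waveform snippets of an upstream
sorter's units:

1. extraction/alignment — high-pass filter at 500 Hz (4th-order
   zero-phase Butterworth), cubic up-sampling to 200 kHz, and circular
   alignment of waveform minima to a fixed sample index;
2. re-clustering — PCA to three components, Gaussian-mixture
   re-clustering into at most three clusters (component count by BIC),
   and rejection of clusters whose interspike-interval refractory
   violation rate (ISIs < 1.2 ms) exceeds 0.1%;
3. merging — pairs of clusters whose mean waveforms correlate with
   R^2 > 0.95 (and positively: polarity-inverted shapes are distinct
   units) are merged transitively, with every pair's R^2 recorded in an
   audit log; merges with 0.95 < R^2 <= 0.97 are flagged for review.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

__all__ = [
    "WaveformSet",
    "UnitCluster",
    "extract_and_align",
    "recluster",
    "isi_violation_rate",
    "merge_clusters",
]

logger = logging.getLogger(__name__)

REFRACTORY_S = 1.2e-3
MAX_VIOLATION_RATE = 1e-3
MERGE_R2 = 0.95
REVIEW_R2 = 0.97
TARGET_RATE = 200_000.0


@dataclass
class WaveformSet:
    """Aligned spike waveform snippets (n_spikes x n_samples, uV)."""

    snippets: np.ndarray
    sample_rate: float
    spike_times: np.ndarray

    def __post_init__(self):
        self.snippets = np.asarray(self.snippets, dtype=float)
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if len(self.snippets) != len(self.spike_times):
            raise ValueError("one snippet per spike time required")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike times must be sorted")


@dataclass
class UnitCluster:
    members: np.ndarray  # indices into the WaveformSet
    mean_waveform: np.ndarray
    isi_violation_rate: float
    accepted: bool
    flags: list = field(default_factory=list)


def extract_and_align(snippets: np.ndarray, sample_rate: float,
                      spike_times: np.ndarray | None = None,
                      target_rate: float = TARGET_RATE,
                      highpass_hz: float = 500.0) -> WaveformSet:
    """Filter, up-sample, and minimum-align raw waveform snippets.

    Snippets whose post-filter minimum falls on the first or last sample
    cannot be aligned reliably and are dropped with a log entry.
    Alignment is a circular shift placing every minimum at the center
    sample of the up-sampled snippet.
    """
    snippets = np.atleast_2d(np.asarray(snippets, dtype=float))
    n_spikes, n_samp = snippets.shape
    if spike_times is None:
        spike_times = np.arange(n_spikes, dtype=float)
    if n_samp < 5:
        raise ValueError("snippets too short to align")
    sos = butter(4, highpass_hz, btype="highpass", fs=sample_rate, output="sos")
    filtered = sosfiltfilt(sos, snippets, axis=1)
    up = int(round(n_samp * target_rate / sample_rate))
    t_old = np.arange(n_samp) / sample_rate
    t_new = np.arange(up) * (t_old[-1] / (up - 1))
    resampled = CubicSpline(t_old, filtered, axis=1)(t_new)
    center = up // 2
    keep, aligned, times = [], [], []
    for i, w in enumerate(resampled):
        k = int(np.argmin(w))
        if k == 0 or k == up - 1:
            logger.info("snippet %d dropped: minimum at edge", i)
            continue
        aligned.append(np.roll(w, center - k))
        keep.append(i)
        times.append(spike_times[i])
    if not aligned:
        raise ValueError("no alignable snippets (all minima at edges)")
    return WaveformSet(snippets=np.array(aligned), sample_rate=target_rate,
                       spike_times=np.array(times))


def isi_violation_rate(spike_times, refractory: float = REFRACTORY_S) -> float:
    """Fraction of interspike intervals strictly below the refractory period."""
    t = np.asarray(spike_times, dtype=float)
    if len(t) < 2:
        warnings.warn("fewer than 2 spikes: violation rate defaults to 0")
        return 0.0
    isi = np.diff(np.sort(t))
    return float(np.mean(isi < refractory))


def recluster(waveforms: WaveformSet, max_clusters: int = 3,
              rng_seed: int = 0) -> list[UnitCluster]:
    """PCA + Gaussian-mixture re-clustering of one unit's waveforms.

    Waveforms are projected onto the first three principal components
    and fitted with Gaussian mixtures of 1..max_clusters components; the
    component count is chosen by BIC.  Each cluster's spike train is
    screened for refractory violations; clusters above the 0.1%
    violation threshold are kept but marked not accepted.
    """
    X = waveforms.snippets
    if len(X) < 10:
        raise ValueError("need at least 10 spikes to recluster")
    n_pc = min(3, X.shape[1], len(X))
    Z = PCA(n_components=n_pc, random_state=rng_seed).fit_transform(X)
    best_labels, best_bic = np.zeros(len(X), dtype=int), np.inf
    for k in range(1, max_clusters + 1):
        try:
            gm = GaussianMixture(n_components=k, random_state=rng_seed,
                                 n_init=3, reg_covar=1e-6).fit(Z)
        except ValueError:
            logger.warning("GMM with %d components failed; skipping", k)
            continue
        bic = gm.bic(Z)
        if bic < best_bic:
            best_bic, best_labels = bic, gm.predict(Z)
    clusters = []
    for lab in np.unique(best_labels):
        members = np.flatnonzero(best_labels == lab)
        viol = isi_violation_rate(waveforms.spike_times[members])
        clusters.append(UnitCluster(
            members=members, mean_waveform=X[members].mean(axis=0),
            isi_violation_rate=viol, accepted=viol <= MAX_VIOLATION_RATE))
    return clusters


def _waveform_r2(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(r, r^2) Pearson correlation of two mean waveforms at zero lag."""
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0, 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return r, r * r


def merge_clusters(clusters: list[UnitCluster], waveforms: WaveformSet,
                   r2_thresh: float = MERGE_R2,
                   ) -> tuple[list[UnitCluster], list[dict]]:
    """Merge clusters whose mean waveforms match with R^2 above threshold.

    R^2 is the squared Pearson correlation at zero lag; a merge
    additionally requires r > 0 so polarity-inverted shapes stay
    separate.  The merge relation is closed transitively, so the result
    is independent of cluster ordering.  Returns the merged clusters and
    an audit log with one entry per pair.
    """
    if not clusters:
        raise ValueError("need at least one cluster")
    n = len(clusters)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    audit = []
    for i in range(n):
        for j in range(i + 1, n):
            r, r2 = _waveform_r2(clusters[i].mean_waveform,
                                 clusters[j].mean_waveform)
            merged = r > 0 and r2 > r2_thresh
            audit.append({"pair": (i, j), "r": r, "r2": r2, "merged": merged,
                          "review": merged and r2 <= REVIEW_R2})
            if merged:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members_idx in sorted(groups.values(), key=min):
        members = np.sort(np.concatenate(
            [clusters[i].members for i in members_idx]))
        viol = isi_violation_rate(waveforms.spike_times[members])
        flags = ["review-merge"] if any(
            e["review"] and set(e["pair"]) <= set(members_idx)
            for e in audit) else []
        out.append(UnitCluster(
            members=members,
            mean_waveform=waveforms.snippets[members].mean(axis=0),
            isi_violation_rate=viol, accepted=viol <= MAX_VIOLATION_RATE,
            flags=flags))
    return out, audit
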