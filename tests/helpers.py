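"""Independent brute-force oracles used by the test suite.

These re-derive expected results from first principles, by a different
route than the library implementation, so they can serve as references.
"""

import numpy as np


def brute_force_saccade_scan(trace, kin, params):
    """Sample-by-sample threshold scan for saccade segments.

    Walks the trace, opening a segment whenever the speed rises above
    the velocity threshold and closing it when it falls back; keeps the
    segment if its peak acceleration crosses the acceleration gate and
    it survives the artifact rules.  Returns (i0, i1) sample-index
    pairs (i1 = one past the last super-threshold sample).
    """
    dt = 1.0 / trace.sample_rate
    segs = []
    inside = False
    for i in range(len(trace)):
        fast = np.isfinite(kin.speed[i]) and kin.speed[i] > params.vel_thresh
        if fast and not inside:
            inside, start = True, i
        elif not fast and inside:
            inside = False
            segs.append((start, i))
    if inside:
        segs.append((start, len(trace)))
    keep = []
    for i0, i1 in segs:
        pa = np.nanmax(kin.accel_mag[i0:i1])
        pv = np.nanmax(kin.speed[i0:i1])
        dur = (i1 - 1 - i0) * dt
        shift = np.hypot(trace.x[i1 - 1] - trace.x[i0],
                         trace.y[i1 - 1] - trace.y[i0])
        if (pa > params.acc_thresh and pv <= params.max_peak_vel
                and pa <= params.max_peak_acc
                and params.min_dur <= dur <= params.max_dur
                and shift >= params.min_shift):
            keep.append((i0, i1))
    return keep


def brute_force_categorize(targets, background=-1):
    """Re-derive fixation order categories by explicit per-object history.

    Keeps, per object, the full list of fixation indices so far, and
    decides each category from that history and the previous fixation's
    target, independent of the implementation's running counters.
    """
    history = {}
    revisits = {}
    out = []
    for i, tgt in enumerate(targets):
        prev = targets[i - 1] if i > 0 else None
        if tgt == background:
            out.append(("background", "none", None))
            continue
        seen = history.get(tgt, [])
        if not seen:
            cat, sub = "first", "none"
        elif prev == tgt:
            cat = "secondplus"
            # anchor = most recent non-consecutive fixation on this object
            # (a first or revisit); chain position counts from it
            j = i - 1
            while j >= 0 and targets[j] == tgt:
                j -= 1
            chain = i - (j + 1)  # fixations since the anchor
            sub = {1: "second1", 2: "second2"}.get(chain, "other")
        else:
            cat = "revisit"
            revisits[tgt] = revisits.get(tgt, 0) + 1
            sub = {1: "revisit1", 2: "revisit2"}.get(revisits[tgt], "other")
        history.setdefault(tgt, []).append(i)
        out.append((cat, sub, len(history[tgt])))
    return out


def minjerk_trace(amplitude, sample_rate=1000.0, pre=0.5, post=0.5,
                  duration=None, x0=0.0):
    """A noiseless trace with one horizontal minimum-jerk saccade.

    Returns (t, x, y, t_on, t_off): the saccade runs from t_on to t_off
    with the given amplitude; duration defaults to the main-sequence
    21 + 2.2*A ms.
    """
    if duration is None:
        duration = 0.021 + 0.0022 * amplitude
    total = pre + duration + post
    n = int(round(total * sample_rate))
    t = np.arange(n) / sample_rate
    x = np.full(n, float(x0))
    tau = np.clip((t - pre) / duration, 0, 1)
    s = 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5
    x = x0 + amplitude * s
    return t, x, np.zeros(n), pre, pre + duration


def minjerk_speed(amplitude, duration, t, t_on):
    """Analytic speed profile of a minimum-jerk saccade, deg/s."""
    tau = (t - t_on) / duration
    v = np.zeros_like(t)
    m = (tau >= 0) & (tau <= 1)
    v[m] = amplitude / duration * 30 * tau[m] ** 2 * (1 - tau[m]) ** 2
    return v
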