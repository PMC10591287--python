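"""Synthetic free-viewing sessions with known ground truth.

Emulates the study conditions of a macaque free-viewing experiment:
5-object scenes on a gray background (objects ~2 deg across, centers
more than 4 deg apart, drawn from a 20-object pool), 5-s trials in
which gaze alternates between fixation plateaus and minimum-jerk
saccades, and object-tuned Poisson spiking whose gain is reduced on
later fixations of the same object (repetition suppression).

Because every generated quantity carries its ground truth (gaze events
with target objects, tuning curves, order-dependent gain), the entire
downstream pipeline — event detection, fixation categorization, rate
analysis, population metrics, decoding — can be validated without any
recorded data.

The saccade kinematic model is a minimum-jerk position profile with
duration 21 + 2.2 * amplitude(deg) ms (a standard main-sequence
approximation); fixation durations are log-normal with a 200-ms median;
fixational jitter is Gaussian with SD 0.05 deg.  Traces are sampled at
1 kHz by default (configurable up to 20 kHz) — the detector thresholds
act on deg/s and deg/s^2 and are rate-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .eye_events import EyeTrace
from .fixation_context import BACKGROUND, categorize_orders

__all__ = [
    "SceneSpec",
    "GazeEvent",
    "GazeGroundTruth",
    "TuningSpec",
    "ModulationSpec",
    "draw_tuning_reshape",
    "SessionBundle",
    "generate_scenes",
    "generate_gaze",
    "generate_spikes",
    "generate_session",
    "save_session",
    "load_session",
]


# ---------------------------------------------------------------- scenes

@dataclass(frozen=True)
class SceneSpec:
    """One stimulus image: object ids with centers, on a gray background."""

    scene_id: int
    objects: tuple  # of (object_id, center_x, center_y)
    image_extent: tuple[float, float] = (38.0, 28.0)


def generate_scenes(n_scenes: int = 60, n_objects_pool: int = 20,
                    n_per_scene: int = 5,
                    extent: tuple[float, float] = (38.0, 28.0),
                    min_dist: float = 4.0, margin: float = 1.5,
                    rng: np.random.Generator | int | None = None,
                    max_attempts: int = 5000) -> list[SceneSpec]:
    """Place ``n_per_scene`` objects from the pool at random, >min_dist apart.

    Rejection sampling per scene; raises if a valid placement cannot be
    found within ``max_attempts`` draws, naming the infeasible
    parameters.
    """
    rng = np.random.default_rng(rng)
    w, h = extent
    scenes = []
    for sid in range(n_scenes):
        ids = rng.choice(n_objects_pool, size=n_per_scene, replace=False)
        for attempt in range(max_attempts):
            xy = np.column_stack([
                rng.uniform(margin - w / 2, w / 2 - margin, n_per_scene),
                rng.uniform(margin - h / 2, h / 2 - margin, n_per_scene)])
            d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
            if min_dist <= 0 or d[np.triu_indices(n_per_scene, 1)].min() > min_dist:
                break
        else:
            raise ValueError(
                f"could not place {n_per_scene} objects > {min_dist} deg apart "
                f"in a {w} x {h} deg extent after {max_attempts} attempts")
        scenes.append(SceneSpec(
            scene_id=sid,
            objects=tuple((int(i), float(x), float(y))
                          for i, (x, y) in zip(ids, xy))))
    return scenes


# ---------------------------------------------------------------- gaze

@dataclass(frozen=True)
class GazeEvent:
    kind: str  # "fixation" | "saccade"
    t_on: float
    t_off: float
    x_land: float
    y_land: float
    target_object: int  # object id, or BACKGROUND


@dataclass(frozen=True)
class GazeGroundTruth:
    """Alternating fixation/saccade events tiling one trial."""

    events: tuple


def _minjerk_duration(amplitude: float) -> float:
    """Main-sequence saccade duration, seconds: 21 ms + 2.2 ms/deg."""
    return 0.021 + 0.0022 * amplitude


def _minjerk_profile(tau: np.ndarray) -> np.ndarray:
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def generate_gaze(scene: SceneSpec, trial_dur: float = 5.0,
                  fix_dur_median: float = 0.2, fix_dur_sigma: float = 0.4,
                  revisit_prob: float = 0.25, consec_prob: float = 0.35,
                  background_prob: float = 0.04,
                  sample_rate: float = 1000.0, noise_sd: float = 0.05,
                  land_sd: float = 0.4,
                  rng: np.random.Generator | int | None = None,
                  ) -> tuple[EyeTrace, GazeGroundTruth]:
    """Simulate one trial's gaze trace with its ground-truth event list.

    After each fixation the next target is the same object with
    probability ``consec_prob`` (a small within-object shift of
    0.8-1.4 deg), an already-visited other object with ``revisit_prob``,
    the background with ``background_prob``, and otherwise an unvisited
    object.  Landing scatter around object centers is Gaussian
    (``land_sd``), truncated at 1.2 deg so object fixations stay within
    the 1.5-deg assignment radius.
    """
    if trial_dur <= 0 or sample_rate <= 0:
        raise ValueError("trial_dur and sample_rate must be > 0")
    if fix_dur_median <= 0 or fix_dur_sigma < 0:
        raise ValueError("degenerate fixation-duration distribution")
    rng = np.random.default_rng(rng)
    centers = {oid: np.array([x, y]) for oid, x, y in scene.objects}
    obj_ids = list(centers)

    def land_near(oid) -> np.ndarray:
        while True:
            off = rng.normal(0, land_sd, 2)
            if np.hypot(*off) <= 1.2:
                return centers[oid] + off

    def land_background() -> np.ndarray:
        w, h = scene.image_extent
        for _ in range(200):
            p = np.array([rng.uniform(-w / 2 + 1, w / 2 - 1),
                          rng.uniform(-h / 2 + 1, h / 2 - 1)])
            if all(np.linalg.norm(p - c) > 2.0 for c in centers.values()):
                return p
        return p

    # event plan: start fixating the background near screen center
    t = 0.0
    pos = np.array([rng.uniform(-2, 2), rng.uniform(-2, 2)])
    if any(np.linalg.norm(pos - c) <= 2.0 for c in centers.values()):
        pos = land_background()
    target = BACKGROUND
    visited: set[int] = set()
    events: list[GazeEvent] = []
    while t < trial_dur:
        dur = float(rng.lognormal(np.log(fix_dur_median), fix_dur_sigma))
        dur = max(dur, 0.08)
        t_off = min(t + dur, trial_dur)
        events.append(GazeEvent("fixation", t, t_off, float(pos[0]),
                                float(pos[1]), target))
        if target != BACKGROUND:
            visited.add(target)
        t = t_off
        if t >= trial_dur:
            break
        # choose the next target among the applicable moves, with weights
        # renormalized over what is actually available from here
        fresh = [o for o in obj_ids if o not in visited]
        other_visited = sorted(visited - {target})
        moves, weights = [], []
        if target != BACKGROUND:
            moves.append("consec")
            weights.append(consec_prob)
        if other_visited:
            moves.append("revisit")
            weights.append(revisit_prob)
        moves.append("background")
        weights.append(background_prob)
        if fresh or other_visited:
            moves.append("new")
            weights.append(max(1.0 - consec_prob - revisit_prob
                               - background_prob, 0.0))
        w = np.asarray(weights, dtype=float)
        if w.sum() == 0:
            choice = "new" if "new" in moves else moves[0]
        else:
            choice = moves[rng.choice(len(moves), p=w / w.sum())]
        if choice == "consec":
            nxt = target
        elif choice == "revisit":
            nxt = int(rng.choice(other_visited))
        elif choice == "background":
            nxt = BACKGROUND
        else:
            pool = fresh if fresh else [o for o in obj_ids if o != target]
            nxt = int(rng.choice(pool))
        if nxt == BACKGROUND:
            new_pos = land_background()
        elif nxt == target:
            # within-object shift: 0.8-1.4 deg, staying near the center
            for _ in range(200):
                cand = land_near(nxt)
                if 0.8 <= np.linalg.norm(cand - pos) <= 1.4:
                    new_pos = cand
                    break
            else:
                off = pos - centers[nxt]
                new_pos = centers[nxt] - off  # diametric fallback
        else:
            new_pos = land_near(nxt)
        amp = float(np.linalg.norm(new_pos - pos))
        sdur = _minjerk_duration(amp)
        t_off = min(t + sdur, trial_dur)
        events.append(GazeEvent("saccade", t, t_off, float(new_pos[0]),
                                float(new_pos[1]), nxt))
        pos, target, t = new_pos, nxt, t_off

    # render the trace
    n = int(round(trial_dur * sample_rate))
    tt = np.arange(n) / sample_rate
    x = np.empty(n)
    y = np.empty(n)
    for k, ev in enumerate(events):
        i0 = int(np.round(ev.t_on * sample_rate))
        i1 = min(int(np.round(ev.t_off * sample_rate)), n)
        if i1 <= i0:
            continue
        if ev.kind == "fixation":
            x[i0:i1] = ev.x_land
            y[i0:i1] = ev.y_land
        else:
            tau = (tt[i0:i1] - ev.t_on) / max(ev.t_off - ev.t_on, 1e-9)
            s = _minjerk_profile(np.clip(tau, 0, 1))
            prev = events[k - 1]
            x[i0:i1] = prev.x_land + (ev.x_land - prev.x_land) * s
            y[i0:i1] = prev.y_land + (ev.y_land - prev.y_land) * s
    if noise_sd > 0:
        # fixational jitter as one continuous, temporally smooth (drift-like)
        # process over the whole trial, so it adds no spurious high-frequency
        # kinematics and no steps at event boundaries
        from scipy.ndimage import gaussian_filter1d

        sigma = 0.01 * sample_rate  # 10-ms correlation time
        for arr in (x, y):
            w = gaussian_filter1d(rng.normal(0, 1, n + 80), sigma,
                                  mode="reflect")[40:-40]
            sd = w.std()
            if sd > 0:
                arr += w * (noise_sd / sd)
    trace = EyeTrace(t=tt, x=x, y=y, sample_rate=sample_rate)
    return trace, GazeGroundTruth(events=tuple(events))


# ---------------------------------------------------------------- spikes

@dataclass(frozen=True)
class TuningSpec:
    """Object tuning of one unit: multiplicative gains on a base rate."""

    unit_id: int
    area: str  # V1 | V2 | IT
    base_rate: float
    object_gains: Mapping[int, float]
    latency: float = 0.1
    response_window: float = 0.05

    def __post_init__(self):
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if any(g < 0 for g in self.object_gains.values()):
            raise ValueError("object gains must be >= 0")


@dataclass(frozen=True)
class ModulationSpec:
    """Fixation-order-dependent gain: order_gain[k] multiplies the response
    on the k-th fixation of an object (order_gain[1] must be 1; orders
    beyond the largest key reuse its value).  ``within_fixation_decay``
    additionally multiplies the later (second-epoch) part of the
    response.  ``per_object`` optionally overrides order_gain for
    specific objects; ``per_unit_object`` additionally scales the
    response of a given (unit, object) pair on later (order >= 2)
    fixations — this is the heterogeneous tuning-reshape mode, the only
    one that changes the *direction* of population vectors (a gain
    uniform across units rescales a vector without rotating it).
    """

    order_gain: Mapping[int, float] = field(default_factory=lambda: {1: 1.0})
    within_fixation_decay: float = 1.0
    per_object: Mapping[int, Mapping[int, float]] | None = None
    per_unit_object: Mapping[tuple[int, int], float] | None = None

    def __post_init__(self):
        if self.order_gain.get(1, 1.0) != 1.0:
            raise ValueError("order_gain[1] must be 1")
        if any(not 0 < g <= 1 for g in self.order_gain.values()):
            raise ValueError("order gains must lie in (0, 1]")

    def gain(self, mix_order: int, object_id: int | None = None,
             unit_id: int | None = None) -> float:
        gains = self.order_gain
        if self.per_object and object_id in self.per_object:
            gains = self.per_object[object_id]
        g = gains.get(min(mix_order, max(gains)), 1.0) if gains else 1.0
        if (self.per_unit_object is not None and mix_order >= 2
                and unit_id is not None):
            g *= self.per_unit_object.get((unit_id, object_id), 1.0)
        return g


def draw_tuning_reshape(unit_ids: Sequence[int], object_ids: Sequence[int],
                        mean_gain: float = 0.8, sd: float = 0.5,
                        rng: np.random.Generator | int | None = None,
                        ) -> dict[tuple[int, int], float]:
    """Log-normal per-(unit, object) later-fixation gains with the given
    mean — heterogeneous repetition effects that rotate population
    vectors rather than merely shrinking them."""
    rng = np.random.default_rng(rng)
    out = {}
    for u in unit_ids:
        for o in object_ids:
            out[(u, o)] = float(
                mean_gain * rng.lognormal(-sd ** 2 / 2, sd))
    return out


def generate_spikes(units: Sequence[TuningSpec], modulation: ModulationSpec,
                    truth: GazeGroundTruth, scene: SceneSpec,
                    trial_dur: float = 5.0,
                    rng: np.random.Generator | int | None = None,
                    bin_width: float = 1e-3) -> list[np.ndarray]:
    """Inhomogeneous-Poisson spike trains for one trial.

    Each unit fires at ``base_rate`` except during the response epoch of
    each object fixation — (onset + latency, onset + latency +
    response_window) at rate base * object_gain * order_gain, followed
    by a same-length second epoch further scaled by
    ``within_fixation_decay``.  Rates are rendered on a 1-ms grid and
    spikes drawn per bin.
    """
    rng = np.random.default_rng(rng)
    scene_ids = {o[0] for o in scene.objects}
    fix_events = [e for e in truth.events if e.kind == "fixation"]
    targets = [e.target_object for e in fix_events]
    for tgt in targets:
        if tgt != BACKGROUND and tgt not in scene_ids:
            raise ValueError(f"truth references object {tgt} absent from scene")
    orders = categorize_orders(targets)
    n_bins = int(round(trial_dur / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    out = []
    for unit in units:
        rate = np.full(n_bins, unit.base_rate)
        for ev, (_, _, mix) in zip(fix_events, orders):
            if ev.target_object == BACKGROUND:
                continue
            g = (unit.base_rate * unit.object_gains.get(ev.target_object, 1.0)
                 * modulation.gain(mix, ev.target_object, unit.unit_id))
            e0 = ev.t_on + unit.latency
            for start, stop, f in (
                    (e0, e0 + unit.response_window, 1.0),
                    (e0 + unit.response_window, e0 + 2 * unit.response_window,
                     modulation.within_fixation_decay)):
                i0 = int(np.ceil(start / bin_width))
                i1 = min(int(np.ceil(stop / bin_width)), n_bins)
                if i1 > i0:
                    rate[i0:i1] = g * f
        counts = rng.poisson(rate * bin_width)
        idx = np.repeat(np.arange(n_bins), counts)
        times = edges[idx] + rng.uniform(0, bin_width, len(idx))
        out.append(np.sort(times))
    return out


# ---------------------------------------------------------------- session

@dataclass
class SessionBundle:
    """One synthetic session: scenes, per-trial traces and ground truth,
    per-unit spike times (per trial), and the generator parameters."""

    scenes: list[SceneSpec]
    trials: list[dict]  # {"trial_id", "scene_id", "trace", "truth"}
    units: list[TuningSpec]
    spikes: list[list[np.ndarray]]  # [trial][unit] -> spike times (trial clock)
    modulation: ModulationSpec
    seed: int
    params: dict = field(default_factory=dict)


def default_tuning(n_units: int = 50, area: str = "IT",
                   object_ids: Sequence[int] = range(20),
                   rng: np.random.Generator | int | None = None,
                   ) -> list[TuningSpec]:
    """Log-normal base rates (~8 Hz median) and log-normal object gains
    (sigma 1.0, emulating object-selective tuning).  Latencies follow the
    area: 40 ms for V1/V2, 100 ms for IT; the response epoch is 70 ms for
    V1/V2 and 50 ms for IT, matching the areas' response windows.
    """
    rng = np.random.default_rng(rng)
    latency, window = (0.04, 0.07) if area in ("V1", "V2") else (0.1, 0.05)
    units = []
    for i in range(n_units):
        gains = {int(o): float(rng.lognormal(0.0, 1.0)) for o in object_ids}
        units.append(TuningSpec(
            unit_id=i, area=area,
            base_rate=float(rng.lognormal(np.log(8.0), 0.5)),
            object_gains=gains, latency=latency, response_window=window))
    return units


def generate_session(seed: int = 0, n_scenes: int = 60, n_repeats: int = 3,
                     n_units: int = 50, area: str = "IT",
                     modulation: ModulationSpec | None = None,
                     trial_dur: float = 5.0, sample_rate: float = 1000.0,
                     **gaze_kwargs) -> SessionBundle:
    """Generate a complete synthetic session (deterministic in ``seed``)."""
    rng = np.random.default_rng(seed)
    modulation = modulation or ModulationSpec()
    scenes = generate_scenes(n_scenes=n_scenes, rng=rng)
    units = default_tuning(n_units=n_units, area=area, rng=rng)
    trials, spikes = [], []
    tid = 0
    for rep in range(n_repeats):
        order = rng.permutation(len(scenes))
        for k in order:
            scene = scenes[k]
            trace, truth = generate_gaze(scene, trial_dur=trial_dur,
                                         sample_rate=sample_rate, rng=rng,
                                         **gaze_kwargs)
            trials.append({"trial_id": tid, "scene_id": scene.scene_id,
                           "trace": trace, "truth": truth})
            spikes.append(generate_spikes(units, modulation, truth, scene,
                                          trial_dur=trial_dur, rng=rng))
            tid += 1
    return SessionBundle(scenes=scenes, trials=trials, units=units,
                         spikes=spikes, modulation=modulation, seed=seed,
                         params={"n_scenes": n_scenes, "n_repeats": n_repeats,
                                 "n_units": n_units, "area": area,
                                 "trial_dur": trial_dur,
                                 "sample_rate": sample_rate, **gaze_kwargs})


# ---------------------------------------------------------------- HDF5 I/O

def save_session(bundle: SessionBundle, path) -> None:
    """Serialize a SessionBundle to one HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["seed"] = bundle.seed
        meta = f.create_group("meta")
        for k, v in bundle.params.items():
            meta.attrs[k] = v
        sc = f.create_group("scenes")
        for s in bundle.scenes:
            g = sc.create_group(str(s.scene_id))
            g.create_dataset("objects", data=np.array(s.objects))
            g.attrs["image_extent"] = s.image_extent
        tr = f.create_group("trials")
        for trial in bundle.trials:
            g = tr.create_group(str(trial["trial_id"]))
            g.attrs["scene_id"] = trial["scene_id"]
            t = trial["trace"]
            g.create_dataset("trace", data=np.column_stack([t.t, t.x, t.y]))
            g.attrs["sample_rate"] = t.sample_rate
            ev = trial["truth"].events
            g.create_dataset("truth_num", data=np.array(
                [[e.t_on, e.t_off, e.x_land, e.y_land, e.target_object]
                 for e in ev]))
            g.create_dataset("truth_kind", data=np.array(
                [e.kind for e in ev], dtype="S8"))
        un = f.create_group("units")
        for j, u in enumerate(bundle.units):
            g = un.create_group(str(u.unit_id))
            g.attrs.update({"area": u.area, "base_rate": u.base_rate,
                            "latency": u.latency,
                            "response_window": u.response_window})
            gains = sorted(u.object_gains.items())
            g.create_dataset("object_gains", data=np.array(gains, dtype=float))
            for trial in bundle.trials:
                g.create_dataset(f"spikes/{trial['trial_id']}",
                                 data=bundle.spikes[trial["trial_id"]][j])


def load_session(path) -> SessionBundle:
    import h5py

    with h5py.File(path, "r") as f:
        scenes = []
        for sid in sorted(f["scenes"], key=int):
            g = f["scenes"][sid]
            objs = tuple((int(a), float(b), float(c))
                         for a, b, c in g["objects"][()])
            scenes.append(SceneSpec(scene_id=int(sid), objects=objs,
                                    image_extent=tuple(g.attrs["image_extent"])))
        units, unit_ids = [], sorted(f["units"], key=int)
        for uid in unit_ids:
            g = f["units"][uid]
            gains = {int(k): float(v) for k, v in g["object_gains"][()]}
            units.append(TuningSpec(unit_id=int(uid), area=g.attrs["area"],
                                    base_rate=float(g.attrs["base_rate"]),
                                    object_gains=gains,
                                    latency=float(g.attrs["latency"]),
                                    response_window=float(
                                        g.attrs["response_window"])))
        trials, spikes = [], []
        for tid in sorted(f["trials"], key=int):
            g = f["trials"][tid]
            arr = g["trace"][()]
            trace = EyeTrace(t=arr[:, 0], x=arr[:, 1], y=arr[:, 2],
                             sample_rate=float(g.attrs["sample_rate"]))
            kinds = [k.decode() for k in g["truth_kind"][()]]
            nums = g["truth_num"][()]
            events = tuple(GazeEvent(kind, *map(float, row[:4]), int(row[4]))
                           for kind, row in zip(kinds, nums))
            trials.append({"trial_id": int(tid), "scene_id": int(g.attrs["scene_id"]),
                           "trace": trace, "truth": GazeGroundTruth(events)})
            spikes.append([f["units"][uid][f"spikes/{tid}"][()]
                           for uid in unit_ids])
        params = dict(f["meta"].attrs)
        return SessionBundle(scenes=scenes, trials=trials, units=units,
                             spikes=spikes, modulation=ModulationSpec(),
                             seed=int(f.attrs["seed"]), params=params)
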