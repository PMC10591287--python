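import numpy as np
import pandas as pd
import pytest

import freeview as fv
from freeview.response_analysis import (DEFAULT_FODR, FODRWindows,
                                        build_rate_table, compute_pfth,
                                        determine_fodr,
                                        per_object_change_counts,
                                        rate_comparison_timecourse)


class TestPFTH:
    def test_empty_train_zero_pfth(self):
        p = compute_pfth(np.array([]), [0.0, 1.0, 2.0])
        assert np.all(p.rate == 0.0)
        assert p.n_fixations == 3

    def test_kernel_mass_conservation(self):
        """A single interior spike smooths to a bump integrating to one
        spike per fixation."""
        p = compute_pfth(np.array([0.05]), [0.0])
        assert p.rate.sum() * 1e-3 == pytest.approx(1.0, rel=1e-6)
        assert p.time_ms[np.argmax(p.rate)] == pytest.approx(50.0, abs=1.0)

    def test_poisson_flat_within_3se(self):
        """Homogeneous 20-Hz spiking over many fixations gives a PFTH
        within 3 SE of 20 spikes/s at every bin."""
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 1000.0, int(20 * 1000)))
        onsets = np.arange(500) * 2.0 + 0.5
        p = compute_pfth(spikes, onsets, window_ms=(-50.0, 150.0))
        # interior bins only: within ~3 kernel SDs of the window edges the
        # Gaussian smoothing leaks mass out of the window
        interior = (p.time_ms > -50 + 30) & (p.time_ms < 150 - 30)
        err = np.abs(p.rate - 20.0)[interior]
        assert np.all(err < 3.2 * np.maximum(p.sem[interior], 1e-9))


class TestRateComparisonTimecourse:
    @staticmethod
    def _pfths(n_units, shift, rng):
        out = {}
        for u in range(n_units):
            base = 20 + rng.normal(0, 1)
            t = np.arange(0, 200, 1.0) + 0.5
            first = np.full_like(t, base)
            later = np.full_like(t, base)
            later[(t > 40) & (t < 90)] -= shift * base
            out[u] = {
                "first": fv.response_analysis.PFTH(t, first, np.zeros_like(t), 10),
                "secondplus": fv.response_analysis.PFTH(t, later,
                                                        np.zeros_like(t), 10)}
        return out

    def test_identical_rates_no_significance(self):
        rng = np.random.default_rng(1)
        out = rate_comparison_timecourse(self._pfths(20, 0.0, rng),
                                         others=("secondplus",))
        assert not out["significant"].any()

    def test_injected_drop_found_in_window(self):
        rng = np.random.default_rng(2)
        out = rate_comparison_timecourse(self._pfths(50, 0.2, rng),
                                         others=("secondplus",))
        sig = out[out["significant"]]
        assert len(sig) > 0
        assert sig["time_ms"].between(40, 90).all()

    def test_two_units_cannot_reach_bonferroni(self):
        """With n = 2 units the smallest attainable signed-rank p is 0.5,
        so no bin survives Bonferroni at 0.01."""
        rng = np.random.default_rng(3)
        out = rate_comparison_timecourse(self._pfths(2, 0.5, rng),
                                         others=("secondplus",))
        assert not out["significant"].any()


def _fodr_units(rng, n_units=50, drop_windows=((40, 90), (110, 160)),
                drop=0.5, base=30.0, n_first=40, n_later=40):
    """Synthetic (spikes, first_onsets, later_onsets) with rate drops
    injected into the given post-onset windows for later fixations."""
    units = []
    for _ in range(n_units):
        first_on = np.arange(n_first) * 1.0
        later_on = n_first + np.arange(n_later) * 1.0
        spikes = []
        for on in first_on:
            t = rng.uniform(0, 0.2, rng.poisson(base * 0.2))
            spikes.append(on + t)
        for on in later_on:
            rate = np.full(200, base)
            for lo, hi in drop_windows:
                rate[int(lo):int(hi)] *= (1 - drop)
            counts = rng.poisson(rate * 1e-3)
            idx = np.repeat(np.arange(200), counts)
            spikes.append(on + idx * 1e-3 + rng.uniform(0, 1e-3, len(idx)))
        units.append((np.sort(np.concatenate(spikes)), first_on, later_on))
    return units


class TestDetermineFodr:
    def test_injected_peaks_recovered(self):
        """Drops injected at 40-90 and 110-160 ms are recovered as window
        centers within 10 ms of 65 and 135 ms."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            wins, curve = determine_fodr(_fodr_units(rng), area="V1")
            c1 = (wins.fodr1[0] + wins.fodr1[1]) / 2
            c2 = (wins.fodr2[0] + wins.fodr2[1]) / 2
            assert abs(c1 - 65.0) <= 10.0
            assert abs(c2 - 135.0) <= 10.0

    def test_unmodulated_falls_back_to_defaults(self):
        rng = np.random.default_rng(10)
        units = _fodr_units(rng, n_units=15, drop=0.0)
        wins, curve = determine_fodr(units, area="IT")
        # near the false-positive floor the curve yields the area defaults
        assert (wins.fodr1, wins.fodr2) == DEFAULT_FODR["IT"] or \
            curve["n_significant"].max() <= 3

    def test_area_defaults_printed_values(self):
        assert DEFAULT_FODR["IT"] == ((100.0, 150.0), (150.0, 200.0))
        assert DEFAULT_FODR["V1"] == ((40.0, 90.0), (110.0, 160.0))

    def test_too_few_units_error(self):
        with pytest.raises(ValueError):
            determine_fodr([], area="V1")

    def test_window_validation(self):
        with pytest.raises(ValueError):
            FODRWindows(area="IT", fodr1=(150, 200), fodr2=(100, 150))
        with pytest.raises(ValueError):
            FODRWindows(area="IT", fodr1=(-10, 40), fodr2=(100, 150))


class TestBuildRateTable:
    @staticmethod
    def _labeled(t_on, t_off=None, target=1, category="first", trial=0):
        return fv.fixation_context.LabeledFixation(
            t_on=t_on, t_off=t_off if t_off is not None else t_on + 0.3,
            x=0.0, y=0.0, trial_id=trial, target=target, category=category,
            sub_order="none", mix_index=1)

    def test_rate_arithmetic(self):
        wins = FODRWindows(area="IT", fodr1=(100, 150), fodr2=(150, 200))
        spikes = np.array([0.11, 0.12, 0.13, 0.14, 0.145])  # 5 in FODR1
        table = build_rate_table([[spikes]], [[self._labeled(0.0)]], wins)
        f1 = table[table["window"] == "FODR1"].iloc[0]
        assert f1["rate"] == pytest.approx(100.0)
        assert table[table["window"] == "FODR2"].iloc[0]["rate"] == 0.0

    def test_background_excluded_short_flagged(self):
        wins = FODRWindows(area="IT", fodr1=(100, 150), fodr2=(150, 200))
        fixes = [self._labeled(0.0, target=-1, category="background"),
                 self._labeled(1.0, t_off=1.12)]
        table = build_rate_table([[np.array([])]], [fixes], wins)
        assert set(table["fixation_id"]) == {1}
        assert table["short"].all()

    def test_count_conservation(self, small_session):
        """Summing table counts over fixations equals a direct in-window
        recount of every unit's spike train."""
        labeled, table = fv.analyze_session(small_session)
        wins = DEFAULT_FODR["IT"]
        total = table["n_spikes"].sum()
        recount = 0
        for trial_fix, trial_spikes in zip(labeled, small_session.spikes):
            for spikes in trial_spikes:
                for lf in trial_fix:
                    if lf.category == "background":
                        continue
                    for lo, hi in wins:
                        recount += np.sum((spikes >= lf.t_on + lo * 1e-3)
                                          & (spikes < lf.t_on + hi * 1e-3))
        assert total == recount


class TestPerObjectChangeCounts:
    def test_null_balanced_and_insignificant(self, small_session):
        _, table = fv.analyze_session(small_session)
        out = per_object_change_counts(table)
        assert out["n_sig_down"].sum() + out["n_sig_up"].sum() <= \
            max(2, int(0.05 * out["n_objects"].sum()) + 2)

    def test_deterministic_rates_no_significance(self):
        wins = FODRWindows(area="IT", fodr1=(100, 150), fodr2=(150, 200))
        rows = []
        for cat in ("first", "secondplus"):
            for k in range(10):
                rows.append({"unit_id": 0, "trial_id": k, "fixation_id": k,
                             "object_id": 1, "category": cat, "sub_order": "none",
                             "mix_index": 1, "window": "FODR1", "n_spikes": 3,
                             "rate": 60.0, "short": False})
        out = per_object_change_counts(pd.DataFrame(rows))
        assert out["n_sig_up"].iloc[0] == 0
        assert out["n_sig_down"].iloc[0] == 0

    def test_suppressed_objects_dominate_decreases(self, modulated_session):
        """With order gain 0.8, significant changes concentrate on the
        decrease side."""
        _, table = fv.analyze_session(modulated_session)
        out = per_object_change_counts(table)
        assert out["n_down"].sum() > out["n_up"].sum()
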