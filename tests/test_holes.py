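"""Hole detection, threshold selection and occupancy classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_force_holes
from pnnquant.errors import SaturationError, ValidationError
from pnnquant.holes import (
    HoleSet,
    classify_occupancy,
    calls_to_frame,
    detect_holes,
    holes_per_perimeter,
    occupancy_summary,
    select_threshold,
    unsaturated_peak,
)
from pnnquant.profiles import LineProfile
from pnnquant.synth import NetSpec, OccupancyProfile, make_profile


def profile_from(x, ds=0.1, extra=None):
    x = np.asarray(x, dtype=float)
    n = x.size
    chans = {"WFA": x}
    if extra:
        chans.update({k: np.asarray(v, float) for k, v in extra.items()})
    return LineProfile(s=np.arange(n) * ds, intensities=chans, ds=ds, L=n * ds)


def rect_trough_profile(n=200, troughs=(), base=1000.0, depth=0.0, ds=0.1):
    """Baseline profile with rectangular troughs given as (start_idx, n_samples, value)."""
    x = np.full(n, base)
    for i0, k, v in troughs:
        for j in range(k):
            x[(i0 + j) % n] = v
    return profile_from(x, ds=ds)


class TestUnsaturatedPeak:
    def test_ignores_saturated_samples(self):
        prof = profile_from([100, 4095, 3800])
        assert unsaturated_peak(prof, "WFA", 4095) == 3800

    def test_plain_maximum_when_unsaturated(self):
        prof = profile_from([100, 2000, 1500])
        assert unsaturated_peak(prof, "WFA", 4095) == 2000

    def test_all_saturated_raises(self):
        prof = profile_from([4095, 4100, 4095])
        with pytest.raises(SaturationError):
            unsaturated_peak(prof, "WFA", 4095)

    def test_generator_peak_recovered_noise_free(self, small_spec):
        occ = OccupancyProfile.from_dict(["M"], {(): 1.0})
        prof, _ = make_profile(small_spec, occ, 0)
        peak = unsaturated_peak(prof, "WFA", small_spec.saturation_level)
        assert peak == pytest.approx(small_spec.wfa_peak_level, rel=0.02)


class TestDetectHoles:
    def test_width_cutoff_drops_narrow_runs(self):
        # troughs of 0.3, 0.6 and 1.2 µm (value 0, baseline 1000, threshold 500
        # puts interpolated crossings exactly half a sample out on either side)
        prof = rect_trough_profile(troughs=[(20, 3, 0.0), (60, 6, 0.0), (120, 12, 0.0)])
        hs = detect_holes(prof, "WFA", 500.0, w_min=0.5)
        assert len(hs) == 2
        assert sorted(np.round(hs.widths(), 6)) == [0.6, 1.2]

    def test_wrap_around_run_merged(self):
        prof = rect_trough_profile(troughs=[(196, 8, 0.0)])  # spans the origin, 0.8 µm
        hs = detect_holes(prof, "WFA", 500.0)
        assert len(hs) == 1
        assert hs.holes[0].width == pytest.approx(0.8)
        assert hs.holes[0].start_s > hs.holes[0].end_s  # circular interval

    def test_all_above_threshold_empty(self):
        prof = rect_trough_profile()
        assert len(detect_holes(prof, "WFA", 500.0)) == 0

    def test_all_below_threshold_single_full_circle_hole(self):
        prof = rect_trough_profile(base=100.0)
        hs = detect_holes(prof, "WFA", 500.0)
        assert len(hs) == 1
        assert hs.holes[0].width == pytest.approx(prof.L)

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 2000))
        x = rng.normal(500, 300, n)
        thr = float(rng.uniform(200, 800))
        prof = profile_from(x, ds=0.05)
        hs = detect_holes(prof, "WFA", thr, w_min=0.2)
        expected = brute_force_holes(prof.s, x, thr, 0.2, prof.L)
        assert len(hs) == len(expected)
        for hole, (es, ee, ew) in zip(hs.holes, expected):
            assert hole.start_s == pytest.approx(es, abs=1e-9)
            assert hole.end_s == pytest.approx(ee, abs=1e-9)
            assert hole.width == pytest.approx(ew, abs=1e-9)

    @given(
        shift=st.integers(min_value=1, max_value=199),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_rotation_invariance(self, shift, seed):
        """Circularly shifting the profile shifts holes by the same offset."""
        rng = np.random.default_rng(seed)
        x = rng.normal(500, 300, 200)
        prof = profile_from(x)
        rolled = profile_from(np.roll(x, shift))
        a = detect_holes(prof, "WFA", 450.0, w_min=0.2)
        b = detect_holes(rolled, "WFA", 450.0, w_min=0.2)
        assert len(a) == len(b)
        offset = shift * prof.ds
        starts_a = sorted(((h.start_s + offset) % prof.L, round(h.width, 9)) for h in a.holes)
        starts_b = sorted((h.start_s % prof.L, round(h.width, 9)) for h in b.holes)
        for (sa, wa), (sb, wb) in zip(starts_a, starts_b):
            assert sa == pytest.approx(sb, abs=1e-6)
            assert wa == pytest.approx(wb, abs=1e-6)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_below_threshold_arc_length_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(500, 300, 300)
        prof = profile_from(x)
        totals = []
        for thr in [300.0, 450.0, 600.0, 750.0]:
            hs = detect_holes(prof, "WFA", thr, w_min=0.0)
            totals.append(hs.widths().sum() if len(hs) else 0.0)
        assert all(a <= b + 1e-9 for a, b in zip(totals, totals[1:]))


class TestSelectThreshold:
    def test_no_drops_selects_fmin_with_zero_holes(self):
        prof = rect_trough_profile()
        tr = select_threshold(prof, "WFA", saturation_level=4095)
        assert tr.n_holes_at_threshold == 0
        assert tr.fraction_of_peak == pytest.approx(0.40)

    def test_two_troughs_smallest_fraction_covering_both(self):
        """Floors at 0.30 and ~0.55 of the peak: counts step from 1 to 2 at 0.56."""
        prof = rect_trough_profile(
            troughs=[(20, 10, 300.0), (120, 10, 555.0)], base=1000.0
        )
        # exhaustive check of the step position
        for f in np.round(np.arange(0.40, 0.67, 0.01), 9):
            n = len(detect_holes(prof, "WFA", f * 1000.0))
            assert n == (2 if f >= 0.56 else 1)
        tr = select_threshold(prof, "WFA", saturation_level=4095)
        assert tr.n_holes_at_threshold == 2
        assert 0.56 <= tr.fraction_of_peak <= 0.66
        assert tr.fraction_of_peak == pytest.approx(0.56)

    def test_zero_noise_cohort_fully_recovered(self, small_spec):
        occ = OccupancyProfile.from_dict(["M"], {(): 1.0})
        for seed in range(5):
            prof, gt = make_profile(small_spec, occ, seed)
            tr = select_threshold(prof, "WFA", saturation_level=small_spec.saturation_level)
            hs = detect_holes(prof, "WFA", tr.threshold)
            assert len(hs) == len(gt.hole_intervals)
            # every truth interval centre falls inside a detected hole
            L = prof.L
            for start, end in gt.hole_intervals:
                c = (start + ((end - start) % L) / 2) % L
                assert any(
                    ((c - h.start_s) % L) < h.width for h in hs.holes
                )


class TestClassifyOccupancy:
    def test_flat_channel_absent_everywhere(self):
        x = np.full(200, 1000.0)
        for i in range(20, 30):
            x[i] = 0.0
        prof = profile_from(x, extra={"M": np.zeros(200)})
        hs = detect_holes(prof, "WFA", 500.0)
        calls = classify_occupancy(hs, prof, "M")
        assert calls and all(not c.present for c in calls)

    def test_generated_bumps_called_present(self, small_spec):
        occ = OccupancyProfile.from_dict(["M"], {("M",): 1.0})
        prof, gt = make_profile(small_spec, occ, 4)  # noise-free
        tr = select_threshold(prof, "WFA", saturation_level=small_spec.saturation_level)
        hs = detect_holes(prof, "WFA", tr.threshold)
        calls = classify_occupancy(hs, prof, "M")
        assert len(calls) == small_spec.n_holes
        assert all(c.present for c in calls)
        # recorded peak positions sit inside their holes
        for c, hole in zip(calls, hs.holes):
            assert ((c.peak_position - hole.start_s) % prof.L) < hole.width

    def test_occupancy_recovery_within_binomial_noise(self):
        """At SNR 10 the recovered marginal stays within 3 binomial sd of truth."""
        spec = NetSpec(contour_radius=6.0, n_holes=15, pixel_size=0.05).with_snr(10)
        occ = OccupancyProfile.from_dict(["M"], {("M",): 0.63, (): 0.37})
        present, total = 0, 0
        for seed in range(10):
            prof, gt = make_profile(spec, occ, seed)
            tr = select_threshold(prof, "WFA", saturation_level=spec.saturation_level)
            hs = detect_holes(prof, "WFA", tr.threshold)
            calls = classify_occupancy(hs, prof, "M")
            present += sum(c.present for c in calls)
            total += len(calls)
        frac = present / total
        sd = np.sqrt(0.63 * 0.37 / total)
        assert abs(frac - 0.63) < 3 * sd + 0.02  # sampling + small call-error budget


class TestOccupancySummary:
    def _table(self, rows, channels=("A", "B")):
        return pd.DataFrame(rows, columns=list(channels))

    def test_four_exclusive_combinations_quarter_each(self):
        df = self._table([(1, 0), (0, 1), (1, 1), (0, 0)]).astype(bool)
        table = occupancy_summary({"cell": df}, ["A", "B"])
        row = table.per_cell.loc["cell"]
        assert row["A"] == pytest.approx(50.0)
        for label in ["A+B", "none", "any"]:
            assert label in row.index
        assert row["A+B"] == pytest.approx(25.0)
        assert row["none"] == pytest.approx(25.0)
        assert row["any"] == pytest.approx(75.0)

    def test_any_plus_none_is_hundred_for_every_cell(self, rng):
        cells = {
            i: self._table(rng.integers(0, 2, size=(rng.integers(3, 20), 2)).astype(bool))
            for i in range(6)
        }
        table = occupancy_summary(cells, ["A", "B"])
        total = table.per_cell["any"] + table.per_cell["none"]
        assert np.allclose(total, 100.0)
        # exclusive partition sums to 100 per cell
        partition = table.per_cell[["A+B", "A", "B", "none"]]  # marginals not exclusive
        excl = (
            table.per_cell["A+B"]
            + (table.per_cell["A"] - table.per_cell["A+B"])
            + (table.per_cell["B"] - table.per_cell["A+B"])
            + table.per_cell["none"]
        )
        assert np.allclose(excl, 100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            occupancy_summary({}, ["A"])


class TestHolesPerPerimeter:
    def test_density(self):
        hs = HoleSet(
            holes=[type("H", (), {"width": 1.0})() for _ in range(10)],
            threshold_used=None,
            perimeter=50.0,
        )
        assert holes_per_perimeter(hs) == pytest.approx(0.2)

    def test_zero_holes(self):
        hs = HoleSet(holes=[], threshold_used=None, perimeter=30.0)
        assert holes_per_perimeter(hs) == 0.0

    def test_generator_truth(self, small_spec):
        occ = OccupancyProfile.from_dict(["M"], {(): 1.0})
        prof, gt = make_profile(small_spec, occ, 2)
        tr = select_threshold(prof, "WFA", saturation_level=small_spec.saturation_level)
        hs = detect_holes(prof, "WFA", tr.threshold)
        assert holes_per_perimeter(hs) == pytest.approx(
            small_spec.n_holes / small_spec.circumference, rel=1e-6
        )
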