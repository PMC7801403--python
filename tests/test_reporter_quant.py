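"""Tests for flow gating, reporter ratios and image geometry."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from clonfate import (IntensityModel, apoptosis_call, burden_activity_correlation,
                      classify_cells_by_ratio, classify_events,
                      cytometry_from_population, detect_cells, distance_to_bone,
                      fit_reference_gate, g0_fraction, inhibition_rate,
                      nutrient_level)
from clonfate.reporter_quant import CellDetection
from clonfate.synth_assets import fret_events, image_stack

MODEL = IntensityModel()


def percentile_oracle(values, p) -> float:
    """Sort-and-index linear interpolation between order statistics."""
    a = np.sort(np.asarray(values, dtype=float))
    h = (len(a) - 1) * p / 100.0
    lo = int(math.floor(h))
    if lo == len(a) - 1:
        return float(a[-1])
    return float(a[lo] + (h - lo) * (a[lo + 1] - a[lo]))


class TestReferenceGate:
    def test_integer_reference_splits_ninety_ten(self):
        ref = np.arange(1, 101, dtype=float)
        gate = fit_reference_gate(ref, percentile=10)
        labels, low_frac, _ = classify_events(pd.DataFrame({"mVenus": ref}), gate)
        assert low_frac == pytest.approx(0.90)
        assert (labels == "mTORC1_high").sum() == 10

    def test_constant_reference_degenerate(self):
        gate = fit_reference_gate(np.full(50, 7.0))
        assert gate.degenerate and gate.threshold == 7.0

    def test_threshold_matches_sort_and_index_oracle(self, rng):
        ref = rng.lognormal(5, 0.5, 100_000)
        gate = fit_reference_gate(ref, percentile=10)
        assert gate.threshold == pytest.approx(percentile_oracle(ref, 10), rel=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_reference_gate(np.arange(5))


class TestClassifyEvents:
    def test_all_above_threshold(self):
        gate = fit_reference_gate(np.linspace(1, 2, 100))
        _, frac, ci = classify_events(pd.DataFrame({"mVenus": [5.0, 6.0]}), gate)
        assert frac == 1.0
        assert ci[0] <= 1.0 <= ci[1] or ci[1] == 1.0

    def test_boundary_event_is_high(self):
        gate = fit_reference_gate(np.linspace(1, 2, 100))
        labels, _, _ = classify_events(
            pd.DataFrame({"mVenus": [gate.threshold]}), gate)
        assert labels.iloc[0] == "mTORC1_high"

    def test_missing_channel(self):
        gate = fit_reference_gate(np.linspace(1, 2, 100))
        with pytest.raises(ValueError, match="mVenus"):
            classify_events(pd.DataFrame({"FRET": [1.0]}), gate)

    def test_mixture_fraction_recovered(self):
        ref = cytometry_from_population(100_000, None, MODEL, seed=1,
                                        reference=True)["mVenus"].to_numpy()
        gate = fit_reference_gate(ref)
        events = cytometry_from_population(100_000, 0.6, MODEL, seed=2)
        _, low_frac, _ = classify_events(events, gate)
        assert (1.0 - low_frac) == pytest.approx(0.60, abs=0.02)


class TestInhibitionRate:
    def test_identity(self):
        v = np.array([1.0, 2.0, 4.0])
        assert inhibition_rate(v, v) == pytest.approx(1.0)

    def test_elementwise_scaling(self):
        v = np.array([1.0, 2.0, 4.0])
        assert inhibition_rate(2 * v, v) == pytest.approx(2.0)

    def test_generator_round_trip_dynamic_range(self):
        treated = cytometry_from_population(50_000, 0.0, MODEL, seed=3)["mVenus"]
        vehicle = cytometry_from_population(50_000, 1.0, MODEL, seed=4)["mVenus"]
        assert inhibition_rate(treated, vehicle) == pytest.approx(
            MODEL.dynamic_range, rel=0.02)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            inhibition_rate([1.0, -2.0], [1.0, 1.0])


class TestBurdenActivityCorrelation:
    def test_perfectly_monotone(self):
        rho_mv, rho_act, _ = burden_activity_correlation(
            [1, 2, 3, 4], [10, 20, 30, 40])
        assert rho_mv == 1.0 and rho_act == -1.0

    def test_constant_input_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            burden_activity_correlation([1, 2, 3], [5, 5, 5])

    def test_simulated_burden_sweep_negative_activity_correlation(self, rng):
        """mVenus rises (activity falls) with burden under nutrient coupling."""
        from clonfate import CloneTable, RateSet, step

        k = 1e6
        burdens = np.array([0.05, 0.2, 0.5, 1.5, 4.0, 10.0]) * k
        mv_means = []
        for b in burdens:
            nu = nutrient_level(b, k)
            rates = RateSet(0.3, 0.3, 0.0, 0.0, 0.3, 0.3, 0, 0,
                            nutrient_coupling=2.0)
            t = CloneTable(np.array([0]), np.array([10_000]), np.array([10_000]))
            for _ in range(80):
                t = step(t, rates, False, nu, 0.1, rng)
            h_frac = t.total_H / t.total_burden
            ev = cytometry_from_population(20_000, h_frac, MODEL,
                                           seed=int(b) % (2 ** 31))
            mv_means.append(float(np.log(ev["mVenus"]).mean()))
        rho_mv, rho_act, _ = burden_activity_correlation(burdens, mv_means)
        assert rho_act < 0 and rho_mv > 0

    def test_permutation_p_uniform_under_null(self, rng):
        """Spearman p-values are ~uniform for independent pairs."""
        ps = []
        for _ in range(200):
            b = rng.random(12)
            m = rng.random(12)
            ps.append(burden_activity_correlation(b, m)[2])
        ps = np.asarray(ps)
        # Kolmogorov-Smirnov style coarse check on uniformity
        assert 0.3 < (ps < 0.5).mean() < 0.7
        assert (ps < 0.05).mean() < 0.15


class TestG0Fraction:
    def test_all_below_gate(self):
        gate = fit_reference_gate(np.linspace(10, 20, 100))
        assert g0_fraction(np.full(100, 1.0), gate) == 0.0

    def test_self_gate_order_statistic(self):
        vals = np.linspace(1, 1000, 10_000)
        gate = fit_reference_gate(vals, percentile=25)
        assert g0_fraction(vals, gate) == pytest.approx(0.75, abs=1e-3)

    def test_known_mixture_recovered(self, rng):
        g0 = rng.lognormal(math.log(300), 0.25, 2000)
        cycling = rng.lognormal(math.log(50), 0.25, 8000)
        values = np.concatenate([g0, cycling])
        ref = rng.lognormal(math.log(300), 0.5, 10_000)
        gate = fit_reference_gate(ref, percentile=10)
        assert g0_fraction(values, gate) == pytest.approx(0.20, abs=0.02)


class TestApoptosisCall:
    def test_control_applied_to_itself(self):
        ctrl = fret_events(20_000, 0.0, MODEL, seed=5)
        frac, _, _ = apoptosis_call(ctrl, ctrl)
        assert frac == pytest.approx(0.01, abs=0.005)

    def test_known_cleaved_fraction_recovered(self):
        events = fret_events(10_000, 0.3, MODEL, seed=6)
        ctrl = fret_events(10_000, 0.0, MODEL, seed=7)
        frac, _, _ = apoptosis_call(events, ctrl)
        assert frac == pytest.approx(0.30, abs=0.02)

    def test_all_cleaved(self):
        events = fret_events(5000, 1.0, MODEL, seed=8)
        ctrl = fret_events(5000, 0.0, MODEL, seed=9)
        frac, _, _ = apoptosis_call(events, ctrl)
        assert frac > 0.97

    def test_nonpositive_amcyan_dropped(self):
        events = fret_events(100, 0.0, MODEL, seed=10)
        events.loc[events.index[:5], "Amcyan"] = 0.0
        ctrl = fret_events(1000, 0.0, MODEL, seed=11)
        _, labels, n_dropped = apoptosis_call(events, ctrl)
        assert n_dropped == 5 and len(labels) == 95


class TestDetectCells:
    def test_empty_stack(self):
        stack = np.zeros((3, 8, 16, 16), dtype=np.float32)
        assert detect_cells(stack, (2.0, 1.0, 1.0)) == []

    def test_single_blob_detected_at_centroid(self):
        img, truth = image_stack(1, (20, 32, 32), voxel_size=(2.0, 1.0, 1.0),
                                 seed=12)
        (det,) = detect_cells(img, (2.0, 1.0, 1.0))
        true = truth.cells.iloc[0][["z_um", "y_um", "x_um"]].to_numpy(float)
        err_vox = np.abs(np.array(det.centroid_um) - true) / np.array([2.0, 1.0, 1.0])
        assert (err_vox <= 1.0).all()

    def test_many_cells_recall_and_precision(self):
        img, truth = image_stack(200, (24, 160, 160), voxel_size=(2.0, 1.0, 1.0),
                                 seed=13)
        dets = detect_cells(img, (2.0, 1.0, 1.0))
        got = np.array([d.centroid_um for d in dets])
        true = truth.cells[["z_um", "y_um", "x_um"]].to_numpy(float)
        cost = cdist(true, got)
        ri, ci = linear_sum_assignment(cost)
        matched = cost[ri, ci] < 4.0  # um, ~2 voxels
        recall = matched.sum() / len(true)
        assert recall >= 0.95
        match_err = cost[ri, ci][matched]
        assert np.median(match_err) <= 2.0  # within one (z) voxel

    def test_metadata_validation(self):
        with pytest.raises(ValueError):
            detect_cells(np.zeros((2, 4, 4)), (1, 1, 1))


class TestRatioClassification:
    def test_boundary_inclusive_to_low(self):
        d = CellDetection((0, 0, 0), mean_mvenus=4.0, mean_tdtomato=10.0)
        (out,) = classify_cells_by_ratio([d])
        assert out.ratio == pytest.approx(0.4) and out.label == "mTORC1_low"

    def test_just_below_boundary_is_high(self):
        d = CellDetection((0, 0, 0), mean_mvenus=3.9, mean_tdtomato=10.0)
        (out,) = classify_cells_by_ratio([d])
        assert out.label == "mTORC1_high"

    def test_zero_tdtomato_unclassifiable(self):
        d = CellDetection((0, 0, 0), mean_mvenus=1.0, mean_tdtomato=0.0)
        (out,) = classify_cells_by_ratio([d])
        assert out.label == "unclassifiable" and out.ratio is None

    def test_probing_recovers_boundary(self):
        """Bisection over the ratio axis localises the decision boundary at 0.4."""
        lo, hi = 0.0, 1.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            d = CellDetection((0, 0, 0), mean_mvenus=mid, mean_tdtomato=1.0)
            (out,) = classify_cells_by_ratio([d])
            if out.label == "mTORC1_high":
                lo = mid
            else:
                hi = mid
        assert hi == pytest.approx(0.4, abs=1e-9)


class TestDistanceToBone:
    def test_coincident_with_bone_voxel(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 2, 3] = True
        d = distance_to_bone(np.array([[2.0, 2.0, 3.0]]), mask, (2.0, 1.0, 1.0))
        assert d[0] == pytest.approx(0.0)

    def test_flat_plane_offset(self):
        mask = np.zeros((10, 8, 8), dtype=bool)
        mask[0] = True
        d = distance_to_bone(np.array([[25.0, 3.0, 3.0]]), mask, (2.5, 1.0, 1.0))
        assert d[0] == pytest.approx(25.0)

    def test_matches_exhaustive_scan_anisotropic(self, rng):
        mask = rng.random((8, 12, 12)) < 0.03
        mask[0, 0, 0] = True
        voxel = (3.0, 1.2, 0.8)
        cents = rng.random((100, 3)) * np.array([8 * 3.0, 12 * 1.2, 12 * 0.8])
        d = distance_to_bone(cents, mask, voxel)
        bone_um = np.argwhere(mask) * np.array(voxel)
        brute = cdist(cents, bone_um).min(axis=1)
        np.testing.assert_allclose(d, brute, atol=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            distance_to_bone(np.zeros((1, 3)), np.zeros((2, 2, 2), bool), (1, 1, 1))
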