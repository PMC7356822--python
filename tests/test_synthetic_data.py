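"""Phantom generation, relaxivity calibration, and the noise model."""

import numpy as np
import pytest

from synthmri.signal_models import FLAIR, TissueParams, synthesize_weighted
from synthmri.synthetic_data import (
    DEFAULT_BRAIN_TISSUES,
    BRAIN_LABELS,
    BrainPhantomSpec,
    PhantomSpec,
    RelaxivityModel,
    TubeSpec,
    add_rician_noise,
    bias_factors_from_table,
    build_brain_phantom,
    build_cylinder_phantom,
    calibrate_relaxivity,
    default_tube_ring,
    ir_protocol,
    me_protocol,
    relaxation_from_concentration,
    simulate_acquisition,
    synthetic_scan_bias,
)


class TestRelaxivity:
    def test_zero_concentration_returns_solvent(self):
        model = RelaxivityModel(r1=0.5, r2=0.9, t1_solvent_ms=2800.0, t2_solvent_ms=2000.0)
        assert relaxation_from_concentration(0.0, model) == (2800.0, 2000.0)

    def test_strictly_decreasing_in_concentration(self, relaxivity_model):
        c = np.linspace(0, 25, 50)
        t1, t2 = relaxation_from_concentration(c, relaxivity_model)
        assert np.all(np.diff(t1) < 0) and np.all(np.diff(t2) < 0)

    def test_negative_concentration_rejected(self, relaxivity_model):
        with pytest.raises(ValueError):
            relaxation_from_concentration(-0.1, relaxivity_model)

    def test_calibrated_model_matches_reference_anchors(self, relaxivity_model):
        t1, _ = relaxation_from_concentration(1.0, relaxivity_model)
        _, t2 = relaxation_from_concentration(20.0, relaxivity_model)
        assert t1 == pytest.approx(1131.5, rel=0.10)
        assert t2 == pytest.approx(58.5, rel=0.10)

    def test_calibration_exact_on_two_synthetic_pairs(self):
        true = RelaxivityModel(r1=0.6, r2=1.1, t1_solvent_ms=3000.0, t2_solvent_ms=2500.0)
        import pandas as pd

        rows = []
        for quantity in ("T1", "T2"):
            for c in (0.5, 2.0):
                t1, t2 = relaxation_from_concentration(c, true)
                rows.append(
                    {
                        "quantity": quantity,
                        "concentration_mM": c,
                        "reference": t1 if quantity == "T1" else t2,
                    }
                )
        fitted = calibrate_relaxivity(pd.DataFrame(rows))
        assert fitted.r1 == pytest.approx(true.r1, rel=1e-9)
        assert fitted.r2 == pytest.approx(true.r2, rel=1e-9)
        assert fitted.t1_solvent_ms == pytest.approx(true.t1_solvent_ms, rel=1e-9)

    def test_calibration_matches_simple_regression_oracle(self, reference_table):
        # closed-form OLS slope: cov(C, 1/T) / var(C)
        model = calibrate_relaxivity(reference_table)
        for quantity, slope_attr in (("T1", "r1"), ("T2", "r2")):
            rows = reference_table[reference_table["quantity"] == quantity]
            c = rows["concentration_mM"].to_numpy(float)
            rate = 1000.0 / rows["reference"].to_numpy(float)
            slope = np.sum((c - c.mean()) * (rate - rate.mean())) / np.sum((c - c.mean()) ** 2)
            assert getattr(model, slope_attr) == pytest.approx(slope, rel=1e-12)

    def test_singular_design_rejected(self, reference_table):
        bad = reference_table.copy()
        bad["concentration_mM"] = 1.0
        with pytest.raises(ValueError, match="singular"):
            calibrate_relaxivity(bad)

    def test_reference_t1_predicted_within_15pct_median(self, relaxivity_model, reference_table):
        rows = reference_table[reference_table["quantity"] == "T1"]
        pred, _ = relaxation_from_concentration(
            rows["concentration_mM"].to_numpy(float), relaxivity_model
        )
        rel_err = np.abs(pred - rows["reference"].to_numpy(float)) / rows["reference"].to_numpy(float)
        assert np.median(rel_err) < 0.15


class TestCylinderPhantom:
    def test_piecewise_constant_per_tube(self, small_t1_phantom, relaxivity_model):
        t1_expected, _ = relaxation_from_concentration(1.0, relaxivity_model)
        label = next(
            k for k, v in small_t1_phantom.label_names.items() if v == "tube_1mM"
        )
        tube_values = small_t1_phantom.t1[small_t1_phantom.labels == label]
        assert tube_values.size > 0
        assert np.all(tube_values == t1_expected)

    def test_seven_distinct_plateaus_ordered_inversely(self, small_t1_phantom):
        concentrations = (1.0, 0.8, 0.7, 0.6, 0.5, 0.4, 0.2)
        plateaus = []
        for c in concentrations:
            label = next(
                k
                for k, v in small_t1_phantom.label_names.items()
                if v == f"tube_{c:g}mM"
            )
            values = np.unique(small_t1_phantom.t1[small_t1_phantom.labels == label])
            assert values.size == 1
            plateaus.append(values[0])
        # lower concentration -> longer T1
        assert np.all(np.diff(plateaus) > 0)

    def test_empty_tube_list_gives_uniform_saline(self, relaxivity_model):
        maps = build_cylinder_phantom(PhantomSpec(tubes=(), shape=(32, 32, 4)), relaxivity_model)
        liquid = maps.labels != 0
        assert liquid.any()
        assert np.unique(maps.t1[liquid]).size == 1

    def test_overlapping_tubes_rejected(self, relaxivity_model):
        tubes = (TubeSpec(1.0, (0.0, 0.0)), TubeSpec(2.0, (5.0, 0.0)))
        with pytest.raises(ValueError, match="overlap"):
            build_cylinder_phantom(PhantomSpec(tubes=tubes), relaxivity_model)

    def test_tube_outside_tank_rejected(self, relaxivity_model):
        tubes = (TubeSpec(1.0, (70.0, 0.0)),)
        with pytest.raises(ValueError, match="fit inside"):
            build_cylinder_phantom(PhantomSpec(tubes=tubes), relaxivity_model)

    def test_label_voxel_counts_conserved(self, small_t1_phantom):
        counts = np.bincount(small_t1_phantom.labels.ravel())
        assert counts.sum() == np.prod(small_t1_phantom.shape)


class TestBrainPhantom:
    def test_all_regions_present(self, brain_maps):
        for name, label in BRAIN_LABELS.items():
            assert (brain_maps.labels == label).any(), name

    def test_default_t1_ordering(self):
        tissues = DEFAULT_BRAIN_TISSUES
        assert tissues["CSF"].t1 > tissues["GM"].t1 > tissues["WM"].t1

    def test_lesion_matching_wm_is_invisible(self):
        tissues = dict(DEFAULT_BRAIN_TISSUES)
        tissues["lesion"] = TissueParams(
            pd=tissues["WM"].pd, t1=tissues["WM"].t1, t2=tissues["WM"].t2, name="lesion"
        )
        maps = build_brain_phantom(BrainPhantomSpec(tissues=tissues))
        from synthmri.signal_models import T2W

        image = synthesize_weighted(maps, T2W)
        lesion_vals = np.unique(image[maps.labels == BRAIN_LABELS["lesion"]])
        wm_vals = np.unique(image[maps.labels == BRAIN_LABELS["WM"]])
        assert np.array_equal(lesion_vals, wm_vals)

    def test_flair_suppresses_csf(self, brain_maps):
        image = synthesize_weighted(brain_maps, FLAIR)
        csf = image[brain_maps.labels == BRAIN_LABELS["CSF"]].mean()
        wm = image[brain_maps.labels == BRAIN_LABELS["WM"]].mean()
        assert csf < 0.1 * wm

    def test_oversized_lesion_rejected(self):
        with pytest.raises(ValueError, match="lesion"):
            build_brain_phantom(BrainPhantomSpec(lesion_radius_mm=80.0))

    def test_lesion_free_spec(self):
        maps = build_brain_phantom(BrainPhantomSpec(lesion_radius_mm=0.0))
        assert not (maps.labels == BRAIN_LABELS["lesion"]).any()


class TestSimulateAcquisition:
    def test_noiseless_equals_synthesized(self, brain_maps):
        protocol = me_protocol(tes=(10.0, 50.0, 100.0))
        series = simulate_acquisition(brain_maps, protocol, sigma=0.0)
        for volume, seq in zip(series.volumes, protocol):
            assert np.array_equal(volume, synthesize_weighted(brain_maps, seq))

    def test_same_seed_bitwise_identical(self, brain_maps):
        protocol = ir_protocol(tis=(100.0, 700.0, 2400.0))
        a = simulate_acquisition(brain_maps, protocol, sigma=0.05, seed=42)
        b = simulate_acquisition(brain_maps, protocol, sigma=0.05, seed=42)
        assert np.array_equal(a.volumes, b.volumes)
        c = simulate_acquisition(brain_maps, protocol, sigma=0.05, seed=43)
        assert not np.array_equal(a.volumes, c.volumes)

    def test_empty_protocol_rejected(self, brain_maps):
        with pytest.raises(ValueError, match="protocol"):
            simulate_acquisition(brain_maps, (), sigma=0.0)

    def test_mode_inferred_from_protocol(self, brain_maps):
        ir = simulate_acquisition(brain_maps, ir_protocol(tis=(100.0, 800.0, 3000.0)), 0.0)
        me = simulate_acquisition(brain_maps, me_protocol(tes=(10.0, 100.0)), 0.0)
        assert ir.mode == "IR" and ir.timing_list == [100.0, 800.0, 3000.0]
        assert me.mode == "ME" and me.timing_list == [10.0, 100.0]


class TestRicianNoise:
    def test_sigma_zero_identity(self):
        image = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(add_rician_noise(image, 0.0, seed=1), image)

    def test_background_rayleigh_moments(self):
        sigma = 2.0
        noisy = add_rician_noise(np.zeros(10**6), sigma, seed=7)
        assert noisy.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=5e-3)
        assert noisy.std(ddof=1) == pytest.approx(sigma * np.sqrt(2 - np.pi / 2), rel=5e-3)
        assert np.all(noisy >= 0)

    def test_high_snr_gaussian_limit(self):
        signal = 100.0
        noisy = add_rician_noise(np.full(10**6, signal), 1.0, seed=3)
        assert noisy.mean() == pytest.approx(signal, rel=1e-3)

    def test_voxelwise_independence(self):
        noisy = add_rician_noise(np.zeros(10**6), 1.0, seed=11)
        x, y = noisy[:-1] - noisy.mean(), noisy[1:] - noisy.mean()
        lag1 = np.sum(x * y) / np.sqrt(np.sum(x * x) * np.sum(y * y))
        assert abs(lag1) < 0.01

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.zeros(3), -1.0)


class TestSyntheticScanBias:
    def test_empty_table_identity(self):
        values = np.array([800.0, 4000.0])
        assert np.array_equal(synthetic_scan_bias(values, None), values)

    def test_low_concentration_t1_bias_exceeds_20pct(self, reference_table):
        factors = bias_factors_from_table(reference_table, "T1")
        biased = synthetic_scan_bias(
            np.array([2117.2]), factors, concentrations=np.array([0.2])
        )
        assert biased[0] / 2117.2 > 1.20

    def test_high_concentration_t2_bias_below_10pct(self, reference_table):
        factors = bias_factors_from_table(reference_table, "T2")
        biased = synthetic_scan_bias(
            np.array([58.5]), factors, concentrations=np.array([20.0])
        )
        assert abs(biased[0] / 58.5 - 1.0) < 0.10

    def test_nearest_neighbour_extrapolation_by_value(self, reference_table):
        factors = bias_factors_from_table(reference_table, "T1")
        # far beyond the calibrated range: clamps to the longest-T1 factor
        far = synthetic_scan_bias(4300.0, factors)
        edge_factor = factors.loc[factors["reference"].idxmax(), "factor"]
        assert far == pytest.approx(4300.0 * edge_factor)


def test_default_tube_ring_fits_default_tank(relaxivity_model):
    tubes = default_tube_ring((1.0, 0.8, 0.7, 0.6, 0.5, 0.4, 0.2))
    maps = build_cylinder_phantom(PhantomSpec(tubes=tubes), relaxivity_model)
    assert len(np.unique(maps.labels)) == 9  # background + saline + 7 tubes
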