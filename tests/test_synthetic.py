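"""Generators: tensor calibration, phantoms, noise, cohorts, fibrosis scores."""

import numpy as np
import pandas as pd
import pytest

from renodki import (
    DiffusionTensor,
    PhantomSpec,
    TissueParams,
    add_rician_noise,
    calibrate_tensors,
    fa,
    fit_volume,
    forward_signal,
    maps_from_fit,
    md,
    mean_kurtosis,
    pearson,
    icc,
    roi_means,
    simulate_cohort,
    simulate_fibrosis_scores,
    simulate_histology_cohort,
    simulate_phantom,
    simulate_rater_pair,
    reference_cohort_params,
)
from renodki.errors import CalibrationError, PhantomSpecError
from renodki.synthetic import CohortDesign, REFERENCE_CELLS, layered_labels


class TestCalibration:
    def test_isotropic_target_is_exact(self):
        d, w = calibrate_tensors(TissueParams(2.0, 0.0, 0.7))
        np.testing.assert_allclose(d.as_matrix(), 2.0e-3 * np.eye(3), atol=1e-15)
        assert w.components[0] == pytest.approx(0.7, abs=1e-9)

    def test_outer_stripe_baseline_triple(self):
        d, w = calibrate_tensors(TissueParams(2.735, 0.444, 0.760, "OS"))
        assert md(d) * 1e3 == pytest.approx(2.735, rel=1e-6)
        assert fa(d) == pytest.approx(0.444, rel=1e-6)
        assert mean_kurtosis(d, w) == pytest.approx(0.760, rel=1e-6)

    def test_prolate_closed_form_inverts_fa(self):
        target_fa = fa(DiffusionTensor(np.array([2e-3, 1e-3, 1e-3, 0, 0, 0])))
        assert target_fa == pytest.approx(0.4082, abs=5e-5)
        d, _ = calibrate_tensors(TissueParams(4.0 / 3.0, target_fa, 0.5))
        lam = np.sort(np.linalg.eigvalsh(d.as_matrix()))[::-1]
        assert lam[0] / lam[1] == pytest.approx(2.0, rel=1e-9)

    def test_right_inverse_over_all_reference_triples(self):
        """metrics(calibrate(t)) == t for every study cell triple."""
        params = reference_cohort_params().pivot_table(
            index=["region", "timepoint", "group"], columns="metric", values="mean"
        )
        for (_, row) in params.iterrows():
            d, w = calibrate_tensors(TissueParams(row["MD"], row["FA"], row["MK"]))
            assert md(d) * 1e3 == pytest.approx(row["MD"], rel=1e-6)
            assert fa(d) == pytest.approx(row["FA"], rel=1e-6)
            assert mean_kurtosis(d, w) == pytest.approx(row["MK"], rel=1e-6)

    def test_extreme_fa_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_tensors(TissueParams(2.0, 0.96, 0.7))


class TestRicianNoise:
    def test_sigma_zero_is_identity(self):
        s = np.linspace(1.0, 10.0, 7)
        np.testing.assert_array_equal(add_rician_noise(s, 0.0, seed=1), s)

    def test_zero_signal_rayleigh_mean(self):
        noisy = add_rician_noise(np.zeros(200_000), 2.5, seed=2)
        assert noisy.mean() == pytest.approx(2.5 * np.sqrt(np.pi / 2.0), rel=0.02)

    def test_high_snr_mean_expansion(self):
        snr = 50.0
        noisy = add_rician_noise(np.full(200_000, snr), 1.0, seed=3)
        assert noisy.mean() / snr == pytest.approx(1.0 + 1.0 / (4.0 * snr**2), rel=0.005)

    def test_seeded_determinism(self):
        s = np.ones(100)
        a = add_rician_noise(s, 0.3, seed=9)
        b = add_rician_noise(s, 0.3, seed=9)
        c = add_rician_noise(s, 0.3, seed=10)
        assert np.array_equal(a, b) and not np.array_equal(a, c)


class TestPhantom:
    def test_noiseless_voxels_equal_forward_model(self, scheme):
        spec = PhantomSpec(shape=(14, 6, 10), rician_sigma=0.0, seed=0)
        dwi, labels = simulate_phantom(spec, scheme)
        d, w = calibrate_tensors(spec.tissue["CO"])
        expected = forward_signal(d, w, spec.s0, scheme)
        co = dwi.data[labels.region_mask("CO")]
        np.testing.assert_array_equal(co, np.broadcast_to(expected, co.shape))

    def test_seeded_determinism(self, scheme):
        spec = PhantomSpec(shape=(14, 6, 10), rician_sigma=40.0, seed=5)
        a, _ = simulate_phantom(spec, scheme)
        b, _ = simulate_phantom(spec, scheme)
        assert np.array_equal(a.data, b.data)

    def test_overlapping_regions_rejected(self):
        boxes = {
            "CO": (0, 6, 0, 6, 0, 6),
            "OS": (3, 9, 0, 6, 0, 6),  # overlaps CO
            "IS": (9, 12, 0, 6, 0, 6),
        }
        with pytest.raises(PhantomSpecError, match="overlap"):
            layered_labels((14, 6, 10), region_boxes=boxes)

    def test_too_small_region_rejected(self):
        boxes = {
            "CO": (0, 4, 0, 4, 0, 4),
            "OS": (4, 8, 0, 4, 0, 4),
            "IS": (8, 9, 0, 2, 0, 2),  # 4 voxels
        }
        with pytest.raises(PhantomSpecError, match="IS"):
            layered_labels((14, 6, 10), region_boxes=boxes)

    def test_noiseless_fit_recovers_regional_triples(self, scheme):
        spec = PhantomSpec(shape=(14, 6, 10), rician_sigma=0.0, seed=0)
        dwi, labels = simulate_phantom(spec, scheme)
        maps = maps_from_fit(fit_volume(dwi, labels), affine=dwi.affine)
        table = roi_means(maps, labels).set_index(["region", "metric"])["value"]
        for region, tp in spec.tissue.items():
            assert table[(region, "MD")] == pytest.approx(tp.md_target, abs=1e-4)
            assert table[(region, "FA")] == pytest.approx(tp.fa_target, abs=1e-4)
            assert table[(region, "MK")] == pytest.approx(tp.mk_target, abs=1e-4)

    def test_snr50_regional_means_within_5_percent(self, scheme):
        """Estimator-bias bound: means over 20 noisy phantoms near targets.

        At the default SNR 25 the b=800 noise floor biases FA upward and MK
        downward beyond this bound (a property of magnitude MRI, not of the
        estimator); the bound is checked where the noise regime permits it.
        """
        spec0 = PhantomSpec()
        targets = {
            r: np.array([p.mk_target, p.fa_target, p.md_target])
            for r, p in spec0.tissue.items()
        }
        acc = {r: [] for r in targets}
        for i in range(20):
            spec = PhantomSpec(rician_sigma=spec0.s0 / 50.0, seed=3000 + i)
            dwi, labels = simulate_phantom(spec, scheme)
            maps = maps_from_fit(fit_volume(dwi, labels), affine=dwi.affine)
            tab = roi_means(maps, labels).set_index(["region", "metric"])["value"]
            for r in targets:
                acc[r].append([tab[(r, "MK")], tab[(r, "FA")], tab[(r, "MD")]])
        for r, t in targets.items():
            rel = np.abs(np.mean(acc[r], axis=0) - t) / t
            assert np.all(rel < 0.05), f"{r}: {rel}"


class TestCohort:
    def test_seeded_determinism(self):
        design = CohortDesign(seed=4)
        a, b = simulate_cohort(design), simulate_cohort(design)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_cohort(CohortDesign(seed=5))
        assert not a["value"].equals(c["value"])

    def test_vanishing_sd_pins_values_to_cell_means(self):
        params = reference_cohort_params().copy()
        params["sd"] = 1e-12
        table = simulate_cohort(CohortDesign(cell_params=params, seed=0))
        lookup = params.set_index(["metric", "region", "timepoint", "group"])["mean"]
        keys = list(zip(table["metric"], table["region"], table["timepoint"], table["group"]))
        np.testing.assert_allclose(
            table["value"].to_numpy(), lookup.loc[keys].to_numpy(), atol=1e-9
        )

    def test_large_n_means_converge_to_cell_means(self):
        table = simulate_cohort(CohortDesign(n_subjects=400, seed=6))
        cell = table[
            (table.metric == "MK") & (table.region == "IS")
            & (table.timepoint == "9d") & (table.group == "HUA")
        ]["value"]
        mean, sd = REFERENCE_CELLS[("MK", "IS")]["9d"][1]
        assert cell.mean() == pytest.approx(mean, abs=4 * sd / np.sqrt(400))

    def test_table_shape(self):
        table = simulate_cohort(CohortDesign(n_subjects=6, seed=0))
        assert len(table) == 4 * 6 * 3 * 3 * 6  # groups·tps·regions·metrics·subjects


class TestRaterPair:
    @staticmethod
    def _single_cell_table(n, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "subject": [f"s{i}" for i in range(n)],
            "group": "HUA", "timepoint": "9d", "region": "IS", "metric": "MK",
            "value": rng.normal(0.787, 0.030, n),
        })

    def test_zero_fraction_gives_identical_raters_and_unit_icc(self):
        table = self._single_cell_table(12, seed=1)
        raters = simulate_rater_pair(table, 0.0, seed=2)
        wide = raters.pivot(index="subject", columns="rater", values="value")
        np.testing.assert_array_equal(wide[1].to_numpy(), wide[2].to_numpy())
        assert icc(wide.to_numpy()).estimate == pytest.approx(1.0)

    def test_variance_ratio_oracle(self):
        # ICC -> σ_b²/(σ_b² + (0.2 σ_b)²) = 1/1.04 ≈ 0.962 for large n
        table = self._single_cell_table(800, seed=3)
        raters = simulate_rater_pair(table, 0.2, seed=4)
        wide = raters.pivot(index="subject", columns="rater", values="value")
        assert icc(wide.to_numpy()).estimate == pytest.approx(1.0 / 1.04, abs=0.01)

    def test_seeded_determinism(self):
        table = self._single_cell_table(10, seed=5)
        a = simulate_rater_pair(table, 0.2, seed=6)
        b = simulate_rater_pair(table, 0.2, seed=6)
        pd.testing.assert_frame_equal(a, b)


class TestFibrosisScores:
    def test_near_unit_correlation(self):
        table = simulate_histology_cohort(seed=1)
        scores = simulate_fibrosis_scores(table, 0.999, seed=2)
        merged = table[(table.metric == "MK") & (table.region == "OS")].merge(
            scores, on=["subject", "region"]
        )
        r, _ = pearson(merged["value"], merged["mod_value"])
        assert r > 0.99

    def test_null_correlation_within_sampling_bounds(self):
        table = simulate_histology_cohort(seed=3, n_per_cell=250)
        scores = simulate_fibrosis_scores(table, 0.0, seed=4)
        merged = table[(table.metric == "MK") & (table.region == "OS")].merge(
            scores, on=["subject", "region"]
        )
        n = len(merged)
        r, _ = pearson(merged["value"], merged["mod_value"])
        assert abs(r) < 2.0 / np.sqrt(n)

    def test_mod_marginal_location(self):
        table = simulate_histology_cohort(seed=5, n_per_cell=120)
        scores = simulate_fibrosis_scores(table, 0.687, seed=6)
        assert scores["mod_value"].mean() == pytest.approx(0.13, abs=0.003)
        assert scores["mod_value"].min() > 0

    def test_histology_cohort_size(self):
        table = simulate_histology_cohort(seed=7)
        assert table["subject"].nunique() == 27  # 3 groups × 3 timepoints × 3 rats
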