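"""Statistical layer: ROI means, ICC, ANOVA + LSD, Pearson, report assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from renodki import (
    LabelMap,
    anova_oneway,
    icc,
    lsd_posthoc,
    pearson,
    roi_means,
    simulate_cohort,
    simulate_fibrosis_scores,
    simulate_histology_cohort,
    simulate_rater_pair,
    summary_report,
)
from renodki.errors import StatsError
from renodki.metrics import ParameterMaps
from renodki.synthetic import CohortDesign, layered_labels


def _uniform_maps(shape, mk=0.760, fa=0.444, mdv=2.735):
    return ParameterMaps(
        mk=np.full(shape, mk), fa=np.full(shape, fa),
        md=np.full(shape, mdv), s0=np.full(shape, 1000.0), affine=np.eye(4),
    )


class TestRoiMeans:
    def test_uniform_maps_give_uniform_regional_means(self):
        shape = (14, 8, 10)
        labels = layered_labels(shape)
        table = roi_means(_uniform_maps(shape), labels)
        assert set(table["region"]) == {"CO", "OS", "IS"}
        mk_rows = table[table.metric == "MK"]
        np.testing.assert_allclose(mk_rows["value"], 0.760)

    def test_sentinels_excluded_from_means(self):
        shape = (14, 8, 10)
        labels = layered_labels(shape)
        maps = _uniform_maps(shape)
        mk = maps.mk.copy()
        co = labels.region_mask("CO")
        idx = np.argwhere(co)
        half = idx[: len(idx) // 2]
        mk[tuple(half.T)] = np.nan
        maps.mk = mk
        table = roi_means(maps, labels).set_index(["region", "metric"])
        assert table.loc[("CO", "MK"), "value"] == pytest.approx(0.760)
        assert table.loc[("CO", "MK"), "n_voxels"] < int(co.sum())

    def test_oversized_slice_request_clips_with_warning(self):
        shape = (14, 4, 10)
        labels = layered_labels(shape)
        with pytest.warns(UserWarning, match="n_slices"):
            table = roi_means(_uniform_maps(shape), labels, n_slices=99)
        assert (table["n_voxels"] > 0).all()

    def test_region_empty_in_slices_raises(self):
        shape = (14, 8, 10)
        labels = layered_labels(shape)
        maps = _uniform_maps(shape)
        mk = maps.mk.copy()
        mk[labels.region_mask("IS")] = np.nan
        maps.mk = mk
        with pytest.raises(StatsError, match="IS"):
            roi_means(maps, labels)

    def test_misaligned_labels_rejected(self):
        labels = layered_labels((14, 8, 10))
        with pytest.raises(StatsError):
            roi_means(_uniform_maps((12, 8, 10)), labels)


class TestIcc:
    def test_identical_raters_give_unity(self):
        x = np.tile(np.linspace(0.6, 0.9, 8)[:, None], (1, 2))
        res = icc(x)
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_lower == res.ci_upper == 1.0

    def test_matches_pingouin_two_way_random_absolute(self):
        """Independent variance-components oracle (pingouin ICC(A,1))."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        x = rng.normal(0.7, 0.03, size=(6, 2))
        res = icc(x)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(6), 2),
            "rater": np.tile([1, 2], 6),
            "value": x.reshape(-1),
        })
        oracle = pg.intraclass_corr(
            df, targets="subject", raters="rater", ratings="value"
        ).set_index("Type")
        assert res.estimate == pytest.approx(oracle.loc["ICC(A,1)", "ICC"], abs=1e-10)
        lo, hi = oracle.loc["ICC(A,1)", "CI95"]
        assert res.ci_lower == pytest.approx(lo, abs=0.01)
        assert res.ci_upper == pytest.approx(hi, abs=0.01)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(StatsError):
            icc(np.ones((2, 2)))

    @given(
        st.floats(-5.0, 5.0, allow_nan=False),
        st.floats(0.1, 10.0, allow_nan=False),
    )
    def test_invariant_to_shift_and_joint_rescale(self, shift, scale):
        rng = np.random.default_rng(12)
        x = rng.normal(0.7, 0.05, size=(8, 2))
        base = icc(x).estimate
        assert icc(scale * (x + shift)).estimate == pytest.approx(base, abs=1e-9)


class TestAnova:
    def test_identical_groups_degenerate(self):
        res = anova_oneway([np.ones(5), np.ones(5), np.ones(5)])
        assert res.f == 0.0 and res.p == 1.0 and res.degenerate

    def test_matches_from_scratch_sums_of_squares(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 0.03, 6) for m in (0.687, 0.787, 0.699, 0.693)]
        res = anova_oneway(groups)
        # independent oracle: direct SS decomposition
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ssb / 3) / (ssw / (len(allv) - 4))
        assert res.f == pytest.approx(f_oracle, abs=1e-10)
        f_scipy, p_scipy = sps.f_oneway(*groups)
        assert res.f == pytest.approx(f_scipy, rel=1e-12)
        assert res.p == pytest.approx(p_scipy, rel=1e-12)

    def test_affine_invariance_of_f(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1.0, 7) for m in (0.0, 1.0, 2.0)]
        f1 = anova_oneway(groups).f
        f2 = anova_oneway([5.0 * g - 3.0 for g in groups]).f
        assert f2 == pytest.approx(f1, rel=1e-12)


class TestLsd:
    def test_identical_pair_has_zero_t(self):
        g = np.array([1.0, 2.0, 3.0])
        res = anova_oneway([g, g.copy(), g + 5.0])
        table = lsd_posthoc(res).set_index(["group_a", "group_b"])
        assert table.loc[("g1", "g2"), "t"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc[("g1", "g2"), "p"] == pytest.approx(1.0)

    def test_two_groups_equal_pooled_t_test(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0.0, 1.0, 8), rng.normal(0.5, 1.0, 6)
        res = anova_oneway([a, b])
        row = lsd_posthoc(res).iloc[0]
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=True)
        assert row["t"] == pytest.approx(t_ref, rel=1e-12)
        assert row["p"] == pytest.approx(p_ref, rel=1e-12)

    def test_formula_oracle_with_pooled_variance(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 0.5, 5) for m in (0.0, 0.3, 1.0)]
        res = anova_oneway(groups)
        row = lsd_posthoc(res).set_index(["group_a", "group_b"]).loc[("g1", "g3")]
        mse = res.ms_error
        t_oracle = (groups[0].mean() - groups[2].mean()) / np.sqrt(mse * (1 / 5 + 1 / 5))
        assert row["t"] == pytest.approx(t_oracle, abs=1e-12)

    def test_separated_groups_yield_tiny_p(self):
        """Means 0.687 vs 0.787 at SD 0.03, n = 6: LSD P < 0.001 nearly always."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 3000
        for _ in range(n_rep):
            groups = [rng.normal(m, sd, 6) for m, sd in
                      ((0.687, 0.029), (0.787, 0.030), (0.699, 0.009), (0.693, 0.013))]
            res = anova_oneway(groups)
            p = lsd_posthoc(res).set_index(["group_a", "group_b"]).loc[("g1", "g2"), "p"]
            hits += p < 0.001
        assert hits / n_rep >= 0.99


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_formula_oracle(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, _ = pearson(x, y)
        r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            pearson(np.ones(5), np.arange(5.0))

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_invariant_to_positive_affine_maps(self, a, b):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r0, _ = pearson(x, y)
        r1, _ = pearson(a * x + b, y)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert pearson(y, x)[0] == pytest.approx(r0, abs=1e-12)


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(CohortDesign(seed=21))


class TestSummaryReport:
    def test_cell_means_calibrated_to_design(self, cohort):
        """Sample cell means scatter around design means as ~N(m, sd/√6)."""
        report = summary_report(cohort)
        from renodki import reference_cohort_params

        ref = reference_cohort_params().set_index(
            ["metric", "region", "timepoint", "group"]
        )
        z = []
        for _, row in report.summary_table.iterrows():
            cell = ref.loc[(row["metric"], row["region"], row["timepoint"], row["group"])]
            z.append((row["mean"] - cell["mean"]) / (cell["sd"] / np.sqrt(row["n"])))
        z = np.abs(z)
        assert (z < 2).mean() >= 0.85
        assert z.max() < 5

    def test_no_fibrosis_leaves_correlations_empty(self, cohort):
        report = summary_report(cohort)
        assert report.correlation_table.empty
        assert not report.anova_table.empty
        assert not report.summary_table.empty

    def test_single_timepoint_yields_single_anova_stratum(self, cohort):
        single = cohort[(cohort.timepoint == "9d") & (cohort.region == "IS")
                        & (cohort.metric == "MK")]
        report = summary_report(single)
        assert len(report.anova_table) == 1

    def test_full_assembly_with_raters_and_fibrosis(self, cohort):
        raters = simulate_rater_pair(cohort[cohort.group == "HUA"], 0.2, seed=22)
        histology = simulate_histology_cohort(seed=23)
        fib = simulate_fibrosis_scores(histology, 0.687, seed=24)
        table = pd.concat([cohort, histology], ignore_index=True)
        report = summary_report(table, raters=raters, fibrosis=fib)
        assert not report.icc_table.empty
        assert (report.icc_table["icc"] > 0.8).all()
        assert not report.correlation_table.empty
        mk_os = report.correlation_table.set_index(["metric", "region"])
        assert mk_os.loc[("MK", "OS"), "r"] > 0.3
        assert (report.anova_table["p"].between(0, 1)).all()

    def test_report_files_round_trip(self, cohort, tmp_path):
        report = summary_report(cohort)
        paths = report.save(tmp_path / "report")
        assert set(paths) == {"icc", "anova", "posthoc", "correlation", "summary", "report"}
        back = pd.read_csv(paths["anova"])
        assert len(back) == len(report.anova_table)
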