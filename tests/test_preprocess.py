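"""Preprocessing: exclusions, RSDqc, filters, LOD, creatinine, INT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import ndtri

import twinmetab as tm
from twinmetab.simulate import MetaboliteMatrix


def _matrix(values: pd.DataFrame, platform="amine", lod=None, censored=None):
    meta = pd.DataFrame(
        {
            "platform": platform,
            "lod": np.nan if lod is None else lod,
        },
        index=values.columns,
    )
    return MetaboliteMatrix(values, meta, censored)


class TestSampleExclusions:
    def test_fixture_counts_match_published_rounds(self, fixture_roster):
        disc = fixture_roster[fixture_roster.cohort == "discovery"]
        rep = fixture_roster[fixture_roster.cohort == "replication"]
        kept_d, report_d = tm.apply_sample_exclusions(disc)
        kept_r, report_r = tm.apply_sample_exclusions(rep)
        assert len(kept_d) == 1300
        assert len(kept_r) == 179
        counts = report_d[~report_d.retained]["reason"].value_counts().to_dict()
        assert counts == {
            "late_freeze": 25,
            "second_multiple": 22,
            "not_first_morning": 13,
            "insufficient_urine": 2,
        }

    def test_clean_roster_is_identity(self, small_cohort):
        _, (cohort, _, _, _) = small_cohort
        kept, report = tm.apply_sample_exclusions(cohort)
        assert len(kept) == len(cohort)
        assert report.retained.all()

    def test_report_counts_sum_exactly(self, fixture_roster):
        kept, report = tm.apply_sample_exclusions(fixture_roster)
        assert (~report.retained).sum() == len(fixture_roster) - len(kept)

    def test_missing_flag_treated_as_pass(self):
        cohort = pd.DataFrame(
            {
                "child_id": ["a", "b"],
                "first_morning": [None, False],
                "freeze_delay": [0.5, 0.5],
                "urine_sufficient": [True, True],
                "second_multiple": [False, False],
                "duplicate_of_other_cohort": [False, False],
            }
        )
        kept, _ = tm.apply_sample_exclusions(cohort)
        assert kept.child_id.tolist() == ["a"]


class TestRsdqc:
    @pytest.mark.parametrize(
        "injections,expected",
        [([10, 9, 11], 10.0), ([5, 5, 5], 0.0), ([10, 13, 7], 30.0)],
    )
    def test_hand_computed_values(self, injections, expected):
        qc = pd.DataFrame({"m1": injections})
        assert tm.compute_rsdqc(qc)["m1"] == pytest.approx(expected)

    def test_zero_mean_is_undefined(self):
        qc = pd.DataFrame({"m1": [-1.0, 1.0]})
        assert np.isnan(tm.compute_rsdqc(qc)["m1"])

    def test_single_injection_rejected(self):
        with pytest.raises(ValueError, match="2 QC injections"):
            tm.compute_rsdqc(pd.DataFrame({"m1": [1.0]}))


class TestFilterMetabolites:
    def test_fixture_panel_attrition(self):
        """66/21/13 panel reduces to 56/20/10 = 86 under the published rules."""
        matrix, qc = tm.make_paper_fixture_panel()
        rsd = tm.compute_rsdqc(qc)
        kept, report = tm.filter_metabolites(matrix, rsd)
        assert kept.values.shape[1] == 86
        by_platform = (
            report[report.retained].platform.value_counts().to_dict()
        )
        assert by_platform == {"amine": 56, "organic_acid": 20, "steroid": 10}
        reasons = report[~report.retained].reason.value_counts().to_dict()
        assert reasons == {"high_rsdqc": 10, "high_missingness": 4}

    def test_rsd_boundary_is_inclusive(self):
        values = pd.DataFrame({"m1": [1.0, 2.0], "m2": [1.0, 2.0]})
        rsd = pd.Series({"m1": 15.0, "m2": 14.999})
        kept, _ = tm.filter_metabolites(_matrix(values), rsd)
        assert list(kept.values.columns) == ["m2"]

    def test_missing_boundary_is_strict(self):
        # exactly 10% missing is retained; just above is dropped
        v = pd.DataFrame(
            {"m1": [np.nan] + [1.0] * 9, "m2": [np.nan, np.nan] + [1.0] * 8}
        )
        rsd = pd.Series({"m1": 1.0, "m2": 1.0})
        kept, _ = tm.filter_metabolites(_matrix(v), rsd)
        assert list(kept.values.columns) == ["m1"]

    def test_idempotent(self):
        matrix, qc = tm.make_paper_fixture_panel()
        rsd = tm.compute_rsdqc(qc)
        once, _ = tm.filter_metabolites(matrix, rsd)
        twice, report = tm.filter_metabolites(once, rsd)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert report.retained.all()


class TestLodImputation:
    def test_half_lod_and_half_minimum(self):
        values = pd.DataFrame({"m1": [np.nan, 1.0], "m2": [np.nan, 0.6]})
        censored = pd.DataFrame({"m1": [True, False], "m2": [True, False]})
        matrix = _matrix(values, lod=[0.8, np.nan], censored=censored)
        out = tm.impute_below_lod(matrix)
        assert out.values.loc[0, "m1"] == pytest.approx(0.4)   # lod/2
        assert out.values.loc[0, "m2"] == pytest.approx(0.3)   # min/2
        assert not out.censored.to_numpy().any()

    def test_no_censoring_is_identity(self):
        values = pd.DataFrame({"m1": [1.0, 2.0]})
        out = tm.impute_below_lod(_matrix(values))
        pd.testing.assert_frame_equal(out.values, values)

    def test_all_censored_without_lod_errors(self):
        values = pd.DataFrame({"m1": [np.nan, np.nan]})
        censored = pd.DataFrame({"m1": [True, True]})
        with pytest.raises(ValueError, match="no LOD"):
            tm.impute_below_lod(_matrix(values, censored=censored))


class TestCreatinineNormalization:
    def test_division_and_scaling(self):
        cohort = pd.DataFrame({"child_id": ["a", "b"], "creatinine": [2.0, 1.0]})
        values = pd.DataFrame({"m1": [10.0, 3.0]}, index=["a", "b"])
        out = tm.normalize_creatinine(_matrix(values), cohort)
        assert out.values["m1"].tolist() == [5.0, 3.0]
        doubled = cohort.assign(creatinine=cohort.creatinine * 2)
        out2 = tm.normalize_creatinine(_matrix(values), doubled)
        np.testing.assert_allclose(out2.values["m1"], out.values["m1"] / 2)

    def test_nonpositive_creatinine_rejected(self):
        cohort = pd.DataFrame({"child_id": ["a"], "creatinine": [0.0]})
        values = pd.DataFrame({"m1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="creatinine"):
            tm.normalize_creatinine(_matrix(values), cohort)


class TestInverseNormalTransform:
    def test_blom_oracle(self):
        # independent oracle: Phi^-1((rank - 3/8) / (n + 1/4))
        out = tm.inverse_normal_transform([5.0, 2.0, 9.0])
        expected = ndtri((np.array([2, 1, 3]) - 0.375) / 3.25)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert out[0] == pytest.approx(0.0)
        assert out[2] == pytest.approx(0.8694, abs=2e-4)

    def test_median_maps_to_zero_and_missing_stays(self):
        out = tm.inverse_normal_transform([1.0, np.nan, 3.0, 2.0])
        assert np.isnan(out[1])
        assert out[3] == pytest.approx(0.0)

    @given(
        st.lists(
            st.integers(-10**6, 10**6), min_size=2, max_size=40, unique=True
        ),
        st.sampled_from([np.exp, np.cbrt, lambda x: 3 * x + 1]),
    )
    def test_rank_invariance_under_monotone_transforms(self, xs, f):
        # spacing >= 3e-5 keeps exp() strictly monotone in float64
        x = np.asarray(xs, dtype=float) * 3e-5
        np.testing.assert_allclose(
            tm.inverse_normal_transform(x),
            tm.inverse_normal_transform(f(x)),
            atol=1e-10,
        )

    def test_constant_vector_degenerates_to_zero(self):
        np.testing.assert_allclose(
            tm.inverse_normal_transform([2.0, 2.0, 2.0]), 0.0
        )


class TestPipeline:
    def test_output_is_standardized_per_metabolite(self, small_cohort):
        _, (cohort, matrix, qc, _) = small_cohort
        pre = tm.preprocess_pipeline(cohort, matrix, qc)
        processed = pre["processed"]
        n = len(processed)
        assert processed.mean().abs().max() < 0.05
        assert (processed.var() - 1).abs().max() < 0.05 + 5 / np.sqrt(n)

    def test_int_is_per_cohort(self, fixture_roster):
        """Each cohort is transformed on its own ranks (both near mean 0)."""
        rng = np.random.default_rng(4)
        kept, _ = tm.apply_sample_exclusions(fixture_roster)
        values = pd.DataFrame(
            # replication on a shifted raw scale
            {"m1": rng.lognormal(
                np.where(kept.cohort == "replication", 3.0, 0.0), 0.5
            )},
            index=kept.child_id,
        )
        matrix = _matrix(values)
        qc = pd.DataFrame({"m1": [10.0, 10.1, 9.9]})
        pre = tm.preprocess_pipeline(fixture_roster, matrix, qc)
        out = pre["processed"]["m1"]
        groups = kept.set_index("child_id")["cohort"]
        for _, block in out.groupby(groups):
            assert abs(block.mean()) < 1e-10
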