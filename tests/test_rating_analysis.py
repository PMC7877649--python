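"""Exclusion rule, design coding, CLMM estimation, LR tests, selection."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.miscmodels.ordinal_model import OrderedModel

from scriptsurp.rating_analysis import (
    ClmmSpec,
    backward_select,
    exclude_subjects,
    feasibility_report,
    final_model_spec,
    fit_clmm,
    load_ratings,
    lr_test,
    prepare_design,
)
from scriptsurp.synthetic_data import RatingSimSpec, sample_ratings


def table_with_controls(control_ratings: dict[str, list[int]]) -> pd.DataFrame:
    """Minimal rating table: 2 experimental rows per subject + given controls."""
    rows = []
    for subj, ctrls in control_ratings.items():
        for i, r in enumerate(ctrls):
            rows.append(
                dict(subject=subj, item=f"ctrl{i}", scenario="control", rating=r,
                     sententiality="sentence", predictability="predictable",
                     script_type="adapted", position=0, familiarity_raw=np.nan,
                     is_control=True, control_kind="ungrammatical")
            )
        for i, cond in enumerate(["sentence", "fragment"]):
            rows.append(
                dict(subject=subj, item=f"i{i}", scenario="s", rating=5,
                     sententiality=cond,
                     predictability="predictable" if i else "unpredictable",
                     script_type="adapted", position=i + 1, familiarity_raw=3,
                     is_control=False, control_kind="")
            )
    return pd.DataFrame(rows)


class TestExclusion:
    def test_three_natural_controls_excluded(self):
        df = table_with_controls({"s1": [7, 7, 7, 1, 1]})
        kept, excluded = exclude_subjects(df)
        assert excluded == ["s1"]
        assert kept.empty

    def test_two_natural_controls_retained_boundary(self):
        df = table_with_controls({"s1": [7, 7, 1, 1, 1]})
        kept, excluded = exclude_subjects(df)
        assert excluded == []
        assert set(kept["subject"]) == {"s1"}

    def test_all_low_controls_retained(self):
        df = table_with_controls({"s1": [1, 1, 1, 1, 1]})
        _, excluded = exclude_subjects(df)
        assert excluded == []

    def test_rating_six_counts_as_natural(self):
        df = table_with_controls({"s1": [6, 6, 6, 1, 1]})
        _, excluded = exclude_subjects(df)
        assert excluded == ["s1"]

    def test_no_controls_is_an_error(self):
        df = table_with_controls({"s1": [1]})
        df = df[~df["is_control"]]
        with pytest.raises(ValueError, match="control"):
            exclude_subjects(df)

    def test_raising_cutoffs_never_excludes_more(self):
        rng = np.random.default_rng(0)
        ctrls = {f"s{i}": list(rng.integers(1, 8, 5)) for i in range(20)}
        df = table_with_controls(ctrls)
        base = len(exclude_subjects(df, 2, 6)[1])
        for min_flagged, cutoff in [(3, 6), (2, 7), (4, 7)]:
            assert len(exclude_subjects(df, min_flagged, cutoff)[1]) <= base


class TestPrepareDesign:
    def test_balanced_table_sum_codes_to_zero(self):
        df = sample_ratings(RatingSimSpec(n_subjects=8, n_items=8, seed=0))
        design = prepare_design(df)
        assert design.frame["sententiality"].sum() == 0
        assert design.frame["predictability"].sum() == 0
        assert set(design.frame["sententiality"].unique()) == {-1.0, 1.0}

    def test_familiarity_z_scored_over_available_values(self):
        df = sample_ratings(
            RatingSimSpec(n_subjects=8, n_items=8, n_missing_familiarity=2, seed=1)
        )
        design = prepare_design(df)
        observed = design.frame.loc[
            design.frame["familiarity_missing"] == 0, "script_familiarity"
        ]
        assert observed.mean() == pytest.approx(0.0, abs=1e-9)
        assert observed.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_missing_familiarity_rows_flagged_and_zeroed(self):
        df = sample_ratings(
            RatingSimSpec(n_subjects=8, n_items=8, n_missing_familiarity=2, seed=1)
        )
        design = prepare_design(df)
        flagged = design.frame["familiarity_missing"] == 1
        assert design.n_missing_familiarity == int(flagged.sum()) > 0
        assert (design.frame.loc[flagged, "script_familiarity"] == 0).all()

    def test_constant_familiarity_flagged_zero_variance(self):
        df = sample_ratings(RatingSimSpec(n_subjects=4, n_items=4, seed=2))
        df["familiarity_raw"] = 3.0
        design = prepare_design(df)
        assert design.familiarity_zero_variance

    def test_single_level_predictor_rejected(self):
        df = sample_ratings(RatingSimSpec(n_subjects=4, n_items=4, seed=2))
        df.loc[~df["is_control"], "sententiality"] = "sentence"
        with pytest.raises(ValueError, match="single level"):
            prepare_design(df)


class TestFitClmm:
    def test_no_random_terms_matches_statsmodels_ordered_model(self):
        sim = RatingSimSpec(n_subjects=24, n_items=12, random_sds={}, seed=5)
        design = prepare_design(exclude_subjects(sample_ratings(sim))[0])
        spec = ClmmSpec(fixed=final_model_spec().fixed, random={})
        fit = fit_clmm(design, spec)
        X = design.X(spec.fixed)
        oracle = OrderedModel(design.y, X, distr="logit").fit(method="bfgs", disp=False)
        np.testing.assert_allclose(
            [fit.estimates[t] for t in spec.fixed], oracle.params[: len(spec.fixed)],
            atol=1e-3,
        )
        np.testing.assert_allclose(
            [fit.std_errors[t] for t in spec.fixed], oracle.bse[: len(spec.fixed)],
            atol=1e-3,
        )
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)

    def test_zero_variance_generator_mixed_fit_close_to_plain_fit(self):
        # with no true random variance, freely estimated SDs stay small and
        # coefficients approach the plain cumulative-logit fit
        sim = RatingSimSpec(n_subjects=24, n_items=12, random_sds={}, seed=9,
                            n_controls=0)
        design = prepare_design(sample_ratings(sim))
        mixed = fit_clmm(design, final_model_spec(), compute_se=False)
        plain = fit_clmm(
            design, ClmmSpec(fixed=final_model_spec().fixed, random={}),
            compute_se=False,
        )
        assert all(sd < 0.4 for sd in mixed.random_sd.values())
        for t in final_model_spec().fixed:
            assert mixed.estimates[t] == pytest.approx(plain.estimates[t], abs=0.06)

    def test_thresholds_strictly_increasing_and_probs_normalize(self):
        sim = RatingSimSpec(n_subjects=12, n_items=8, seed=3)
        design = prepare_design(exclude_subjects(sample_ratings(sim))[0])
        spec = ClmmSpec(
            fixed=("sententiality", "predictability"),
            random={"subject": ("1",), "item": ("1",)},
        )
        fit = fit_clmm(design, spec)
        th = np.array(fit.thresholds)
        assert (np.diff(th) > 0).all()
        # category probabilities at a few linear predictors sum to 1
        from scipy.special import expit
        for eta in (-2.0, 0.0, 1.5):
            cum = np.concatenate([[0.0], expit(th - eta), [1.0]])
            assert np.diff(cum).sum() == pytest.approx(1.0)
            assert (np.diff(cum) >= 0).all()
        assert all(fit.std_errors[t] > 0 for t in spec.fixed)

    def test_null_model_estimates_mostly_within_two_se(self):
        spec = ClmmSpec(
            fixed=("sententiality", "predictability"),
            random={"subject": ("1",), "item": ("1",)},
        )
        hits = []
        for seed in range(40):
            sim = RatingSimSpec(
                n_subjects=12, n_items=8, fixed_effects={},
                random_sds={"subject": {"1": 0.8}, "item": {"1": 0.4}},
                n_controls=0, seed=1000 + seed,
            )
            design = prepare_design(sample_ratings(sim))
            fit = fit_clmm(design, spec)
            for t in spec.fixed:
                hits.append(abs(fit.estimates[t]) < 2 * fit.std_errors[t])
        assert np.mean(hits) >= 0.9


class TestLrTest:
    @pytest.fixture(scope="class")
    def small_design(self):
        sim = RatingSimSpec(
            n_subjects=12, n_items=8,
            fixed_effects={"sententiality": -0.9},
            random_sds={"subject": {"1": 0.8}, "item": {"1": 0.4}},
            n_controls=0, seed=21,
        )
        return prepare_design(sample_ratings(sim))

    def test_identical_models_statistic_zero_p_one(self, small_design):
        spec = ClmmSpec(fixed=("sententiality",),
                        random={"subject": ("1",), "item": ("1",)})
        fit = fit_clmm(small_design, spec, compute_se=False)
        res = lr_test(fit, fit)
        assert res.statistic == 0.0 and res.df == 0 and res.p_value == 1.0

    def test_statistic_is_twice_loglik_difference(self, small_design):
        random = {"subject": ("1",), "item": ("1",)}
        full = fit_clmm(
            small_design,
            ClmmSpec(fixed=("sententiality", "predictability"), random=random),
            compute_se=False,
        )
        reduced = fit_clmm(
            small_design, ClmmSpec(fixed=("sententiality",), random=random),
            compute_se=False,
        )
        res = lr_test(full, reduced)
        assert res.statistic == pytest.approx(
            max(0.0, 2 * (full.loglik - reduced.loglik)), abs=1e-9
        )
        assert res.df == 1

    def test_non_nested_specs_rejected(self, small_design):
        random = {"subject": ("1",), "item": ("1",)}
        a = fit_clmm(small_design, ClmmSpec(fixed=("sententiality",), random=random),
                     compute_se=False)
        b = fit_clmm(small_design, ClmmSpec(fixed=("predictability",), random=random),
                     compute_se=False)
        with pytest.raises(ValueError, match="subset"):
            lr_test(a, b)


class TestBackwardSelection:
    @pytest.fixture(scope="class")
    def design(self):
        sim = RatingSimSpec(
            n_subjects=16, n_items=8,
            fixed_effects={"sententiality": -1.2},
            random_sds={"subject": {"1": 0.6}, "item": {"1": 0.3}},
            n_controls=0, seed=33,
        )
        return prepare_design(sample_ratings(sim))

    SPEC = ClmmSpec(
        fixed=("sententiality", "predictability", "sententiality:predictability"),
        random={"subject": ("1",), "item": ("1",)},
    )

    def test_marginality_respected_and_true_effect_retained(self, design):
        final, fit, trail = backward_select(design, self.SPEC, alpha=0.05)
        assert "sententiality" in final.fixed
        # the interaction must be dropped before either main effect
        dropped = [s.term for s in trail if s.dropped]
        if "predictability" in dropped:
            assert dropped.index("sententiality:predictability") < dropped.index(
                "predictability"
            )

    def test_alpha_zero_drops_everything_droppable(self, design):
        # every p-value satisfies p >= 0, so no term is ever significant
        final, _, trail = backward_select(design, self.SPEC, alpha=0.0)
        assert final.fixed == ()
        assert all(s.dropped for s in trail)

    def test_alpha_above_any_p_keeps_full_model(self, design):
        final, _, trail = backward_select(design, self.SPEC, alpha=1.0 + 1e-9)
        assert final.fixed == self.SPEC.fixed
        assert not any(s.dropped for s in trail)


class TestLoadRatings:
    def test_column_mapping_and_validation(self, tmp_path):
        df = sample_ratings(RatingSimSpec(n_subjects=4, n_items=4, seed=0))
        renamed = df.rename(columns={"subject": "VP", "rating": "answer"})
        p = tmp_path / "r.csv"
        renamed.to_csv(p, index=False)
        got = load_ratings(p, column_map={"VP": "subject", "answer": "rating"})
        assert {"subject", "rating"} <= set(got.columns)
        report = feasibility_report(got)
        assert report["subject_exclusion"] and report["core_model"]

    def test_out_of_range_rating_rejected(self, tmp_path):
        df = sample_ratings(RatingSimSpec(n_subjects=4, n_items=4, seed=0))
        df.loc[df.index[0], "rating"] = 9
        p = tmp_path / "r.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="outside"):
            load_ratings(p)

    def test_feasibility_degrades_gracefully_without_optional_columns(self, tmp_path):
        df = sample_ratings(RatingSimSpec(n_subjects=4, n_items=4, seed=0))
        df = df[~df["is_control"]][["subject", "item", "rating"]]
        p = tmp_path / "r.csv"
        df.to_csv(p, index=False)
        got = load_ratings(p)
        report = feasibility_report(got)
        assert not report["subject_exclusion"]
        assert not report["familiarity_predictor"]
        assert not report["core_model"]
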