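import numpy as np
import pandas as pd
import pytest

from panelscreen.screen import (AnalysisSpec, MatchDecision, ModelResult,
                                ModelSkipped, binary_roc, bootstrap_auc,
                                build_subgroup, design_frame, fit_cox,
                                fit_logistic, km_stratify, match_models,
                                run_screen, screen_report,
                                time_dependent_roc, youden_cutoff)


def synth_clinical(n, rng, group="hgOvCa"):
    df = pd.DataFrame({
        "sample_id": [f"S{i:05d}" for i in range(n)],
        "group": group,
        "histotype": rng.choice(["serous", "other"], n, p=[0.8, 0.2]),
        "age": rng.normal(57, 10, n).round(1),
        "primary_tumor": rng.integers(0, 2, n),
        "chemo": (rng.choice(["none", "PC", "TP"], n)
                  if group in ("BOT", "BOT.V600E")
                  else rng.choice(["PC", "TP"], n)),
        "tp53_accumulation": rng.integers(0, 2, n),
        "figo_stage": rng.integers(1, 5, n),
        "residual_tumor": rng.choice(["none", "lt2cm", "ge2cm"], n),
        "cr": rng.integers(0, 2, n),
        "ps": rng.integers(0, 2, n),
        "microinvasion": rng.integers(0, 2, n),
        "implants": rng.integers(0, 2, n),
    })
    for ep in ("os", "dfs", "rfs"):
        df[f"{ep}_time"] = rng.exponential(40, n).round(2)
        df[f"{ep}_event"] = rng.integers(0, 2, n)
    return df


def survival_frame(n, loghr, seed, censor=0.0, p_alt=0.5):
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < p_alt).astype(float)
    t = rng.exponential(40.0 / np.exp(loghr * x))
    if censor > 0:
        c = rng.exponential(40.0 * (1 - censor) / censor, n)
        e = (t <= c).astype(float)
        t = np.minimum(t, c)
    else:
        e = np.ones(n)
    return pd.DataFrame({"gene": x, "age": rng.normal(57, 10, n),
                         "histotype_serous": rng.integers(0, 2, n).astype(float),
                         "figo_stage": rng.integers(1, 5, n).astype(float),
                         "rt_lt2cm": 0.0, "rt_ge2cm": 0.0,
                         "duration": t, "event": e},
                        index=[f"S{i}" for i in range(n)])


HG_SPEC = AnalysisSpec("hgOvCa", "OS", "G1")
CR_SPEC = AnalysisSpec("hgOvCa", "CR", "G1")


class TestAnalysisSpec:
    def test_lgovca_refused(self):
        with pytest.raises(ValueError, match="BOTS and hgOvCa"):
            AnalysisSpec("lgOvCa", "OS", "G1")

    def test_rfs_is_bots_only(self):
        with pytest.raises(ValueError, match="BOTS-only"):
            AnalysisSpec("hgOvCa", "RFS", "G1")

    def test_dfs_is_hgovca_only(self):
        with pytest.raises(ValueError, match="hgOvCa-only"):
            AnalysisSpec("BOTS", "DFS", "G1")

    def test_covariate_sets_fixed_per_class(self):
        assert AnalysisSpec("BOTS", "RFS", "G1").covariates == (
            "chemo_given", "primary_tumor", "histotype_serous", "age")
        assert HG_SPEC.covariates == (
            "histotype_serous", "figo_stage", "rt_lt2cm", "rt_ge2cm")


class TestBuildSubgroup:
    def test_filter_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        samples = synth_clinical(300, rng)
        spec = AnalysisSpec("hgOvCa", "OS", "G1", chemo="TP",
                            tp53_accumulation="no")
        sub = build_subgroup(samples, spec)
        oracle = samples[(samples["group"] == "hgOvCa")
                         & (samples["chemo"] == "TP")
                         & (samples["tp53_accumulation"] == 0)]
        assert set(sub["sample_id"]) == set(oracle["sample_id"])

    def test_any_filters_identity(self):
        rng = np.random.default_rng(1)
        samples = synth_clinical(100, rng)
        sub = build_subgroup(samples, HG_SPEC)
        assert len(sub) == 100

    def test_dfs_restricted_to_cr(self):
        rng = np.random.default_rng(2)
        samples = synth_clinical(100, rng)
        spec = AnalysisSpec("hgOvCa", "DFS", "G1")
        sub = build_subgroup(samples, spec)
        assert (sub["cr"] == 1).all()

    def test_bots_subset_selection(self):
        rng = np.random.default_rng(3)
        samples = pd.concat([synth_clinical(30, rng, "BOT"),
                             synth_clinical(20, rng, "BOT.V600E")],
                            ignore_index=True)
        samples["sample_id"] = [f"B{i}" for i in range(50)]
        spec = AnalysisSpec("BOTS", "RFS", "G1", bots_subset="BOT.V600E")
        assert (build_subgroup(samples, spec)["group"] == "BOT.V600E").all()


class TestFitCox:
    def test_planted_loghr_recovered(self):
        frame = survival_frame(2000, np.log(6.82), seed=4)
        res = fit_cox(HG_SPEC, frame, "univariable")
        assert np.log(res.estimate) == pytest.approx(np.log(6.82), abs=0.15)
        assert res.ci_low <= res.estimate <= res.ci_high
        assert res.ph_ok is not None

    def test_null_gene_near_one(self):
        frame = survival_frame(2000, 0.0, seed=5)
        res = fit_cox(HG_SPEC, frame, "univariable")
        assert res.ci_low < 1.0 < res.ci_high

    def test_zero_events_skipped(self):
        frame = survival_frame(50, 0.0, seed=6)
        frame["event"] = 0.0
        with pytest.raises(ModelSkipped, match="zero events"):
            fit_cox(HG_SPEC, frame, "univariable")

    def test_constant_gene_skipped(self):
        frame = survival_frame(50, 0.0, seed=7)
        frame["gene"] = 1.0
        with pytest.raises(ModelSkipped, match="constant gene"):
            fit_cox(HG_SPEC, frame, "univariable")

    def test_multivariable_has_covariate_table(self):
        frame = survival_frame(300, np.log(2), seed=8)
        res = fit_cox(HG_SPEC, frame, "multivariable")
        assert res.covariate_table is not None
        assert "histotype_serous" in res.covariate_table.index


class TestFitLogistic:
    @staticmethod
    def logistic_frame(n, logor, seed, p_alt=0.5):
        rng = np.random.default_rng(seed)
        x = (rng.random(n) < p_alt).astype(float)
        p = 1 / (1 + np.exp(-(0.0 + logor * x)))
        return pd.DataFrame({
            "gene": x, "histotype_serous": rng.integers(0, 2, n).astype(float),
            "figo_stage": rng.integers(1, 5, n).astype(float),
            "rt_lt2cm": 0.0, "rt_ge2cm": 0.0,
            "outcome": (rng.random(n) < p).astype(float),
        }, index=[f"S{i}" for i in range(n)])

    def test_planted_logor_recovered(self):
        frame = self.logistic_frame(2000, np.log(7.06), seed=9)
        res = fit_logistic(CR_SPEC, frame, "univariable")
        assert 5.0 <= res.estimate <= 10.0

    def test_null_or_near_one(self):
        frame = self.logistic_frame(2000, 0.0, seed=10)
        res = fit_logistic(CR_SPEC, frame, "univariable")
        assert res.ci_low < 1.0 < res.ci_high

    def test_degenerate_outcome_rejected(self):
        frame = self.logistic_frame(50, 0.0, seed=11)
        frame["outcome"] = 1.0
        with pytest.raises(ModelSkipped, match="degenerate outcome"):
            fit_logistic(CR_SPEC, frame, "univariable")

    def test_complete_separation_flagged_unstable(self):
        frame = self.logistic_frame(60, 0.0, seed=12)
        frame["outcome"] = frame["gene"]
        res = fit_logistic(CR_SPEC, frame, "univariable")
        assert res.unstable


class TestRoc:
    def test_auc_matches_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(13)
        labels = rng.integers(0, 2, 300).astype(float)
        scores = rng.normal(size=300) + labels
        roc = binary_roc(labels, scores)
        assert roc.auc == pytest.approx(
            float(roc_auc_score(labels, scores)), abs=1e-10)

    def test_auc_matches_trapezoid_quadrature(self):
        rng = np.random.default_rng(14)
        labels = rng.integers(0, 2, 100).astype(float)
        scores = rng.normal(size=100)
        roc = binary_roc(labels, scores)
        fpr = np.concatenate([[0.0], 1 - roc.specificity, [1.0]])
        tpr = np.concatenate([[0.0], roc.sensitivity, [1.0]])
        manual = float(np.sum((fpr[1:] - fpr[:-1]) * (tpr[1:] + tpr[:-1]) / 2))
        assert roc.auc == pytest.approx(manual, abs=1e-12)

    def test_event_indicator_scores_give_auc_one(self):
        rng = np.random.default_rng(15)
        t = rng.exponential(40, 200)
        e = np.ones(200)
        scores = (t <= 20).astype(float)
        roc = time_dependent_roc(scores, t, e, eval_time=20.0)
        assert roc.auc == 1.0

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(16)
        n = 4000
        t = rng.exponential(40, n)
        e = np.ones(n)
        scores = rng.normal(size=n)
        roc = time_dependent_roc(scores, t, e, eval_time=30.0)
        assert roc.auc == pytest.approx(0.5, abs=0.03)

    def test_no_cases_errors(self):
        with pytest.raises(ValueError, match="no cases"):
            time_dependent_roc(np.ones(5), np.full(5, 100.0), np.ones(5),
                               eval_time=1.0)

    def test_censored_before_eval_time_excluded(self):
        t = np.array([5.0, 5.0, 50.0, 50.0])
        e = np.array([1.0, 0.0, 0.0, 0.0])
        scores = np.array([4.0, 3.0, 2.0, 1.0])
        roc = time_dependent_roc(scores, t, e, eval_time=10.0)
        assert roc.auc == 1.0  # censored-at-5 subject dropped


class TestYouden:
    def test_perfect_classifier_j_one(self):
        labels = np.array([0, 0, 1, 1], dtype=float)
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        roc = binary_roc(labels, scores)
        cutoff, sens, spec = youden_cutoff(roc)
        assert sens + spec - 1 == pytest.approx(1.0)
        assert cutoff == pytest.approx(0.8)

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(17)
        labels = rng.integers(0, 2, 200).astype(float)
        scores = rng.normal(size=200) + 0.8 * labels
        roc = binary_roc(labels, scores)
        cutoff, sens, spec = youden_cutoff(roc)
        pos, neg = labels.sum(), (1 - labels).sum()
        best_j = max((labels[scores >= t].sum() / pos)
                     + ((1 - labels)[scores < t].sum() / neg) - 1
                     for t in np.unique(scores))
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)

    def test_uninformative_scores_j_near_zero(self):
        rng = np.random.default_rng(18)
        labels = rng.integers(0, 2, 3000).astype(float)
        scores = rng.normal(size=3000)
        cutoff, sens, spec = youden_cutoff(binary_roc(labels, scores))
        assert sens + spec - 1 == pytest.approx(0.0, abs=0.1)

    def test_tie_broken_toward_lowest_cutoff(self):
        labels = np.array([1.0, 0.0])
        scores = np.array([1.0, 1.0])  # flat curve, J = 0 everywhere
        cutoff, sens, spec = youden_cutoff(binary_roc(labels, scores))
        assert cutoff == 1.0


class TestBootstrapAuc:
    def test_deterministic_given_seed(self):
        frame = survival_frame(150, np.log(3), seed=19, censor=0.2)
        a = bootstrap_auc(HG_SPEC, frame, "univariable", B=10, seed=3)
        b = bootstrap_auc(HG_SPEC, frame, "univariable", B=10, seed=3)
        assert a == b

    def test_perfect_marker_auc_one(self):
        frame = TestFitLogistic.logistic_frame(80, 0.0, seed=20)
        frame["outcome"] = frame["gene"]
        auc = bootstrap_auc(CR_SPEC, frame, "univariable", B=5, seed=1)
        assert auc == pytest.approx(1.0)

    def test_null_marker_auc_half(self):
        frame = TestFitLogistic.logistic_frame(1000, 0.0, seed=21)
        auc = bootstrap_auc(CR_SPEC, frame, "univariable", B=20, seed=2)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_invalid_b_rejected(self):
        frame = TestFitLogistic.logistic_frame(50, 0.0, seed=22)
        with pytest.raises(ValueError):
            bootstrap_auc(CR_SPEC, frame, "univariable", B=0, seed=1)


class TestKmStratify:
    def test_unsplittable_scores_error(self):
        with pytest.raises(ValueError, match="does not split"):
            km_stratify([1.0, 2.0], [1, 1], [0.5, 0.5], cutoff=0.4)

    def test_hand_enumerated_logrank(self):
        # 6 patients, all events; verified against lifelines' own published
        # observed-minus-expected formulation
        from lifelines.statistics import logrank_test
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.ones(6)
        scores = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        out = km_stratify(t, e, scores, cutoff=0.5)
        oracle = logrank_test(t[:3], t[3:], e[:3], e[3:])
        assert out["logrank_stat"] == pytest.approx(
            float(oracle.test_statistic))
        assert out["logrank_p"] == pytest.approx(float(oracle.p_value))

    def test_strong_separation_small_p(self):
        rng = np.random.default_rng(23)
        n = 500
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(40 / np.exp(np.log(4) * x))
        out = km_stratify(t, np.ones(n), x, cutoff=0.5)
        assert out["logrank_p"] < 1e-3

    def test_km_ordering_agrees_with_cox_direction(self):
        frame = survival_frame(500, np.log(3), seed=24)
        res = fit_cox(HG_SPEC, frame, "univariable")
        assert res.estimate > 1
        out = km_stratify(frame["duration"], frame["event"], frame["gene"],
                          cutoff=0.5)
        med_high = out["curves"]["high"].median_survival_time_
        med_low = out["curves"]["low"].median_survival_time_
        assert med_high < med_low


def result(spec=HG_SPEC, mode="univariable", est=6.8, p=0.01, auc=0.75,
           boot=0.74, unstable=False):
    return ModelResult(spec=spec, mode=mode, estimate=est, ci_low=est / 2,
                       ci_high=est * 2, p_value=p, n=100,
                       auc_original=auc, auc_boot=boot, unstable=unstable)


class TestMatchModels:
    def test_matched_example(self):
        d = match_models(result(), result(mode="multivariable", auc=0.78))
        assert d.matched and d.reasons == ()

    def test_opposite_directions_fail_c2(self):
        d = match_models(result(est=1.4), result(mode="multivariable", est=0.8))
        assert not d.matched and "direction" in d.reasons

    def test_auc_exactly_floor_fails(self):
        d = match_models(result(auc=0.65),
                         result(mode="multivariable", auc=0.78))
        assert not d.matched and "auc_floor" in d.reasons

    def test_insignificant_fails(self):
        d = match_models(result(p=0.2), result(mode="multivariable"))
        assert "significance" in d.reasons

    def test_unstable_never_matches(self):
        d = match_models(result(unstable=True), result(mode="multivariable"))
        assert not d.matched and "unstable" in d.reasons

    def test_mismatched_specs_rejected(self):
        other = AnalysisSpec("hgOvCa", "OS", "G2")
        with pytest.raises(ValueError):
            match_models(result(), result(spec=other, mode="multivariable"))

    def test_monotone_in_alpha_and_floor(self):
        uni, multi = result(p=0.03), result(mode="multivariable", p=0.04)
        base = match_models(uni, multi, alpha=0.05, auc_floor=0.65)
        tighter_alpha = match_models(uni, multi, alpha=0.01, auc_floor=0.65)
        higher_floor = match_models(uni, multi, alpha=0.05, auc_floor=0.80)
        assert base.matched
        assert not tighter_alpha.matched
        assert not higher_floor.matched


class TestScreenReport:
    def test_empty_when_nothing_matched(self):
        assert screen_report({"results": [], "decisions": []}).empty

    def test_row_count_bookkeeping(self):
        uni = result()
        multi = result(mode="multivariable")
        dec = match_models(uni, multi)
        report = screen_report({"results": [(uni, multi)],
                                "decisions": [dec]})
        assert (report["term"] == "gene").sum() == 2

    def test_run_screen_skips_small_subgroups(self):
        rng = np.random.default_rng(25)
        samples = synth_clinical(5, rng)
        matrix = pd.DataFrame({"G1": [1.0, 0.0, 1.0, 0.0, 1.0]},
                              index=samples["sample_id"])
        out = run_screen(samples, matrix, [HG_SPEC], B=5, seed=0)
        assert not out["results"]
        assert any("too small" in n for n in out["notices"])
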