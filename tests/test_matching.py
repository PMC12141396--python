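"""Propensity estimation, greedy matching and balance diagnostics."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from racea.cohort import CohortSpec, generate_cohort
from racea.errors import CollinearityError, ConfigurationError, SeparationError
from racea.matching import (MatchedCohort, PropensityFit, balance_table,
                            fit_propensity, match_pairs)
from racea.records import PatientRecord

from conftest import coreset


def _patient(pid, arm, **kw):
    base = coreset(**{k: v for k, v in kw.items() if k in
                      ("sjc", "tjc", "stiffness", "vas", "haq", "esr", "crp", "rf")})
    base = base.__class__(**{**base.__dict__, "das28": 3.0})
    return PatientRecord(id=pid, arm=arm, age=kw.get("age", 50.0),
                         female=kw.get("female", True), bmi=kw.get("bmi", 22.0),
                         duration=kw.get("duration", 5.0), baseline=base)


def _fit_from_scores(scores: dict, arms: dict) -> PropensityFit:
    return PropensityFit(covariate_names=[], coefficients=np.zeros(1),
                         scores=pd.Series(scores), arms=pd.Series(arms))


class TestFitPropensity:
    def test_constant_covariate_gives_arm_fraction(self):
        recs = [_patient(f"T{i}", "TOF") for i in range(6)]
        recs += [_patient(f"A{i}", "ADA") for i in range(4)]
        fit = fit_propensity(recs, covariates=["bmi"])
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(fit.scores, 0.6, atol=1e-8)

    def test_monotone_scores_and_grid_optimum(self):
        # four hand-listed patients with overlapping covariate support (a
        # fully separated layout has no finite maximum-likelihood estimate)
        recs = [
            _patient("T1", "TOF", age=1.0), _patient("T2", "TOF", age=3.0),
            _patient("A1", "ADA", age=2.0), _patient("A2", "ADA", age=4.0),
        ]
        fit = fit_propensity(recs, covariates=["age"])
        s = fit.scores
        assert s["T1"] > s["A1"] > s["T2"] > s["A2"]

        # the IRLS optimum must beat every point of a coarse likelihood grid
        x = np.array([1.0, 3.0, 2.0, 4.0])
        y = np.array([1.0, 1.0, 0.0, 0.0])

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(y * eta - np.log1p(np.exp(eta))))

        ll_fit = loglik(fit.coefficients[0], fit.coefficients[1])
        grid = [loglik(b0, b1)
                for b0 in np.linspace(-20, 20, 81)
                for b1 in np.linspace(-8, 8, 81)]
        assert ll_fit >= max(grid) - 1e-6

    def test_confounded_cohort_separates_means(self):
        recs = generate_cohort(CohortSpec(n_per_arm=150, seed=4))
        fit = fit_propensity(recs)
        mean_tof = fit.scores[fit.arms == "TOF"].mean()
        mean_ada = fit.scores[fit.arms == "ADA"].mean()
        assert mean_tof > mean_ada

    def test_perfect_separation_raises(self):
        recs = [_patient(f"T{i}", "TOF", haq=0.2) for i in range(5)]
        recs += [_patient(f"A{i}", "ADA", haq=2.5) for i in range(5)]
        with pytest.raises(SeparationError):
            fit_propensity(recs, covariates=["haq"])

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(20):
            age = float(rng.uniform(30, 70))
            rec = _patient(f"P{i}", "TOF" if i % 2 else "ADA", age=age)
            rec.bmi = age * 0.5  # exact linear copy
            recs.append(rec)
        with pytest.raises(CollinearityError, match="bmi|age"):
            fit_propensity(recs, covariates=["age", "bmi"])

    def test_too_few_patients_rejected(self):
        recs = [_patient("T1", "TOF"), _patient("A1", "ADA")]
        with pytest.raises(ConfigurationError):
            fit_propensity(recs, covariates=["age"])


class TestMatchPairs:
    def test_identical_score_multisets_all_matched(self):
        scores = {f"T{i}": s for i, s in enumerate((0.2, 0.5, 0.8))}
        scores.update({f"A{i}": s for i, s in enumerate((0.2, 0.5, 0.8))})
        arms = {k: ("TOF" if k.startswith("T") else "ADA") for k in scores}
        cohort = match_pairs(_fit_from_scores(scores, arms), caliper_sd=math.inf)
        assert cohort.n_pairs == 3
        assert cohort.n_matched == 6
        assert all(d == pytest.approx(0.0, abs=1e-12) for _, _, d in cohort.pairs)

    def test_greedy_descending_example(self):
        scores = {"T1": 0.9, "T2": 0.5, "A1": 0.55, "A2": 0.1}
        arms = {"T1": "TOF", "T2": "TOF", "A1": "ADA", "A2": "ADA"}
        cohort = match_pairs(_fit_from_scores(scores, arms), caliper_sd=math.inf)
        assert [(t, a) for t, a, _ in cohort.pairs] == [("T1", "A1"), ("T2", "A2")]

    def test_caliper_excludes_distant_pair(self):
        scores = {"T1": 0.9, "T2": 0.5, "A1": 0.55, "A2": 0.1}
        arms = {"T1": "TOF", "T2": "TOF", "A1": "ADA", "A2": "ADA"}
        # pooled logit SD ~1.80; caliper 0.5 SD ~0.90 excludes
        # |logit 0.9 - logit 0.55| ~ 2.0 but admits |logit 0.5 - logit 0.55|
        cohort = match_pairs(_fit_from_scores(scores, arms), caliper_sd=0.5)
        assert [(t, a) for t, a, _ in cohort.pairs] == [("T2", "A1")]
        assert set(cohort.unmatched) == {"T1", "A2"}

    def test_zero_pairs_warns_not_errors(self):
        scores = {"T1": 0.99, "A1": 0.01}
        arms = {"T1": "TOF", "A1": "ADA"}
        with pytest.warns(UserWarning, match="empty matched cohort"):
            cohort = match_pairs(_fit_from_scores(scores, arms), caliper_sd=1e-6)
        assert cohort.n_pairs == 0

    def test_partial_injection_and_permutation_stability(self):
        recs = generate_cohort(CohortSpec(n_per_arm=60, seed=9))
        fit = fit_propensity(recs)
        cohort = match_pairs(fit)
        ids = [x for t, a, _ in cohort.pairs for x in (t, a)]
        assert len(ids) == len(set(ids))  # no reuse

        shuffled = list(reversed(recs))
        cohort2 = match_pairs(fit_propensity(shuffled))
        assert cohort.pairs == cohort2.pairs

    def test_fifty_eight_pairs_report_116_patients(self):
        pairs = [(f"T{i}", f"A{i}", 0.0) for i in range(58)]
        cohort = MatchedCohort(pairs=pairs, unmatched=[], caliper=math.inf)
        assert cohort.n_matched == 116


class TestBalanceTable:
    def test_identical_arms_zero_smd(self):
        recs = [_patient(f"T{i}", "TOF", age=40 + i) for i in range(5)]
        recs += [_patient(f"A{i}", "ADA", age=40 + i) for i in range(5)]
        cohort = MatchedCohort(
            pairs=[(f"T{i}", f"A{i}", 0.0) for i in range(5)],
            unmatched=[], caliper=math.inf)
        table = balance_table(recs, cohort, covariates=["age", "bmi"])
        assert np.allclose(table["smd_pre"], 0.0)
        assert np.allclose(table["smd_post"], 0.0)

    def test_hand_computed_smd(self):
        # arm means 1 and 2, each arm's variance 1 → |SMD| = 1
        d = 1 / math.sqrt(2)
        recs = [_patient("T1", "TOF", age=1 - d), _patient("T2", "TOF", age=1 + d),
                _patient("A1", "ADA", age=2 - d), _patient("A2", "ADA", age=2 + d)]
        cohort = MatchedCohort(pairs=[], unmatched=[r.id for r in recs],
                               caliper=math.inf)
        table = balance_table(recs, cohort, covariates=["age"])
        assert abs(table.loc["age", "smd_pre"]) == pytest.approx(1.0, abs=1e-12)

    def test_matching_reduces_imbalance(self):
        recs = generate_cohort(CohortSpec(n_per_arm=100, seed=2))
        fit = fit_propensity(recs)
        cohort = match_pairs(fit)
        table = balance_table(recs, cohort)
        assert table["smd_post"].abs().max() < table["smd_pre"].abs().max()

    def test_unknown_pair_ids_rejected(self):
        recs = [_patient("T1", "TOF"), _patient("A1", "ADA")]
        cohort = MatchedCohort(pairs=[("T1", "missing", 0.0)], unmatched=[],
                               caliper=math.inf)
        with pytest.raises(ConfigurationError):
            balance_table(recs, cohort, covariates=["age"])

    def test_zero_sd_unequal_means_is_infinite(self):
        recs = [_patient(f"T{i}", "TOF", age=50.0) for i in range(3)]
        recs += [_patient(f"A{i}", "ADA", age=60.0) for i in range(3)]
        cohort = MatchedCohort(pairs=[(f"T{i}", f"A{i}", 0.0) for i in range(3)],
                               unmatched=[], caliper=math.inf)
        with pytest.warns(UserWarning, match="infinite"):
            table = balance_table(recs, cohort, covariates=["age"])
        assert math.isinf(table.loc["age", "smd_pre"])

    def test_balance_reduction_across_seeds(self):
        """Matching shrinks the worst imbalance on every default cohort."""
        for seed in range(1, 21):
            recs = generate_cohort(CohortSpec(n_per_arm=100, seed=seed))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_propensity(recs)
                cohort = match_pairs(fit)
                table = balance_table(recs, cohort)
            assert cohort.n_pairs >= 20
            assert table["smd_post"].abs().max() < table["smd_pre"].abs().max()
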