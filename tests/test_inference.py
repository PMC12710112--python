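import numpy as np
import pandas as pd
import pytest

from restdyn.inference import (
    CohortDesign,
    cox_conversion,
    cross_sectional_glm,
    fdr_adjust,
    longitudinal_lmm,
)
from restdyn.io import ValidationError
from restdyn.simulate import simulate_outcomes


def cohort_frame(n, rng, group=None):
    frame = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "visit_id": "V1",
            "group": group
            if group is not None
            else np.repeat(["case", "control"], [n // 2, n - n // 2]),
            "months_from_baseline": 0.0,
            "age": rng.normal(66, 7, size=n),
            "sex": np.where(rng.random(n) < 0.5, "M", "F"),
            "education": rng.normal(14, 3, size=n),
        }
    )
    return frame


class TestCrossSectionalGlm:
    def test_noiseless_recovery_of_planted_group_effect(self, rng):
        frame = cohort_frame(40, rng)
        y = 2.0 * (frame["group"] == "case") + 0.1 * frame["age"]
        metric = pd.Series(y.to_numpy(), index=frame["subject_id"])
        res = cross_sectional_glm(metric, frame, CohortDesign(outcome="m"))
        assert res.estimate == pytest.approx(2.0, abs=1e-8)
        assert res.p_value < 1e-12

    def test_recentering_covariates_leaves_group_estimate(self, rng):
        frame = cohort_frame(60, rng)
        y = 0.4 * (frame["group"] == "case") + 0.05 * frame["age"] + rng.standard_normal(60)
        metric = pd.Series(y.to_numpy(), index=frame["subject_id"])
        res1 = cross_sectional_glm(metric, frame, CohortDesign(outcome="m"))
        shifted = frame.copy()
        shifted["age"] = shifted["age"] - 66.0
        shifted["education"] = shifted["education"] - 14.0
        res2 = cross_sectional_glm(metric, shifted, CohortDesign(outcome="m"))
        assert res1.estimate == pytest.approx(res2.estimate, abs=1e-10)
        assert res1.statistic == pytest.approx(res2.statistic, abs=1e-8)

    def test_small_group_rejected(self, rng):
        frame = cohort_frame(10, rng, group=np.array(["case"] + ["control"] * 9))
        metric = pd.Series(rng.standard_normal(10), index=frame["subject_id"])
        with pytest.raises(ValidationError, match="2 subjects"):
            cross_sectional_glm(metric, frame, CohortDesign(outcome="m"))

    def test_rank_deficient_design_rejected(self, rng):
        frame = cohort_frame(20, rng)
        frame["education"] = frame["age"]  # perfectly collinear covariates
        metric = pd.Series(rng.standard_normal(20), index=frame["subject_id"])
        with pytest.raises(ValidationError, match="rank"):
            cross_sectional_glm(metric, frame, CohortDesign(outcome="m"))


class TestLongitudinalLmm:
    def _long_frame(self, rng, n_subjects=30, months=(0.0, 24.0, 48.0)):
        rows = []
        for i in range(n_subjects):
            age, edu = rng.normal(66, 7), rng.normal(14, 3)
            sex = "M" if rng.random() < 0.5 else "F"
            for m in months:
                rows.append(
                    {"subject_id": f"s{i}", "months_from_baseline": m,
                     "age": age, "sex": sex, "education": edu}
                )
        return pd.DataFrame(rows)

    def test_planted_slope_recovered(self, rng):
        frame = self._long_frame(rng)
        slope = -0.002
        b = {f"s{i}": rng.normal(0, 0.1) for i in range(30)}
        y = [
            0.5 + b[r.subject_id] + slope * r.months_from_baseline + rng.normal(0, 0.05)
            for r in frame.itertuples()
        ]
        res = longitudinal_lmm(pd.Series(y), frame, CohortDesign(outcome="m"))
        assert np.sign(res.estimate) == -1
        assert res.estimate == pytest.approx(slope, rel=0.5)
        assert res.converged

    def test_single_visit_cohort_not_identifiable(self, rng):
        frame = self._long_frame(rng, months=(0.0,))
        with pytest.raises(ValidationError, match="single visit"):
            longitudinal_lmm(
                pd.Series(rng.standard_normal(len(frame))), frame,
                CohortDesign(outcome="m"),
            )


class TestCoxConversion:
    def _cohort(self, measure, outcomes):
        frame = outcomes.copy()
        frame["group"] = "case"
        frame["visit_id"] = "V1"
        frame["months_from_baseline"] = 0.0
        frame["age"], frame["sex"], frame["education"] = 65.0, "M", 14.0
        return frame

    def test_planted_hazard_ratio_point_estimate(self, rng):
        n = 4000
        measure = pd.Series(rng.standard_normal(n), index=[f"s{i}" for i in range(n)])
        outcomes = simulate_outcomes(
            measure, log_hazard_per_sd=np.log(1.66), censor_rate=0.3, seed=7
        )
        res = cox_conversion(measure, self._cohort(measure, outcomes))
        assert res.hazard_ratio == pytest.approx(1.66, rel=0.10)
        lo, hi = res.hazard_ratio_ci
        assert lo <= res.hazard_ratio <= hi

    def test_dlb_only_endpoint_censors_pd(self, rng):
        n = 300
        measure = pd.Series(rng.standard_normal(n), index=[f"s{i}" for i in range(n)])
        outcomes = simulate_outcomes(
            measure, log_hazard_per_sd=0.0, censor_rate=0.2, seed=11
        )
        frame = self._cohort(measure, outcomes)
        res_any = cox_conversion(measure, frame, endpoint="any_synucleinopathy")
        res_dlb = cox_conversion(measure, frame, endpoint="dlb_only")
        n_dlb = (frame["conversion_event"] == "DLB").sum()
        assert res_dlb.extra["n_events"] == n_dlb
        assert res_any.extra["n_events"] > n_dlb

    def test_affine_rescaling_invariance(self, rng):
        n = 200
        measure = pd.Series(rng.standard_normal(n), index=[f"s{i}" for i in range(n)])
        outcomes = simulate_outcomes(
            measure, log_hazard_per_sd=0.4, censor_rate=0.3, seed=5
        )
        frame = self._cohort(measure, outcomes)
        res1 = cox_conversion(measure, frame)
        res2 = cox_conversion(measure * 250.0 - 3.0, frame)
        assert res1.hazard_ratio == pytest.approx(res2.hazard_ratio, rel=1e-6)

    def test_all_censored_rejected(self, rng):
        n = 50
        measure = pd.Series(rng.standard_normal(n), index=[f"s{i}" for i in range(n)])
        outcomes = simulate_outcomes(
            measure, log_hazard_per_sd=0.0, censor_rate=1.0, seed=3
        )
        with pytest.raises(ValidationError, match="no events"):
            cox_conversion(measure, self._cohort(measure, outcomes))


class TestFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.005, 0.02, 0.04], [0.015, 0.03, 0.04]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_worked_bh_examples(self, p, expected):
        np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-12)

    def test_monotone_and_never_below_raw(self, rng):
        p = rng.random(50)
        adj = fdr_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_empty_family_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            fdr_adjust([])
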