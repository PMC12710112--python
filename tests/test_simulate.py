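import numpy as np
import pandas as pd
import pytest

from restdyn.simulate import (
    SimulationSpec,
    SpecError,
    StateSchedule,
    simulate_bold_cohort,
    simulate_outcomes,
    simulate_receptor_maps,
)
from restdyn.static import fc_matrix, network_aggregates


def small_spec(**kwargs):
    defaults = dict(
        n_cases=1, n_controls=1, n_regions=24, n_timepoints=100,
        include_seeds=False, state_schedule=None, seed=5,
    )
    defaults.update(kwargs)
    return SimulationSpec(**defaults)


class TestBoldCohort:
    def test_single_regime_within_coupling_recovered(self):
        spec = small_spec(
            n_timepoints=2000, within_network_r=0.6, between_network_r=0.0,
            group_effect=0.0, subject_coupling_sd=0.0,
        )
        cohort = simulate_bold_cohort(spec)
        agg = network_aggregates(fc_matrix(cohort.series[0]), cohort.metadata)
        within = [agg.internetwork_fc[(n, n)] for n in cohort.metadata.networks]
        assert 0.55 <= float(np.mean(within)) <= 0.65

    def test_zero_coupling_gives_near_zero_fc(self):
        spec = small_spec(
            n_timepoints=2000, within_network_r=0.0, between_network_r=0.0,
            group_effect=0.0, subject_coupling_sd=0.0,
        )
        cohort = simulate_bold_cohort(spec)
        fc = fc_matrix(cohort.series[0]).values
        off = fc[np.triu_indices_from(fc, k=1)]
        assert abs(off.mean()) <= 0.05

    def test_identical_spec_and_seed_bit_identical(self):
        a = simulate_bold_cohort(small_spec())
        b = simulate_bold_cohort(small_spec())
        for sa, sb in zip(a.series, b.series):
            np.testing.assert_array_equal(sa.values, sb.values)
        pd.testing.assert_frame_equal(a.cohort.frame, b.cohort.frame)
        pd.testing.assert_frame_equal(a.receptors.frame, b.receptors.frame)

    def test_case_visual_deficit_planted(self):
        spec = small_spec(
            n_cases=1, n_controls=1, n_timepoints=4000,
            within_network_r=0.6, group_effect=0.2, subject_coupling_sd=0.0,
        )
        cohort = simulate_bold_cohort(spec)
        by_group = {}
        for s in cohort.series:
            agg = network_aggregates(fc_matrix(s), cohort.metadata)
            group = cohort.cohort.frame.set_index("subject_id").loc[
                s.subject_id, "group"
            ]
            by_group[group] = agg.internetwork_fc[("visual", "visual")]
        assert by_group["control"] - by_group["case"] > 0.1

    def test_longitudinal_decline_planted(self):
        spec = small_spec(
            n_cases=1, n_controls=0, n_timepoints=3000,
            within_network_r=0.6, group_effect=0.0, subject_coupling_sd=0.0,
            longitudinal_slope=-0.004, visit_months=(0.0, 48.0),
        )
        cohort = simulate_bold_cohort(spec)
        within = {}
        for s in cohort.series:
            agg = network_aggregates(fc_matrix(s), cohort.metadata)
            nets = cohort.metadata.networks
            within[s.visit_id] = np.mean(
                [agg.internetwork_fc[(n, n)] for n in nets if n != "visual"]
            )
        # planted drop of 0.192 over 48 months
        assert within["V1"] - within["V2"] == pytest.approx(0.192, abs=0.06)

    def test_regime_dwell_matches_markov_mean(self):
        spec = small_spec(
            n_cases=1, n_controls=0, n_timepoints=20000, n_regions=8,
            network_sizes=(1, 1, 1, 1, 1, 1, 1, 1), group_effect=0.0,
            state_schedule=StateSchedule(mean_dwell=50.0),
        )
        cohort = simulate_bold_cohort(spec)
        labels = np.asarray(cohort.ground_truth["regime_labels"]["case001__V1"])
        runs, start = [], 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                runs.append(i - start)
                start = i
        assert np.mean(runs) == pytest.approx(50.0, rel=0.10)

    def test_non_psd_spec_rejected_before_sampling(self):
        with pytest.raises(SpecError, match="positive semi-definite"):
            SimulationSpec(
                within_network_r=0.3,
                state_schedule=StateSchedule(integrated_coupling=0.5,
                                             integrated_within_r=None),
            ).validate()

    def test_network_sizes_must_sum(self):
        with pytest.raises(SpecError, match="sum"):
            small_spec(network_sizes=(3,) * 8, n_regions=25).validate()


class TestReceptorMaps:
    def _effect(self, rng, n=400):
        return pd.Series(rng.standard_normal(n), index=[f"r{i}" for i in range(n)])

    def test_planted_rho_recovered(self, rng):
        from scipy.stats import spearmanr

        effect = self._effect(rng)
        table = simulate_receptor_maps(effect, planted_rho=0.5, n_maps=1, seed=2)
        rho = spearmanr(effect, table.frame.iloc[:, 0]).statistic
        assert 0.40 <= rho <= 0.60

    def test_null_rho_small_at_400_regions(self, rng):
        from scipy.stats import spearmanr

        effect = self._effect(rng)
        table = simulate_receptor_maps(effect, planted_rho=0.0, n_maps=1, seed=3)
        rho = spearmanr(effect, table.frame.iloc[:, 0]).statistic
        assert abs(rho) <= 0.12

    def test_perfect_rho_is_exact_rank_copy(self, rng):
        from scipy.stats import spearmanr

        effect = self._effect(rng, n=50)
        table = simulate_receptor_maps(effect, planted_rho=1.0, n_maps=1, seed=4)
        assert spearmanr(effect, table.frame.iloc[:, 0]).statistic == pytest.approx(1.0)

    def test_out_of_range_rho_rejected(self, rng):
        with pytest.raises(SpecError):
            simulate_receptor_maps(self._effect(rng, 10), planted_rho=1.5,
                                   n_maps=1, seed=0)


class TestOutcomes:
    def test_censor_rate_one_censors_everyone(self, rng):
        measure = pd.Series(rng.standard_normal(30), index=[f"s{i}" for i in range(30)])
        out = simulate_outcomes(measure, log_hazard_per_sd=0.5, censor_rate=1.0, seed=1)
        assert (out["conversion_event"] == "none").all()
        assert (out["months_to_event_or_censor"] > 0).all()

    def test_zero_variance_measure_rejected(self):
        measure = pd.Series([1.0] * 10, index=[f"s{i}" for i in range(10)])
        with pytest.raises(SpecError, match="variance"):
            simulate_outcomes(measure, log_hazard_per_sd=0.5, censor_rate=0.3, seed=1)

    def test_censor_rate_roughly_calibrated(self, rng):
        measure = pd.Series(rng.standard_normal(3000),
                            index=[f"s{i}" for i in range(3000)])
        out = simulate_outcomes(measure, log_hazard_per_sd=0.0, censor_rate=0.6, seed=9)
        frac = (out["conversion_event"] == "none").mean()
        assert frac == pytest.approx(0.6, abs=0.05)
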