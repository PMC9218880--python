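import numpy as np
import pandas as pd
import pytest

from pharmacohort.cohort import apply_eligibility, classify_user_type
from pharmacohort.adherence import adherence_outcomes
from pharmacohort.datamodel import ValidationError
from pharmacohort.exacerbation import qualifying_mask
from pharmacohort.refill_model import (RefillModel, calibrate_gap_mean,
                                       expected_pdc)
from pharmacohort.simulate import (SimulationConfig, simulate_cohort,
                                   simulate_known_effect)


def zero_rate(val=0.0):
    return {"sara": {"before": val, "after": val},
            "control": {"before": val, "after": val}}


class TestRenewalModel:
    def test_expected_pdc_decreases_with_gap_mean(self):
        pdcs = [expected_pdc(RefillModel(gap_mean=g), "after")
                for g in (0.0, 5.0, 20.0, 60.0)]
        assert all(a > b for a, b in zip(pdcs, pdcs[1:]))
        assert pdcs[0] > 99.9

    @pytest.mark.parametrize("period, target", [
        ("before", 73.29), ("after", 77.77), ("before", 70.53),
        ("after", 77.26)])
    def test_calibration_hits_target(self, period, target):
        model = calibrate_gap_mean(target, period)
        assert expected_pdc(model, period) == pytest.approx(target, abs=1e-3)

    def test_unachievable_target_raises(self):
        with pytest.raises(ValidationError):
            calibrate_gap_mean(100.5, "after")

    def test_expected_pdc_matches_monte_carlo(self):
        # fresh-start window: simulate refill chains directly
        from pharmacohort.refill_model import ChainSampler

        model = RefillModel(gap_mean=15.0)
        rng = np.random.default_rng(0)
        sampler = ChainSampler(rng)
        frailty = sampler.draw_frailty(model, 4000)
        total = 0
        for w in frailty:
            days, covers = sampler.sample_chain(model, w, 0, 364)
            covered = np.zeros(365, dtype=bool)
            for d, c in zip(days, covers):
                if d <= 364:
                    covered[max(d, 0):min(d + c, 365)] = True
            total += covered.sum()
        mc = 100.0 * total / 4000 / 365
        exact = expected_pdc(model, "after")
        assert mc == pytest.approx(exact, abs=0.5)


class TestGenerator:
    def test_same_seed_reproduces_tables_exactly(self):
        cfg = SimulationConfig(n_patients=300, seed=42)
        p1, d1 = simulate_cohort(cfg)
        p2, d2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(d1, d2)

    def test_zero_exacerbation_rate_emits_no_qualifying_courses(self):
        cfg = SimulationConfig(n_patients=400, seed=1,
                               exacerbation_rate=zero_rate(),
                               distractor_prednisone_rate=0.0)
        _, disp = simulate_cohort(cfg)
        assert not disp["atc_code"].isin(["H02AB06", "H02AB07"]).any()

    def test_distractor_courses_never_qualify(self):
        cfg = SimulationConfig(n_patients=400, seed=2,
                               exacerbation_rate=zero_rate(),
                               distractor_prednisone_rate=1.0)
        _, disp = simulate_cohort(cfg)
        pred = disp.loc[disp["atc_code"].isin(["H02AB06", "H02AB07"])]
        assert len(pred) > 50
        assert not qualifying_mask(disp).any()

    def test_zero_gap_perfect_adherence(self):
        cfg = SimulationConfig(
            n_patients=120, seed=3, gap_means=zero_rate(0.0),
            covering_days_choices=(30,), covering_days_probs=(1.0,),
            frailty_multipliers=(1.0,), frailty_probs=(1.0,),
            p_new_user=0.0, p_minor=0.0, p_missing_status=0.0,
            reliever_rate=0.0, p_nebulizer_user=0.0,
            indication_probs={"asthma": 1.0, "copd": 0.0,
                              "bronchitis": 0.0, "other": 0.0},
            p_same_day_registration=1.0)
        patients, disp = simulate_cohort(cfg)
        cohort, _ = apply_eligibility(patients, disp)
        cohort = classify_user_type(cohort, disp)
        out = adherence_outcomes(cohort, disp)
        chronic = out.loc[out["user_type"] == "chronic"]
        assert len(chronic) > 100
        assert (chronic["pdc_before"] == 100.0).all()
        assert (chronic["pdc_after"] == 100.0).all()

    def test_group_period_poisson_means_match_configuration(self):
        cfg = SimulationConfig(n_patients=20000, seed=4)
        patients, disp = simulate_cohort(cfg)
        cohort, _ = apply_eligibility(patients, disp)
        from pharmacohort.exacerbation import count_exacerbations

        counts = count_exacerbations(cohort, disp)
        for group in ("sara", "control"):
            sub = counts.loc[counts["group"] == group]
            for period, col in (("before", "count_before"),
                                ("after", "count_after")):
                lam = cfg.exacerbation_rate[group][period]
                se = np.sqrt(lam / len(sub))
                assert abs(sub[col].mean() - lam) <= 3.0 * se, \
                    (group, period, sub[col].mean(), lam)

    def test_demographic_marginals_match_configuration(self):
        cfg = SimulationConfig(n_patients=12000, seed=5)
        patients, _ = simulate_cohort(cfg)
        status = patients["status"]
        sara = patients.loc[status == "sara"]
        p_hat = len(sara) / len(patients)
        p_cfg = cfg.p_sara * (1 - cfg.p_missing_status)
        assert abs(p_hat - p_cfg) <= 3.0 * np.sqrt(p_cfg * (1 - p_cfg)
                                                   / len(patients))
        # female share among intervention patients
        p_f = (sara["gender"] == "female").mean()
        expect = cfg.p_female["sara"]
        assert abs(p_f - expect) <= 3.5 * np.sqrt(expect * (1 - expect)
                                                  / len(sara))
        # indication mix
        p_asthma = (patients["indication"] == "asthma").mean()
        assert abs(p_asthma - 0.57) <= 3.0 * np.sqrt(0.57 * 0.43
                                                     / len(patients))

    def test_all_dates_inside_simulation_horizon(self):
        cfg = SimulationConfig(n_patients=500, seed=6)
        _, disp = simulate_cohort(cfg)
        # anchors span 2017-03..2019-06; windows and bracketing records
        # extend ~3.2 years around them
        assert disp["dispense_date"].min() >= pd.Timestamp("2013-06-01")
        assert disp["dispense_date"].max() <= pd.Timestamp("2021-06-01")

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(p_sara=1.4)


class TestKnownEffect:
    def test_truth_records_injected_uplifts(self):
        cfg = SimulationConfig(n_patients=200, seed=7)
        _, _, truth = simulate_known_effect(cfg, pdc_uplift_sara=2.25,
                                            exac_uplift_diff=0.10)
        assert truth["pdc_uplift_sara"] == 2.25
        assert truth["exac_did_sara_minus_control"] == -0.10
        exp = truth["expected_pdc"]
        assert exp["sara"]["after"] - exp["control"]["after"] == \
            pytest.approx(2.25, abs=5e-3)
        assert exp["sara"]["before"] == pytest.approx(exp["control"]["before"],
                                                      abs=5e-3)

    def test_infeasible_exacerbation_uplift_raises(self):
        cfg = SimulationConfig(n_patients=50, seed=8)
        with pytest.raises(ValidationError):
            simulate_known_effect(cfg, exac_uplift_diff=5.0)

    def test_null_configuration_groups_exchangeable(self):
        cfg = SimulationConfig(n_patients=4000, seed=9)
        patients, disp, truth = simulate_known_effect(cfg, 0.0, 0.0)
        assert truth["expected_pdc"]["sara"] == \
            truth["expected_pdc"]["control"]
        cohort, _ = apply_eligibility(patients, disp)
        cohort = classify_user_type(cohort, disp)
        out = adherence_outcomes(cohort, disp)
        chronic = out.loc[out["user_type"] == "chronic"]
        means = chronic.groupby("group")["difference"].mean()
        sds = chronic.groupby("group")["difference"].std()
        ns = chronic.groupby("group").size()
        se = np.sqrt((sds["sara"] ** 2 / ns["sara"])
                     + (sds["control"] ** 2 / ns["control"]))
        assert abs(means["sara"] - means["control"]) <= 3.0 * se
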