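import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seqmediate as sm
from seqmediate.mediation_engine import monte_carlo_oracle
from seqmediate.synthetic_cohort import (CohortConfig, DiseaseModel, MediatorModel,
                                         _joint_exposure, generate_cohort,
                                         mediator_from_margin, true_mediation_effects,
                                         validate_config)


def _null_config(n=1000, disease_intercept=-2.0, **over):
    cfg = CohortConfig(
        n_participants=n,
        mediators={"ever_smoking": MediatorModel(intercept=0.0, exposure_coef=0.0),
                   "early_overweight": MediatorModel(intercept=-1.5, exposure_coef=0.0)},
        diseases={"depression": DiseaseModel(mediator="ever_smoking",
                                             intercept=disease_intercept,
                                             exposure_coef=0.0, mediator_coef=0.0,
                                             interaction_coef=0.0)},
        **over,
    )
    return cfg


class TestValidateConfig:
    def test_all_zero_coefficients_valid(self):
        cfg = _null_config(disease_intercept=0.0)
        cfg.abuse_prevalence = 0.5
        cfg.neglect_prevalence = 0.5
        cfg.exposure_correlation = 0.0
        assert validate_config(cfg) == []

    def test_positive_log_risk_intercept_flags_risk(self):
        cfg = _null_config(disease_intercept=0.1)
        msgs = validate_config(cfg)
        assert len(msgs) == 1 and "risk exceeds 1" in msgs[0]

    def test_out_of_range_prevalence_names_field(self):
        cfg = _null_config()
        cfg.abuse_prevalence = 1.2
        msgs = validate_config(cfg)
        assert any("abuse_prevalence" in m for m in msgs)

    def test_infeasible_exposure_correlation(self):
        cfg = _null_config()
        cfg.exposure_correlation = -0.99
        assert any("exposure_correlation" in m for m in validate_config(cfg))

    def test_validation_never_raises(self):
        cfg = _null_config(n=-5)
        cfg.timing.dx_age_min = 5
        msgs = validate_config(cfg)
        assert any("n_participants" in m for m in msgs)
        assert any("dx_age_min" in m for m in msgs)


class TestGenerateCohort:
    def test_empty_cohort_has_full_schema(self):
        df = generate_cohort(_null_config(n=0))
        assert len(df) == 0
        assert list(df.columns) == list(sm.synthetic_cohort.COHORT_COLUMNS)

    def test_invalid_config_raises_naming_first_violation(self):
        cfg = _null_config(disease_intercept=0.5)
        with pytest.raises(sm.ConfigurationError, match="risk exceeds 1"):
            generate_cohort(cfg)

    def test_seed_determinism(self):
        cfg = _null_config(n=500)
        a = generate_cohort(cfg, seed=42)
        b = generate_cohort(cfg, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(cfg, seed=43)
        assert not a["ever_smoked"].equals(c["ever_smoked"])

    def test_calibrated_margins(self, calibrated_cohort):
        """Every configured margin is recovered within 3 binomial SEs."""
        _, coh = calibrated_cohort
        n = len(coh)

        def check(frac, target):
            se = np.sqrt(target * (1 - target) / n)
            assert abs(frac - target) < 3 * se, (frac, target)

        from seqmediate.cohort_derivation import _score_cts_frame
        abuse, neglect, ok = _score_cts_frame(coh)
        assert ok.all()
        check(abuse.mean(), 0.1632)
        check(neglect.mean(), 0.1493)
        check((abuse | neglect).mean(), 0.2582)  # implied by the correlation knob
        check(coh["ever_smoked"].mean(), 0.5280)
        check(coh["_gen_early_overweight"].mean(), 0.1709)

    def test_null_generative_model_gives_rr_one(self):
        cfg = _null_config(n=100_000, disease_intercept=np.log(0.10))
        coh = generate_cohort(cfg, seed=5)
        from seqmediate.cohort_derivation import _score_cts_frame
        abuse, _, _ = _score_cts_frame(coh)
        y = coh["diagnosed_depression"].to_numpy()
        p1, p0 = y[abuse].mean(), y[~abuse].mean()
        se_log_rr = np.sqrt((1 - p1) / y[abuse].sum() + (1 - p0) / y[~abuse].sum())
        assert abs(np.log(p1 / p0)) < 3 * se_log_rr

    def test_temporal_coherence(self, calibrated_cohort):
        _, coh = calibrated_cohort
        for d in sm.cohort_derivation.DISEASES:
            dx = coh[f"age_at_dx_{d}"].dropna()
            assert (dx >= 18).all()
            assert (dx <= coh.loc[dx.index, "baseline_age"]).all()
        init = coh["smoking_init_age"]
        quit_ = coh["smoking_quit_age"]
        both = init.notna() & quit_.notna()
        assert (init[both] <= quit_[both]).all()
        assert (init.dropna() >= 10).all()

    def test_initiation_after_diagnosis_injection(self):
        cfg = _null_config(n=30_000, disease_intercept=np.log(0.3))
        cfg.timing.init_after_dx_fraction = 1.0
        coh = generate_cohort(cfg, seed=9)
        case_smoker = (coh["diagnosed_depression"] == 1) & (coh["ever_smoked"] == 1)
        assert case_smoker.any()
        init = coh.loc[case_smoker, "smoking_init_age"]
        dx = coh.loc[case_smoker, "age_at_dx_depression"]
        assert (init >= dx).mean() > 0.9  # injected records violate the time sequence

    def test_csv_round_trip(self, tmp_path):
        cfg = sm.calibrated_config(300, seed=3)
        coh = generate_cohort(cfg, seed=3)
        path = tmp_path / "cohort.csv"
        sm.write_cohort(coh, path)
        back = sm.read_cohort(path)
        assert len(back) == len(coh)
        pd.testing.assert_series_equal(back["ever_smoked"], coh["ever_smoked"])
        np.testing.assert_allclose(back["weight_kg_18"], coh["weight_kg_18"])


class TestMediationTruth:
    def test_no_interaction_limits(self):
        """Zero additive interaction on the risk scale (RERI = 0) zeroes the
        interaction components; zero multiplicative interaction (l3 = 0)
        makes the direct-effect RR collapse to the controlled direct RR."""
        l1, l2 = 0.4, 0.5
        # l3 chosen so exp(l1+l2+l3) - exp(l1) - exp(l2) + 1 = 0
        l3_additive_null = float(np.log(np.exp(l1) + np.exp(l2) - 1.0) - l1 - l2)
        cfg = _null_config()
        cfg.diseases["depression"] = DiseaseModel(
            mediator="ever_smoking", intercept=-3.0, exposure_coef=l1,
            mediator_coef=l2, interaction_coef=l3_additive_null)
        t = true_mediation_effects(cfg, "depression")
        assert abs(t.err_intref) < 1e-14 and abs(t.err_intmed) < 1e-14
        # multiplicative no-interaction: PDE equals the controlled direct RR
        cfg.diseases["depression"] = DiseaseModel(
            mediator="ever_smoking", intercept=-3.0, exposure_coef=l1,
            mediator_coef=l2, interaction_coef=0.0)
        t0 = true_mediation_effects(cfg, "depression")
        assert t0.rr_pde == pytest.approx(np.exp(l1), rel=1e-12)
        # ... and with no mediator main effect either, both limits coincide
        cfg.diseases["depression"] = DiseaseModel(
            mediator="ever_smoking", intercept=-3.0, exposure_coef=l1,
            mediator_coef=0.0, interaction_coef=0.0)
        tz = true_mediation_effects(cfg, "depression")
        assert tz.err_intref == 0.0 and tz.err_intmed == 0.0

    def test_blocked_mediator_path(self):
        cfg = _null_config()
        cfg.diseases["depression"] = DiseaseModel(
            mediator="ever_smoking", intercept=-3.0, exposure_coef=0.4,
            mediator_coef=0.5, interaction_coef=0.1)
        cfg.mediators["ever_smoking"] = MediatorModel(intercept=-0.5, exposure_coef=0.0)
        t = true_mediation_effects(cfg, "depression")
        assert t.rr_tie == pytest.approx(1.0, abs=1e-15)
        assert t.pm == pytest.approx(0.0, abs=1e-15)

    def test_unknown_disease_raises(self):
        with pytest.raises(KeyError, match="unknown disease"):
            true_mediation_effects(_null_config(), "gout")

    def test_truth_matches_potential_outcome_simulation(self):
        """Closed-form truth equals the Monte-Carlo potential-outcome average."""
        cfg = _null_config()
        cfg.mediators["ever_smoking"] = MediatorModel(intercept=-0.5, exposure_coef=0.4)
        cfg.diseases["depression"] = DiseaseModel(
            mediator="ever_smoking", intercept=-4.0, exposure_coef=0.2,
            mediator_coef=0.6, interaction_coef=0.1)
        t = true_mediation_effects(cfg, "depression")
        t.check_identities()
        mc = monte_carlo_oracle([-4.0, 0.2, 0.6, 0.1], [-0.5, 0.4],
                                n_draws=10**6, seed=21)
        for name in ("rr_te", "pm", "err_intmed"):
            val, se = mc[name]
            assert abs(getattr(t, name) - val) < 3 * se, name

    @given(
        g0=st.floats(-1.5, 1.5), g1=st.floats(-1.0, 1.0),
        l1=st.floats(-0.8, 0.8), l2=st.floats(-0.8, 0.8), l3=st.floats(-0.4, 0.4),
    )
    @settings(max_examples=15)
    def test_truth_consistency_property(self, g0, g1, l1, l2, l3):
        """For any valid config the analytic truth sits within the MC band."""
        cfg = _null_config()
        cfg.mediators["ever_smoking"] = MediatorModel(intercept=g0, exposure_coef=g1)
        cfg.diseases["depression"] = DiseaseModel(
            mediator="ever_smoking", intercept=-4.0, exposure_coef=l1,
            mediator_coef=l2, interaction_coef=l3)
        assert validate_config(cfg) == []
        t = true_mediation_effects(cfg, "depression")
        t.check_identities()
        mc = monte_carlo_oracle([-4.0, l1, l2, l3], [g0, g1], n_draws=200_000, seed=33)
        for name in ("rr_te", "rr_pde", "rr_tie"):
            val, se = mc[name]
            assert abs(getattr(t, name) - val) < 4 * se, name


class TestCalibration:
    def test_mediator_from_margin(self):
        mm = mediator_from_margin(0.5280, 1.23, 0.1632)
        from scipy.special import expit
        p0 = expit(mm.intercept)
        p1 = expit(mm.intercept + mm.exposure_coef)
        assert p1 / p0 == pytest.approx(1.23, rel=1e-10)
        assert (1 - 0.1632) * p0 + 0.1632 * p1 == pytest.approx(0.5280, rel=1e-10)

    def test_calibrated_config_hits_requested_effects(self):
        cfg = sm.calibrated_config(1000)
        assert validate_config(cfg) == []
        for disease, (_, _, rr, pm) in sm.synthetic_cohort.DISEASE_TARGETS.items():
            t = true_mediation_effects(cfg, disease)
            assert t.rr_te == pytest.approx(rr, rel=1e-9)
            assert t.pm == pytest.approx(pm, rel=1e-9)

    def test_pm_benchmark_solves_exactly(self):
        for target in (0.0, 0.30):
            _, truth = sm.pm_benchmark_config(target)
            assert truth.pm == pytest.approx(target, abs=1e-10)
            truth.check_identities()

    def test_joint_exposure_matches_table_overlap(self):
        cfg = sm.calibrated_config(10)
        p11 = _joint_exposure(cfg)
        either = cfg.abuse_prevalence + cfg.neglect_prevalence - p11
        assert either == pytest.approx(0.2582, abs=0.002)
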