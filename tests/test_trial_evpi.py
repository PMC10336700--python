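"""Tests for the patient-level EVPI pipeline."""

import math

import numpy as np
import pandas as pd
import pytest

from bivoi.synthetic_trial import SynthConfig, generate
from bivoi.trial_evpi import (
    EVPICurve,
    PatientRecord,
    TrialDataset,
    arm_summaries,
    evpi_bootstrap,
    evpi_unli,
    incremental_nb_params,
    patient_nb,
    rubin_pool,
    wtp_sweep,
)

ARMS = ("single", "double", "triple")


def make_dataset(nb_by_arm: dict[str, list[float]], reference: str = "single") -> TrialDataset:
    """Dataset where cost = -nb and qaly = 0, so patient NB = nb at any wtp."""
    rows = []
    i = 0
    for arm, nbs in nb_by_arm.items():
        for nb in nbs:
            rows.append({"patient_id": f"P{i}", "arm": arm, "cost": -nb, "qaly": 0.0})
            i += 1
    return TrialDataset(pd.DataFrame(rows), ARMS, reference)


class TestPatientNb:
    def test_case_study_arm_means(self):
        r = PatientRecord("a", "single", cost=2678.0, qaly=0.7092)
        assert patient_nb(r, 50_000) == pytest.approx(32_782.0)
        r2 = PatientRecord("b", "triple", cost=4042.0, qaly=0.7217)
        assert patient_nb(r2, 50_000) == pytest.approx(32_043.0)

    def test_zero_case(self):
        assert patient_nb(PatientRecord("c", "single", 0.0, 0.0), 123.0) == 0.0

    def test_missing_named_in_error(self):
        with pytest.raises(ValueError, match="'p77'"):
            patient_nb(PatientRecord("p77", "single", cost=None, qaly=0.5), 1000.0)

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            patient_nb(PatientRecord("a", "single", 1.0, 1.0), -1.0)


class TestDatasetValidation:
    def test_reference_must_be_an_arm(self):
        with pytest.raises(ValueError):
            make_dataset({a: [1.0, 2.0] for a in ARMS}, reference="quad")

    def test_undeclared_arm_label(self):
        df = pd.DataFrame(
            {"patient_id": ["a", "b", "c", "d"], "arm": ["single", "double", "triple", "oops"],
             "cost": [1.0] * 4, "qaly": [0.5] * 4}
        )
        with pytest.raises(ValueError, match="oops"):
            TrialDataset(df, ARMS, "single")

    def test_empty_arm_rejected(self):
        df = pd.DataFrame(
            {"patient_id": ["a", "b"], "arm": ["single", "double"], "cost": [1.0, 2.0],
             "qaly": [0.5, 0.6]}
        )
        with pytest.raises(ValueError, match="triple"):
            TrialDataset(df, ARMS, "single")

    def test_csv_round_trip(self, tmp_path, synth_trial):
        path = tmp_path / "trial.csv"
        synth_trial.to_csv(path)
        back = TrialDataset.from_csv(path, synth_trial.arms, synth_trial.reference)
        pd.testing.assert_frame_equal(
            back.data.reset_index(drop=True), synth_trial.data.reset_index(drop=True)
        )

    def test_records_round_trip(self):
        d = make_dataset({a: [1.0, 2.0] for a in ARMS})
        back = TrialDataset.from_records(d.records, d.arms, d.reference)
        pd.testing.assert_frame_equal(back.data, d.data)


class TestMissingPolicies:
    def test_error_policy_names_record(self, synth_trial_missing):
        with pytest.raises(ValueError, match="missing cost/qaly"):
            synth_trial_missing.resolve_missing("error")

    def test_analysis_refuses_missing(self, synth_trial_missing):
        with pytest.raises(ValueError, match="missing"):
            evpi_unli(synth_trial_missing, 50_000)

    def test_complete_case(self, synth_trial_missing):
        cc = synth_trial_missing.resolve_missing("complete-case")
        assert not cc.has_missing()
        assert len(cc.data) < len(synth_trial_missing.data)

    def test_mean_impute(self, synth_trial_missing):
        mi = synth_trial_missing.resolve_missing("mean-impute")
        assert not mi.has_missing()
        assert len(mi.data) == len(synth_trial_missing.data)
        # imputation preserves each arm's observed mean
        for arm in mi.arms:
            observed = synth_trial_missing.data.loc[
                synth_trial_missing.data["arm"] == arm, "cost"
            ].dropna()
            imputed = mi.data.loc[mi.data["arm"] == arm, "cost"]
            assert imputed.mean() == pytest.approx(observed.mean(), rel=1e-12)

    def test_unknown_policy(self, synth_trial_missing):
        with pytest.raises(ValueError, match="policy"):
            synth_trial_missing.resolve_missing("oracle")


class TestIncrementalNbParams:
    def test_exchangeable_arms_mean_zero(self):
        cfg = SynthConfig(
            n=(20_000, 20_000, 20_000),
            cost_mean=(3000.0,) * 3, cost_sd=(1500.0,) * 3,
            qaly_mean=(0.7,) * 3, qaly_sd=(0.1,) * 3,
            missing_rate=0.0, seed=13,
        )
        p = incremental_nb_params(generate(cfg), 50_000)
        # SE of each incremental mean is sigma_i itself
        assert abs(p.mu1) <= 3.0 * p.sigma1
        assert abs(p.mu2) <= 3.0 * p.sigma2

    def test_constant_reference_gives_zero_rho(self):
        d = make_dataset(
            {"single": [5.0] * 10, "double": [4.0, 6.0, 5.0, 7.0], "triple": [3.0, 8.0, 5.5, 6.5]}
        )
        p = incremental_nb_params(d, 1000.0)
        assert p.rho == pytest.approx(0.0, abs=1e-15)

    def test_variance_composition(self):
        d = make_dataset(
            {"single": [1.0, 3.0, 2.0], "double": [4.0, 6.0, 5.0, 9.0], "triple": [3.0, 8.0, 4.0]}
        )
        summaries = {s.arm: s for s in arm_summaries(d, 1000.0)}
        p = incremental_nb_params(d, 1000.0)
        v_ref = summaries["single"].var_of_mean
        assert p.sigma1**2 == pytest.approx(summaries["double"].var_of_mean + v_ref)
        assert p.sigma2**2 == pytest.approx(summaries["triple"].var_of_mean + v_ref)
        assert p.rho == pytest.approx(v_ref / (p.sigma1 * p.sigma2))

    def test_parameter_recovery(self, big_synth_trial):
        cfg, dataset = big_synth_trial
        wtp = 50_000.0
        p = incremental_nb_params(dataset, wtp)
        ref, a1, a2 = 0, 1, 2
        true_mu1 = cfg.nb_mean(a1, wtp) - cfg.nb_mean(ref, wtp)
        true_mu2 = cfg.nb_mean(a2, wtp) - cfg.nb_mean(ref, wtp)
        v = [cfg.nb_sd(k, wtp) ** 2 / cfg.n[k] for k in range(3)]
        true_sigma1 = math.sqrt(v[a1] + v[ref])
        true_sigma2 = math.sqrt(v[a2] + v[ref])
        true_rho = v[ref] / (true_sigma1 * true_sigma2)
        # means: SE of the estimated incremental mean is sigma_i
        assert abs(p.mu1 - true_mu1) <= 3.0 * true_sigma1
        assert abs(p.mu2 - true_mu2) <= 3.0 * true_sigma2
        # spread/correlation: generous 3%-scale bands (variance-of-variance
        # plus the qaly clip make these approximate)
        assert p.sigma1 == pytest.approx(true_sigma1, rel=0.03)
        assert p.sigma2 == pytest.approx(true_sigma2, rel=0.03)
        assert p.rho == pytest.approx(true_rho, abs=0.03)

    def test_tiny_arm_rejected(self):
        d = make_dataset({"single": [1.0], "double": [4.0, 6.0], "triple": [3.0, 8.0]})
        with pytest.raises(ValueError, match="n=1"):
            incremental_nb_params(d, 1000.0)


class TestEvpiUnli:
    def test_dominant_arm_gives_zero(self):
        rng = np.random.default_rng(0)
        d = make_dataset(
            {
                "single": list(1000.0 + rng.normal(0, 1, 200)),
                "double": list(rng.normal(0, 1, 200)),
                "triple": list(rng.normal(0, 1, 200)),
            }
        )
        assert evpi_unli(d, 1000.0) == pytest.approx(0.0, abs=1e-9)

    def test_reference_invariance(self, synth_trial):
        values = [
            evpi_unli(synth_trial.with_reference(arm), 50_000.0) for arm in synth_trial.arms
        ]
        base = values[0]
        assert base > 0
        for v in values[1:]:
            assert v == pytest.approx(base, rel=1e-6)

    def test_agrees_with_bootstrap(self, synth_trial):
        u = evpi_unli(synth_trial, 50_000.0)
        b, se = evpi_bootstrap(synth_trial, 50_000.0, B=1000, seed=17)
        assert abs(u - b) <= 3.0 * se


class TestEvpiBootstrap:
    def test_degenerate_data_gives_zero(self):
        d = make_dataset({a: [5.0] * 20 for a in ARMS})
        evpi, se = evpi_bootstrap(d, 1000.0, B=200, seed=0)
        assert evpi == 0.0
        assert se == 0.0

    def test_determinism(self, synth_trial):
        a = evpi_bootstrap(synth_trial, 50_000.0, B=250, seed=5)
        b = evpi_bootstrap(synth_trial, 50_000.0, B=250, seed=5)
        assert a == b

    def test_non_negative(self, synth_trial):
        evpi, _ = evpi_bootstrap(synth_trial, 25_000.0, B=250, seed=1)
        assert evpi >= 0.0

    def test_b_too_small(self, synth_trial):
        with pytest.raises(ValueError):
            evpi_bootstrap(synth_trial, 50_000.0, B=50, seed=0)


class TestRubinPool:
    def test_identical_estimates(self):
        mean = np.array([1.0, -2.0])
        cov = np.array([[2.0, 0.5], [0.5, 3.0]])
        pooled = rubin_pool([(mean, cov)] * 5)
        np.testing.assert_allclose(pooled.mean_vector, mean)
        np.testing.assert_allclose(pooled.covariance, cov)
        assert pooled.m == 5

    def test_two_point_example(self):
        cov = np.array([[1.0, 0.2], [0.2, 1.0]])
        pooled = rubin_pool([(np.zeros(2), cov), (np.full(2, 2.0), cov)])
        np.testing.assert_allclose(pooled.mean_vector, [1.0, 1.0])
        between = np.full((2, 2), 2.0)  # sample covariance of {(0,0), (2,2)}
        np.testing.assert_allclose(pooled.covariance, cov + 1.5 * between)

    def test_pooled_at_least_within(self):
        rng = np.random.default_rng(3)
        estimates = []
        for _ in range(10):
            a = rng.normal(size=(2, 2))
            estimates.append((rng.normal(size=2), a @ a.T))
        pooled = rubin_pool(estimates)
        within = np.mean([c for _, c in estimates], axis=0)
        assert np.all(np.diag(pooled.covariance) >= np.diag(within) - 1e-12)
        np.testing.assert_allclose(pooled.covariance, pooled.covariance.T)

    def test_errors(self):
        with pytest.raises(ValueError):
            rubin_pool([(np.zeros(2), np.eye(2))])
        with pytest.raises(ValueError):
            rubin_pool([(np.zeros(2), np.eye(2)), (np.zeros(3), np.eye(3))])


class TestWtpSweep:
    def test_single_point(self, synth_trial):
        curve = wtp_sweep(synth_trial, [50_000.0], B=200, seed=0)
        assert len(curve.points) == 1
        assert set(curve.points.columns) == {"wtp", "evpi_unli", "evpi_boot", "boot_se"}

    def test_methods_consistent_across_grid(self, synth_trial):
        # relative-error floor set to the bootstrap-noise scale: where EVPI is
        # a few currency units, the ratio to EVPI itself is pure MC noise
        curve = wtp_sweep(synth_trial, [25_000, 50_000, 75_000, 100_000], B=1000, seed=1)
        rel = (
            (curve.points["evpi_unli"] - curve.points["evpi_boot"]).abs()
            / curve.points["evpi_boot"].clip(lower=50.0)
        )
        assert rel.max() < 0.15

    def test_non_negative_everywhere(self, synth_trial):
        curve = wtp_sweep(synth_trial, [10_000, 40_000, 90_000], B=200, seed=2)
        assert (curve.points["evpi_unli"] >= 0).all()
        assert (curve.points["evpi_boot"] >= 0).all()

    def test_all_dominant_dataset(self):
        cfg = SynthConfig(
            cost_mean=(1000.0, 8000.0, 9000.0),
            qaly_mean=(1.1, 0.3, 0.35),
            qaly_sd=(0.02, 0.02, 0.02),
            cost_sd=(200.0, 200.0, 200.0),
            missing_rate=0.0,
            seed=8,
        )
        d = generate(cfg)
        curve = wtp_sweep(d, [25_000, 50_000, 100_000], B=200, seed=0)
        assert (curve.points["evpi_unli"] < 1e-6).all()
        assert (curve.points["evpi_boot"] < 1e-6).all()

    def test_bad_grid(self, synth_trial):
        with pytest.raises(ValueError):
            wtp_sweep(synth_trial, [], B=200, seed=0)
        with pytest.raises(ValueError):
            wtp_sweep(synth_trial, [50_000, 25_000], B=200, seed=0)

    def test_curve_requires_columns(self):
        with pytest.raises(ValueError):
            EVPICurve(points=pd.DataFrame({"wtp": [1.0]}))
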