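import numpy as np
import pytest

from cada.errors import DegenerateInputError, DomainError, JoinError
from cada.features import FeatureRecord
from cada.stats import (ClinicalRecord, correlate_severity, fit_exponential,
                        fit_linear, spearman)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, x ** 3)[0] == pytest.approx(1.0)
        assert spearman(x, -np.sqrt(x + 1))[0] == pytest.approx(-1.0)

    def test_hand_computed_instance(self):
        """rho = 1 - 6*sum(d^2)/(n(n^2-1)) on a tie-free example."""
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 5.0])
        d2 = np.sum((np.argsort(np.argsort(x)) -
                     np.argsort(np.argsort(y))) ** 2.0)
        expected = 1 - 6 * d2 / (5 * 24)
        assert spearman(x, y)[0] == pytest.approx(expected)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        r1, _ = spearman(x, y)
        r2, _ = spearman(np.exp(x), y ** 3 + 5 * y)
        assert r1 == pytest.approx(r2)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman(np.ones(10), np.arange(10.0))


class TestLinearFit:
    def test_exact_line(self):
        x = np.linspace(0, 5, 10)
        fit = fit_linear(x, 2.0 - 3.0 * x)
        assert fit.coefficients["slope"] == pytest.approx(-3.0)
        assert fit.coefficients["intercept"] == pytest.approx(2.0)
        assert fit.r2_adjusted == pytest.approx(1.0)

    def test_pure_noise_r2_near_zero(self, rng):
        x = rng.normal(size=200)
        fit = fit_linear(x, rng.normal(size=200))
        assert abs(fit.r2_adjusted) < 0.05

    def test_slope_recovery_within_2se(self, rng):
        x = rng.uniform(0, 4, 31)
        y = 40.0 - 3.0 * x + rng.normal(0, 1.0, 31)
        fit = fit_linear(x, y)
        assert abs(fit.coefficients["slope"] + 3.0) < 2 * fit.stderr["slope"]

    def test_residual_orthogonality(self, rng):
        x = rng.uniform(0, 10, 50)
        y = 1 + 2 * x + rng.normal(size=50)
        fit = fit_linear(x, y)
        resid = y - (fit.coefficients["intercept"]
                     + fit.coefficients["slope"] * x)
        assert abs(resid @ x) < 1e-8 * np.abs(y).sum() * np.abs(x).max()


class TestExponentialFit:
    def test_noiseless_recovery(self):
        x = np.linspace(0, 4, 20)
        fit = fit_exponential(x, 10.0 * np.exp(-0.5 * x))
        assert fit.coefficients["a"] == pytest.approx(10.0, abs=1e-6)
        assert fit.coefficients["b"] == pytest.approx(-0.5, abs=1e-6)
        assert fit.r2_adjusted == pytest.approx(1.0)

    def test_constant_y_no_better_than_mean(self, rng):
        x = rng.uniform(0, 3, 25)
        fit = fit_exponential(x, np.full(25, 4.0) + 1e-12 * rng.normal(size=25))
        assert fit.r2_adjusted <= 1e-6

    def test_parameter_recovery_within_2se(self, rng):
        x = rng.uniform(0, 4, 31)
        y = np.clip(40.0 * np.exp(-0.4 * x) + rng.normal(0, 2.0, 31), 0.5,
                    None)
        fit = fit_exponential(x, y)
        assert abs(fit.coefficients["a"] - 40.0) < 2 * fit.stderr["a"]
        assert abs(fit.coefficients["b"] + 0.4) < 2 * fit.stderr["b"]

    def test_nonpositive_y_rejected(self):
        with pytest.raises(DomainError):
            fit_exponential(np.arange(5.0), np.array([1, 2, 0, 3, 4.0]))


def cohort_records(rng, n=31, slope=-8.0, noise=3.0):
    feats, clin = [], []
    for i in range(n):
        smu_l, smu_r = rng.uniform(0.5, 3.0, size=2)
        mean_smu = (smu_l + smu_r) / 2
        updrs = max(1.0, 45.0 + slope * mean_smu + rng.normal(0, noise))
        sid = f"pd{i:02d}"
        feats.append(FeatureRecord(subject_id=sid, smu_left=smu_l,
                                   smu_right=smu_r))
        clin.append(ClinicalRecord(subject_id=sid, group="PD",
                                   updrs_me=updrs,
                                   updrs_me_left=updrs / 2,
                                   updrs_me_right=updrs / 2,
                                   most_affected_side="left"))
    return feats, clin


class TestCorrelateSeverity:
    def test_monotone_link_gives_negative_rho(self, rng):
        feats, clin = cohort_records(rng)
        fits = correlate_severity(feats, clin, mode="mean_smu")
        assert fits["linear"].spearman_rho < 0
        assert fits["linear"].spearman_p < 0.05

    def test_mas_uses_contralateral_side(self, rng):
        """All-left-affected cohort: x must be the right-side SMU."""
        feats, clin = cohort_records(rng, n=12)
        for c, f in zip(clin, feats):
            c.updrs_me_left = 50.0 - 10.0 * f.smu_right  # link via smu_r
        fits = correlate_severity(feats, clin, mode="mas")
        assert fits["linear"].spearman_rho == pytest.approx(-1.0)

    def test_no_overlap_raises(self, rng):
        feats, _ = cohort_records(rng, n=5)
        clin = [ClinicalRecord(subject_id="zz", group="PD", updrs_me=30.0)]
        with pytest.raises(JoinError):
            correlate_severity(feats, clin)

    def test_hc_subjects_ignored(self, rng):
        feats, clin = cohort_records(rng, n=10)
        clin.append(ClinicalRecord(subject_id=feats[0].subject_id + "x",
                                   group="HC"))
        fits = correlate_severity(feats, clin)
        assert fits["linear"].n == 10

    def test_shuffled_pairing_kills_correlation(self, rng):
        feats, clin = cohort_records(rng, n=31, noise=0.5)
        rhos = []
        for _ in range(40):
            ids = [f.subject_id for f in feats]
            shuffled = rng.permutation(ids)
            remapped = [
                ClinicalRecord(subject_id=s, group="PD", updrs_me=c.updrs_me)
                for s, c in zip(shuffled, clin)
            ]
            rhos.append(correlate_severity(feats, remapped)
                        ["linear"].spearman_rho)
        assert abs(np.mean(rhos)) < 0.15
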