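"""Variational-Laplace inversion: free-energy math and estimation behavior."""

import numpy as np
import pytest

from tcdcm import (
    BoldTimeSeries,
    DcmParameters,
    DesignSpec,
    InversionSettings,
    Priors,
    default_priors,
    free_energy,
    generate_cohort,
    hc_spec,
    invert,
    make_design,
    masks,
    simulate_bold,
)
from tcdcm.inversion import ParamMap
from tcdcm.model_space import ConnState, N_REGIONS, enumerate_models

from conftest import truth_vector

_LOG2PI = np.log(2 * np.pi)


def linear_gaussian_evidence(y, x_mat, m0, s0_var, lam):
    """Closed-form log marginal likelihood of y = X theta + e.

    theta ~ N(m0, diag(s0_var)); e has independent per-region precision
    exp(lam_r), regions blocked row-major in y.ravel().
    """
    n_out = x_mat.shape[0]
    n_per = n_out // N_REGIONS
    prec = np.repeat(np.exp(lam), n_per)
    cov = np.diag(1.0 / prec) + x_mat @ np.diag(s0_var) @ x_mat.T
    resid = y.ravel() - x_mat @ m0
    sign, logdet = np.linalg.slogdet(cov)
    return -0.5 * (
        n_out * _LOG2PI + logdet + resid @ np.linalg.solve(cov, resid)
    )


def analytic_posterior(y, x_mat, m0, s0_var, lam):
    n_per = x_mat.shape[0] // N_REGIONS
    prec = np.repeat(np.exp(lam), n_per)
    h = x_mat.T @ (x_mat * prec[:, None]) + np.diag(1.0 / s0_var)
    sigma = np.linalg.inv(h)
    mu = sigma @ (x_mat.T @ (prec * y.ravel()) + m0 / s0_var)
    return mu, (sigma + sigma.T) / 2


class TestFreeEnergy:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.n = 40
        self.p = 4
        self.x_mat = rng.normal(size=(N_REGIONS * self.n, self.p))
        self.theta_true = rng.normal(size=self.p) * 0.5
        self.lam = np.array([0.3, 0.0, -0.2, 0.1, 0.4, -0.1])
        noise = rng.normal(size=N_REGIONS * self.n) * np.repeat(
            np.exp(-self.lam / 2), self.n
        )
        self.y = (self.x_mat @ self.theta_true + noise).reshape(N_REGIONS, self.n)
        self.priors = Priors(mean=np.zeros(self.p), variance=np.full(self.p, 0.5))

    def test_zero_kl_at_prior(self):
        # prediction == data with q equal to the prior: F is the Gaussian
        # log-likelihood of zero residuals, the KL term vanishes
        sigma0 = np.diag(self.priors.variance)
        f = free_energy(
            self.y, self.y, self.priors.mean, sigma0, self.priors, self.lam
        )
        expected = sum(
            0.5 * self.n * (l - _LOG2PI) for l in self.lam
        )
        assert f == pytest.approx(expected, abs=1e-10)

    def test_matches_linear_gaussian_log_evidence(self):
        mu, sigma = analytic_posterior(
            self.y, self.x_mat, self.priors.mean, self.priors.variance, self.lam
        )
        pred = (self.x_mat @ mu).reshape(N_REGIONS, self.n)
        f = free_energy(
            self.y, pred, mu, sigma, self.priors, self.lam, jacobian=self.x_mat
        )
        evidence = linear_gaussian_evidence(
            self.y, self.x_mat, self.priors.mean, self.priors.variance, self.lam
        )
        assert f == pytest.approx(evidence, abs=1e-6)

    def test_posterior_variance_never_exceeds_prior(self):
        _, sigma = analytic_posterior(
            self.y, self.x_mat, self.priors.mean, self.priors.variance, self.lam
        )
        assert np.all(np.diag(sigma) <= self.priors.variance + 1e-12)

    def test_inert_extra_parameter_never_raises_evidence(self):
        mu, sigma = analytic_posterior(
            self.y, self.x_mat, self.priors.mean, self.priors.variance, self.lam
        )
        pred = (self.x_mat @ mu).reshape(N_REGIONS, self.n)
        f_small = free_energy(
            self.y, pred, mu, sigma, self.priors, self.lam, jacobian=self.x_mat
        )
        # an extra parameter whose outputs never move: zero Jacobian column
        x_big = np.hstack([self.x_mat, np.zeros((N_REGIONS * self.n, 1))])
        priors_big = Priors(
            mean=np.zeros(self.p + 1), variance=np.full(self.p + 1, 0.5)
        )
        mu_b, sigma_b = analytic_posterior(
            self.y, x_big, priors_big.mean, priors_big.variance, self.lam
        )
        f_big = free_energy(
            self.y, pred, mu_b, sigma_b, priors_big, self.lam, jacobian=x_big
        )
        assert f_big <= f_small + 1e-9

    def test_rejects_asymmetric_or_indefinite_sigma(self):
        sigma = np.diag(self.priors.variance)
        bad = sigma.copy()
        bad[0, 1] = 0.3
        with pytest.raises(ValueError, match="symmetric"):
            free_energy(self.y, self.y, self.priors.mean, bad, self.priors, self.lam)
        with pytest.raises(ValueError, match="positive semi-definite"):
            free_energy(
                self.y, self.y, self.priors.mean, -sigma, self.priors, self.lam
            )


class TestPriors:
    def test_free_parameter_counts(self, template, model_specs):
        saturated = default_priors(masks(model_specs[161], template))
        assert len(saturated.mean) == 13 + 5 + 5 + 2
        skeleton = default_priors(masks(model_specs[0], template))
        assert len(skeleton.mean) == 8 + 0 + 0 + 2
        assert np.all(saturated.variance > 0)

    def test_variances_by_parameter_class(self, full_mask):
        pm = ParamMap(full_mask)
        priors = default_priors(full_mask)
        for name, var in zip(pm.names, priors.variance):
            assert var == (0.25 if name.startswith("C:") else 1.0 / 16.0)


class TestInvert:
    def test_truth_at_prior_mean_recovered_exactly(self, short_design, full_mask):
        # zero coupling (the prior mean) generates silent data; the
        # posterior mean must stay at the prior mean
        data = BoldTimeSeries(
            y=np.zeros((N_REGIONS, short_design.n_scans)), tr=short_design.tr
        )
        est = invert(data, short_design, full_mask)
        assert est.converged
        assert np.max(np.abs(est.mu)) < 0.01

    def test_accepted_f_sequence_is_monotone(self, short_design, full_mask, hemo, rng):
        p = DcmParameters.zeros()
        p.c[0, :] = 0.4
        p.a[2, 0] = 0.3
        p.a[5, 2] = 0.25
        ts = simulate_bold(p, hemo, short_design, full_mask, noise_sd=1.0, seed=3)
        est = invert(ts, short_design, full_mask)
        assert np.all(np.diff(est.f_trace) >= -1e-9)
        assert len(est.f_trace) >= 2

    def test_inversion_is_deterministic(self, short_design, full_mask, hemo):
        p = DcmParameters.zeros()
        p.c[0, :] = 0.4
        p.a[2, 0] = 0.3
        ts = simulate_bold(p, hemo, short_design, full_mask, noise_sd=0.8, seed=4)
        a = invert(ts, short_design, full_mask)
        b = invert(ts, short_design, full_mask)
        assert a.free_energy == pytest.approx(b.free_energy, abs=1e-9)
        assert np.array_equal(a.mu, b.mu)

    def test_evidence_prefers_true_structure_on_noiseless_data(
        self, template, short_design, hemo
    ):
        # a strong present connection: the model containing it must beat
        # the model lacking it at the evidence level
        specs = enumerate_models(template)
        with_conn = next(
            s
            for s in specs
            if s.states[("Thal", "dPFC")] is ConnState.PRESENT
            and all(
                st is ConnState.ABSENT
                for c, st in s.states.items()
                if c != ("Thal", "dPFC")
            )
        )
        without = specs[0]
        m_with = masks(with_conn, template)
        m_without = masks(without, template)
        p = DcmParameters.zeros()
        p.c[0, :] = 0.5
        p.a[2, 0] = 0.35  # V1 -> Thal (fixed skeleton)
        p.a[5, 2] = 0.4  # Thal -> dPFC, the connection under test
        ts = simulate_bold(p, hemo, short_design, m_with, noise_sd=0.0)
        f_with = invert(ts, short_design, m_with).free_energy
        f_without = invert(ts, short_design, m_without).free_energy
        assert f_with > f_without

    def test_estimator_is_calibrated_at_snr_one(self, template, full_mask):
        # posterior SD should predict the realized error magnitude, and the
        # pooled truth/estimate correlation should clear the information
        # floor that the posterior variances imply
        design_spec = DesignSpec(n_cycles=2, microtime_bins=8)
        cohort = generate_cohort(
            hc_spec(n_subjects=5),
            hc_spec(n_subjects=2, group="OCD"),
            design_spec,
            template,
            master_seed=5,
        )
        pm = ParamMap(full_mask)
        ab = [i for i, n in enumerate(pm.names) if not n.startswith("C:")]
        errs, sds, truths, ests = [], [], [], []
        for s in cohort.group("HC"):
            est = invert(s.bold, s.design, full_mask)
            tv = truth_vector(s.truth, pm)
            errs.append((est.mu - tv)[ab])
            sds.append(np.sqrt(np.diag(est.sigma))[ab])
            truths.append(tv[ab])
            ests.append(est.mu[ab])
        rms_err = np.sqrt(np.mean(np.concatenate(errs) ** 2))
        mean_sd = np.mean(np.concatenate(sds))
        assert 0.5 < rms_err / mean_sd < 2.0
        corr = np.corrcoef(np.concatenate(truths), np.concatenate(ests))[0, 1]
        assert corr > 0.5


def test_hc_spec_accepts_group_override():
    spec = hc_spec(n_subjects=4, group="OCD")
    assert spec.group == "OCD"
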