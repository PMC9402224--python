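"""Forward model: bilinear neural dynamics and balloon-Windkessel BOLD."""

import numpy as np
import pytest
from scipy.linalg import expm

from tcdcm import (
    DcmParameters,
    DesignSpec,
    HemoParams,
    TaskDesign,
    hemodynamics,
    integrate_neural,
    make_design,
    simulate_bold,
)
from tcdcm.forward_model import IntegrationError, predict_bold
from tcdcm.model_space import N_REGIONS


def expm_neural_oracle(params, design, x0=None):
    """Piecewise-constant-input stepper via the augmented matrix exponential.

    Independent oracle for the RK4 integrator: within each microtime bin the
    system dx/dt = M x + d is linear time-invariant, so the exact step is
    exp([[M, d], [0, 0]] * dt) applied to (x, 1).
    """
    a_eff = params.a - params.self_decay * np.eye(N_REGIONS)
    dt = design.dt
    x = np.zeros(N_REGIONS) if x0 is None else np.asarray(x0, float)
    out = [x.copy()]
    cache = {}
    for t in range(design.u.shape[1]):
        u = design.u[:, t]
        key = (u[0], u[1])
        if key not in cache:
            m = a_eff + u[0] * params.b_low + u[1] * params.b_high
            d = params.c @ u
            aug = np.zeros((N_REGIONS + 1, N_REGIONS + 1))
            aug[:N_REGIONS, :N_REGIONS] = m
            aug[:N_REGIONS, N_REGIONS] = d
            cache[key] = expm(aug * dt)
        step = cache[key]
        x = step[:N_REGIONS, :N_REGIONS] @ x + step[:N_REGIONS, N_REGIONS]
        out.append(x.copy())
    return np.array(out).T


def random_stable_params(rng, scale=0.1):
    p = DcmParameters.zeros()
    p.a += rng.uniform(-scale, scale, p.a.shape) * (1 - np.eye(N_REGIONS))
    p.b_low += rng.uniform(-scale / 2, scale / 2, p.a.shape) * (1 - np.eye(N_REGIONS))
    p.b_high += rng.uniform(-scale / 2, scale / 2, p.a.shape) * (1 - np.eye(N_REGIONS))
    p.c[0, :] = 0.3
    return p


class TestNeuralIntegration:
    def test_zero_drive_stays_at_rest(self, short_design):
        x = integrate_neural(DcmParameters.zeros(), short_design)
        assert np.all(x == 0.0)

    def test_scalar_exponential_decay(self):
        # one region initialized away from rest with no input decays at
        # the self-decay rate: x(t) = exp(-0.5 t)
        design = TaskDesign(u=np.zeros((2, 160)), tr=1.6, microtime_bins=16)
        p = DcmParameters.zeros(self_decay=0.5)
        x0 = np.zeros(N_REGIONS)
        x0[0] = 1.0
        traj = expm_neural_oracle(p, design, x0=x0)
        times = np.arange(161) * design.dt
        assert np.allclose(traj[0], np.exp(-0.5 * times), atol=1e-12)
        # and the RK4 path from rest with a constant drive reaches the
        # analytic fixed point C/self_decay
        p2 = DcmParameters.zeros(self_decay=0.5)
        p2.c[0, 0] = 0.5
        design_on = TaskDesign(
            u=np.vstack([np.ones(320), np.zeros(320)]), tr=1.6, microtime_bins=16
        )
        x = integrate_neural(p2, design_on)
        assert x[0, -1] == pytest.approx(0.5 / 0.5, abs=1e-6)

    def test_rk4_matches_matrix_exponential_oracle(self, rng):
        p = random_stable_params(rng)
        design = make_design(DesignSpec(n_cycles=1, microtime_bins=260))  # dt = 0.01 s
        x_rk4 = integrate_neural(p, design)
        x_oracle = expm_neural_oracle(p, design)
        assert np.max(np.abs(x_rk4 - x_oracle)) < 1e-6

    def test_linearity_without_modulation(self, short_design, rng):
        p = random_stable_params(rng)
        p.b_low[:] = 0.0
        p.b_high[:] = 0.0
        x1 = integrate_neural(p, short_design)
        p.c *= 2.0
        x2 = integrate_neural(p, short_design)
        denom = np.max(np.abs(x2))
        assert np.max(np.abs(x2 - 2.0 * x1)) / denom < 1e-9

    def test_unstable_coupling_raises_with_bin_index(self):
        p = DcmParameters.zeros(self_decay=0.01)
        p.a[1, 0] = 3.0
        p.a[0, 1] = 3.0
        p.c[0, :] = 1.0
        design = make_design(DesignSpec(n_cycles=1, microtime_bins=16))
        with pytest.raises(IntegrationError, match="bin"):
            integrate_neural(p, design)

    def test_bounded_at_half_hertz_coupling(self):
        # all |a_ij| at 0.5 Hz with self-decay 0.5 stays bounded over 600 s
        p = DcmParameters.zeros(self_decay=0.5)
        p.a += 0.5 * (1 - np.eye(N_REGIONS)) * np.sign(
            np.sin(np.arange(36).reshape(6, 6) + 1.0)
        )
        np.fill_diagonal(p.a, 0.0)
        p.c[0, :] = 1.0
        u = np.zeros((2, 6000))
        u[0, :3000] = 1.0
        u[1, 3000:] = 1.0
        design = TaskDesign(u=u, tr=1.6, microtime_bins=16)
        x = integrate_neural(p, design)
        assert np.all(np.isfinite(x))


class TestHemodynamics:
    def test_rest_is_a_fixed_point(self, hemo):
        y = hemodynamics(np.zeros((N_REGIONS, 101)), hemo, dt=0.1)
        assert np.allclose(y, 0.0)

    def test_constant_activity_drives_flow_to_steady_state(self, hemo):
        # f converges to 1 + epsilon * x / gamma
        xbar = 0.3
        neural = np.full((N_REGIONS, 4001), xbar)
        dt = 0.1
        # recover f from the volume ODE at steady state: dv/dt = 0 implies
        # f = v**(1/alpha); check via a long integration of the full system
        y = hemodynamics(neural, hemo, dt)
        # at steady state the BOLD output must be constant
        assert abs(y[0, -1] - y[0, -100]) < 1e-8
        # independent check on f itself through a tiny reimplementation
        s = f = None
        state = np.array([0.0, 1.0, 1.0, 1.0])  # s, f, v, q

        def deriv(st):
            s_, f_, v_, q_ = st
            e = 1.0 - (1.0 - hemo.e0) ** (1.0 / f_)
            return np.array(
                [
                    hemo.epsilon * xbar - hemo.kappa * s_ - hemo.gamma * (f_ - 1.0),
                    s_,
                    (f_ - v_ ** (1.0 / hemo.alpha)) / hemo.tau,
                    (f_ * e / hemo.e0 - v_ ** (1.0 / hemo.alpha) * q_ / v_)
                    / hemo.tau,
                ]
            )

        for _ in range(40000):
            k1 = deriv(state)
            k2 = deriv(state + 0.05 * k1)
            k3 = deriv(state + 0.05 * k2)
            k4 = deriv(state + 0.1 * k3)
            state = state + 0.1 / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        f_expected = 1.0 + hemo.epsilon * xbar / hemo.gamma
        assert state[1] == pytest.approx(f_expected, abs=1e-6)

    def test_zero_efficacy_silences_bold(self, short_design, rng):
        p = random_stable_params(rng)
        hemo0 = HemoParams(epsilon=0.0)
        y = predict_bold(p, hemo0, short_design)
        assert np.allclose(y, 0.0)

    def test_negative_sustained_activity_leaves_domain(self, hemo):
        neural = np.full((N_REGIONS, 2001), -1.5)
        with pytest.raises(IntegrationError, match="positive domain"):
            hemodynamics(neural, hemo, dt=0.1)


class TestSimulateBold:
    def test_zero_drive_zero_noise_is_all_zero(self, short_design, hemo):
        ts = simulate_bold(DcmParameters.zeros(), hemo, short_design, noise_sd=0.0)
        assert np.all(ts.y == 0.0)
        assert ts.n_scans == short_design.n_scans

    def test_same_seed_is_bit_identical(self, short_design, hemo, rng):
        p = random_stable_params(rng)
        a = simulate_bold(p, hemo, short_design, noise_sd=0.4, seed=99)
        b = simulate_bold(p, hemo, short_design, noise_sd=0.4, seed=99)
        assert np.array_equal(a.y, b.y)

    def test_noise_sd_is_calibrated(self, hemo):
        # 10,000 noisy scans of a silent region: sample sd within 2% of 0.5
        design = TaskDesign(u=np.zeros((2, 10_000)), tr=1.0, microtime_bins=1)
        ts = simulate_bold(DcmParameters.zeros(), hemo, design, noise_sd=0.5, seed=7)
        assert 0.49 < ts.y[0].std() < 0.51

    def test_halving_dt_converges(self, hemo, rng):
        # epoch boundaries chosen to fall on bin edges at both resolutions,
        # so the comparison isolates integrator error from boxcar
        # quantization of the input
        p = random_stable_params(rng, scale=0.08)

        def design_at(bins):
            per_scan = bins
            n_scans = 100  # TR 2 s -> 200 s
            n_bins = n_scans * per_scan
            u = np.zeros((2, n_bins))
            starts = np.arange(n_bins) * (2.0 / bins)
            u[0, (starts >= 0) & (starts < 80)] = 1.0
            u[1, (starts >= 100) & (starts < 180)] = 1.0
            return TaskDesign(u=u, tr=2.0, microtime_bins=bins)

        y_coarse = predict_bold(p, hemo, design_at(16))
        y_fine = predict_bold(p, hemo, design_at(32))
        assert np.max(np.abs(y_coarse - y_fine)) < 1e-4

    def test_modulation_raises_task_response(self, hemo):
        # stronger Thal->dPFC low-demand modulation on a positive thalamic
        # drive increases the dPFC response during low-demand epochs
        design = make_design(DesignSpec(n_cycles=1, microtime_bins=16))
        low_bins = design.u[0].astype(bool)
        scan_low = low_bins[(np.arange(design.n_scans) + 1) * design.microtime_bins - 1]
        integrals = []
        for b in (0.0, 0.15, 0.3):
            p = DcmParameters.zeros()
            p.c[0, :] = 0.5
            p.a[2, 0] = 0.3  # V1 -> Thal
            p.a[5, 2] = 0.1  # Thal -> dPFC
            p.b_low[5, 2] = b
            y = predict_bold(p, hemo, design)
            integrals.append(y[5, scan_low].sum())
        assert integrals[0] < integrals[1] < integrals[2]
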