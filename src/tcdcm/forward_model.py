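"""Bilinear neural state equation and balloon-Windkessel observation model.

Neural dynamics follow dx/dt = (A_eff + u1 B_low + u2 B_high) x + C u with
A_eff = A - self_decay * I: the off-diagonal coupling A is free while the
diagonal is a fixed leak (default 0.5 Hz) that guarantees stability and
matches the reporting granularity of inter-regional pathways only.  The
two inputs are the low- and high-demand condition boxcars at microtime
resolution (inputs drive the neural level and are not HRF-convolved).

Each region's neural activity is read out through the balloon-Windkessel
cascade (vasodilatory signal s, blood flow f, volume v, deoxyhemoglobin q)
and the static BOLD observation equation; output is percent signal change
about zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _integrators
from .model_space import CONDITIONS, N_INPUTS, N_REGIONS, REGIONS, MaskSet

DEFAULT_SELF_DECAY = 0.5  # Hz, fixed diagonal of A


@dataclass
class DcmParameters:
    """Numeric coupling parameters (Hz) for one subject/model."""

    a: np.ndarray
    b_low: np.ndarray
    b_high: np.ndarray
    c: np.ndarray
    self_decay: float = DEFAULT_SELF_DECAY

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b_low = np.asarray(self.b_low, dtype=float)
        self.b_high = np.asarray(self.b_high, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.a.shape != (N_REGIONS, N_REGIONS) or self.c.shape != (
            N_REGIONS,
            N_INPUTS,
        ):
            raise ValueError("parameter matrices have wrong shape")
        if self.self_decay <= 0:
            raise ValueError("self_decay must be positive")

    @classmethod
    def zeros(cls, self_decay: float = DEFAULT_SELF_DECAY) -> "DcmParameters":
        z = np.zeros((N_REGIONS, N_REGIONS))
        return cls(
            a=z.copy(),
            b_low=z.copy(),
            b_high=z.copy(),
            c=np.zeros((N_REGIONS, N_INPUTS)),
            self_decay=self_decay,
        )

    def masked(self, mask: MaskSet) -> "DcmParameters":
        """Copy with entries outside the mask zeroed."""
        return replace(
            self,
            a=self.a * mask.a_mask,
            b_low=self.b_low * mask.b_mask_low,
            b_high=self.b_high * mask.b_mask_high,
            c=self.c * mask.c_mask,
        )


@dataclass
class TaskDesign:
    """Condition boxcars on the microtime grid plus scan geometry."""

    u: np.ndarray  # (2, T_micro), row 0 = low demand, row 1 = high demand
    tr: float
    microtime_bins: int
    epochs: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 2 or self.u.shape[0] != N_INPUTS:
            raise ValueError("u must be a 2 x T_micro matrix")
        if not np.isin(self.u, (0.0, 1.0)).all():
            raise ValueError("u entries must be 0 or 1")
        if np.any(self.u.sum(axis=0) > 1):
            raise ValueError("low and high demand inputs overlap")
        if self.u.shape[1] % self.microtime_bins != 0:
            raise ValueError("grid length must be a multiple of microtime_bins")

    @property
    def n_scans(self) -> int:
        return self.u.shape[1] // self.microtime_bins

    @property
    def dt(self) -> float:
        return self.tr / self.microtime_bins

    @property
    def scan_times(self) -> np.ndarray:
        """Acquisition time of each scan (end of its TR)."""
        return (np.arange(self.n_scans) + 1) * self.tr


@dataclass
class HemoParams:
    """Balloon-Windkessel constants, one value (or per-region vector) each.

    kappa: vasodilatory signal decay (Hz); gamma: flow feedback (Hz);
    tau: mean transit time (s); alpha: Grubb stiffness exponent;
    e0: resting oxygen extraction; v0: resting venous volume fraction;
    epsilon: neuronal efficacy.
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    e0: float = 0.4
    v0: float = 0.04
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "v0"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")
        if not np.all((0 < np.asarray(self.alpha)) & (np.asarray(self.alpha) < 1)):
            raise ValueError("alpha must lie in (0, 1)")
        if not np.all((0 < np.asarray(self.e0)) & (np.asarray(self.e0) < 1)):
            raise ValueError("e0 must lie in (0, 1)")
        if np.any(np.asarray(self.epsilon) < 0):
            raise ValueError("epsilon must be non-negative")

    def as_vectors(self) -> tuple[np.ndarray, ...]:
        return tuple(
            np.broadcast_to(np.asarray(getattr(self, n), dtype=float), (N_REGIONS,))
            .copy()
            for n in ("kappa", "gamma", "tau", "alpha", "e0", "v0", "epsilon")
        )


@dataclass
class BoldTimeSeries:
    """Region x scan BOLD matrix in percent-signal units."""

    y: np.ndarray  # (6, n_scans)
    tr: float
    regions: tuple[str, ...] = REGIONS

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2 or self.y.shape[0] != N_REGIONS:
            raise ValueError("y must be a 6 x n_scans matrix")
        if tuple(self.regions) != REGIONS:
            raise ValueError(f"regions must be the canonical order {REGIONS}")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("BOLD series contains non-finite values")

    @property
    def n_scans(self) -> int:
        return self.y.shape[1]


class IntegrationError(RuntimeError):
    """The forward integration left its admissible domain."""


def _effective_batch(params: DcmParameters, mask: MaskSet | None):
    p = params if mask is None else params.masked(mask)
    a_eff = p.a - p.self_decay * np.eye(N_REGIONS)
    return (
        a_eff[None, :, :].copy(),
        p.b_low[None, :, :].copy(),
        p.b_high[None, :, :].copy(),
        p.c[None, :, :].copy(),
    )


def neural_midpoints(
    x_batch: np.ndarray,
    a_eff: np.ndarray,
    b_low: np.ndarray,
    b_high: np.ndarray,
    c: np.ndarray,
    u: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Hermite half-step values of a neural trajectory, per microtime bin.

    Uses the exact derivative dx/dt = M x + C u at both bin edges (with the
    bin's own piecewise-constant input), so the balloon stage sees the
    trajectory to the same order as the RK4 that produced it.
    x_batch : (B, T+1, R) -> (B, T, R).
    """
    nb, nt1, nr = x_batch.shape
    nt = nt1 - 1
    xm = np.empty((nb, nt, nr))
    # contiguous segments of constant input
    change = np.flatnonzero(np.any(np.diff(u, axis=1) != 0, axis=0)) + 1
    bounds = np.concatenate(([0], change, [nt]))
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        m = a_eff + u[0, t0] * b_low + u[1, t0] * b_high
        drive = c @ u[:, t0]  # (B, R)
        xl = x_batch[:, t0:t1, :]
        xr = x_batch[:, t0 + 1 : t1 + 1, :]
        xd_l = np.einsum("brs,bts->btr", m, xl) + drive[:, None, :]
        xd_r = np.einsum("brs,bts->btr", m, xr) + drive[:, None, :]
        xm[:, t0:t1, :] = 0.5 * (xl + xr) + (dt / 8.0) * (xd_l - xd_r)
    return xm


def integrate_neural(
    params: DcmParameters, design: TaskDesign, mask: MaskSet | None = None
) -> np.ndarray:
    """Neural trajectory (6, T_micro+1) at bin edges, starting from rest.

    Classical RK4 with fixed step dt = tr / microtime_bins; the condition
    boxcar is constant within each bin.
    """
    a_eff, bl, bh, c = _effective_batch(params, mask)
    x = _integrators.neural_rk4(a_eff, bl, bh, c, design.u, design.dt)[0]
    if not np.all(np.isfinite(x)):
        bad = int(np.argwhere(~np.isfinite(x).all(axis=1))[0, 0])
        raise IntegrationError(
            f"neural trajectory became non-finite at microtime bin {bad} "
            f"(t = {bad * design.dt:.3f} s); coupling is likely unstable"
        )
    return x.T


def hemodynamics(
    neural: np.ndarray,
    hemo: HemoParams,
    dt: float,
    neural_midpoints_: np.ndarray | None = None,
) -> np.ndarray:
    """BOLD trajectory (6, T_micro+1) from a neural trajectory at bin edges.

    ``neural_midpoints_`` (6, T_micro) supplies the trajectory's half-step
    values for the RK4 intermediate stages; when omitted they are estimated
    by Hermite interpolation with finite-difference edge slopes.
    """
    x = np.asarray(neural, dtype=float)
    if x.shape[0] != N_REGIONS:
        raise ValueError("neural trajectory must have 6 region rows")
    if not np.all(np.isfinite(x)):
        raise ValueError("neural trajectory must be finite")
    xb = x.T[None, :, :].copy()
    if neural_midpoints_ is None:
        xd = np.gradient(xb, dt, axis=1)
        xm = 0.5 * (xb[:, :-1] + xb[:, 1:]) + (dt / 8.0) * (
            xd[:, :-1] - xd[:, 1:]
        )
    else:
        xm = np.ascontiguousarray(neural_midpoints_.T)[None, :, :]
    kappa, gamma, tau, alpha, e0, v0, eps = hemo.as_vectors()
    y, bad = _integrators.balloon_rk4(
        xb, np.ascontiguousarray(xm), kappa, gamma, tau, alpha, e0, v0, eps, dt
    )
    if bad >= 0:
        raise IntegrationError(
            f"balloon state (f, v or q) left the positive domain at bin {bad}"
        )
    return y[0].T


def predict_bold(
    params: DcmParameters,
    hemo: HemoParams,
    design: TaskDesign,
    mask: MaskSet | None = None,
) -> np.ndarray:
    """Noiseless BOLD prediction g(theta): (6, n_scans) at scan acquisitions."""
    p = params if mask is None else params.masked(mask)
    a_eff, bl, bh, c = _effective_batch(p, None)
    x = integrate_neural(params, design, mask)
    xm = neural_midpoints(
        np.ascontiguousarray(x.T)[None, :, :], a_eff, bl, bh, c, design.u, design.dt
    )
    y_micro = hemodynamics(x, hemo, design.dt, neural_midpoints_=xm[0].T)
    return sample_at_scans(y_micro, design)


def sample_at_scans(y_micro: np.ndarray, design: TaskDesign) -> np.ndarray:
    """Take the microtime value at each scan's acquisition bin (end of TR)."""
    idx = (np.arange(design.n_scans) + 1) * design.microtime_bins
    return y_micro[:, idx]


def simulate_bold(
    params: DcmParameters,
    hemo: HemoParams,
    design: TaskDesign,
    mask: MaskSet | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> BoldTimeSeries:
    """Forward-simulate one subject's scan-resolution BOLD series.

    ``noise_sd`` is the standard deviation of i.i.d. Gaussian scanner noise
    in percent-signal units; 0 gives the deterministic prediction.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    y = predict_bold(params, hemo, design, mask)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return BoldTimeSeries(y=y, tr=design.tr)
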