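"""Random-effects Bayesian model selection over a group's free energies.

Treats the generating model as a random effect across subjects: model
frequencies r follow a Dirichlet posterior whose concentrations are found
by the standard variational fixed point (Stephan-style RFX-BMS).  Expected
probabilities are the Dirichlet mean; exceedance probabilities (chance a
model is the most frequent in the population) are estimated by seeded
Monte Carlo over Dirichlet draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma


@dataclass
class EvidenceMatrix:
    """Per-subject, per-model free energies (nats), columns in space order."""

    f: np.ndarray  # (n_subjects, n_models)
    subject_ids: tuple[str, ...] = ()
    model_ids: tuple[int, ...] = ()
    group: str = ""

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 2:
            raise ValueError("evidence matrix must be 2-D")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("free energies must be finite")
        if not self.subject_ids:
            self.subject_ids = tuple(f"sub-{i:03d}" for i in range(self.f.shape[0]))
        if not self.model_ids:
            self.model_ids = tuple(range(self.f.shape[1]))


@dataclass
class BmsResult:
    alpha: np.ndarray
    expected_prob: np.ndarray
    exceedance_prob: np.ndarray | None
    n_iter: int
    converged: bool
    model_ids: tuple[int, ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "model_ids": list(self.model_ids),
            "alpha": self.alpha.tolist(),
            "expected_prob": self.expected_prob.tolist(),
            "exceedance_prob": None
            if self.exceedance_prob is None
            else self.exceedance_prob.tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def rfx_bms(
    ev: EvidenceMatrix,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    n_exceedance_samples: int = 100_000,
    seed: int | np.random.Generator | None = 0,
) -> BmsResult:
    """Variational Dirichlet posterior over model frequencies.

    Iterates u_nk proportional to exp(F_nk + psi(alpha_k) - psi(sum alpha))
    with per-subject recentring of F for overflow safety (a pure shift of a
    subject's row cancels in the normalization), then alpha_k = alpha0 +
    sum_n u_nk, until max |delta alpha| < tol.
    """
    f = ev.f
    n, k = f.shape
    if k < 2:
        raise ValueError("need at least two models")
    f = f - f.max(axis=1, keepdims=True)
    alpha = np.full(k, alpha0, dtype=float)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_u = f + digamma(alpha) - digamma(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    expected = alpha / alpha.sum()
    xp = exceedance(alpha, n_samples=n_exceedance_samples, seed=seed)
    return BmsResult(
        alpha=alpha,
        expected_prob=expected,
        exceedance_prob=xp,
        n_iter=it,
        converged=converged,
        model_ids=ev.model_ids,
    )


def exceedance(
    alpha: np.ndarray,
    n_samples: int = 100_000,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet(alpha) posterior.

    Frequency with which each component is the largest across seeded draws;
    argmax ties break to the first index (a probability-zero event for
    continuous draws).  The output is a partition's frequencies and sums to
    one exactly.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = int(n_samples)
    counts = np.zeros(len(alpha), dtype=np.int64)
    chunk = 20_000
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        draws = rng.dirichlet(alpha, size=m)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=len(alpha))
        done += m
    return counts / n_samples
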