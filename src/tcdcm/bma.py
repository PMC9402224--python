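"""Bayesian model averaging of coupling parameters inside Occam's window.

Models whose group-level expected probability falls within a fixed odds
ratio of the best model form the window; per-subject parameter estimates
are then averages over posterior draws, sampling a model from the window
weights and a parameter vector from that model's subject posterior, with
parameters absent from the drawn model contributing zero.  The average is
expressed on the full saturated parameterization (13 intrinsic + 2 x 5
modulation + 2 driving parameters) so subjects and groups share one
parameter naming regardless of which models entered the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inversion import ParamMap, PosteriorEstimate
from .model_space import MaskSet, ModelSpec, NetworkTemplate, full_model, masks


def occams_window(
    expected_prob: np.ndarray,
    model_ids: list[int] | None = None,
    ratio: float = 1.0 / 20.0,
) -> tuple[list[int], np.ndarray]:
    """Models whose probability exceeds ``ratio`` times the best model's.

    Returns the retained model ids and their renormalized weights.
    """
    p = np.asarray(expected_prob, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("expected probabilities must sum to 1")
    if model_ids is None:
        model_ids = list(range(len(p)))
    keep = p / p.max() > ratio
    w = p[keep]
    return [m for m, k in zip(model_ids, keep) if k], w / w.sum()


@dataclass
class BmaResult:
    """Sampled model-averaged parameters, one row per subject."""

    subject_ids: tuple[str, ...]
    param_names: tuple[str, ...]
    means: np.ndarray  # (n_subjects, n_params)
    mc_se: np.ndarray  # (n_subjects, n_params)
    window_model_ids: tuple[int, ...]
    window_weights: np.ndarray
    n_samples: int
    seed: int | None


def bma_average(
    posteriors: dict[tuple[str, int], PosteriorEstimate],
    window_model_ids: list[int],
    window_weights: np.ndarray,
    template: NetworkTemplate,
    model_masks: dict[int, MaskSet],
    n_samples: int = 20_000,
    seed: int | None = 0,
) -> BmaResult:
    """Monte-Carlo model averaging over the window for every subject.

    ``posteriors`` maps (subject_id, model_id) to that pair's variational
    posterior; every window model must be present for every subject.
    """
    window_weights = np.asarray(window_weights, dtype=float)
    if len(window_model_ids) == 0:
        raise ValueError("Occam's window is empty")
    if not np.isclose(window_weights.sum(), 1.0, atol=1e-9):
        raise ValueError("window weights must sum to 1")
    subject_ids = sorted({s for s, _ in posteriors})
    missing = [
        (s, m)
        for s in subject_ids
        for m in window_model_ids
        if (s, m) not in posteriors
    ]
    if missing:
        raise KeyError(f"missing posteriors for (subject, model) pairs: {missing}")

    full_map = ParamMap(masks(full_model(template), template))
    maps = {m: ParamMap(model_masks[m]) for m in window_model_ids}
    embed_idx = {
        m: np.array(
            [full_map.names.index(name) for name in maps[m].names], dtype=int
        )
        for m in window_model_ids
    }

    rng = np.random.default_rng(seed)
    # one multinomial split of the samples over window models, shared by all
    # subjects (group-level weights)
    counts = rng.multinomial(n_samples, window_weights)
    n_sub = len(subject_ids)
    n_par = full_map.n_free
    sums = np.zeros((n_sub, n_par))
    sq = np.zeros((n_sub, n_par))
    for m, n_m in zip(window_model_ids, counts):
        if n_m == 0:
            continue
        idx = embed_idx[m]
        for si, s in enumerate(subject_ids):
            post = posteriors[(s, m)]
            cov = post.sigma + 1e-12 * np.eye(len(post.mu))
            draws = rng.multivariate_normal(post.mu, cov, size=n_m, method="cholesky")
            full = np.zeros((n_m, n_par))
            full[:, idx] = draws
            sums[si] += full.sum(axis=0)
            sq[si] += (full**2).sum(axis=0)
    means = sums / n_samples
    var = sq / n_samples - means**2
    mc_se = np.sqrt(np.maximum(var, 0.0) / n_samples)
    return BmaResult(
        subject_ids=tuple(subject_ids),
        param_names=full_map.names,
        means=means,
        mc_se=mc_se,
        window_model_ids=tuple(window_model_ids),
        window_weights=window_weights,
        n_samples=n_samples,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )


def analytic_bma_mean(
    posteriors: dict[tuple[str, int], PosteriorEstimate],
    subject_id: str,
    window_model_ids: list[int],
    window_weights: np.ndarray,
    template: NetworkTemplate,
    model_masks: dict[int, MaskSet],
) -> np.ndarray:
    """Closed-form mixture mean sum_k w_k mu_k (embedded), for validation."""
    full_map = ParamMap(masks(full_model(template), template))
    out = np.zeros(full_map.n_free)
    for m, w in zip(window_model_ids, np.asarray(window_weights, dtype=float)):
        pm = ParamMap(model_masks[m])
        out += w * pm.embed(posteriors[(subject_id, m)].mu, full_map)
    return out
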