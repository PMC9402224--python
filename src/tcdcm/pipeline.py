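"""End-to-end pipeline driver: cohort -> inversion -> BMS -> BMA -> stats.

Stages run in order with per-(subject, model) inversion results cached on
disk, keyed by a content hash of the data, mask, priors and settings, so a
full-space run is resumable and a warm rerun performs zero new inversions.
Outputs are a pure function of (inputs, config, seeds).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tcio
from .bma import bma_average, occams_window
from .bms import BmsResult, EvidenceMatrix, rfx_bms
from .forward_model import HemoParams
from .group_stats import GroupParameterTable, build_stats_table
from .inversion import InversionSettings, ParamMap, PosteriorEstimate, default_priors, invert
from .model_space import default_template, enumerate_models, masks
from .synthetic_data import DesignSpec, SyntheticCohort, generate_cohort, hc_spec, ocd_spec

log = logging.getLogger("tcdcm")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, in one serializable object."""

    out_dir: str = "tcdcm_out"
    cohort_dir: str | None = None  # None -> simulate a synthetic cohort
    master_seed: int = 0
    n_hc: int = 32
    n_ocd: int = 30
    n_cycles: int = 2
    microtime_bins: int = 16
    subspace: list[int] | None = None  # model ids; None -> full space
    alpha0: float = 1.0
    window_ratio: float = 1.0 / 20.0
    bma_samples: int = 20_000
    exceedance_samples: int = 100_000
    stats_alpha: float = 0.05
    max_iter: int = 64
    tol: float = 0.01
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def inversion_plan(config: RunConfig) -> dict:
    """Job count the pipeline will schedule, reported before execution."""
    n_models = (
        len(config.subspace)
        if config.subspace is not None
        else default_template().n_models
    )
    n_subjects = config.n_hc + config.n_ocd
    plan = {
        "n_subjects": n_subjects,
        "n_models": n_models,
        "n_fits": n_subjects * n_models,
    }
    log.info(
        "inversion plan: %d subjects x %d models = %d fits",
        n_subjects,
        n_models,
        plan["n_fits"],
    )
    return plan


def load_or_generate_cohort(config: RunConfig) -> SyntheticCohort:
    if config.cohort_dir is not None:
        return read_cohort(config.cohort_dir, microtime_bins=config.microtime_bins)
    design_spec = DesignSpec(
        n_cycles=config.n_cycles, microtime_bins=config.microtime_bins
    )
    return generate_cohort(
        hc_spec(n_subjects=config.n_hc),
        ocd_spec(n_subjects=config.n_ocd),
        design_spec,
        default_template(),
        master_seed=config.master_seed,
    )


def read_cohort(cohort_dir: str | Path, microtime_bins: int = 16) -> SyntheticCohort:
    """Load a TSV/JSON cohort bundle written by the synthetic generator."""
    from .synthetic_data import SubjectDataset

    d = Path(cohort_dir)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    epochs = tcio.read_events(d / "design.tsv")
    subjects = []
    design = None
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        bold = tcio.read_timeseries(d / f"{sid}_bold.tsv")
        if design is None:
            design = tcio.design_from_events(
                epochs,
                tr=manifest.get("tr_s", bold.tr),
                microtime_bins=manifest.get("microtime_bins", microtime_bins),
                total_s=bold.n_scans * bold.tr,
            )
        subjects.append(
            SubjectDataset(
                subject_id=sid, group=entry["group"], bold=bold, design=design
            )
        )
    return SyntheticCohort(
        subjects=subjects,
        design=design,
        master_seed=manifest.get("master_seed", -1),
        noise_sd=manifest.get("noise_sd", {}),
    )


def _cache_key(subject, mask, priors, settings) -> str:
    return tcio.content_hash(
        subject.bold.y,
        np.asarray(mask.a_mask),
        np.asarray(mask.b_mask_low),
        np.asarray(mask.c_mask),
        priors.mean,
        priors.variance,
        priors.noise_log_precision_prior,
        settings.max_iter,
        settings.tol,
        settings.fd_step,
        settings.self_decay,
    )


def invert_all(
    cohort: SyntheticCohort,
    model_specs,
    template,
    settings: InversionSettings,
    cache_dir: str | Path | None = None,
) -> tuple[dict[tuple[str, int], PosteriorEstimate], int]:
    """Invert every (subject, model) pair, reusing cached results.

    Returns the posterior dict and the number of fresh (non-cached)
    inversions performed.
    """
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    n_jobs = len(cohort.subjects) * len(model_specs)
    log.info(
        "inversion plan: %d subjects x %d models = %d fits",
        len(cohort.subjects),
        len(model_specs),
        n_jobs,
    )
    posteriors: dict[tuple[str, int], PosteriorEstimate] = {}
    fresh = 0
    for spec in model_specs:
        mask = masks(spec, template)
        priors = default_priors(mask)
        pm = ParamMap(mask)
        for subject in cohort.subjects:
            key = (subject.subject_id, spec.model_id)
            cache_file = (
                cache / f"{_cache_key(subject, mask, priors, settings)}.json"
                if cache is not None
                else None
            )
            if cache_file is not None and cache_file.exists():
                posteriors[key] = _read_posterior(cache_file, pm)
                continue
            t0 = time.time()
            est = invert(subject.bold, subject.design, mask, priors, settings)
            fresh += 1
            log.info(
                "inverted %s model %d: F=%.2f iters=%d converged=%s (%.2fs)",
                subject.subject_id,
                spec.model_id,
                est.free_energy,
                est.n_iter,
                est.converged,
                time.time() - t0,
            )
            posteriors[key] = est
            if cache_file is not None:
                _write_posterior(est, spec.model_id, cache_file)
    return posteriors, fresh


def _write_posterior(est: PosteriorEstimate, model_id: int, path: Path) -> None:
    tcio.write_json(
        {
            "model_id": model_id,
            "F": est.free_energy,
            "mu": est.mu,
            "sigma": est.sigma,
            "lambda": est.lam,
            "n_iter": est.n_iter,
            "converged": est.converged,
            "param_names": list(est.param_names),
        },
        path,
    )


def _read_posterior(path: Path, pm: ParamMap) -> PosteriorEstimate:
    with open(path) as fh:
        d = json.load(fh)
    return PosteriorEstimate(
        mu=np.asarray(d["mu"]),
        sigma=np.asarray(d["sigma"]),
        free_energy=d["F"],
        lam=np.asarray(d["lambda"]),
        n_iter=d["n_iter"],
        converged=d["converged"],
        param_names=tuple(d["param_names"]),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts; returns a result summary."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    template = default_template()
    all_specs = enumerate_models(template)
    if config.subspace is not None:
        spec_by_id = {s.model_id: s for s in all_specs}
        model_specs = [spec_by_id[m] for m in config.subspace]
    else:
        model_specs = all_specs
    settings = InversionSettings(max_iter=config.max_iter, tol=config.tol)

    stage = "cohort"
    try:
        cohort = load_or_generate_cohort(config)
        if config.cohort_dir is None:
            from .synthetic_data import write_cohort

            write_cohort(cohort, out / "cohort")

        stage = "inversion"
        posteriors, fresh = invert_all(
            cohort, model_specs, template, settings, cache_dir=out / "cache"
        )

        stage = "bms"
        results: dict[str, dict] = {}
        seed_root = np.random.SeedSequence(config.master_seed)
        group_tables = {}
        for gi, group in enumerate(("HC", "OCD")):
            members = cohort.group(group)
            if not members:
                continue
            f = np.array(
                [
                    [posteriors[(s.subject_id, m.model_id)].free_energy for m in model_specs]
                    for s in members
                ]
            )
            ev = EvidenceMatrix(
                f=f,
                subject_ids=tuple(s.subject_id for s in members),
                model_ids=tuple(m.model_id for m in model_specs),
                group=group,
            )
            tcio.write_evidence(ev, out / f"evidence_{group}.tsv")
            bms_res = rfx_bms(
                ev,
                alpha0=config.alpha0,
                n_exceedance_samples=config.exceedance_samples,
                seed=np.random.default_rng(seed_root.spawn(1)[0]),
            )
            tcio.write_json(bms_res.to_json_dict(), out / f"bms_{group}.json")

            window_ids, weights = occams_window(
                bms_res.expected_prob,
                model_ids=list(ev.model_ids),
                ratio=config.window_ratio,
            )
            model_masks = {
                m.model_id: masks(m, template)
                for m in model_specs
                if m.model_id in window_ids
            }
            bma_res = bma_average(
                {k: v for k, v in posteriors.items() if k[0] in ev.subject_ids},
                window_ids,
                weights,
                template,
                model_masks,
                n_samples=config.bma_samples,
                seed=config.master_seed + 1000 + gi,
            )
            _write_bma(bma_res, out / f"bma_{group}.tsv", out / f"bma_{group}.json")
            group_tables[group] = GroupParameterTable(
                group=group,
                subject_ids=bma_res.subject_ids,
                param_names=bma_res.param_names,
                values=bma_res.means,
            )
            results[group] = {
                "bms": bms_res.to_json_dict(),
                "window": list(window_ids),
            }

        stage = "stats"
        stats = build_stats_table(
            group_tables["HC"], group_tables["OCD"], alpha=config.stats_alpha
        )
        tcio.write_stats_table(stats, out / "stats.tsv")

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "n_subjects": len(cohort.subjects),
            "n_models": len(model_specs),
            "n_inversions_planned": len(cohort.subjects) * len(model_specs),
            "n_inversions_fresh": fresh,
            "groups": results,
        }
        tcio.write_json(manifest, out / "manifest.json")
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    return {"stats": stats, "manifest": manifest, "posteriors": posteriors}


def _write_bma(bma_res, tsv_path: Path, json_path: Path) -> None:
    import pandas as pd

    df = pd.DataFrame(bma_res.means, columns=list(bma_res.param_names))
    df.insert(0, "subject_id", list(bma_res.subject_ids))
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")
    tcio.write_json(
        {
            "window_model_ids": list(bma_res.window_model_ids),
            "window_weights": bma_res.window_weights,
            "n_samples": bma_res.n_samples,
            "seed": bma_res.seed,
        },
        json_path,
    )
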