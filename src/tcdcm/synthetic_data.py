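"""Synthetic CPT-IP cohorts with the generative structure the analysis assumes.

The task design emulates the identical-pairs continuous performance
paradigm: 120 s task epochs (rapid 50 ms digit presentations at a 250 ms
SOA, alternating low/high attention demand) separated by 20 s rests,
sampled at TR 2.6 s.  Individual stimulus events are deliberately not
modeled as neural events — the design drives the neural state with
epoch-level boxcars, matching an analysis of sustained rather than
phasic responses; the stimulus arithmetic exists to validate the design
(480 stimuli per block, 25% targets).

Cohorts draw each subject's coupling parameters independently from
group-level pathway means/SDs (defaults follow the published healthy
control and patient summaries), push them through the forward model, and
add white scanner noise calibrated to SNR of about 1 unless an explicit
noise SD is given.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .forward_model import (
    BoldTimeSeries,
    DcmParameters,
    HemoParams,
    IntegrationError,
    TaskDesign,
    simulate_bold,
)
from .model_space import (
    Connection,
    NetworkTemplate,
    connection_label,
    full_model,
    masks,
    ModelSpec,
    REGION_INDEX,
)

#: published group summaries: pathway -> (mean, sd), intrinsic coupling (Hz)
HC_INTRINSIC: dict[Connection, tuple[float, float]] = {
    ("V1", "SPC"): (0.09, 0.12),
    ("V1", "Thal"): (0.12, 0.12),
    ("SPC", "Thal"): (0.02, 0.14),
    ("SPC", "BG"): (0.00, 0.02),
    ("Thal", "BG"): (0.02, 0.14),
    ("Thal", "dACC"): (0.10, 0.14),
    ("Thal", "dPFC"): (0.09, 0.14),
    ("BG", "Thal"): (0.00, 0.14),
    ("BG", "dPFC"): (0.04, 0.15),
    ("dACC", "Thal"): (0.04, 0.13),
    ("dACC", "BG"): (-0.01, 0.14),
    ("dPFC", "Thal"): (0.00, 0.13),
    ("dPFC", "BG"): (0.02, 0.13),
}
OCD_INTRINSIC: dict[Connection, tuple[float, float]] = {
    ("V1", "SPC"): (-0.06, 0.12),
    ("V1", "Thal"): (0.08, 0.12),
    ("SPC", "Thal"): (0.01, 0.14),
    ("SPC", "BG"): (0.00, 0.02),
    ("Thal", "BG"): (0.03, 0.14),
    ("Thal", "dACC"): (0.12, 0.14),
    ("Thal", "dPFC"): (0.08, 0.14),
    ("BG", "Thal"): (-0.04, 0.14),
    ("BG", "dPFC"): (0.07, 0.14),
    ("dACC", "Thal"): (0.07, 0.13),
    ("dACC", "BG"): (0.03, 0.14),
    ("dPFC", "Thal"): (-0.03, 0.13),
    ("dPFC", "BG"): (0.03, 0.14),
}
#: modulation (Hz) per condition for the 5 modulable pathways
HC_MODULATION = {
    "low": {
        ("dACC", "Thal"): (0.05, 0.28),
        ("dPFC", "Thal"): (0.04, 0.22),
        ("Thal", "dACC"): (0.08, 0.28),
        ("Thal", "dPFC"): (0.23, 0.27),
        ("dPFC", "BG"): (0.03, 0.25),
    },
    "high": {
        ("dACC", "Thal"): (0.10, 0.26),
        ("dPFC", "Thal"): (-0.02, 0.24),
        ("Thal", "dACC"): (0.17, 0.29),
        ("Thal", "dPFC"): (0.28, 0.29),
        ("dPFC", "BG"): (0.07, 0.26),
    },
}
OCD_MODULATION = {
    "low": {
        ("dACC", "Thal"): (0.03, 0.25),
        ("dPFC", "Thal"): (-0.03, 0.27),
        ("Thal", "dACC"): (0.20, 0.28),
        ("Thal", "dPFC"): (-0.06, 0.27),
        ("dPFC", "BG"): (-0.06, 0.30),
    },
    "high": {
        ("dACC", "Thal"): (0.04, 0.27),
        ("dPFC", "Thal"): (0.03, 0.26),
        ("Thal", "dACC"): (0.21, 0.31),
        ("Thal", "dPFC"): (0.09, 0.30),
        ("dPFC", "BG"): (-0.04, 0.30),
    },
}
#: driving efficacy on the input targets: not covered by the published
#: tables; one fixed generative choice (see methods note)
DEFAULT_DRIVING = (0.3, 0.05)


@dataclass
class DesignSpec:
    """Geometry of the blocked CPT-IP run."""

    task_epoch_s: float = 120.0
    rest_epoch_s: float = 20.0
    soa_ms: float = 250.0
    stim_ms: float = 50.0
    tr_s: float = 2.6
    n_cycles: int = 2  # each cycle: low epoch, rest, high epoch, rest
    microtime_bins: int = 16

    def __post_init__(self) -> None:
        for name in (
            "task_epoch_s",
            "rest_epoch_s",
            "soa_ms",
            "stim_ms",
            "tr_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.soa_ms < self.stim_ms:
            raise ValueError("SOA must be at least the stimulus duration")
        if self.microtime_bins < 1:
            raise ValueError("microtime_bins must be at least 1")

    @property
    def total_s(self) -> float:
        return self.n_cycles * 2 * (self.task_epoch_s + self.rest_epoch_s)


@dataclass
class GroupTruthSpec:
    """Generative distribution of one group's coupling parameters."""

    group: str
    n_subjects: int
    intrinsic: dict[Connection, tuple[float, float]]
    modulation: dict[str, dict[Connection, tuple[float, float]]]
    driving: tuple[float, float] = DEFAULT_DRIVING
    noise_sd: float | None = None  # None -> calibrate to SNR ~ 1

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least two subjects per group")
        for mean_sd in self.intrinsic.values():
            if mean_sd[1] < 0:
                raise ValueError("SDs must be non-negative")
        for cond in self.modulation.values():
            for mean_sd in cond.values():
                if mean_sd[1] < 0:
                    raise ValueError("SDs must be non-negative")


def hc_spec(n_subjects: int = 32, **kw) -> GroupTruthSpec:
    """Healthy-control generative defaults from the published summaries."""
    kw.setdefault("group", "HC")
    kw.setdefault("intrinsic", dict(HC_INTRINSIC))
    kw.setdefault("modulation", {c: dict(v) for c, v in HC_MODULATION.items()})
    return GroupTruthSpec(n_subjects=n_subjects, **kw)


def ocd_spec(n_subjects: int = 30, **kw) -> GroupTruthSpec:
    """Patient-group generative defaults from the published summaries."""
    kw.setdefault("group", "OCD")
    kw.setdefault("intrinsic", dict(OCD_INTRINSIC))
    kw.setdefault("modulation", {c: dict(v) for c, v in OCD_MODULATION.items()})
    return GroupTruthSpec(n_subjects=n_subjects, **kw)


def stimulus_count(epoch_s: float, soa_ms: float) -> int:
    """Stimuli fitting one task epoch at the given onset asynchrony."""
    if soa_ms <= 0:
        raise ValueError("SOA must be positive")
    return int(np.floor(epoch_s * 1000.0 / soa_ms))


def target_count(count: int, target_fraction: float) -> int:
    return int(round(count * target_fraction))


def make_design(spec: DesignSpec) -> TaskDesign:
    """Blocked low/rest/high/rest boxcar design on the microtime grid.

    Scans are acquired at the end of each TR; the grid covers
    floor(total/tr) scans, so a trailing sub-TR remainder is dropped.
    """
    if spec.n_cycles < 1:
        raise ValueError("need at least one task cycle")
    epochs: list[tuple[str, float, float]] = []
    t = 0.0
    for _ in range(spec.n_cycles):
        for cond in ("low", "rest", "high", "rest"):
            dur = spec.task_epoch_s if cond in ("low", "high") else spec.rest_epoch_s
            epochs.append((cond, t, dur))
            t += dur
    n_scans = int(np.floor(spec.total_s / spec.tr_s))
    if n_scans < 1:
        raise ValueError("design shorter than one TR")
    t_grid = spec.tr_s / spec.microtime_bins
    n_bins = n_scans * spec.microtime_bins
    u = np.zeros((2, n_bins))
    starts = np.arange(n_bins) * t_grid
    for cond, onset, dur in epochs:
        if cond == "rest":
            continue
        row = 0 if cond == "low" else 1
        u[row, (starts >= onset) & (starts < onset + dur)] = 1.0
    return TaskDesign(
        u=u, tr=spec.tr_s, microtime_bins=spec.microtime_bins, epochs=epochs
    )


def sample_group_truth(
    spec: GroupTruthSpec,
    template: NetworkTemplate,
    seed: int | np.random.Generator | None = 0,
) -> list[DcmParameters]:
    """Draw each subject's parameters from the group's pathway distributions.

    Entries are independent normals masked by the saturated (every permuted
    connection present and modulated) architecture.
    """
    known = set(template.all_connections())
    for conn in spec.intrinsic:
        if conn not in known:
            raise ValueError(f"pathway {connection_label(conn)} not in template")
    modulable = set(template.permuted_connections())
    for cond in spec.modulation.values():
        for conn in cond:
            if conn not in modulable:
                raise ValueError(
                    f"pathway {connection_label(conn)} is not modulable"
                )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = masks(full_model(template), template)
    out = []
    for _ in range(spec.n_subjects):
        p = DcmParameters.zeros()
        for (src, dst), (mean, sd) in spec.intrinsic.items():
            p.a[REGION_INDEX[dst], REGION_INDEX[src]] = rng.normal(mean, sd)
        for cond, table in spec.modulation.items():
            b = p.b_low if cond == "low" else p.b_high
            for (src, dst), (mean, sd) in table.items():
                b[REGION_INDEX[dst], REGION_INDEX[src]] = rng.normal(mean, sd)
        dm, dsd = spec.driving
        for tgt in template.driving_targets:
            p.c[REGION_INDEX[tgt], :] = rng.normal(dm, dsd, size=2)
        out.append(p.masked(mask))
    return out


@dataclass
class SubjectDataset:
    subject_id: str
    group: str
    bold: BoldTimeSeries
    design: TaskDesign
    truth: DcmParameters | None = None


@dataclass
class SyntheticCohort:
    subjects: list[SubjectDataset]
    design: TaskDesign
    master_seed: int
    noise_sd: dict[str, float] = field(default_factory=dict)

    def group(self, label: str) -> list[SubjectDataset]:
        return [s for s in self.subjects if s.group == label]


def calibrate_noise_sd(
    spec: GroupTruthSpec,
    design: TaskDesign,
    template: NetworkTemplate,
    hemo: HemoParams,
    generating_model: ModelSpec,
) -> float:
    """Noise SD giving SNR of about 1 for the typical region.

    The SD of the noiseless series of a subject whose parameters sit at the
    group means, taken per region and summarized by the median: the driven
    V1 row would otherwise dominate a pooled SD and leave the five
    downstream regions far below unit SNR."""
    mean_spec = replace(
        spec,
        intrinsic={c: (m, 0.0) for c, (m, _) in spec.intrinsic.items()},
        modulation={
            cond: {c: (m, 0.0) for c, (m, _) in tab.items()}
            for cond, tab in spec.modulation.items()
        },
        driving=(spec.driving[0], 0.0),
        n_subjects=2,
    )
    truth = sample_group_truth(mean_spec, template, seed=0)[0]
    mask = masks(generating_model, template)
    y = simulate_bold(truth, hemo, design, mask, noise_sd=0.0)
    return float(np.median(y.y.std(axis=1)))


def generate_cohort(
    hc: GroupTruthSpec,
    ocd: GroupTruthSpec,
    design_spec: DesignSpec,
    template: NetworkTemplate,
    master_seed: int = 0,
    hemo: HemoParams | None = None,
    generating_model: ModelSpec | None = None,
    out_dir: str | Path | None = None,
) -> SyntheticCohort:
    """Simulate both groups under one generating architecture.

    Subject seeds derive deterministically from ``master_seed``; a subject
    whose drawn parameters destabilize the forward model is redrawn once
    with halved coupling, then the generation fails.
    """
    hemo = hemo or HemoParams()
    generating_model = generating_model or full_model(template)
    design = make_design(design_spec)
    mask = masks(generating_model, template)
    subjects: list[SubjectDataset] = []
    noise_by_group: dict[str, float] = {}
    ss = np.random.SeedSequence(master_seed)
    group_seeds = ss.spawn(2)
    for gi, (spec, gseed) in enumerate(zip((hc, ocd), group_seeds)):
        noise_sd = (
            spec.noise_sd
            if spec.noise_sd is not None
            else calibrate_noise_sd(spec, design, template, hemo, generating_model)
        )
        noise_by_group[spec.group] = noise_sd
        truth_rng = np.random.default_rng(gseed.spawn(1)[0])
        truths = sample_group_truth(spec, template, seed=truth_rng)
        for i, truth in enumerate(truths):
            sid = f"sub-{spec.group}{i:03d}"
            noise_rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=master_seed, spawn_key=(gi, i)
                )
            )
            bold, truth = _simulate_stable(
                truth, spec, template, hemo, design, mask, noise_sd, noise_rng
            )
            subjects.append(
                SubjectDataset(
                    subject_id=sid,
                    group=spec.group,
                    bold=bold,
                    design=design,
                    truth=truth,
                )
            )
    cohort = SyntheticCohort(
        subjects=subjects,
        design=design,
        master_seed=master_seed,
        noise_sd=noise_by_group,
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def _simulate_stable(
    truth: DcmParameters,
    spec: GroupTruthSpec,
    template: NetworkTemplate,
    hemo: HemoParams,
    design: TaskDesign,
    mask,
    noise_sd: float,
    noise_rng: np.random.Generator,
) -> tuple[BoldTimeSeries, DcmParameters]:
    """Simulate one subject, keeping draws inside the stable domain.

    Strongly negative sustained coupling can push the balloon's blood flow
    out of its positive domain; such a draw is first retried with halved
    coupling, then replaced by fresh draws (rejection sampling from the
    group distribution truncated to the stable domain), and only then does
    generation fail.
    """
    candidates = [truth, replace(truth, a=truth.a * 0.5, b_low=truth.b_low * 0.5,
                                 b_high=truth.b_high * 0.5)]
    last_err: IntegrationError | None = None
    for attempt, cand in enumerate(candidates):
        try:
            return (
                simulate_bold(cand, hemo, design, mask, noise_sd=noise_sd, seed=noise_rng),
                cand,
            )
        except IntegrationError as err:
            last_err = err
            if attempt == 0:
                # append fresh redraws lazily, derived from the noise stream
                for k in range(3):
                    redraw = sample_group_truth(
                        replace(spec, n_subjects=2),
                        template,
                        seed=np.random.default_rng(noise_rng.integers(2**31)),
                    )[0]
                    candidates.append(redraw)
    raise IntegrationError(f"could not draw a stable subject: {last_err}")


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """TSV/JSON bundle: events, per-subject series, ground truth, manifest."""
    from . import io as tcio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tcio.write_events(cohort.design.epochs, out / "design.tsv")
    truth_rows = []
    for s in cohort.subjects:
        tcio.write_timeseries(s.bold, out / f"{s.subject_id}_bold.tsv")
        if s.truth is not None:
            truth_rows.append((s.subject_id, s.group, s.truth))
    tcio.write_truth_table(truth_rows, out / "truth.tsv")
    manifest = {
        "master_seed": cohort.master_seed,
        "noise_sd": cohort.noise_sd,
        "tr_s": cohort.design.tr,
        "microtime_bins": cohort.design.microtime_bins,
        "n_scans": cohort.design.n_scans,
        "subjects": [
            {"subject_id": s.subject_id, "group": s.group} for s in cohort.subjects
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
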