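"""Plain-text file formats: BOLD TSV, events TSV, evidence/statistics tables.

Everything is TSV or JSON so every artifact of a run can be inspected and
diffed; there are no binary formats at these data sizes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bms import EvidenceMatrix
from .forward_model import BoldTimeSeries, TaskDesign
from .model_space import REGIONS

_TIME_COL = "time_s"


def write_timeseries(bold: BoldTimeSeries, path: str | Path) -> None:
    """Region x time BOLD to TSV: time_s column then the canonical regions."""
    t = (np.arange(bold.n_scans) + 1) * bold.tr
    df = pd.DataFrame({_TIME_COL: t})
    for i, r in enumerate(REGIONS):
        df[r] = bold.y[i]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timeseries(path: str | Path) -> BoldTimeSeries:
    """Read a BOLD TSV; validates columns and uniform sampling."""
    df = pd.read_csv(path, sep="\t")
    if _TIME_COL not in df.columns:
        raise ValueError(f"{path}: missing required column '{_TIME_COL}'")
    missing = [r for r in REGIONS if r not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing region column(s) {missing}")
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged rows / missing values")
    t = df[_TIME_COL].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
        raise ValueError(f"{path}: non-uniform sampling in '{_TIME_COL}'")
    y = df[list(REGIONS)].to_numpy(dtype=float).T
    return BoldTimeSeries(y=y, tr=float(dt[0]))


def write_events(epochs: list[tuple[str, float, float]], path: str | Path) -> None:
    """Task epochs to a BIDS-events-style TSV (onset, duration, trial_type)."""
    rows = [
        {"onset": onset, "duration": dur, "trial_type": cond}
        for cond, onset, dur in epochs
        if cond != "rest"
    ]
    pd.DataFrame(rows, columns=["onset", "duration", "trial_type"]).to_csv(
        path, sep="\t", index=False
    )


def read_events(path: str | Path) -> list[tuple[str, float, float]]:
    """Read task epochs; rest periods are implicit gaps."""
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration", "trial_type"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    bad = set(df["trial_type"]) - {"low", "high"}
    if bad:
        raise ValueError(f"{path}: unknown trial_type values {sorted(bad)}")
    epochs = [
        (str(r.trial_type), float(r.onset), float(r.duration))
        for r in df.itertuples()
    ]
    intervals = sorted((on, on + dur) for _, on, dur in epochs)
    for (a0, a1), (b0, _) in zip(intervals, intervals[1:]):
        if b0 < a1 - 1e-9:
            raise ValueError(f"{path}: overlapping task epochs")
    return epochs


def design_from_events(
    epochs: list[tuple[str, float, float]],
    tr: float,
    microtime_bins: int = 16,
    total_s: float | None = None,
) -> TaskDesign:
    """Build the microtime boxcar design from an epoch list."""
    if total_s is None:
        total_s = max(on + dur for _, on, dur in epochs)
    n_scans = int(np.floor(total_s / tr + 1e-9))
    n_bins = n_scans * microtime_bins
    starts = np.arange(n_bins) * (tr / microtime_bins)
    u = np.zeros((2, n_bins))
    for cond, onset, dur in epochs:
        if cond == "rest":
            continue
        u[0 if cond == "low" else 1, (starts >= onset) & (starts < onset + dur)] = 1.0
    return TaskDesign(u=u, tr=tr, microtime_bins=microtime_bins, epochs=list(epochs))


def write_evidence(ev: EvidenceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ev.f, columns=[str(m) for m in ev.model_ids])
    df.insert(0, "subject_id", list(ev.subject_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_evidence(path: str | Path, group: str = "") -> EvidenceMatrix:
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing 'subject_id' column")
    model_cols = [c for c in df.columns if c != "subject_id"]
    return EvidenceMatrix(
        f=df[model_cols].to_numpy(dtype=float),
        subject_ids=tuple(df["subject_id"].astype(str)),
        model_ids=tuple(int(c) for c in model_cols),
        group=group,
    )


def write_truth_table(rows, path: str | Path) -> None:
    """Ground-truth parameter table: one row per subject, named entries."""
    from .inversion import ParamMap
    from .model_space import REGION_INDEX, default_template, full_model, masks

    template = default_template()
    pm = ParamMap(masks(full_model(template), template))
    recs = []
    for sid, group, truth in rows:
        rec = {"subject_id": sid, "group": group}
        for name in pm.names:
            kind, lbl = name.split(":", 1)
            if kind == "C":
                cond, dst = lbl.split("->")
                rec[name] = truth.c[REGION_INDEX[dst], 0 if cond == "low" else 1]
            else:
                src, dst = lbl.split("->")
                m = {"A": truth.a, "Blow": truth.b_low, "Bhigh": truth.b_high}[kind]
                rec[name] = m[REGION_INDEX[dst], REGION_INDEX[src]]
        recs.append(rec)
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_stats_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def content_hash(*parts) -> str:
    """Stable hash of arrays/strings/numbers for the inversion cache key."""
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(np.ascontiguousarray(p).tobytes())
            h.update(str(p.shape).encode())
        else:
            h.update(repr(p).encode())
    return h.hexdigest()[:24]
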