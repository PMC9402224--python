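"""Group-level inference on model-averaged connectivity parameters.

One-sample t-tests ask whether a pathway's coupling differs from zero
within each group; pooled-variance independent-samples t-tests compare the
groups.  Tests are two-sided and uncorrected at the configured alpha (a
Benjamini-Hochberg column is emitted for reference but does not drive the
significance flags).  The between-group sign convention is explicit
because intrinsic and modulation tables conventionally print opposite
directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PARAM_CLASSES = ("intrinsic", "modulation_low", "modulation_high")
_CLASS_PREFIX = {"intrinsic": "A:", "modulation_low": "Blow:", "modulation_high": "Bhigh:"}


@dataclass
class GroupParameterTable:
    """Per-subject model-averaged parameter vectors for one group."""

    group: str
    subject_ids: tuple[str, ...]
    param_names: tuple[str, ...]
    values: np.ndarray  # (n_subjects, n_params)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.param_names)):
            raise ValueError("value matrix shape does not match ids/names")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.param_names.index(name)]


def one_sample_t(values: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sd, t, p) against zero; sd uses the n-1 denominator.

    Zero-variance samples leave t and p undefined (NaN).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return mean, sd, float("nan"), float("nan")
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return mean, sd, float(t), float(p)


def two_sample_t_pooled(
    g1: np.ndarray, g2: np.ndarray, direction: str = "g1-g2"
) -> tuple[float, float]:
    """Pooled-variance independent-samples t-test, two-sided.

    ``direction`` ("g1-g2" or "g2-g1") sets whose mean is subtracted from
    whose, i.e. the sign of t; p is unaffected.
    """
    x1 = np.asarray(g1, dtype=float)
    x2 = np.asarray(g2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    t, p = two_sample_t_from_summary(
        x1.mean(), x1.std(ddof=1), n1, x2.mean(), x2.std(ddof=1), n2
    )
    if direction == "g2-g1":
        t = -t
    elif direction != "g1-g2":
        raise ValueError("direction must be 'g1-g2' or 'g2-g1'")
    return t, p


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled t from group summaries (mean1 - mean2 in the numerator)."""
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if sp2 == 0.0:
        return float("nan"), float("nan")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return float(t), float(p)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def build_stats_table(
    hc: GroupParameterTable,
    ocd: GroupParameterTable,
    alpha: float = 0.05,
    between_direction: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Intrinsic- and modulation-parameter statistics for two groups.

    One row per pathway and parameter class: group means/SDs, one-sample t
    and p per group, and the pooled two-sample t/p.  By default the
    between-group direction is HC-OCD for intrinsic rows and OCD-HC for
    modulation rows (the conventional printed signs); both signed values
    are reported.
    """
    if hc.param_names != ocd.param_names:
        raise ValueError("groups disagree on parameter naming")
    between_direction = between_direction or {
        "intrinsic": "hc-ocd",
        "modulation_low": "ocd-hc",
        "modulation_high": "ocd-hc",
    }
    rows = []
    for cls in PARAM_CLASSES:
        prefix = _CLASS_PREFIX[cls]
        for name in hc.param_names:
            if not name.startswith(prefix):
                continue
            pathway = name.split(":", 1)[1]
            hx = hc.column(name)
            ox = ocd.column(name)
            h_mean, h_sd, h_t, h_p = one_sample_t(hx)
            o_mean, o_sd, o_t, o_p = one_sample_t(ox)
            t_oh, p_b = two_sample_t_pooled(ox, hx)  # OCD - HC
            direction = between_direction.get(cls, "ocd-hc")
            t_between = t_oh if direction == "ocd-hc" else -t_oh
            rows.append(
                {
                    "pathway": pathway,
                    "class": cls,
                    "hc_mean": h_mean,
                    "hc_sd": h_sd,
                    "hc_t": h_t,
                    "hc_p": h_p,
                    "hc_sig": bool(h_p < alpha) if np.isfinite(h_p) else False,
                    "ocd_mean": o_mean,
                    "ocd_sd": o_sd,
                    "ocd_t": o_t,
                    "ocd_p": o_p,
                    "ocd_sig": bool(o_p < alpha) if np.isfinite(o_p) else False,
                    "between_direction": direction,
                    "t_between": t_between,
                    "t_between_ocd_minus_hc": t_oh,
                    "t_between_hc_minus_ocd": -t_oh,
                    "p_between": p_b,
                    "between_sig": bool(p_b < alpha) if np.isfinite(p_b) else False,
                }
            )
    table = pd.DataFrame(rows)
    table["p_between_bh"] = _bh_adjust(table["p_between"].to_numpy())
    return table
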