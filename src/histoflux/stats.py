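"""Group summaries, one-way ANOVA and the caliper tumor-volume utility.

Per-section metrics are aggregated per treatment group as mean +/- sample
standard deviation (n-1 denominator), with percent change against a
reference group and an omnibus one-way ANOVA (F = MS_between / MS_within)
across groups for each metric.  Significance stars follow the reporting
convention * p < 0.05, ** p < 0.005; they annotate the omnibus test, no
post-hoc procedure is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .penetration import percent_change

__all__ = ["GroupSummary", "summarize", "tumor_volume"]


@dataclass
class GroupSummary:
    group: str
    metric: str
    n: int
    mean: float
    sd: float
    pct_change_vs_ref: float | None
    anova_F: float
    anova_p: float


def _stars(p: float) -> str:
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize(data: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Aggregate a tidy (group, metric, value) table into group summaries.

    For every metric: per-group mean and sample SD, percent change of the
    group mean vs the reference group's mean, and a one-way ANOVA F and p
    across all groups (requires >= 2 groups).  Rows are sorted by
    (metric, group) so output order is deterministic.
    """
    required = {"group", "metric", "value"}
    if not required.issubset(data.columns):
        raise ValueError(f"expected columns {sorted(required)}")
    if reference_group not in set(data["group"]):
        raise ValueError(f"reference group {reference_group!r} missing")

    rows = []
    for metric, sub in data.groupby("metric"):
        groups = {g: np.asarray(v["value"], float) for g, v in sub.groupby("group")}
        if len(groups) < 2:
            raise ValueError(f"metric {metric!r}: need >= 2 groups for ANOVA")
        samples = list(groups.values())
        if all(len(s) == len(samples[0]) and np.allclose(s, samples[0])
               for s in samples[1:]):
            f_stat, p_val = 0.0, 1.0   # identical groups: no between-group variance
        else:
            f_stat, p_val = sstats.f_oneway(*samples)
        ref_mean = float(np.mean(groups[reference_group]))
        for g in sorted(groups):
            vals = groups[g]
            if len(vals) < 2:
                raise ValueError(
                    f"group {g!r}, metric {metric!r}: single observation, "
                    "sample SD undefined")
            sd = float(np.std(vals, ddof=1))
            pct = percent_change(float(np.mean(vals)), ref_mean) \
                if ref_mean > 0 else None
            rows.append({
                "metric": metric, "group": g, "n": len(vals),
                "mean": float(np.mean(vals)), "sd": sd,
                "pct_change_vs_ref": pct,
                "anova_F": float(f_stat), "anova_p": float(p_val),
                "stars": _stars(float(p_val)),
            })
    out = pd.DataFrame(rows).sort_values(["metric", "group"]).reset_index(drop=True)
    return out


def tumor_volume(width_mm: float, length_mm: float) -> float:
    """Caliper tumor volume in mm^3: width^2 * length * 0.4."""
    if width_mm <= 0 or length_mm <= 0:
        raise ValueError("width and length must be > 0")
    return width_mm**2 * length_mm * 0.4
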