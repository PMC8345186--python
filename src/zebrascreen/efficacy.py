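"""Tumor-growth efficacy metrics for vehicle-vs-treated comparisons.

Per embryo, with TA the fluorescent tumor area:

    RTG % = 100 x (TA_final - TA_baseline) / TA_baseline
    NTA   = TA_final / TA_baseline            (so NTA == 1 + RTG/100)

Between groups:

    DTG % = tumor growth vehicle % - tumor growth treated %
    absolute difference in efficacy = summary(NTA_vehicle) - summary(NTA_treated)

A DTG (or absolute difference) of 0 indicates no drug effect; positive
values mean the treatment slowed tumor growth.  Group tumor growth is the
summary (mean by default, median available) of per-embryo RTGs, and only
embryos alive on the final day contribute.  An optional advisory flag
marks per-embryo NTAs further than 3 scaled MADs from their group median;
points are flagged, never removed (this is not an outlier-removal
procedure).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .data_model import CohortTable

Stat = Literal["mean", "median"]


def _summary(values, stat: Stat) -> float:
    if stat == "mean":
        return float(np.mean(values))
    if stat == "median":
        return float(np.median(values))
    raise ValueError(f"unknown summary statistic {stat!r} (use 'mean' or 'median')")


def rtg(ta_baseline: float, ta_final: float) -> float:
    """Relative tumor growth (%) from baseline to final day."""
    if ta_baseline <= 0:
        raise ValueError("RTG requires a positive baseline tumor area")
    return 100.0 * (ta_final - ta_baseline) / ta_baseline


def nta(ta_baseline: float, ta_final: float) -> float:
    """Normalized tumor area: final-day TA divided by baseline TA."""
    if ta_baseline <= 0:
        raise ValueError("NTA requires a positive baseline tumor area")
    return ta_final / ta_baseline


def dtg(growth_vehicle_pct: float, growth_treated_pct: float) -> float:
    """Difference in tumor growth (%): vehicle minus treated."""
    if not (math.isfinite(growth_vehicle_pct) and math.isfinite(growth_treated_pct)):
        raise ValueError("group growth percentages must be finite")
    return growth_vehicle_pct - growth_treated_pct


def absolute_difference_efficacy(
    nta_vehicle: Iterable[float],
    nta_treated: Iterable[float],
    stat: Stat = "mean",
) -> float:
    """Vehicle-group NTA summary minus treated-group NTA summary.

    0 indicates no efficacy; swapping the groups negates the value.
    """
    v = np.asarray(list(nta_vehicle), dtype=float)
    t = np.asarray(list(nta_treated), dtype=float)
    if v.size == 0 or t.size == 0:
        raise ValueError("both NTA groups must be nonempty")
    return _summary(v, stat) - _summary(t, stat)


@dataclass
class EfficacyReport:
    """All efficacy metrics for one vehicle-vs-treated comparison.

    ``per_embryo`` has one row per surviving embryo with its RTG and NTA;
    ``group_growth_pct`` and ``nta_summary`` cover every group present in
    the cohort, keyed by group label.
    """

    per_embryo: pd.DataFrame
    group_growth_pct: dict[str, float]
    nta_summary: dict[str, float]
    dtg_pct: float
    absolute_difference: float
    group_sizes: dict[str, int]
    vehicle_group: str
    treated_group: str
    stat: Stat = "mean"

    def to_dict(self) -> dict:
        return {
            "per_embryo": self.per_embryo.to_dict(orient="records"),
            "group_growth_pct": dict(self.group_growth_pct),
            "nta_summary": dict(self.nta_summary),
            "dtg_pct": self.dtg_pct,
            "absolute_difference": self.absolute_difference,
            "group_sizes": dict(self.group_sizes),
            "vehicle_group": self.vehicle_group,
            "treated_group": self.treated_group,
            "stat": self.stat,
        }


def efficacy_report(
    cohort: CohortTable,
    vehicle_group: str = "vehicle",
    treated_group: str = "treated",
    stat: Stat = "mean",
    flag_outliers: bool = False,
) -> EfficacyReport:
    """Per-embryo RTG/NTA plus group-level DTG and absolute difference.

    Only embryos alive at ``cohort.final_dpi`` with a positive baseline TA
    contribute.  Raises when either comparison group has no surviving
    embryo.
    """
    b, f = cohort.baseline_dpi, cohort.final_dpi
    rows: list[dict] = []
    for rec in cohort.records:
        ta_b, ta_f = rec.ta(b), rec.ta(f)
        if not rec.is_alive(f) or ta_b is None or ta_f is None:
            continue
        rows.append(
            {
                "embryo_id": rec.embryo_id,
                "replicate_id": rec.replicate_id,
                "group": rec.group,
                "ta_baseline": ta_b,
                "ta_final": ta_f,
                "rtg_pct": rtg(ta_b, ta_f),
                "nta": nta(ta_b, ta_f),
            }
        )
    per_embryo = pd.DataFrame(
        rows,
        columns=[
            "embryo_id",
            "replicate_id",
            "group",
            "ta_baseline",
            "ta_final",
            "rtg_pct",
            "nta",
        ],
    ).sort_values(["group", "replicate_id", "embryo_id"], kind="stable").reset_index(
        drop=True
    )

    if flag_outliers and len(per_embryo):
        # Advisory only: |NTA - group median| > 3 x scaled MAD.
        def _flag(sub: pd.Series) -> pd.Series:
            med = sub.median()
            mad = 1.4826 * (sub - med).abs().median()
            if mad == 0:
                return pd.Series(False, index=sub.index)
            return (sub - med).abs() > 3 * mad

        per_embryo["nta_outlier_flag"] = per_embryo.groupby("group")["nta"].transform(
            _flag
        )

    group_growth = {
        g: _summary(sub["rtg_pct"].to_numpy(), stat)
        for g, sub in per_embryo.groupby("group")
    }
    nta_summary = {
        g: _summary(sub["nta"].to_numpy(), stat)
        for g, sub in per_embryo.groupby("group")
    }
    sizes = per_embryo.groupby("group").size().to_dict()
    for g in (vehicle_group, treated_group):
        if sizes.get(g, 0) == 0:
            raise ValueError(
                f"group {g!r} has no surviving embryos at {f} dpi; efficacy "
                "metrics are undefined"
            )
    return EfficacyReport(
        per_embryo=per_embryo,
        group_growth_pct=group_growth,
        nta_summary=nta_summary,
        dtg_pct=dtg(group_growth[vehicle_group], group_growth[treated_group]),
        absolute_difference=nta_summary[vehicle_group] - nta_summary[treated_group],
        group_sizes={str(k): int(v) for k, v in sizes.items()},
        vehicle_group=vehicle_group,
        treated_group=treated_group,
        stat=stat,
    )
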