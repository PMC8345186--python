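"""Per-embryo engraftment classification and the pooled engraftment metric.

An embryo is considered to carry engrafted cells when its tumor area on
the final day of the experiment is equal to or higher than at baseline
(1 dpi) — the boundary is inclusive.  The headline percentage is pooled:

    engrafted % = 100 x (living embryos at final dpi with TA_final >= TA_baseline)
                        / (living embryos at final dpi)

Embryos that died before the final day (or lack a final tumor area) are
not classifiable and enter neither numerator nor denominator.  Per-
replicate percentages plus their mean and sample SD across replicates are
reported alongside the pooled value.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import CohortTable


def classify_engrafted(ta_baseline: float, ta_final: float) -> bool:
    """True iff the final tumor area is >= the baseline tumor area."""
    if ta_baseline < 0 or ta_final < 0:
        raise ValueError("tumor areas must be nonnegative")
    return ta_final >= ta_baseline


@dataclass
class EngraftmentSummary:
    """Pooled and per-replicate engraftment percentages.

    ``flags`` maps (replicate_id, embryo_id) -> engrafted flag, or None
    when the embryo was not classifiable (dead / no final TA).
    """

    flags: dict[tuple[str, str], bool | None]
    n_engrafted: int
    n_living_final: int
    percentage: float
    per_replicate: dict[str, float]
    replicate_mean: float
    replicate_sd: float

    def to_dict(self) -> dict:
        return {
            "n_engrafted": self.n_engrafted,
            "n_living_final": self.n_living_final,
            "percentage": self.percentage,
            "per_replicate": dict(self.per_replicate),
            "replicate_mean": self.replicate_mean,
            "replicate_sd": self.replicate_sd,
        }


def engraftment_percentage(cohort: CohortTable, annotate: bool = True) -> EngraftmentSummary:
    """Compute the engrafted-cell percentage over living embryos at final dpi.

    When ``annotate`` is true (default), each classifiable record's
    ``engrafted`` flag is set in place.
    """
    b, f = cohort.baseline_dpi, cohort.final_dpi
    flags: dict[tuple[str, str], bool | None] = {}
    per_rep_counts: dict[str, list[int]] = {}
    for rec in cohort.records:
        key = (rec.replicate_id, rec.embryo_id)
        ta_b, ta_f = rec.ta(b), rec.ta(f)
        if not rec.is_alive(f) or ta_b is None or ta_f is None:
            flags[key] = None
            continue
        eng = classify_engrafted(ta_b, ta_f)
        flags[key] = eng
        if annotate:
            rec.engrafted = eng
        n_eng, n_tot = per_rep_counts.setdefault(rec.replicate_id, [0, 0])
        per_rep_counts[rec.replicate_id] = [n_eng + int(eng), n_tot + 1]

    n_living = sum(v is not None for v in flags.values())
    if n_living == 0:
        raise ValueError(
            "engraftment percentage is undefined: no living embryo with a "
            "final tumor area"
        )
    n_engrafted = sum(bool(v) for v in flags.values())
    per_rep = {
        rep: 100.0 * n_eng / n_tot for rep, (n_eng, n_tot) in per_rep_counts.items()
    }
    values = list(per_rep.values())
    rep_mean = float(np.mean(values))
    rep_sd = float(np.std(values, ddof=1)) if len(values) > 1 else math.nan
    return EngraftmentSummary(
        flags=flags,
        n_engrafted=n_engrafted,
        n_living_final=n_living,
        percentage=100.0 * n_engrafted / n_living,
        per_replicate=per_rep,
        replicate_mean=rep_mean,
        replicate_sd=rep_sd,
    )
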