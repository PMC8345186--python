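"""User-independent inclusion criterion, replicate discard rule, survival.

The inclusion threshold is an assay-dependent cutoff computed from the
baseline (1 dpi) tumor areas of the whole experiment:

    IT = median(TA at baseline) - multiplier x IQR(TA at baseline)

with multiplier 1.25 by default.  Only embryos whose baseline TA is
strictly higher than IT are included — the criterion exists to remove
mis-injected embryos with little or no tumor mass, replacing the
user-dependent fluorescence sort.  An experimental replicate is removed
outright when strictly more than ``discard_fraction`` (default 25%) of
its embryos fall below the threshold.

Quantiles use linear interpolation between order statistics ("type 7",
numpy's default); no convention is prescribed by the procedure itself, so
the choice is configurable and recorded in results.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .data_model import CohortTable, CohortValidationError

DEFAULT_MULTIPLIER = 1.25
DEFAULT_DISCARD_FRACTION = 0.25


def inclusion_threshold(
    ta_baseline: Iterable[float],
    multiplier: float = DEFAULT_MULTIPLIER,
    method: str = "linear",
) -> float:
    """Inclusion threshold ``median - multiplier * IQR`` of baseline TAs.

    May be negative, in which case no embryo is excluded (all areas are
    nonnegative).  ``method`` is the quantile interpolation convention
    passed to :func:`numpy.quantile`.
    """
    x = np.asarray(list(ta_baseline), dtype=float)
    if x.size < 2:
        raise ValueError("inclusion threshold needs at least 2 baseline areas")
    if not np.all(np.isfinite(x)):
        raise ValueError("baseline tumor areas must be finite")
    q1, q3 = np.quantile(x, [0.25, 0.75], method=method)
    return float(np.median(x) - multiplier * (q3 - q1))


@dataclass
class InclusionResult:
    """Outcome of the inclusion stage.

    ``threshold_it`` is the pooled threshold (None when computed per
    replicate, see ``replicate_thresholds``).  ``included`` maps
    (replicate_id, embryo_id) -> flag; ``replicate_discard_fraction`` and
    ``replicate_removed`` record the replicate-level rule.
    """

    threshold_it: float | None
    replicate_thresholds: dict[str, float]
    included: dict[tuple[str, str], bool]
    replicate_discard_fraction: dict[str, float]
    replicate_removed: dict[str, bool]
    multiplier: float = DEFAULT_MULTIPLIER
    discard_fraction: float = DEFAULT_DISCARD_FRACTION
    quantile_method: str = "linear"

    @property
    def n_included(self) -> int:
        return sum(self.included.values())

    @property
    def n_excluded(self) -> int:
        return sum(not v for v in self.included.values())

    def to_dict(self) -> dict:
        return {
            "threshold_it": self.threshold_it,
            "replicate_thresholds": dict(self.replicate_thresholds),
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "replicate_discard_fraction": dict(self.replicate_discard_fraction),
            "replicate_removed": dict(self.replicate_removed),
            "multiplier": self.multiplier,
            "discard_fraction": self.discard_fraction,
            "quantile_method": self.quantile_method,
        }


def apply_inclusion(
    cohort: CohortTable,
    multiplier: float = DEFAULT_MULTIPLIER,
    discard_fraction: float = DEFAULT_DISCARD_FRACTION,
    *,
    per_replicate: bool = False,
    method: str = "linear",
) -> tuple[InclusionResult, CohortTable]:
    """Apply the inclusion criterion and the replicate discard rule.

    By default the threshold is computed once across the whole experiment
    (all groups and replicates pooled); ``per_replicate=True`` recomputes
    it within each replicate.  An embryo is included iff its baseline TA
    is strictly greater than the threshold.  A replicate is removed iff
    the excluded fraction among its embryos is strictly greater than
    ``discard_fraction``.  Returns the result plus a filtered cohort of
    included embryos from retained replicates, with ``included`` flags set.
    """
    if len(cohort) == 0:
        raise ValueError("cannot apply inclusion to an empty cohort")
    b = cohort.baseline_dpi
    baselines: dict[tuple[str, str], float] = {}
    for rec in cohort.records:
        ta = rec.ta(b)
        if ta is None:
            raise CohortValidationError(
                f"embryo {rec.embryo_id} (replicate {rec.replicate_id}) has no "
                f"baseline tumor area at {b} dpi"
            )
        baselines[(rec.replicate_id, rec.embryo_id)] = ta

    reps = cohort.by_replicate()
    thresholds: dict[str, float] = {}
    pooled_it: float | None = None
    if per_replicate:
        for rep, recs in reps.items():
            thresholds[rep] = inclusion_threshold(
                [baselines[(rep, r.embryo_id)] for r in recs], multiplier, method
            )
    else:
        pooled_it = inclusion_threshold(baselines.values(), multiplier, method)
        thresholds = {rep: pooled_it for rep in reps}

    included = {
        key: ta > thresholds[key[0]] for key, ta in baselines.items()
    }
    discard: dict[str, float] = {}
    removed: dict[str, bool] = {}
    for rep, recs in reps.items():
        n = len(recs)
        n_excl = sum(not included[(rep, r.embryo_id)] for r in recs)
        discard[rep] = n_excl / n
        removed[rep] = discard[rep] > discard_fraction

    kept = [
        replace(rec, included=True)
        for rec in cohort.records
        if included[(rec.replicate_id, rec.embryo_id)]
        and not removed[rec.replicate_id]
    ]
    result = InclusionResult(
        threshold_it=pooled_it,
        replicate_thresholds=thresholds,
        included=included,
        replicate_discard_fraction=discard,
        replicate_removed=removed,
        multiplier=multiplier,
        discard_fraction=discard_fraction,
        quantile_method=method,
    )
    return result, cohort.subset(kept)


def survival_percentage(cohort: CohortTable, dpi: int) -> float:
    """Percentage of baseline embryos still alive at ``dpi``."""
    if len(cohort) == 0:
        raise ValueError("survival percentage is undefined for an empty cohort")
    n_alive = sum(rec.is_alive(dpi) for rec in cohort.records)
    return 100.0 * n_alive / len(cohort)
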