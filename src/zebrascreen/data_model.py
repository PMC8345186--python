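"""Core domain types and tabular I/O for xenograft screening cohorts.

The unit of analysis is a single xenografted embryo observed on integer
days post-injection (dpi); the baseline observation is 1 dpi, immediately
after fluorescence sorting.  Tumor burden is the fluorescent tumor area
(TA), carried in abstract area units (pixel counts by default).  Unit
metadata travels in run configuration and is never converted implicitly.

Cohorts are exchanged as long (tidy) CSV tables — one row per embryo per
observed day — so a variable number of observation days needs no schema
change.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Conventional experimental-group labels. Arbitrary labels are accepted;
#: these are the ones the screening design uses.
GROUP_LABELS = ("vehicle", "treated", "untreated-control", "no-cells-control")

#: Candidate implantation / injection sites in the embryo.
SITE_LABELS = ("PCS", "dorsal-PVS", "ventral-PVS", "yolk", "other")

#: Required columns of the long-format cohort CSV. ``alive`` is encoded 0/1.
COHORT_COLUMNS = (
    "embryo_id",
    "replicate_id",
    "group",
    "site",
    "dpi",
    "tumor_area",
    "alive",
)

#: Optional per-embryo flag columns written once the corresponding
#: pipeline stage has run.
FLAG_COLUMNS = ("included", "engrafted")


class SchemaError(ValueError):
    """A table lacks required structure (e.g. a missing column)."""


class CohortValidationError(ValueError):
    """A cohort violates a domain invariant."""


@dataclass(frozen=True)
class ZScoreParams:
    """Negative-control location/scale used for Z-score normalization.

    ``mu_neg_ctrl`` and ``sigma_neg_ctrl`` are the mean and standard
    deviation of the measurement in non-injected (negative-control)
    embryos; scores are ``(x - mu) / sigma``.
    """

    mu_neg_ctrl: float
    sigma_neg_ctrl: float

    def __post_init__(self) -> None:
        if not (self.sigma_neg_ctrl > 0):
            raise ValueError(
                f"sigma_neg_ctrl must be > 0, got {self.sigma_neg_ctrl}"
            )


@dataclass
class EmbryoRecord:
    """One embryo: identity, assignment, TA trajectory and vital status.

    ``ta_by_dpi`` maps observed day -> tumor area; ``alive_by_dpi`` maps
    observed day -> vital status.  Death is absorbing and a tumor area may
    only exist on a day the embryo is alive.
    """

    embryo_id: str
    replicate_id: str
    group: str
    site: str
    ta_by_dpi: dict[int, float] = field(default_factory=dict)
    alive_by_dpi: dict[int, bool] = field(default_factory=dict)
    included: bool | None = None
    engrafted: bool | None = None

    def validate(self) -> None:
        for d, ta in self.ta_by_dpi.items():
            if not isinstance(d, (int, np.integer)) or d < 1:
                raise CohortValidationError(
                    f"embryo {self.embryo_id}: dpi must be an integer >= 1, got {d!r}"
                )
            if not math.isfinite(ta) or ta < 0:
                raise CohortValidationError(
                    f"embryo {self.embryo_id}: tumor area at {d} dpi must be "
                    f"finite and >= 0, got {ta!r}"
                )
        days = sorted(self.alive_by_dpi)
        dead_seen = False
        for d in days:
            if dead_seen and self.alive_by_dpi[d]:
                raise CohortValidationError(
                    f"embryo {self.embryo_id}: alive at {d} dpi after an "
                    "earlier death (death is absorbing)"
                )
            if not self.alive_by_dpi[d]:
                dead_seen = True
        for d in self.ta_by_dpi:
            if not self.alive_by_dpi.get(d, False):
                raise CohortValidationError(
                    f"embryo {self.embryo_id}: tumor area recorded at {d} dpi "
                    "but embryo is not alive on that day"
                )

    def is_alive(self, dpi: int) -> bool:
        """Vital status at ``dpi``, carrying the last observation forward."""
        if dpi in self.alive_by_dpi:
            return self.alive_by_dpi[dpi]
        prior = [d for d in self.alive_by_dpi if d <= dpi]
        if not prior:
            return False
        return self.alive_by_dpi[max(prior)]

    def ta(self, dpi: int) -> float | None:
        return self.ta_by_dpi.get(dpi)


@dataclass
class CohortTable:
    """A collection of :class:`EmbryoRecord` with the design endpoints.

    ``baseline_dpi`` (default 1) and ``final_dpi`` bound the experiment;
    inclusion, engraftment and efficacy all compare TA between the two.
    """

    records: list[EmbryoRecord]
    baseline_dpi: int = 1
    final_dpi: int = 3

    def validate(self) -> None:
        if not self.baseline_dpi < self.final_dpi:
            raise CohortValidationError(
                f"baseline_dpi ({self.baseline_dpi}) must precede final_dpi "
                f"({self.final_dpi})"
            )
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.replicate_id, rec.embryo_id)
            if key in seen:
                raise CohortValidationError(
                    f"duplicate (replicate_id, embryo_id) pair {key}"
                )
            seen.add(key)
            rec.validate()

    def __len__(self) -> int:
        return len(self.records)

    def replicate_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.replicate_id not in out:
                out.append(rec.replicate_id)
        return out

    def by_replicate(self) -> dict[str, list[EmbryoRecord]]:
        groups: dict[str, list[EmbryoRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.replicate_id, []).append(rec)
        return groups

    def subset(self, keep: Iterable[EmbryoRecord]) -> "CohortTable":
        keep = list(keep)
        return CohortTable(
            records=keep, baseline_dpi=self.baseline_dpi, final_dpi=self.final_dpi
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format frame, one row per embryo per observed day."""
        rows: list[dict] = []
        any_flags = any(
            rec.included is not None or rec.engrafted is not None
            for rec in self.records
        )
        for rec in self.records:
            for d in sorted(set(rec.alive_by_dpi) | set(rec.ta_by_dpi)):
                row = {
                    "embryo_id": rec.embryo_id,
                    "replicate_id": rec.replicate_id,
                    "group": rec.group,
                    "site": rec.site,
                    "dpi": int(d),
                    "tumor_area": rec.ta_by_dpi.get(d, np.nan),
                    "alive": int(rec.alive_by_dpi.get(d, False)),
                }
                if any_flags:
                    row["included"] = rec.included
                    row["engrafted"] = rec.engrafted
                rows.append(row)
        columns = list(COHORT_COLUMNS) + (list(FLAG_COLUMNS) if any_flags else [])
        return pd.DataFrame(rows, columns=columns)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        baseline_dpi: int = 1,
        final_dpi: int | None = None,
    ) -> "CohortTable":
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        records: list[EmbryoRecord] = []
        if len(df):
            for (rep, emb), sub in df.groupby(
                ["replicate_id", "embryo_id"], sort=False
            ):
                first = sub.iloc[0]
                rec = EmbryoRecord(
                    embryo_id=str(emb),
                    replicate_id=str(rep),
                    group=str(first["group"]),
                    site=str(first["site"]),
                )
                for _, row in sub.iterrows():
                    d = int(row["dpi"])
                    rec.alive_by_dpi[d] = bool(int(row["alive"]))
                    ta = row["tumor_area"]
                    if ta is not None and not pd.isna(ta):
                        rec.ta_by_dpi[d] = float(ta)
                if "included" in sub.columns and not pd.isna(first.get("included")):
                    rec.included = bool(first["included"])
                if "engrafted" in sub.columns and not pd.isna(first.get("engrafted")):
                    rec.engrafted = bool(first["engrafted"])
                records.append(rec)
        if final_dpi is None:
            final_dpi = (
                int(df["dpi"].max()) if len(df) else baseline_dpi + 1
            )
            if final_dpi <= baseline_dpi:
                final_dpi = baseline_dpi + 1
        cohort = cls(records=records, baseline_dpi=baseline_dpi, final_dpi=final_dpi)
        cohort.validate()
        return cohort


def read_cohort(
    path: str | Path,
    config: Mapping | None = None,
    *,
    baseline_dpi: int | None = None,
    final_dpi: int | None = None,
) -> CohortTable:
    """Read and validate a long-format cohort CSV.

    ``config`` may supply ``baseline_dpi`` / ``final_dpi``; explicit
    keyword arguments win.  Rows for dead embryos after death must carry
    no tumor area; violations raise :class:`CohortValidationError` naming
    the embryo.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if config:
        baseline_dpi = baseline_dpi if baseline_dpi is not None else config.get(
            "baseline_dpi"
        )
        final_dpi = final_dpi if final_dpi is not None else config.get("final_dpi")
    return CohortTable.from_dataframe(
        df,
        baseline_dpi=1 if baseline_dpi is None else int(baseline_dpi),
        final_dpi=None if final_dpi is None else int(final_dpi),
    )


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write ``cohort`` to a long-format CSV (UTF-8, header row).

    ``read_cohort(write_cohort(x))`` reproduces ``x`` exactly (Python float
    repr round-trips through text).
    """
    cohort.validate()
    df = cohort.to_dataframe()
    df.to_csv(path, index=False)
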