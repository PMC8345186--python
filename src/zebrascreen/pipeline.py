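"""End-to-end orchestration of the screening roadmap.

One call runs the full decision sequence on a cohort table (measured or
simulated): inclusion filtering, engraftment verification (the vehicle
group must show tumor growth from baseline to the final day — a failure
is a prominent warning, never a silent pass), engraftment percentage,
and the efficacy metrics, emitting a machine-readable JSON report plus
the filtered cohort CSV.

Reports carry no timestamps: the same configuration and seed produce a
byte-identical report.  The report schema is the pydantic model
:class:`ScreenReport`; :func:`report_json_schema` exports it as JSON
Schema.
"""
from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .data_model import CohortTable, read_cohort, write_cohort
from .efficacy import efficacy_report
from .engraftment import engraftment_percentage
from .qc_inclusion import (
    DEFAULT_DISCARD_FRACTION,
    DEFAULT_MULTIPLIER,
    apply_inclusion,
    survival_percentage,
)
from .imaging import DEFAULT_THRESHOLD, DICE_SUCCESS_CUTOFF
from .synthetic import CohortSimParams, simulate_cohort

logger = logging.getLogger("zebrascreen")


class EngraftmentVerificationWarning(UserWarning):
    """Raised (as a warning) when the vehicle group shows no tumor growth."""


class RunConfig(BaseModel):
    """Configuration of one screening run; defaults are the roadmap's
    stated constants (threshold 7000, IQR multiplier 1.25, replicate
    discard fraction 0.25, Dice cutoff 0.60)."""

    cohort_path: Optional[str] = None
    simulate: Optional[dict[str, Any]] = None
    out_dir: str = "zebrascreen_out"
    baseline_dpi: int = 1
    final_dpi: Optional[int] = None
    vehicle_group: str = "vehicle"
    treated_group: str = "treated"
    image_threshold: float = DEFAULT_THRESHOLD
    inclusion_multiplier: float = DEFAULT_MULTIPLIER
    discard_fraction: float = DEFAULT_DISCARD_FRACTION
    dice_cutoff: float = DICE_SUCCESS_CUTOFF
    stat: Literal["mean", "median"] = "mean"
    area_units: str = "pixels"
    seed: int = 0

    @model_validator(mode="after")
    def _one_input(self) -> "RunConfig":
        if (self.cohort_path is None) == (self.simulate is None):
            raise ValueError("provide exactly one of cohort_path or simulate")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        return cls.model_validate(data)


class ScreenReport(BaseModel):
    """Machine-readable outcome of one screening run."""

    version: str
    config: RunConfig
    n_embryos: int
    inclusion: dict[str, Any]
    survival_pct_final: float
    engraftment: dict[str, Any]
    engraftment_verified: bool
    vehicle_growth_pct: float
    efficacy: dict[str, Any]


def report_json_schema() -> dict:
    """JSON Schema of the screening report."""
    return ScreenReport.model_json_schema()


def run_screen(config: RunConfig) -> ScreenReport:
    """Execute the roadmap end to end and write report files to
    ``config.out_dir``.

    Stages: ingest (or simulate) the cohort, apply the inclusion
    criterion and replicate discard rule, verify engraftment in the
    vehicle group, compute the engraftment percentage and the efficacy
    metrics, then write ``report.json`` and ``included_cohort.csv``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        params = CohortSimParams(**config.simulate)
        if "seed" not in config.simulate:
            params.seed = config.seed
        cohort, truth = simulate_cohort(params)
        truth.to_csv(out / "ground_truth.csv", index=False)
        write_cohort(cohort, out / "simulated_cohort.csv")
        logger.info("simulated cohort: %d embryos", len(cohort))
    else:
        cohort = read_cohort(
            config.cohort_path,
            baseline_dpi=config.baseline_dpi,
            final_dpi=config.final_dpi,
        )
        logger.info("loaded cohort %s: %d embryos", config.cohort_path, len(cohort))
    if config.final_dpi is not None:
        cohort.final_dpi = config.final_dpi
    cohort.validate()

    incl, filtered = apply_inclusion(
        cohort,
        multiplier=config.inclusion_multiplier,
        discard_fraction=config.discard_fraction,
    )
    logger.info(
        "inclusion: IT=%s, %d included / %d embryos",
        incl.threshold_it,
        incl.n_included,
        len(cohort),
    )
    if len(filtered) == 0:
        raise RuntimeError("inclusion stage removed every embryo; nothing to analyze")

    survival = survival_percentage(cohort, cohort.final_dpi)
    eng = engraftment_percentage(filtered)
    eff = efficacy_report(
        filtered,
        vehicle_group=config.vehicle_group,
        treated_group=config.treated_group,
        stat=config.stat,
    )

    vehicle_growth = eff.group_growth_pct[config.vehicle_group]
    verified = vehicle_growth > 0
    if not verified:
        warnings.warn(
            "Engraftment verification FAILED: vehicle-group tumor growth is "
            f"{vehicle_growth:.1f}% (expected growth > 0). Efficacy metrics "
            "from this run are not interpretable as drug effects.",
            EngraftmentVerificationWarning,
            stacklevel=2,
        )
        logger.warning("engraftment verification failed (vehicle growth %.1f%%)",
                       vehicle_growth)

    report = ScreenReport(
        version=__version__,
        config=config,
        n_embryos=len(cohort),
        inclusion=incl.to_dict(),
        survival_pct_final=survival,
        engraftment=eng.to_dict(),
        engraftment_verified=verified,
        vehicle_growth_pct=vehicle_growth,
        efficacy=eff.to_dict(),
    )
    (out / "report.json").write_text(report.model_dump_json(indent=2) + "\n")
    write_cohort(filtered, out / "included_cohort.csv")
    eff.per_embryo.to_csv(out / "per_embryo_metrics.csv", index=False)
    return report
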