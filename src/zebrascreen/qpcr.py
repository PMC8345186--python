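"""qPCR standard curves, primer QC, and cell quantification by inverse
interpolation.

A standard curve is an ordinary least-squares fit of mean cycle threshold
(Ct) on log10(known cell count) across a dilution series of cell
standards spiked into pools of embryos.  Zero-cell standards are negative
controls: log10(0) is undefined, so they are excluded from the regression
and their Cts kept aside for contamination checks.

Primer quality gates (all must hold): R^2 >= 0.9, slope >= -3.3,
amplification efficiency between 90% and 120% inclusive, and exactly one
peak in the melting curve.  Efficiency derives from the slope as

    E% = (10^(-1/slope) - 1) x 100

(100% means perfect per-cycle doubling, slope = -1/log10(2) ~ -3.32).
The literal "slope >= -3.3" gate admits arbitrarily shallow slopes on its
own; it is the simultaneous efficiency ceiling (<= 120%) that bounds
shallowness.  All gate boundaries are configurable.

Unknown samples are quantified as cells = 10^((Ct - intercept)/slope);
estimates outside the calibrated range of the standards are flagged as
extrapolations.  Samples are pools of embryos (10 per pool by default),
so estimated counts are per pool; the per-embryo figure is a plain
average over the pool and is labeled as such.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Default primer QC gates.
QC_R2_MIN = 0.9
QC_SLOPE_MIN = -3.3
QC_EFFICIENCY_BOUNDS = (90.0, 120.0)

#: Embryos per qPCR sample pool.
DEFAULT_POOL_SIZE = 10

QPCR_COLUMNS = ("sample_id", "role", "template", "known_cells", "ct", "melt_peaks")


@dataclass(frozen=True)
class StandardPoint:
    """One standard: a known cell count with replicate Ct measurements."""

    known_cells: float
    ct_values: tuple[float, ...]
    template: str = "gDNA"

    def __post_init__(self) -> None:
        if self.known_cells < 0:
            raise ValueError("known_cells must be nonnegative")
        for ct in self.ct_values:
            if not (0 < ct <= 45):
                raise ValueError(f"Ct values must lie in (0, 45], got {ct}")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_values))


@dataclass(frozen=True)
class QcVerdict:
    passed: bool
    reasons: tuple[str, ...]
    checks: dict[str, bool] = field(default_factory=dict)


@dataclass
class StandardCurve:
    """Fitted Ct = intercept + slope x log10(cells) with its standards.

    ``slope`` is Ct per log10(cells) (negative for valid amplification),
    ``intercept`` the Ct at one cell.  ``qc`` is set by :func:`primer_qc`.
    """

    slope: float
    intercept: float
    r_squared: float
    points: tuple[StandardPoint, ...]
    template: str = "gDNA"
    qc: QcVerdict | None = None

    @property
    def efficiency_pct(self) -> float:
        return amplification_efficiency(self.slope)

    @property
    def calibrated_range(self) -> tuple[float, float]:
        cells = [p.known_cells for p in self.points if p.known_cells > 0]
        return (min(cells), max(cells))

    def predict_ct(self, cells: float) -> float:
        if cells <= 0:
            raise ValueError("cell count must be positive")
        return self.intercept + self.slope * math.log10(cells)


def fit_standard_curve(
    points: Iterable[StandardPoint], template: str | None = None
) -> StandardCurve:
    """OLS fit of mean Ct on log10(known cells) over the positive standards.

    Requires at least 3 points with ``known_cells > 0`` and at least two
    distinct counts; zero-cell negative controls are carried along but not
    fitted.  Technical-replicate Cts are averaged before fitting.
    """
    pts = tuple(points)
    positive = [p for p in pts if p.known_cells > 0]
    if len(positive) < 3:
        raise ValueError(
            f"standard-curve fit needs >= 3 positive-count points, got {len(positive)}"
        )
    x = np.log10([p.known_cells for p in positive])
    y = np.array([p.mean_ct for p in positive])
    if np.unique(x).size < 2:
        raise ValueError("standards have identical cell counts; fit is degenerate")
    fit = stats.linregress(x, y)
    if template is None:
        template = positive[0].template
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        points=pts,
        template=template,
    )


def amplification_efficiency(slope: float) -> float:
    """Amplification efficiency E% = (10^(-1/slope) - 1) x 100 for slope < 0."""
    if slope >= 0:
        raise ValueError("efficiency is defined only for negative slopes")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def primer_qc(
    curve: StandardCurve,
    n_melt_peaks: int,
    r2_min: float = QC_R2_MIN,
    slope_min: float = QC_SLOPE_MIN,
    efficiency_bounds: tuple[float, float] = QC_EFFICIENCY_BOUNDS,
) -> QcVerdict:
    """Primer quality gates; all must pass, failures itemized.

    Gates (defaults): R^2 >= 0.9, slope >= -3.3, 90 <= efficiency <= 120
    (inclusive bounds), exactly one melt-curve peak.  The verdict is also
    stored on ``curve.qc``.
    """
    eff = curve.efficiency_pct
    lo, hi = efficiency_bounds
    checks = {
        "r_squared": curve.r_squared >= r2_min,
        "slope": curve.slope >= slope_min,
        "efficiency": lo <= eff <= hi,
        "melt_peaks": n_melt_peaks == 1,
    }
    reasons = []
    if not checks["r_squared"]:
        reasons.append(f"R² {curve.r_squared:.4f} < {r2_min}")
    if not checks["slope"]:
        reasons.append(f"slope {curve.slope:.4f} < {slope_min}")
    if not checks["efficiency"]:
        reasons.append(f"efficiency {eff:.1f}% outside [{lo}, {hi}]%")
    if not checks["melt_peaks"]:
        reasons.append(f"melt peaks {n_melt_peaks} != 1")
    verdict = QcVerdict(passed=all(checks.values()), reasons=tuple(reasons), checks=checks)
    curve.qc = verdict
    return verdict


@dataclass(frozen=True)
class CellEstimate:
    """An interpolated cell count; ``extrapolated`` marks estimates outside
    the calibrated range of the standards."""

    cells: float
    extrapolated: bool

    def __float__(self) -> float:
        return self.cells


def interpolate_cell_count(
    ct: float, curve: StandardCurve, allow_failed_qc: bool = False
) -> CellEstimate:
    """Inverse interpolation: cells = 10^((ct - intercept)/slope).

    Refuses a curve whose primer QC failed unless ``allow_failed_qc`` is
    set (then a warning is emitted).  A curve with no QC verdict is used
    as-is.
    """
    if curve.slope == 0:
        raise ValueError("cannot invert a flat standard curve (slope 0)")
    if curve.qc is not None and not curve.qc.passed:
        if not allow_failed_qc:
            raise ValueError(
                "standard curve failed primer QC "
                f"({'; '.join(curve.qc.reasons)}); pass allow_failed_qc=True "
                "to interpolate anyway"
            )
        warnings.warn(
            "interpolating on a standard curve that failed primer QC: "
            + "; ".join(curve.qc.reasons),
            stacklevel=2,
        )
    cells = 10.0 ** ((ct - curve.intercept) / curve.slope)
    lo, hi = curve.calibrated_range
    return CellEstimate(cells=float(cells), extrapolated=not (lo <= cells <= hi))


@dataclass(frozen=True)
class DynamicRangeSpacing:
    """Resolvable log10-fold separations between adjacent standards."""

    separations: tuple[float, ...]
    mean: float


def dynamic_range_spacing(curve: StandardCurve) -> DynamicRangeSpacing:
    """Resolvable fold change between adjacent standards, in log10 units.

    For each adjacent pair of positive standards (ordered by cell count)
    the separation is |ΔmeanCt| / |slope| — the log10-fold change in cell
    count the assay resolves between them.  Wider separations mean a
    larger dynamic range but a coarser (less sensitive) readout.
    """
    positive = sorted(
        (p for p in curve.points if p.known_cells > 0), key=lambda p: p.known_cells
    )
    if len(positive) < 2:
        raise ValueError("dynamic-range spacing needs >= 2 positive standards")
    counts = [p.known_cells for p in positive]
    if len(set(counts)) != len(counts):
        raise ValueError("duplicate standard cell counts")
    if curve.slope == 0:
        raise ValueError("spacing is undefined for a flat curve")
    seps = tuple(
        abs(b.mean_ct - a.mean_ct) / abs(curve.slope)
        for a, b in zip(positive, positive[1:])
    )
    return DynamicRangeSpacing(separations=seps, mean=float(np.mean(seps)))


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read the qPCR CSV (one row per technical replicate).

    Columns: sample_id, role (standard|unknown|negative), template
    (gDNA|RNA), known_cells, ct, melt_peaks.  "undetermined" Cts (blank or
    the literal string) become missing values.
    """
    df = pd.read_csv(path)
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR table missing column(s): {', '.join(missing)}")
    df["ct"] = pd.to_numeric(
        df["ct"].replace({"undetermined": np.nan, "Undetermined": np.nan}),
        errors="coerce",
    )
    return df


def standards_from_table(df: pd.DataFrame, template: str = "gDNA") -> list[StandardPoint]:
    """Build :class:`StandardPoint` objects from standard/negative rows.

    Replicate rows sharing a sample_id are collapsed into one point; a
    point whose Cts are all missing is dropped with a warning.
    """
    sub = df[(df["template"] == template) & (df["role"].isin(["standard", "negative"]))]
    points: list[StandardPoint] = []
    for sid, grp in sub.groupby("sample_id", sort=False):
        cts = tuple(float(c) for c in grp["ct"].dropna())
        cells = float(grp["known_cells"].iloc[0])
        if not cts:
            if cells > 0:
                warnings.warn(
                    f"standard {sid!r}: all Ct replicates undetermined; point dropped",
                    stacklevel=2,
                )
            continue
        points.append(StandardPoint(known_cells=cells, ct_values=cts, template=template))
    return points


def quantify_unknowns(
    df: pd.DataFrame,
    curve: StandardCurve,
    pool_size: int = DEFAULT_POOL_SIZE,
    allow_failed_qc: bool = False,
) -> pd.DataFrame:
    """Interpolate cell counts for every unknown sample in the table.

    Returns one row per unknown with the pooled estimate and a per-embryo
    average (``cells_per_pool / pool_size`` — an average over the pool,
    not an individual measurement).
    """
    sub = df[(df["template"] == curve.template) & (df["role"] == "unknown")]
    rows = []
    for sid, grp in sub.groupby("sample_id", sort=False):
        cts = grp["ct"].dropna()
        if cts.empty:
            continue
        est = interpolate_cell_count(
            float(cts.mean()), curve, allow_failed_qc=allow_failed_qc
        )
        rows.append(
            {
                "sample_id": sid,
                "template": curve.template,
                "mean_ct": float(cts.mean()),
                "cells_per_pool": est.cells,
                "cells_per_embryo_avg": est.cells / pool_size,
                "extrapolated": est.extrapolated,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "template",
            "mean_ct",
            "cells_per_pool",
            "cells_per_embryo_avg",
            "extrapolated",
        ],
    )
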