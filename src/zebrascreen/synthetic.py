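"""Synthetic generators for every input the screening pipeline consumes.

The cohort generator emulates the structure the analysis assumes rather
than any biophysical tumor model: baseline (1 dpi) tumor areas are
lognormal with a mis-injected subpopulation scaled down by a fixed
factor; growth is multiplicative per day,

    TA(d+1) = TA(d) x g_i x m x eps_d,

where ``g_i`` is the embryo's daily growth factor (lognormal around the
site's factor, dispersion ``growth_log_sd``), ``m`` the treated-group
growth multiplier (1 for vehicle), and ``eps_d`` mean-one lognormal
day-to-day noise — mean-one so that the expected normalized tumor area
over ``k`` days is exactly ``(g m)^k``.  Death is a daily Bernoulli
event, absorbing, and independent of tumor size by default.

Site presets approximate the reported behavior of the four implantation
sites (pericardial space best, yolk worst); they are conveniences for
realistic simulations and are never asserted as ground truth.

All generators are deterministic under their seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .data_model import CohortTable, EmbryoRecord
from .imaging import DEFAULT_THRESHOLD, dice


# ---------------------------------------------------------------------------
# cohorts

#: Per-site daily growth factor, embryo-to-embryo growth dispersion (log SD),
#: day-to-day multiplicative noise (log SD) and daily mortality probability.
#: Tuned so pooled summaries land near the reported site behavior
#: (e.g. pericardial-space engraftment ~93%, yolk ~27%) — approximations,
#: not assertions.
SITE_PRESETS: dict[str, dict[str, float]] = {
    "PCS": {
        "growth_factor": 1.47,
        "growth_log_sd": 0.15,
        "noise_sd": 0.25,
        "daily_mortality": 0.0353,
    },
    "dorsal-PVS": {
        "growth_factor": 1.65,
        "growth_log_sd": 0.12,
        "noise_sd": 0.20,
        "daily_mortality": 0.134,
    },
    "ventral-PVS": {
        "growth_factor": 1.443,
        "growth_log_sd": 0.20,
        "noise_sd": 0.30,
        "daily_mortality": 0.195,
    },
    "yolk": {
        "growth_factor": 0.82,
        "growth_log_sd": 0.335,
        "noise_sd": 0.30,
        "daily_mortality": 0.323,
    },
}


@dataclass
class CohortSimParams:
    """Design of a simulated screening cohort.

    Defaults follow the screening design: 24 embryos per experimental
    group, 3 independent replicates, baseline at 1 dpi, final day 4 dpi,
    pericardial-space growth/mortality, a 10% mis-injected subpopulation
    whose baseline TA is scaled by 0.1, and 10% (log) day-to-day
    measurement/process noise unless a site preset overrides it.
    """

    n_per_group: int = 24
    n_replicates: int = 3
    groups: tuple[str, ...] = ("vehicle", "treated")
    site: str = "PCS"
    baseline_log_mean: float = math.log(2000.0)
    baseline_log_sd: float = 0.35
    misinjection_fraction: float = 0.10
    misinjection_factor: float = 0.10
    growth_factor: float = 1.47
    growth_log_sd: float = 0.15
    treated_growth_multiplier: float = 1.0
    daily_mortality: float = 0.0353
    noise_sd: float = 0.10
    baseline_dpi: int = 1
    final_dpi: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1 or self.n_replicates < 1 or not self.groups:
            raise ValueError("cohort design must be nonempty")
        if not 0 <= self.misinjection_fraction <= 1:
            raise ValueError("misinjection_fraction must be a probability in [0, 1]")
        if not 0 <= self.daily_mortality <= 1:
            raise ValueError("daily_mortality must be a probability in [0, 1]")
        if not (0 < self.misinjection_factor < 1):
            raise ValueError("misinjection_factor must lie in (0, 1)")
        if self.growth_factor <= 0 or self.treated_growth_multiplier <= 0:
            raise ValueError("growth factors must be positive")
        if self.growth_log_sd < 0 or self.noise_sd < 0 or self.baseline_log_sd < 0:
            raise ValueError("dispersion parameters must be nonnegative")
        if not self.baseline_dpi < self.final_dpi:
            raise ValueError("baseline_dpi must precede final_dpi")

    @classmethod
    def for_site(cls, site: str, **overrides) -> "CohortSimParams":
        """Parameters preset for an implantation site (see SITE_PRESETS)."""
        if site not in SITE_PRESETS:
            raise ValueError(f"no preset for site {site!r}; known: {sorted(SITE_PRESETS)}")
        kwargs = {"site": site, **SITE_PRESETS[site], **overrides}
        return cls(**kwargs)


def simulate_cohort(
    params: CohortSimParams, seed: int | None = None
) -> tuple[CohortTable, pd.DataFrame]:
    """Simulate a cohort plus its latent ground truth.

    Returns ``(cohort, truth)`` where ``truth`` has one row per embryo
    with its mis-injection flag, realized daily growth factor (including
    any treatment multiplier) and death day (NaN when it survived).
    Deterministic under the seed (``seed`` overrides ``params.seed``).
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    records: list[EmbryoRecord] = []
    truth_rows: list[dict] = []
    days = range(params.baseline_dpi, params.final_dpi + 1)
    counter = 0
    for r in range(1, params.n_replicates + 1):
        rep_id = f"R{r}"
        for group in params.groups:
            mult = (
                params.treated_growth_multiplier if group == "treated" else 1.0
            )
            for _ in range(params.n_per_group):
                counter += 1
                emb_id = f"E{counter:04d}"
                misinjected = bool(rng.random() < params.misinjection_fraction)
                ta = float(
                    np.exp(
                        params.baseline_log_mean
                        + params.baseline_log_sd * rng.standard_normal()
                    )
                )
                if misinjected:
                    ta *= params.misinjection_factor
                g_i = params.growth_factor * math.exp(
                    params.growth_log_sd * rng.standard_normal()
                )
                rec = EmbryoRecord(
                    embryo_id=emb_id,
                    replicate_id=rep_id,
                    group=group,
                    site=params.site,
                )
                rec.alive_by_dpi[params.baseline_dpi] = True
                rec.ta_by_dpi[params.baseline_dpi] = ta
                death_dpi: float = math.nan
                alive = True
                for d in days:
                    if d == params.baseline_dpi:
                        continue
                    if alive and rng.random() < params.daily_mortality:
                        alive = False
                        death_dpi = d
                    rec.alive_by_dpi[d] = alive
                    if alive:
                        # mean-one lognormal day-to-day noise
                        eps = math.exp(
                            -0.5 * params.noise_sd**2
                            + params.noise_sd * rng.standard_normal()
                        )
                        ta = ta * g_i * mult * eps
                        rec.ta_by_dpi[d] = ta
                records.append(rec)
                truth_rows.append(
                    {
                        "embryo_id": emb_id,
                        "replicate_id": rep_id,
                        "group": group,
                        "site": params.site,
                        "misinjected": misinjected,
                        "daily_growth_factor": g_i * mult,
                        "death_dpi": death_dpi,
                    }
                )
    cohort = CohortTable(
        records=records,
        baseline_dpi=params.baseline_dpi,
        final_dpi=params.final_dpi,
    )
    cohort.validate()
    return cohort, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# qPCR

#: Four-fold serial dilution from 1.28e5 cells down to 500, plus a
#: zero-cell negative control appended by the generator.
DEFAULT_DILUTION: tuple[float, ...] = (128000.0, 32000.0, 8000.0, 2000.0, 500.0)

#: Slope of a perfect per-cycle doubling: -1/log10(2).
IDEAL_SLOPE = -1.0 / math.log10(2.0)


@dataclass
class QpcrSimParams:
    """Design of a simulated qPCR standard-curve experiment.

    ``dilution`` are the known spiked cell counts (positive standards); a
    zero-cell negative-control row (undetermined Ct) is always emitted.
    ``unknown_cells`` are true counts of unknown samples to measure.
    """

    slope: float = IDEAL_SLOPE
    intercept: float = 35.0
    noise_sd: float = 0.2
    dilution: tuple[float, ...] = DEFAULT_DILUTION
    replicates: int = 3
    template: str = "gDNA"
    unknown_cells: tuple[float, ...] = ()
    melt_peaks: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.slope >= 0:
            raise ValueError("slope must be negative (Ct falls as template rises)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate per point")
        if any(c <= 0 for c in self.dilution):
            raise ValueError("dilution counts must be positive (the zero-cell "
                             "negative control is added automatically)")


def simulate_qpcr(params: QpcrSimParams, seed: int | None = None) -> pd.DataFrame:
    """Simulate a qPCR table: Ct = intercept + slope·log10(cells) + noise.

    One row per technical replicate, in the CSV schema the reader
    consumes (sample_id, role, template, known_cells, ct, melt_peaks).
    The zero-cell negative control has an undetermined (missing) Ct.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rows: list[dict] = []
    for i, cells in enumerate(params.dilution, start=1):
        true_ct = params.intercept + params.slope * math.log10(cells)
        for _ in range(params.replicates):
            rows.append(
                {
                    "sample_id": f"STD{i}",
                    "role": "standard",
                    "template": params.template,
                    "known_cells": cells,
                    "ct": true_ct + params.noise_sd * rng.standard_normal(),
                    "melt_peaks": params.melt_peaks,
                }
            )
    rows.append(
        {
            "sample_id": "NEG",
            "role": "negative",
            "template": params.template,
            "known_cells": 0.0,
            "ct": np.nan,
            "melt_peaks": params.melt_peaks,
        }
    )
    for j, cells in enumerate(params.unknown_cells, start=1):
        true_ct = params.intercept + params.slope * math.log10(cells)
        for _ in range(params.replicates):
            rows.append(
                {
                    "sample_id": f"UNK{j}",
                    "role": "unknown",
                    "template": params.template,
                    "known_cells": np.nan,
                    "ct": true_ct + params.noise_sd * rng.standard_normal(),
                    "melt_peaks": params.melt_peaks,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# images

@dataclass
class ImageSimParams:
    """A fluorescent blob on an autofluorescent background.

    The background stays strictly below ``threshold`` and the blob
    strictly above it, so the thresholded tumor area of the generated
    image equals the blob pixel count exactly.
    """

    shape: tuple[int, int] = (256, 256)
    background: float = 3000.0
    background_noise_sd: float = 300.0
    blob_center: tuple[float, float] | None = None
    blob_radius: float = 20.0
    blob_intensity: float = 20000.0
    blob_noise_sd: float = 500.0
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    def validate(self) -> None:
        h, w = self.shape
        if h < 1 or w < 1:
            raise ValueError("image shape must be positive")
        if not (0 <= self.background < self.threshold):
            raise ValueError("background level must lie below the threshold")
        if not (self.threshold < self.blob_intensity <= 65535):
            raise ValueError("blob intensity must exceed the threshold")
        cy, cx = self.blob_center if self.blob_center else (h / 2, w / 2)
        r = self.blob_radius
        if r <= 0:
            raise ValueError("blob radius must be positive")
        if cy - r < 0 or cx - r < 0 or cy + r > h - 1 or cx + r > w - 1:
            raise ValueError("blob does not fit inside the frame")


@dataclass(frozen=True)
class ImageSample:
    """A simulated acquisition with its exact ground truth."""

    image: np.ndarray
    true_area: int
    blob_mask: np.ndarray


def simulate_image(params: ImageSimParams, seed: int | None = None) -> ImageSample:
    """Render the blob-on-background image and return its exact tumor area.

    Background noise is clipped below the threshold and blob noise above
    it, so ``tumor_area(image, threshold)`` recovers ``true_area``
    exactly regardless of the noise draw.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    h, w = params.shape
    img = params.background + params.background_noise_sd * rng.standard_normal((h, w))
    img = np.clip(img, 0, params.threshold - 1)
    cy, cx = params.blob_center if params.blob_center else (h / 2, w / 2)
    rr, cc = draw_disk((cy, cx), params.blob_radius, shape=(h, w))
    blob = params.blob_intensity + params.blob_noise_sd * rng.standard_normal(rr.size)
    img[rr, cc] = np.clip(blob, params.threshold + 1, 65535)
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    return ImageSample(
        image=img.astype(np.uint16), true_area=int(rr.size), blob_mask=mask
    )


# ---------------------------------------------------------------------------
# mask pairs

def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    mask[rr, cc] = True
    return mask


def simulate_mask_pair(
    shape: tuple[int, int],
    target_dice: float,
    seed: int = 0,
    radius: float | None = None,
    tolerance: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Two disk masks whose Dice coefficient is within ``tolerance`` of
    ``target_dice``.

    The second mask is the first translated by a (sub-pixel) offset found
    by bisection; target 1 returns identical masks and target 0 two
    disjoint disks.  Raises when the geometry cannot reach the target in
    the given frame.
    """
    if not (0 <= target_dice <= 1):
        raise ValueError("target_dice must lie in [0, 1]")
    h, w = shape
    r = radius if radius is not None else max(6.0, min(h, w) / 6.0)
    if 2 * r + 2 > min(h, w):
        raise ValueError("mask radius does not fit in the frame")
    rng = np.random.default_rng(seed)
    cy = h / 2 + rng.uniform(-2, 2)
    cx0 = r + 1 + rng.uniform(0, 2)
    base = _disk_mask(shape, (cy, cx0), r)
    if target_dice == 1.0:
        return base, base.copy()
    if target_dice == 0.0:
        cx1 = cx0 + 2 * r + 2
        if cx1 + r > w - 1:
            raise ValueError("frame too small for two disjoint masks")
        return base, _disk_mask(shape, (cy, cx1), r)
    lo, hi = 0.0, 2 * r + 2
    if cx0 + hi + r > w - 1:
        hi = w - 1 - r - cx0
        if dice(base, _disk_mask(shape, (cy, cx0 + hi), r)) > target_dice + tolerance:
            raise ValueError("frame too small to reach the requested Dice target")
    best = None
    for _ in range(60):
        mid = (lo + hi) / 2
        other = _disk_mask(shape, (cy, cx0 + mid), r)
        d = dice(base, other)
        if best is None or abs(d - target_dice) < abs(best[0] - target_dice):
            best = (d, other)
        if abs(d - target_dice) <= tolerance / 2:
            break
        if d > target_dice:
            lo = mid
        else:
            hi = mid
    assert best is not None
    if abs(best[0] - target_dice) > tolerance:
        raise ValueError(
            f"could not construct masks within {tolerance} of Dice "
            f"{target_dice} (best {best[0]:.3f}); try a larger frame/radius"
        )
    return base, best[1]
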