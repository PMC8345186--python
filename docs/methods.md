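# Methods

## Scope and model

`zebrascreen` implements the quantitative layer of a zebrafish-embryo
xenograft drug screen: deterministic metrics and QC rules applied to
per-embryo tumor-area (TA) trajectories, fluorescence images, qPCR
tables and dose specifications. It deliberately contains no inferential
statistics of its own — ANOVA-family tests, survival-curve estimation,
correlation tests and outlier removal are standard off-the-shelf
procedures that users can run on the package's outputs with statsmodels,
lifelines, or any stats package; re-implementing them here would add
nothing. The implemented contribution is the metric pipeline itself:
inclusion → engraftment → efficacy, plus the imaging, qPCR and dosing
arithmetic it depends on.

## Inclusion criterion

The threshold `IT = median(TA at baseline) − multiplier × IQR`
(multiplier 1.25) is computed across the whole experiment's baseline
TAs, all groups and replicates pooled. A per-replicate mode exists but
is off by default: the criterion is defined per experiment, and pooling
gives the threshold more support. Comparison is strict (`TA > IT`),
reading "higher than the threshold" literally, so boundary embryos are
excluded; the replicate-discard rule is likewise strict (removed when
the excluded fraction exceeds 0.25). Quantiles use linear interpolation
between order statistics (numpy's default, spreadsheet "type 7"); no
convention is prescribed by the procedure, alternatives (e.g. Tukey
hinges) shift IT slightly, and the convention used is configurable and
recorded in every `InclusionResult`.

**The criterion is not idempotent.** For a homogeneous location-scale
baseline population, `median − 1.25×IQR` sits near the 4.6th percentile
(Φ(−1.686) for a Gaussian; the same quantile for a lognormal, since the
rule is applied on the raw scale but the quantile position is
scale-free), so re-applying the filter to its own output trims another
~4–5%. Idempotency holds only when the threshold falls in a density gap
— the intended regime, with a mis-injected subpopulation well separated
from the main one. The pipeline applies the criterion exactly once,
matching how it is defined.

Degenerate inputs: a constant baseline set gives IQR 0 and IT equal to
the common value, so the strict comparison excludes every embryo. This
is the faithful reading of the rule; callers with discrete TA scales
should be aware of it.

## Engraftment and efficacy

Engraftment is inclusive (`TA_final ≥ TA_baseline`): an unchanged tumor
counts as engrafted. The percentage's denominator is living embryos on
the final day; embryos dead before then (or lacking a final TA) are
excluded from numerator and denominator alike, and appear only in
survival percentages. Per-replicate percentages are summarized by their
mean and sample SD (ddof 1) across replicates.

Efficacy metrics are computed per embryo and summarized per group. The
group summary statistic is the arithmetic mean by default — group
growth % is the mean of per-embryo RTGs, not the RTG of summed areas,
because per-embryo distributions (and their SDs) are the reported unit
of variation — with the median available via configuration for
long-tailed cohorts; the statistic used is recorded in every report.
Only embryos alive at the final day with a positive baseline TA
contribute. Outlier handling is advisory only: an optional flag marks
NTAs further than 3 scaled MADs from their group median but removes
nothing; any removal policy is the caller's responsibility.

The end-to-end runner additionally *verifies engraftment*: the vehicle
group must show positive mean tumor growth, otherwise the run emits an
`EngraftmentVerificationWarning` and the report carries
`engraftment_verified: false` — efficacy numbers from such a run are not
interpretable as drug effects.

## Imaging

Tumor area counts pixels strictly above the threshold (default 7000 of
65535): the threshold's purpose is to remove autofluorescence at or
below it, so the boundary intensity is background. Whether a borderline
pixel is counted is therefore a documented choice, configurable via the
threshold value itself. ROI metrics are plain pixel count, mean and sum;
the identity `IntDen = Mean × Area` holds to floating tolerance by
construction. Dice similarity uses the usual `2|a∩b|/(|a|+|b|)` on
boolean grids; a delineation pair is "successful" strictly above 0.60,
so a coefficient of exactly 0.60 fails. Both masks empty is an error
(0/0). Images are single-channel; acquisition settings are metadata the
computation never sees, and there is no automated embryo segmentation —
the search region is the whole image or a caller-supplied mask.

## qPCR

Standard curves are OLS fits (scipy) of mean Ct on log10(known cells).
Technical replicates are averaged before fitting; "undetermined" Cts are
missing values, and a standard whose replicates are all missing is
dropped with a warning. Zero-cell standards are negative controls:
log10(0) is undefined, so they never enter the fit and their Cts are
kept for contamination checks. Amplification efficiency is
`(10^(−1/slope) − 1) × 100`.

QC gates: R² ≥ 0.9, slope ≥ −3.3, efficiency in [90, 120]% (inclusive
bounds), exactly one melt peak. The slope gate is implemented literally
even though on its own it admits arbitrarily shallow slopes — the
efficiency ceiling is what bounds shallowness, and the gate thresholds
are configurable for labs using the conventional `slope ≤ −3.3` reading.
Melt-peak counting is an input field, not a computation: raw
fluorescence processing and Ct calling are out of scope.

Inverse interpolation `cells = 10^((Ct − intercept)/slope)` flags
estimates outside the calibrated range of the standards as
extrapolations and refuses a QC-failed curve unless explicitly
overridden (with a warning). Dynamic-range spacing reports
`|ΔmeanCt|/|slope|` per adjacent standard pair — the resolvable
log10-fold change between points, the quantity that trades dynamic range
against sensitivity when choosing a dilution design. Quantified samples
are pools (10 embryos by default); the per-embryo figure is an average
over the pool, labeled as such.

## Dosing

All conversions are exact closed forms over three fixed compartments:
4 nL injection bolus, 270 nL embryo (total volume at 3 dpf), 200 µL
bath well; custom volumes are accepted in liters. External units are ng
and µM to match reporting convention, SI internally. Molar mass is
always a caller input (tests use selinexor, 443.31 g/mol). The published
6.1 ng ↔ 50 µM embryo-compartment pairing is internally rounded
(back-calculation implies ≈452 g/mol or ≈275 nL); tests therefore assert
embryo-compartment conversions within 3% and bath conversions at the
printed precision, rather than guessing which constant was rounded.

## Synthetic data

The cohort generator emulates the statistical structure the metrics
assume, not tumor biology:

- Baseline TA ~ lognormal (default median 2000 area units, log-SD 0.35 —
  a unimodal, right-skewed population typical of thresholded
  fluorescence areas), with a mis-injected fraction (default 10%) scaled
  by 0.1, the population the inclusion criterion exists to remove.
- Growth is multiplicative per day with per-embryo daily factor
  `g_i = g·exp(τZ)` (site factor `g`, inter-embryo dispersion `τ`) times
  a treated-group multiplier, times mean-one lognormal day-to-day noise
  (default log-SD 0.10, i.e. ~10% CV, modest measurement/process noise
  for threshold-area quantification). Mean-one noise makes the expected
  NTA over `k` days exactly `(g·m)^k`, which is what the
  parameter-recovery checks exploit. A multiplicative model is the
  natural partner of ratio metrics (NTA, RTG) and of the skewed
  distributions these assays produce; it is a modeling choice, not a
  claim about melanoma growth kinetics.
- Death is a daily Bernoulli event, absorbing, independent of tumor size
  by default (no mortality model is prescribed by the assay; a
  size-linked mechanism would require assumptions the data cannot
  support).

Site presets (PCS, dorsal/ventral PVS, yolk) set `g`, `τ`, noise and
mortality so that pooled summaries land near the reported site ranking —
pericardial space engrafting ~93% with the best survival, yolk ~27%
with shrinking tumors. They are conveniences for realistic simulations:
under a mean-one lognormal model the yolk's reported pair (27%
engraftment alongside a 33% mean TA drop) is not exactly reachable
without heavy per-embryo growth dispersion, so the yolk preset
prioritizes the engraftment fraction. Tests assert only the qualitative
site ordering, never the published percentages, which derive from
undeposited wet-lab measurements.

The qPCR generator draws Ct = intercept + slope·log10(cells) + Gaussian
noise over a 4-fold dilution series from 1.28×10⁵ down to 500 cells
plus a zero-cell negative control (3 replicates/point, noise SD 0.2 —
ordinary technical-replicate scatter). The image generator renders a
disk blob (intensity clipped above the threshold) on a noisy background
(clipped below it), so the thresholded area equals the blob pixel count
exactly — by construction, which is what makes it a ground-truth
oracle. The mask-pair generator reaches a prescribed Dice coefficient
by bisecting the sub-pixel translation of a disk.

What passing tests on these generators shows: the metric chain computes
what it claims on data with the assumed structure, at known effect
sizes, under seeded noise. What it does not show: robustness to real
segmentation artifacts, focal-plane loss, spatially structured
autofluorescence, non-lognormal growth, or informative dropout — real
acquisitions need their own QC before these metrics are trusted.

## Numerical and reproducibility choices

- Strict vs inclusive boundaries follow the wording of each rule:
  inclusion strict, replicate discard strict, engraftment inclusive,
  Dice success strict, efficiency bounds inclusive.
- Every generator takes a seed and is bit-deterministic under it;
  pipeline reports contain no timestamps, so a fixed config and seed
  reproduce `report.json` byte for byte.
- Cohort CSVs round-trip exactly (floats written at full precision and
  parsed with round-trip precision).
- Problem sizes in the test and acceptance runs — 1,000 brute-force
  cohorts, 500 random mask pairs, 100 seeded qPCR replicates, 500
  embryos/group for parameter recovery, a 3×24-embryo end-to-end
  screen — were chosen to hold sampling error comfortably inside the
  asserted tolerances while keeping the suite fast.

## Known limitations

- No hit-calling threshold: the pipeline reports DTG and absolute
  differences but does not declare hits; no quantitative cutoff is part
  of the roadmap, so the decision stays with the user.
- No plate/position metadata, no confocal z-stacks or registration, no
  melt-curve signal analysis, no pharmacokinetics; mixed-model handling
  of missing intermediate time points is out of scope (embryos dead
  before the final day simply leave the efficacy metrics).
- The inclusion criterion's non-idempotency (above) is a property of
  the published rule itself, reproduced faithfully here.
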