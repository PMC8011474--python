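# Methods

## Problem and data model

The analysis asks whether fluorescent spots seen once at baseline on an
en-face retinal image (marker-labeled stressed cells, "DARC" spots)
anticipate new subretinal fluid (SRF) on follow-up OCT volume scans of the
same eye. Three coordinate frames are involved: the baseline
autofluorescence image (the reference frame), the post-injection DARC image
(registered to the reference by an affine transform fitted to fiducial
pairs, optionally refined non-rigidly), and the OCT volume (a stack of
B-scans whose fundus placement is described by an `OCTGeometry`: first-slice
row, inter-slice spacing, per-slice column origin/scale). All coordinates
are 0-based pixel centers, `(x, y) = (column, row)`.

## Fluid quantification and conversion

* Visit SRF = pixel sum of the binary per-slice segmentation masks.
* Accumulated SRF per 6-month interval = total SRF pixels across the
  interval's scans / number of scans. The scan-count average is the only
  normalization applied; it makes the summary invariant to duplicated
  scans and to uneven visit schedules.
* An interval is SRF-positive when accumulated SRF exceeds `min_pixels`
  (default 0, i.e. any detected fluid; raise it to reject speckle-sized
  segmentations).
* Intervals are half-open `[6k, 6(k+1))` months from the baseline date;
  boundary visits belong to the later interval. Intervals with no scans
  carry the previous status forward, are flagged, and are excluded from
  correlation analyses.
* Conversion = first SRF-positive interval whose preceding period
  (baseline for the first interval) was negative. Baseline-positive eyes
  never convert. By default only the first transition counts
  (`allow_recurrence` flags later negative-to-positive transitions too,
  but the conversion interval stays the first).

## Unique spots and eye classification

Spots within `baseline_match_radius` (default 3 px) of a
baseline-autofluorescent spot are removed first: they fluoresce before the
marker is injected and are not marker signal. Spots overlying baseline SRF
are excluded from prediction. Each remaining spot is checked per interval
against that interval's masks within a tolerance window of ±1 slice and
±10 columns around its mapped (slice, column) — the field has no published
quantification of "overlying", so both tolerances are configuration. A
spot counts once, at its first overlap with any fluid present; afterwards
it is retired.

Per interval an eye is TP / FN / FP / TN according to whether it has new
SRF and whether any unique spot first overlapped this interval. Note the
FP cell is reachable because first overlaps can occur outside the
conversion interval (fluid persists and grows after conversion, and chance
overlaps exist); under a fully spot-seeded generator every first overlap
coincides with conversion and PPV is exactly 1 — a designed limit the test
suite exercises. Baseline-SRF-positive eyes are excluded from the matrices
by default (`include_baseline_positive` keeps them; they can then only
land in FP/TN). Already-converted eyes remain in later matrices,
classified by that interval's new-SRF flag. Undefined ratios (zero
denominators) are reported as NaN, never as 0 or 1.

The spot-fluid association uses the *cumulative* unique-spot count up to
interval k against interval k's accumulated SRF: after the conversion
interval the per-interval count is almost always zero, so only the
cumulative count can carry a monotone association with accumulated fluid.

## Registration

`fit_affine` solves the least-squares normal equations for a 2×3 affine
from ≥3 non-collinear fiducial pairs (exact on exact correspondences;
collinearity detected via the singular values of the centered sources).
`fundus_to_oct` maps a registered point to the nearest slice row (half-way
ties to the lower index, a documented deterministic rule) and the nearest
column. `nonrigid_refine` resamples the moving image through the affine,
then optimizes a free-form B-spline deformation with SimpleITK: mean
squared intensity difference, 3-level multi-resolution schedule (4×, 2×,
1× downsampling with 2/1/0-px smoothing), control-point spacing 32 px by
default, and the L-BFGS-B gradient-based optimizer — first-order descent
proved unstable on this objective at typical image scales. The refinement
is guaranteed never to worsen the objective: if the optimized field does
not lower the MSE, the zero field is returned with a warning flag.
Identical or constant inputs short-circuit to the zero field (flat
objective). Grid spacing, schedule and stopping tolerance are declared
defaults of this implementation, not reproductions of any published
configuration.

## Spot detection

A classical matched filter stands in for a trained spot classifier:
normalized cross-correlation against a Gaussian template (σ = 2 px,
half-width 3σ), local maxima above a correlation threshold (0.5), optional
area gating of the connected above-threshold region, then greedy
non-maximum suppression by descending score with ties broken by (y, x) —
NMS is idempotent and the accepted count is non-increasing in the
threshold. Matching between spot sets (for baseline subtraction and
tracking) is greedy nearest-neighbor within a radius, taking candidate
pairs in order of increasing distance; it coincides with the optimal
assignment whenever jitter is below half the radius. The template scale
has no field calibration and is configurable.

## Synthetic cohorts

The generator emulates the structure of a small longitudinal AMD cohort,
not its photometric realism. Defaults (the study conditions):

| parameter | default | meaning |
|---|---|---|
| `n_eyes` | 29 | eyes with OCT follow-up |
| `months_followup` / `interval_length` | 36 / 6 | six 6-month intervals |
| `visits_per_interval_mean` | 2.1 | Poisson scans per interval, min 1 (emulated range ≈1.7–2.6) |
| `slices_per_volume` | 50 | B-scans per OCT volume |
| `spot_count_mean` | 6 | angiogenic (marker) spots per eye, Poisson |
| `nuisance_spot_mean` / `autofluorescent_spot_mean` | 2 / 3 | clutter; autofluorescent spots appear in both images and are subtracted |
| `association_strength` | 0.06 | P(an angiogenic spot seeds a lesion centered on itself) |
| `spontaneous_lesion_mean` | 0.1 | Poisson spot-independent lesions per eye |
| `baseline_srf_fraction` | 0.3 | eyes fluid-positive at baseline (≈10/29 emulated) |
| `spot_amplitude` / `background_noise_sd` | 100 / 10 | rendered blob SNR 10 |
| `clinical_flip_prob` | 0.15 | clinical-vs-automated baseline disagreement |

With Poisson(6) spots and per-spot seeding probability 0.06 plus the
spontaneous rate, about 35–40% of at-risk eyes convert by 36 months,
matching the reported-scale conversion prevalence of such cohorts; eyes
with more spots convert more often, which drives the DARC-count>5 survival
split. All of an eye's seeded lesions share one onset interval drawn
uniformly from intervals 1–5 (marker signal precedes leakage by at least
one interval); spontaneous lesions may onset from interval 0. Lesions are
axis-aligned ellipses (semi-axes 8–25 px by default) rasterized onto
B-scan masks as chord-spanning blocks of 4 depth rows, growing 15% of
their linear size per interval of age and never regressing; footprints are
margin-clamped to stay inside the image at maximal growth. A small random
rotation (±2°) plus translation (±5 px) misaligns the DARC frame from the
reference, with exact fiducial pairs provided, so the registration stage
does real work. Visit months are uniform within each interval with
Poisson counts (min 1), reproducing the uneven-scan problem the interval
average normalizes for. Everything is driven by per-eye substreams of one
seed: identical configuration and seed give byte-identical outputs.

What the generator does *not* emulate — OCT speckle, vasculature,
intraretinal fluid and pigment-epithelial detachment, segmentation errors,
real DARC-count distributions per diagnosis group — bounds what passing
tests show: they validate the analysis logic and its parameter recovery,
not clinical performance on patient images.

## Statistics

Cohen's kappa is computed directly from the 2×2 agreement table
(undefined, NaN, when expected agreement is 1). Spearman correlation is the
Pearson correlation of mid-ranks. Mann-Whitney U and Wilcoxon signed-rank
use exact enumeration at small n (all C(n+m, n) group assignments for ≤10
per group; all 2^n sign patterns over mid-ranked |differences| for ≤12
nonzero pairs) so that small-cohort p-values are reproducible as counts —
e.g. seven uniformly signed pairs give exactly 2/2⁷ = 0.015625 two-sided.
Larger samples delegate to scipy's tie-corrected normal approximations
(continuity-corrected for the signed-rank test), which agree with the
exact branch to within 0.02 at the boundary sizes. All p-values are
two-sided (2 × min tail, capped at 1). The slope comparison of the two
survival curves is the t test of the group×time interaction in a pooled
OLS fit (closed-form normal equations). When the two curves are identical
the Wilcoxon statistic is undefined (no nonzero differences); the group
comparison reports p = 1 with the undefined flag preserved.

## Numerical and degenerate-input conventions

Ties: slice assignment to the lower index; NMS by (score desc, y, x);
matching by (distance, then index). Empty windows, empty groups, all-tied
correlations and zero-denominator metrics are NaN plus a flag, never a
silent 0/1. Per-eye failures (out-of-volume spots, unregisterable eyes)
skip the eye with a logged reason; only an empty cohort is a hard error.
The high/low SRF split threshold defaults to 2000 px and is configurable,
as is every other analysis constant (DARC-count split 5, overlap
tolerance, positivity threshold).

## Problem sizes

The test and acceptance runs use reduced cohorts — 6–10 eyes, 128-px
images, 25-slice volumes, and 100 seeded replicates for the
parameter-recovery checks; the detector gate uses 100 images of 256² px
with 20 spots each. These sizes give stable Monte-Carlo estimates (the
recovery checks compare pooled rates over ~600 eye-interval events) while
keeping a full run in well under a minute.

## Known limitations

The detector is a matched filter, not a learned classifier; its 0.9+
sensitivity/precision gate holds on rendered Gaussian blobs, not real
cSLO frames. The per-visit "normalized sum" is implemented as the raw
pixel sum with all normalization carried by the per-interval scan average;
areas are in pixels, not µm². Recurrent conversion after clearing is
supported only as an opt-in flag, and kappa is reported without a
standard error or p-value (the variance model is out of scope).
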