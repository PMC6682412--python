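# Methods

This note documents the models, numerical choices and limitations of
`redoxtrace` at the level of detail a maintainer or reviewer needs.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Ratiometric OxD model

The probe's degree of oxidation is computed from the excitation ratio
R = i405/i488 as

    OxD(R) = (R − R_red) / [ k·(R_ox − R) + (R − R_red) ],   k = i488_ox / i488_red,

anchored by the fully reduced (DTT) and fully oxidized (H2O2)
calibration references.  The anchors are exact by construction
(OxD(R_red) = 0, OxD(R_ox) = 1 to machine precision), the map is
strictly increasing on [R_red, R_ox], and when k = 1 it degenerates to
the linear interpolant (R − R_red)/(R_ox − R_red).  The closed-form
inverse

    R(OxD) = [R_red·(1 − OxD) + OxD·k·R_ox] / [1 − OxD·(1 − k)]

is used by the simulator; the round-trip identity holds to 1e−12 and
is enforced by property tests over randomized calibrations.

**Out-of-range policy.** On real data OxD can exceed 1 (probe noise,
chlorophyll autofluorescence leaking into the i405 channel).  Values
in (1.0, 1.10] are retained and flagged `OVER_RANGE`; values above
1.10 (110%) are flagged `EXCLUDED` and never enter summary statistics,
fractions or histograms.  A non-positive denominator (possible for
R far above R_ox when i488_ox > i488_red) yields NaN flagged
`EXCLUDED` — never an unflagged number.  Ratios with i488 at or below
a configurable floor (default 1e−12) are flagged `INVALID`; for scalar
inputs this raises instead, so a division by zero can never pass
silently.

**Calibration aggregation.** When a calibration is derived from
reference acquisitions, the per-event/per-pixel ratios are aggregated
by the mean for event data (matching how probe dynamic range is
conventionally reported) and the median is recommended for pixel data,
where leakage outliers are common.  Both are trivially available since
the `CalibrationSet` takes plain scalars.  Dynamic range is
R_ox/R_red.

OxD is stored as a fraction throughout; percent appears only in
display strings and report keys, which avoids unit ambiguity inside
the pipeline.

## Synthetic data: what it emulates, and what it does not

The simulator encodes the study conditions as defaults; it is the
ground-truth oracle for every downstream stage.

*Flow cytometry* (`FlowSimConfig`): each sample draws events from a
three-part mixture — probe-positive *reduced* cells following a
piecewise-linear OxD trajectory (baseline 0.33, mild peak 0.38 at
~15 min, recovery to 0.15 by 8 h), probe-positive *oxidized* cells
saturating at OxD 1.0 within ~20 min, and a dim autofluorescence-only
cloud (5% of events) that the i405·i488 expression gate removes.
Per-event OxD noise is Gaussian (sd 0.03, clipped to [0, 1]); the
noisy OxD is converted to intensities through the inverse OxD map and
a lognormal expression scale, so i405/i488 exactly encodes the true
OxD.  The oxidized fraction per dose is {0: 0, 50: 0.2, 80: 0.5,
100: 0.8} and ramps up with time constant 10 min, stabilizing within
~45 min of treatment.  Death at the terminal staining time follows
the line dead = 1.09·frac_oxidized − 0.16 (clipped to [0, 1]), with
dead events drawn from the oxidized subpopulation first — death nests
inside early oxidation.  Sytox intensities are lognormal background
for live cells and ~500× background for dead ones.

*Imaging* (`ImagingSimConfig`): settled elliptical cells (semi-axes
6–9 × 3–5 px, non-overlapping, ≥30 px apart) are rendered into a
256×256, 4-channel (i405/i488/chlorophyll/Sytox), 16-bit stack at
20-min frame intervals.  The whole field drifts (0.4, −0.3) px/frame
— cells settled on chamber glass do not move individually, so drift is
purely global.  Per-cell OxD trajectories follow the flow-simulation
shapes with per-cell offsets (sd 0.01) and per-frame jitter (sd 0.02).
i488 brightness dims with oxidation by the instrument factor k while
i405 = R·i488, so the rendered ratio encodes the true OxD exactly
before background and noise.  Background (5% of full scale) and
Gaussian camera noise (sd 0.5%) are added; optional chlorophyll→i405
additive leakage (default 0, i.e. off) reproduces the mechanism that
inflates OxD beyond 100%.  At the Sytox frame (default: last), a
nucleus-sized blob is rendered for exactly the cells whose true OxD at
the decision frame (nearest 40 min) exceeded the 0.74 fate threshold —
fate is wired to thresholded truth, exactly.

Not emulated: optics (PSF, flat-field, focus drift), organelle
substructure (the probe region is the whole cell ellipse), diurnal
light cycling, cell motility, and by default cell division.  Passing
tests therefore demonstrate correctness of the algorithms under
controlled drift/noise/leakage, not robustness to out-of-focus frames
or morphologically complex real cells.

## Flow pipeline

Gating keeps events with i405·i488 above a threshold (the product is
the standard probe-expression proxy and separates transformants from
the wild-type autofluorescence cloud).  Gated + rejected events
partition the input exactly.

**Subpopulation splitting** replaces the manual sorting gates of a
bench experiment with a seeded, reproducible procedure.  Default: a
2-component Gaussian mixture on OxD; the threshold is the posterior
flip point between the component means.  Alternatives: the KDE-valley
between the two highest density modes, or a user-fixed cutoff.  A
unimodality guard — mode separation must exceed 2 pooled SDs and the
minor component must carry >2% of the weight — returns a degenerate
split (fraction 0 or 1, by whether the population median exceeds
OxD 0.7) instead of hallucinating a boundary on control samples.
Splits need ≥200 events.  Histogram summaries use fixed bins
[−0.1, 1.2] of width 0.01 for comparability across timepoints.

The Sytox dead/alive cutoff is taken from an unstained control sample
(99.9th percentile by default).  The death-versus-early-oxidation
relation is ordinary least squares of the 24-h dead fraction on the
1–2-h oxidized fraction, with r² and the standard t-test p-value; no
multiple-testing correction (a single headline regression).  Because
the dead fraction cannot go below zero while the line's intercept is
negative, the line should be fitted on treated samples (doses with a
positive expected dead fraction); including untreated controls biases
the slope downward — the acceptance script does exactly this.
Fractions are computed per replicate and then averaged (mean ± SEM).

## Image pipeline

Order of operations is fixed: register → normalize by bit depth →
subtract background → channel masks → expression mask → pixel OxD →
watershed segmentation → shape filter → measure.

*Registration* is translation-only phase cross-correlation against
frame 0 (stage drift is translational; rotation/scaling are out of
scope), with configurable subpixel upsampling (default 10).  Integer
drifts are recovered exactly; subpixel drifts to within 0.5 px.
Border pixels revealed by the shift are filled with the frame's median
intensity — the median is background in a sparse field — so the
automatic background-tile search cannot lock onto an artificial dark
border; those pixels are additionally reported in a validity mask.

*Background* is the mean of a user-defined cell-free rectangle,
subtracted with a floor at 0; the fallback is the lowest-mean 32×32
tile.  A ROI overlapping segmented cells triggers a warning, not an
error (matching how a mis-drawn bench ROI should surface).

*Masks*: each fluorescence channel is thresholded after normalization
(defaults 0.02 of full scale, chosen on synthetic data and exposed in
config); the roGFP expression mask keeps pixels present in both
excitation-channel masks whose i405·i488 product exceeds a second
threshold (default 2.5e−4).  Pixel OxD is computed only inside the
expression mask; outside it is NaN/`INVALID`.

*Segmentation* is watershed on the inverted smoothed seed channel
(i405 for probe-carrying strains, chlorophyll otherwise), seeded at
local maxima ≥8 px apart (smoothing sigma 1 px).  With no interior
maxima the mask's connected components are returned.  Objects are
filtered on area (20–500 px²), major axis (≤40 px), minor axis
(≥2 px) and eccentricity (≤0.97) to remove debris, clumps and
doublets; removal reasons are logged per object.

*Measurement*: one record per label per frame with centroid (x =
column, y = row, 0-based, origin top-left), shape, per-channel means,
and OxD summarized over defined, non-excluded pixels only.  The
default per-cell statistic is the median (robust to leakage pixels);
on even counts the lower-middle element is taken so the median is
always an observed pixel value.  The mean is reported alongside.
Per-cell OxD is invariant to rescaling both excitation channels by a
common factor (ratio property, tested).

## Tracking and fate

Adjacent frames are linked by min-cost bipartite matching on centroid
distance with a hard limit (default 15 px): among matchings whose
pairs all lie within the limit, the assignment maximizes cardinality
and then minimizes total distance (implemented with a big-M padded
Hungarian solve; a greedy nearest-neighbour linker is available for
comparison).  Exhaustive enumeration on ≤6-cell instances confirms
optimality.  Tracks are chains of consecutive links — no gap closing,
no lineage merging; a new object near an existing track simply starts
a new track.

Tracks shorter than 6 consecutive frames, or absent from the Sytox
frame, are `unresolved` and never enter fate statistics (the length
filter is applied before fate assignment, so excluded tracks never
receive fates).  Fate is `dead` iff thresholded Sytox signal overlaps
the track's segmented region dilated by 3 px (the extended cell
region: a dying cell's stained nucleus can sit at the cell edge).
Decision OxD is the track's per-cell OxD at the frame nearest the
configured decision time (default 40 min); ties break toward the
earlier frame.

## Fate model

Terminal fate is regressed on decision OxD by maximum-likelihood
logistic regression (statsmodels `Logit`, no regularization by
default; an optional ridge penalty exists for degenerate data).  The
death threshold is the OxD where predicted death probability crosses
0.5, i.e. −β₀/β₁.  Completely separated classes have no finite MLE;
the model then reports the midpoint between the highest alive OxD and
the lowest dead OxD with `separated=True` — on clean simulated data
this is the expected path, since the two subpopulations sit far on
either side of the threshold.

Scores are computed in-sample with predictions OxD > threshold.  FP
(alive predicted dead) and FN (dead predicted alive) are reported as
fractions of *all* cells, so accuracy = 1 − FP − FN holds exactly by
construction; per-class rates are also emitted.

## Problem sizes and seeds

Simulated problem sizes were chosen as the smallest that exercise each
statistical claim: 10,000 events per sample for fraction-recovery
checks (binomial SE ~0.005), 250 cells for fate-threshold recovery
(the study scale for per-treatment cell counts), and 20-cell /
30-frame / 256×256 stacks for the imaging pipeline.  All randomness
derives from explicit integer seeds; a fixed seed reproduces event
tables and image stacks bit for bit.  The acceptance script derives
stage seeds from its single `--seed` argument.

## Known limitations

* FCS files are not read; CSV is the canonical event format (the
  documented schema covers the needed channels and metadata).
* Complete separation in the fate model yields a midpoint threshold
  whose exact value depends on the two boundary cells; with wide class
  gaps it is correspondingly loose.  The logistic-noise fate simulator
  exists precisely to test threshold recovery in the overlapping
  regime.
* The unimodality guard's 2-SD / 2%-weight constants are heuristics
  chosen on synthetic data; heavily skewed unimodal distributions
  could still split.
* Watershed seeding assumes roughly convex cells ≥ the min-distance
  apart; chains of touching cells may merge or oversplit.
* Background estimation assumes a cell-free region exists; fully
  confluent fields would need flat-field correction, which is out of
  scope.
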