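# Methods

## Scope and model of the data

`ms2burst` analyzes two-channel time-lapse movies of nascent transcription
in early fly embryos. One channel carries a histone-fusion marker
(His2Av-type) labeling all nuclei; the other carries the coat-protein
signal (MCP-GFP-type) that lights up the stem-loop array on a nascent
reporter transcript as a diffraction-limited nuclear dot. The analysis
window is within one nuclear cycle (blastoderm, cycle 14), so nuclei
drift slowly and do not divide. The pipeline converts the movie into
per-nucleus intensity traces, calls transcriptional bursts on them, and
compares burst properties between reporter genotypes. A separate module
computes Pol II ChIP-derived metrics (pausing index, per-peak fold
change) from coverage tracks and interval files.

## Synthetic movies and the telegraph model

Real embryo movies are large and not generally available, so every stage
is validated against a simulator that produces movies plus exact ground
truth.

Promoter kinetics follow the two-state telegraph model: switching
OFF→ON at rate `k_on` (1/s), ON→OFF at `k_off`, and initiating
transcripts as a Poisson process at `loading_rate` while ON. The chain
is simulated exactly in continuous time (Gillespie; exponential holding
times), never on a time grid, so there is no discretization bias in the
kinetics. Each initiation contributes a unit boxcar of signal lasting
`dwell_time` seconds — the residence time of one transcript's stem-loop
signal at the site. The trace sampled at frame `t` is therefore the
number of initiations in the trailing `dwell_time` window (an M/D/∞
queue driven by the telegraph process), which has the closed-form checks
used in the tests: mean occupancy `k_on/(k_on+k_off)` and, when held ON,
mean signal `loading_rate × dwell_time`.

Default kinetics (`k_on = 1/120 s⁻¹`, `k_off = 1/90 s⁻¹`,
`loading_rate = 1/6 s⁻¹`, `dwell_time = 140 s`) give ON/OFF episodes of
a couple of minutes and on the order of 20 transcripts at the site while
ON — bursty traces of the kind this class of reporter produces at a
16.8 s frame interval. They were chosen once, on those physical grounds.

Rendering: nuclei are uniform disks (radius 8 px) with a soft 1-px edge,
placed on a jittered grid that guarantees edge-to-edge gaps of ~5 px,
and drifting by a reflected Gaussian random walk (default σ = 0.5
px/frame) in which any step that would bring two nuclei closer than
`2r + 4 px` is voided — nuclei never overlap by construction. The spot
is an elliptical Gaussian (default σ = 1.5 px) at the nucleus centroid
plus a fixed subpixel offset, on the middle z-plane, scaled so its
continuous integral equals the trace value (200 intensity units per
transcript by default). Noise is Poisson shot noise plus Gaussian read
noise (sd 2), both optional. All randomness derives from one seed
through a spawned seed sequence, so identical configs give identical
movies and ground truth.

What the simulator does *not* emulate: optical sectioning and 3-D PSF
structure, photobleaching, chromatic or stage drift between channels,
nuclear divisions, chromatin texture inside nuclei, and spot motion
within the nucleus. Passing recovery tests on these movies therefore
demonstrates the correctness of the analysis logic — not robustness to
every artifact of real microscopy.

## Segmentation

Per frame: maximum z-projection; optional edge crop (for 512×512 inputs
the conventional trim is a centered 300×430 box; the offset is
configurable because only the output size is conventional); Gaussian
blur (σ = 1.5 px); bright-pixel suppression; threshold-adaptive
binarization; small-object removal; dot-aware boundary correction;
Voronoi partition.

Two deliberately explicit conventions:

- **Bright-pixel removal.** The rule "remove pixels brighter than 5% of
  the global maximum of the histogram" admits two readings. The default
  clips the brightest 5% of pixels to the 95th-percentile value
  (quantile clipping); an `absolute` mode instead clips at
  `0.95 × max`. Clipping rather than zeroing avoids punching holes in
  nuclei. Both are exposed in `SegmentationConfig`.
- **Adaptive threshold.** Candidate thresholds are the 5th–95th
  percentiles of the preprocessed frame in 1-percentile steps. Each is
  scored by two indicators — connected-component count within an
  expected range, and median component area within size bounds — with
  ties broken toward the candidate nearest Otsu's threshold. A frame
  where no candidate satisfies both indicators is flagged *degraded*
  (and an all-flat frame returns an empty mask). This scanner is a
  concrete, reproducible scoring rule for a procedure usually done by
  eye; the Otsu tie-break makes it behave sensibly when the indicator
  ranges are uninformative.

Transcription dots are pixels above twice the spot-channel frame mean;
a dot centroid falling outside all nuclei causes the nucleus with the
nearest boundary pixel (Euclidean; ties to the lower label) to be
dilated along the straight pixel path to the dot. Only background
pixels are written, so regions stay disjoint. Finally, nucleus
centroids define a Voronoi partition (exhaustive nearest-centroid
assignment, ties to the lower label) that bounds each nucleus's
measurement territory. Interactive mask curation is replaced by an
optional per-frame label-image override.

Coordinates are 0-based `(row, col)` pixel centers; crop boxes are
half-open.

## Tracking

Nuclei are linked frame-to-frame by minimum centroid displacement:
candidate pairs in ascending distance order, each nucleus used once,
pairs beyond `max_displacement` (default 8 px = nucleus radius) never
formed, distance ties to the lower previous label. Unmatched current
nuclei start new tracks; unmatched previous nuclei terminate; there is
no gap closing — a missed detection ends the track. Greedy matching
rather than a global assignment mirrors the per-nucleus
minimum-distance description of the procedure; in the regime the
tracker targets (per-frame displacement far below inter-nucleus
spacing) the two coincide, which a property-based test checks against
exhaustive optimal matching for n ≤ 6.

## Spot quantification

For each track and frame, the transcription site is the brightest voxel
over all z within the nucleus mask (ties to the lowest `(z, row, col)`).
An 11×11 window on that single z-plane is fit by ordinary (unweighted)
nonlinear least squares with the model

    I(x, y) = α + I₀·exp(−((x−x₀)²/2σx² + (y−y₀)²/2σy²))

and the spot intensity reported as the background-subtracted integral
`2π·σx·σy·I₀`. Numerical choices:

- Initialization: α = window median, I₀ = max − median, center at the
  window center, σ = 1.5 px. Analytic Jacobian; trust-region reflective
  with bounds I₀ ≥ 0, σ ∈ [0.3, 6] px, peak inside the window.
- `fit_ok` additionally requires a meaningfully positive amplitude and
  σ strictly inside its bounds — a pinned bound signals a degenerate
  (flat or ramp-dominated) window. Failed fits contribute integral 0.
- A cheap pre-gate skips iteration when the window maximum does not
  exceed the median by 4 robust standard deviations (1.4826·MAD): such
  windows contain no discernible peak and the Gaussian model is
  degenerate there. The practical consequence is a detection floor —
  spots below ~4σ of the pixel noise read as 0 — which is the physically
  honest answer for them.
- Windows truncated by the image edge are fit if at least 7 pixels a
  side remain, else flagged failed.

Frames where a track is absent are *missing* (NaN), distinguished from
zeros, and excluded from baselining. After assembly, each trajectory has
its minimum subtracted so the baseline is exactly zero.

## Burst calling

On the 5-frame moving-average-smoothed, baseline-zeroed trace
(shrinking windows at the edges):

- OFF→ON at the first frame above `start_threshold`.
- While ON, the *local peak* is the running maximum since burst start —
  the only reading of "local peak" that is well defined online. ON→OFF
  at the first frame below 55% of it; the burst ends on the frame
  before (declared convention).
- Candidates shorter than 5 frames are discarded as detection noise.
- Candidates whose smoothed values strictly decrease over their opening
  5 frames (configurable; default = smoothing window) are rejected — a
  decaying signal inherited from before the analysis window, not a new
  activation.
- Survivors are translated +2 frames (start and end equally — the rule
  moves the burst, it does not resize it), clamped to the trace.

The start threshold is a per-experiment constant; the default ties it
to the control condition's signal scale (10% of the pooled
99th-percentile smoothed value) and the same value is applied to every
condition of the set. Missing frames split a track into independently
processed segments.

Per burst: amplitude = peak of the smoothed trace within the
(post-shift) burst; duration = interval length, in frames and seconds.
Per nucleus: burst count, means over bursts, and total output = area
under the **raw** trajectory over the whole analysis window (plain sum,
one frame per sample). Nuclei with zero bursts have undefined
amplitude/duration (NaN), not zero.

## Condition comparison

Per metric — total output, amplitude, duration, burst frequency — each
condition is compared with the control by the two-sided Wilcoxon
rank-sum test, with medians reported relative to the control.
Zero-burst nuclei are included in total output and frequency and
excluded from amplitude/duration, following the metric definitions.
Nuclei are pooled across embryos of a condition.

The rank-sum p-value is exact (full enumeration of the permutation
distribution over midranks) when the smaller sample has ≤ 8
observations and the subset count is tractable, otherwise a
tie-corrected normal approximation with continuity correction. The two
agree to < 0.02 around the crossover. p-values are reported per
comparison without correction, as is conventional for this per-panel
presentation; a Benjamini–Hochberg column is emitted alongside for
transparency.

The report renders a per-condition trajectory heatmap with nuclei
ordered by transcription onset (first smoothed frame above threshold;
silent nuclei last), metric boxplots, and a burst-frequency histogram,
with all plotted numbers duplicated in TSVs.

## ChIP metrics

Pausing index = promoter coverage sum / gene-body coverage sum, with
promoter `[TSS−250, TSS+250)` and body `[TSS+500, TES−500)` oriented by
strand (for a − strand gene the TSS is the interval end). Windows are
half-open in 0-based coordinates — endpoint inclusivity is a declared
convention. Genes shorter than 1500 bp are removed; zero-body genes get
a missing index rather than infinity. "Reads in a window" is implemented
as summed per-base coverage, equal to read counts up to a constant
factor under uniform read length — a factor that cancels in the ratio.
Overlapping genes are scored independently.

Peak comparison: per peak, the maximum RPM coverage in each condition;
peaks with control maximum below 5 RPM (or a zero maximum on either
side) are filtered; the rest are classified *diminished* when
`log2(max_treatment/max_control) < −0.1`, else *associated* — a strict
partition. Inputs are BED6 intervals and bedGraph coverage (a
raw-count→RPM scaler is provided).

## Benchmark problem sizes

The recovery benchmarks (in `ms2burst.benchmarks`, asserted in
`tests/test_acceptance.py` and reported by `scripts/acceptance.py`) use:
200 noise-free + 500 Poisson replicates for fit fidelity; a 50-nucleus,
200-frame noisy demo movie for segmentation/tracking; 100 constructed
ON/OFF traces at SNR 10 for burst recovery; two fully rendered
100-nucleus, 120-frame conditions for effect detection; 100 trace-level
replicates for null calibration (the imaging chain adds nothing to the
null, so calibration is measured at the summary level); 200 random
sample pairs for the rank-sum sweep; and a 40-gene toy genome for the
pausing oracle. These sizes were chosen so each benchmark answers its
question with comfortable statistical margin on a single CPU.

## Known limitations

- Single-z Gaussian fitting under-measures spots defocused away from
  their brightest plane; no 3-D fitting.
- One spot per nucleus; sister-chromatid doublets are measured as one.
- The adaptive-threshold scoring rule and the burst-caller's default
  threshold rule are this package's own concrete choices for steps that
  are usually manual; both are fully configurable.
- The greedy tracker has no division/merge handling and no motion
  model; it is correct only in the slow-drift regime it targets.
- Intensity is in arbitrary units; no calibration to absolute mRNA
  counts.
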