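# Methods

`ktrdiv` implements an end-to-end analysis linking single-cell ERK and Akt
kinase activity — read out with kinase translocation reporters (KTRs) — to
cell-division fate in growth-factor-stimulated epithelial cells, together
with a synthetic-data generator that makes every stage testable against
known ground truth.

## The measurement model

A KTR shuttles between nucleus and cytoplasm as it is phosphorylated by its
target kinase, so the single-cell activity readout is the ratio of
cytoplasmic to nuclear reporter fluorescence (the C/N ratio). Per frame the
pipeline:

1. corrects illumination (optional flatfield division by a unit-mean smooth
   field, and/or robust background subtraction),
2. segments nuclei from the nuclear-marker channel (Otsu threshold, hole
   filling, optional distance-transform watershed split of touching nuclei,
   area sieve),
3. builds the **cytoring** — the perinuclear ring extending 10 px
   (Euclidean distance, exact EDT) outward from the nuclear mask, excluding
   all nuclear pixels, with contested pixels assigned to the nearest
   nucleus (ties to the lower label),
4. measures per-label nuclear mean, ring mean, and
   `cn_ratio = ring_mean / nuc_mean`.

The ring construction is verified exactly (set equality) against a
brute-force per-pixel nearest-nucleus oracle. The mean is used as the
compartment statistic; C/N is invariant to any global positive scaling of
the KTR channel.

Background is estimated per frame as the median of sub-Otsu (non-cell)
pixels. A blind low percentile of all pixels systematically undershoots the
true background by about 1.6 noise standard deviations and biases C/N
toward 1; the non-cell median does not. Flatfield correction uses a
supplied calibration field when available, or the heavily smoothed temporal
median frame.

## Tracking

Nuclear labels are linked frame-to-frame by an optimal one-to-one
assignment (Hungarian algorithm) on centroid distance with a hard
displacement gate (default 25 px). Unmatched new labels found tracks;
unmatched old tracks terminate; no gap closing is attempted. When division
places a second nucleus next to an existing track, the track continues as
the nearer daughter and the other daughter founds a new track — one track
per founder cell, matching a one-call-per-cell analysis. A full-duration
filter then keeps only tracks spanning every frame, removing transiently
tracked cells.

## Division detection and fate assignment

At mitosis the cell rounds up, the cytoplasm collapses, and the C/N ratio
drops steeply and transiently. The detector scans each trace for the
earliest frame `p` whose relative drop `(cn[p-s] - cn[p]) / cn[p-s]`
exceeds `min_drop_frac` (default 0.35) over a span `s` of at most 2 frames
and that sits at a local minimum of prominence at least `min_prominence`
(default 0.2 C/N units). Candidates whose drop is not sustained for at
least one further frame, or that fall within the truncation offset of the
trace start, are flagged (`SPURIOUS_CANDIDATE`, `NEAR_START`) and routed to
a QC report rather than silently dropped — the programmatic stand-in for
manual review of spurious peaks. These thresholds were calibrated once on
the default synthetic ensemble and are fully exposed in `DetectParams`.

Accepted calls truncate the trace five timepoints before the drop, so that
only genuine kinase activity enters downstream statistics; the remainder of
a dividing cell's trace (mitotic artifact plus daughter) is discarded.
Fate assignment: *dividing* = accepted call; *non-dividing* = no call and
presence for at least 48 h (15-min sampling) or 41.67 h (5-min sampling);
everything else *excluded* with a reason code. In dual-reporter data the
Akt channel drives detection at 15-min sampling, the ERK channel at 5-min
sampling.

## Statistics

- **Windowed medians.** Per cell, the median C/N inside the 8.5–40 h
  post-stimulus window (inclusive endpoints), computed only over frames
  surviving truncation; at least 10 in-window frames are required,
  otherwise the feature is absent.
- **Rank-sum.** Right-tailed Wilcoxon rank-sum of dividing vs non-dividing
  medians: exact enumeration when `n_x + n_y <= 12` with no ties, otherwise
  the normal approximation with tie and continuity corrections. Verified
  against an exhaustive dynamic-programming enumeration for every no-tie
  configuration up to total size 12.
- **Logistic regression.** Binomial GLM with logit link,
  `divided ~ median_erk + median_akt`, fitted by IRLS with Wald standard
  errors. Quasi-separation is reported via a `converged=False` flag (the
  diverging coefficients are still shown), never an exception.
- **Pooled correlation.** Pearson r over all pooled (cell x in-window
  timepoint) ERK/Akt pairs per fate class, with the cell-time point count.
  Uncertainty band: draw the same number of points from a bivariate normal
  with the class's empirical mean and covariance, compute r, repeat 1000
  times, report the 5th–95th percentiles, each rounded *up* to the nearest
  0.01 (a `half_up` mode is available for sensitivity checks). Means and
  covariances are computed per class by default; a global option exists.
  A per-cell-mean alternative to point pooling is exposed but not default.
- **Crosstalk.** For the 2-node ERK–Akt network, three conditions are
  compared: no inhibitor, ERK-pathway inhibitor, Akt-pathway inhibitor.
  The effect of a perturbation on the other node is the in-window time
  average of the difference of per-timepoint population median
  trajectories, with a cell-level percentile bootstrap CI (1000 resamples).
  An edge is declared only when the CI excludes zero *and* the effect
  clears a practical floor, default 10% of the control trajectory's dynamic
  range — an explicit formalization of a judgement that is otherwise made
  visually. No multiple-testing correction is applied; raw p-values are
  reported per comparison.

## The synthetic-data generator

`simulate_cell_population` draws, per cell:

- a latent mean trajectory: baseline C/N 0.4, then after growth-factor
  addition (default 1 h) a logistic rise (half-rise 1 h, tau 0.25 h) to a
  plateau with population median 1.0 for non-dividing cells, plus an
  additive effect for dividing cells (defaults: ERK +0.35, Akt +0.15);
- a per-cell plateau offset pair (sd 0.25 C/N) drawn from a bivariate
  normal with the class's ERK–Akt correlation (defaults: 0.35 dividing,
  0.7 non-dividing), giving the broad, overlapping per-cell feature spread
  seen in real single-cell data;
- multiplicative AR(1) noise (fractional sd 0.1, lag-1 coefficient 0.8)
  whose innovations share the class correlation. Noise proportional to the
  signal level matches ratio imaging; because both the per-cell offsets and
  the noise carry the class correlation, the pooled cell-time correlation
  hits the configured target.

Exactly `round(frac_dividing * n_cells)` cells divide, at a time drawn
uniformly from 16–36 h (inside the S/G2 analysis window); at division the
observed C/N of both channels is multiplied by `1 - drop_frac` (default
0.5) for 2 frames, after which the trace continues as the nearer daughter.
One division per cell, maximum. Cells move on reflected Gaussian random
walks (step sd 0.5 px/frame) inside a margined arena. All output is a pure
function of `(config, seed)`.

An optional pulsing mode (sinusoidal activity modulation) exists but is
disabled by default: the data this emulates showed no significant pulsing,
and no pulse parameters are available to copy.

The renderer places, per nucleus, a disk in the nuclear-marker channel and
splits each KTR channel's total intensity between the nuclear disk and the
cytoplasmic annulus via the monotone map `phi = a / (1 + a)` (clipped to
[0.05, 0.95] so both compartments always carry signal), which makes the
annulus/nucleus per-pixel ratio equal the ground-truth C/N exactly. At
division a second nucleus appears displaced by two nuclear radii plus two
pixels. Frames are blurred by a Gaussian PSF (default sigma 0.3 px,
appropriate for 20x widefield at ~0.65 um/px), shaded by a unit-mean
tilted-plane flatfield (amplitude 0.1), offset by 100 ADU and corrupted by
Gaussian noise (sd 20 ADU against a total KTR intensity of 2000).

### What the generator does and does not emulate

It reproduces the statistical structure the analysis keys on: class-
dependent plateau medians, class-dependent ERK–Akt correlation, the
division drop signature, broad overlapping per-cell feature distributions,
and realistic optics corruptions. It does **not** model photobleaching,
shot noise, cell crowding or confluency, 3-D structure, multi-generation
lineages, or probe-specificity regimes. Passing tests therefore demonstrate
the correctness of the computations under these study conditions, not
segmentation or tracking robustness on arbitrarily hard real movies.

## Design notes and numerical choices

- **Intensity statistic**: mean per compartment; ring distance metric:
  exact Euclidean EDT; contested cytoplasm: nearest nucleus, ties to the
  lower label (deterministic and symmetric).
- **Assignment tie-breaks**: ring assembly iterates labels in ascending
  order with a strict-less distance update, which realises the lower-label
  tie rule exactly.
- **"Noiseless" fidelity checks** use ideal optics (zero PSF) as well as
  zero noise/shading: a finite PSF mixes intensity across the
  nucleus/ring boundary, an optics effect rather than a quantification
  error; the realistic-optics case is checked separately with correction
  enabled (5% tolerance).
- **Logistic specificity experiment**: when only ERK carries a division
  effect but the two channels are generated with their usual correlation,
  the regression correctly produces a significant *negative* Akt
  coefficient (a classical suppressor term, beta_akt ~ -rho * beta_erk).
  The specificity property "only ERK is significant" is therefore defined
  on an experiment with independently generated channels, which isolates
  attribution of the effect.
- **Crosstalk experiment size**: 300 cells per arm (12 h at 15-min
  sampling), reflecting a realistic imaging experiment; the no-edge
  decision is driven by the cell-level bootstrap spread, which at this size
  puts the 10%-of-range floor at ~2.5 sd of the null effect.
- **GLM fit**: IRLS to tolerance 1e-8, maxiter 100; a minimal
  ridge-stabilised IRLS reports coefficients when the main fit errors out.
- **Degenerate inputs**: blank frames segment to zero labels; empty rings
  and non-positive nuclear means yield NaN C/N plus a flag; a perfectly
  correlated (singular) resampling covariance yields the limit band
  (1.00, 1.00).

## Problem sizes used in the shipped checks

Verification runs use deliberately desk-scale problems: 200 random masks
(<= 96x96) for the ring oracle; an 8-cell, 6-h movie for quantification
fidelity; 30 cells over 193 frames for tracking; 200 traces (100 dividing)
for detection; n=5000 for coefficient recovery and 100 runs of 300 cells
for regression specificity; 500 outer replicates for correlation-band
coverage; 300-cell ensembles and 100 perturbation runs (300 cells/arm) for
the end-to-end checks.
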