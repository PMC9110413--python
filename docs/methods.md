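# Methods

This note records the models behind each pipeline stage, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the procedure was genuinely
open.

## Coordinate and data conventions

One convention everywhere: x = column, y = row, in nanometres, origin at the
centre of pixel (0, 0); frames 0-based; the time of frame f is
f × frame_interval_ms. Localization tables are data frames with columns
`frame, t_ms, x_nm, y_nm, intensity, precision_nm`, sorted by frame then x.
Camera pixel pitch defaults to 107.2 nm (the TIRF setup being modelled);
SMLM exposure to 20 ms; cell movies to 1 s/frame. All stage parameters live
in `AnalysisConfig`, serialize losslessly to YAML, and are logged per run
together with input/output record counts.

## Diffraction-limited morphometry

The averaged stack is band-passed with a difference of Gaussians (default
sigmas 1 px and 20 px — small enough to keep single-particle structure,
large enough to remove slow background modulation; the cutoffs are
configurable since no single pair suits every camera), with the DC level
restored so that the subsequent multiplicative threshold is meaningful. The
foreground criterion is `processed > median × 1.02` ("2 % above the
background", the background being the image median). Reading the 2 % as
multiplicative keeps segmentation exactly invariant to intensity rescaling,
which the test suite asserts; the alternative (2 % of dynamic range) would
be scale-dependent. Components smaller than 3 px are discarded as noise
(configurable; a pragmatic floor, not a measured one).

Length is measured by thinning the particle footprint to a one-pixel
skeleton and summing 8-connectivity step distances (1 or √2 px) along the
longest geodesic path. Two genuinely open choices:

* **Thinning backend.** We use Lee's 3-D thinning
  (`skimage.morphology.skeletonize(method="lee")`). Unlike the default 2-D
  method it preserves end-point extent: a 3 × 10 px bar thins to a 10 px
  centreline (9 steps = 964.8 nm at 107.2 nm/px) and a 10 px diagonal is
  preserved verbatim (9√2 steps ≈ 1364.4 nm). Both are asserted
  digitization-exactly against step-count oracles.
* **Longest geodesic vs total skeleton length.** Elongated fibrils are the
  object of interest and branched skeletons would overcount, so the longest
  geodesic is the reported `length_nm`; the total skeleton length is emitted
  as a secondary column for users who prefer it.

The geodesic is computed exactly (all-pairs Dijkstra on the skeleton graph)
up to 1500 skeleton pixels, above which a double-sweep (exact on trees) is
used. Per-pixel SBR correction uses the median of the *raw* averaged image
as background; a zero background raises an error rather than returning an
infinite ratio.

## SMLM pipeline

Filtering and grouping follow fixed, published-style parameters: signal
strength ≥ 3 and precision ≤ 30 nm; fiducial sites are localized in > 500
frames; staged DBSCAN with ε = 15 nm / minPts = 3 spatially, ε = 21 ms /
min 2 frames temporally (with 20 ms frames this makes adjacent frames
neighbours and breaks bursts at gaps of ≥ 2 frames, which also removes
single-frame localizations), and ε = 200 nm / min 20 bursts for the final
clustering.

DBSCAN is implemented in-package as the classic algorithm with pinned
semantics — minPts counts the point itself, clusters expand breadth-first in
ascending index order, border points join the first-discovering core — so
output is bit-reproducible. Equivalence with a brute-force
distance-matrix oracle is asserted on random tables, and the core-point
partition is cross-checked against scikit-learn's DBSCAN.

**Fiducial compactness.** "Long-lived at the same location" needs a spatial
criterion as well as a temporal one: a large fibril is also detected across
thousands of frames. A candidate site is a fiducial only if its RMS radial
spread is within the grouping radius (default 15 nm, the stage-1 ε). This
cleanly separates point markers (spread ≈ localization precision of a bright
bead, a few nm) from extended aggregates (spread ≈ their size).

**Cluster length grid.** Burst centroids are scaled 8× relative to the base
camera pixel and rounded to integers, i.e. a 107.2/8 = 13.4 nm grid, then
closed with a disk of radius 2 grid units and skeletonized (Lee). The base
pixel for the ×8 scaling is configurable; 107.2 nm is the default because on
a much finer base grid (e.g. 10 nm → 1.25 nm grid) a radius-2 closing can
never bridge realistic inter-burst spacings and every cluster would
fragment. On the 13.4 nm grid, closing bridges gaps up to ~2 grid units,
matching inter-burst spacings at realistic labelling densities.

**What recovery shows.** With bursts at a labelling density of
0.25 bursts/nm of fibril length (equivalently 6.25 × 10⁻³ bursts/nm² of
aggregate area — cluster burst counts then range from ~50 to ~500, inside
the plausible range for this kind of data) and 20 nm precision over 10,000
frames, fibrils of 200–2000 nm are recovered with mean |bias| < 15 % (in
practice < 10 %), and blobs of radius ≤ 100 nm always measure < 300 nm
because their closed footprints skeletonize to stubs. Sparser labelling
degrades this gracefully: too few bursts per 200 nm neighbourhood and long
fibrils stop clustering at all — a real limitation of the fixed 200 nm / 20
parameters, not of the simulation.

**FRC.** Localizations are split into random halves (seeded), each rendered
as a 10 nm-pixel 2-D histogram, and the ring-averaged normalized
cross-spectrum computed with one-frequency-bin rings and no
spurious-correlation correction. The resolution is 1/q at the first crossing
below 1/7, linearly interpolated between bins; a curve that never crosses
reports "not determined" (e.g. an image correlated with itself, FRC ≡ 1).
On dense simulated structures the resolution tracks the 2.35 σ localization
FWHM plus digitization: ~30 nm at σ = 10 nm, ~60 nm at σ = 20 nm, ~110 nm at
σ = 40 nm, monotone in σ.

## Native-MS phospho-stoichiometry

The sampler needs a posterior, and the operational definition here is:
weight of state (p, a) ∝ spectral area within ±5 Da of
m(p, a) = M₀ + 80p + 23a, with uniform priors on 0 ≤ p, a < 50 and a
pseudo-area floor of 10⁻⁶ × total area so log-weights stay finite and the
chain ergodic. The 23 Da adduct is treated as a single species (sodium and
ammonium are indistinguishable at this window width). Windows of
neighbouring states may overlap and share area; that is intentional — it is
exactly what makes the assignment uncertain and the posterior spread
informative.

Three numerical choices worth knowing:

* **Noise-floor subtraction** (on by default). Before integration, the
  intensity axis is lowered by 3× a robust noise scale (the 84th intensity
  percentile, which for zero-truncated Gaussian noise approximates one
  s.d. when peaks occupy a minority of the grid) and clipped at zero. With
  2500 states × 10 Da windows, an unsubtracted baseline contributes far more
  total area than a single true peak and would dominate a uniform-prior
  posterior; subtracting the floor makes the posterior mean track the real
  peaks. Noise-free spectra pass through unchanged.
* **Walker initialization.** Walkers start at states sampled from the
  enumerated weight table (jittered within the unit cell). The landscape is
  a near-flat pseudo-floor dotted with a few populated cells; blind uniform
  initialization reliably strands all walkers on the floor. Initializing
  from the enumerable posterior is the standard "start near the MAP" advice;
  the burn-in is still discarded and the chains must hold the distribution,
  which the enumeration cross-check verifies (total-variation distance
  < 0.05 against exhaustive enumeration on small grids at ≥ 5000 retained
  samples).
* **Aliasing.** 80·2 = 160 and 23·7 = 161, so states (p, a) and
  (p−2, a+7) sit 1 Da apart and a single peak is shared by up to six
  near-equal-weight states on the full 50 × 50 grid. Mode recovery is
  therefore only meaningful on adduct-restricted grids (the recovery suite
  uses a ≤ 5; with adducts disabled, recovery of p is exact across the full
  range). On the full grid the *arithmetic* count from the highest peak
  (`phosphate_count_from_peak`) is the robust summary; the posterior's
  breadth then honestly reflects the adduct confound. Mean and mode are both
  reported and may legitimately differ for asymmetric state mixtures;
  neither is forced to match the other. Half-integer peak-mass differences
  (e.g. 0.6 kDa / 80 Da = 7.5) are flagged as ties and resolved to the lower
  count.

The default schedule (6 chains × 3000 steps, burn-in 800, thin 100) retains
132 draws — enough for a mode and a dispersion, deliberately thin to kill
autocorrelation. The oracle-equivalence and recovery studies use more
walkers and lighter thinning to reach thousands of retained samples.

## Calcium / ROS traces

Preprocessing: per-frame background = 5th intensity percentile (subtracted,
clipped at 0), flat-field division (field normalized to unit mean), Gaussian
smoothing. Tracking: per-frame local maxima, greedy nearest-neighbour
linking gated at one cell radius, new tracks for unmatched maxima; tracks
shorter than 25 % of the movie or with positional s.d. > radius/2 are
discarded, the rest frozen at their mean position. Traces are disk means at
the frozen position (edge-clipped disks are flagged and averaged over
in-frame pixels), Gaussian-smoothed along time, and normalized to the
pre-stimulus baseline mean so all thresholds are unitless.

Spike calling is two-stage, and the threshold is deliberately *not* a
built-in default — it is derived from the noise level, either analytically
(`calibrate_derivative_threshold`: k × the s.d. of the differenced smoothing
kernel response to white noise of the stated s.d., k = 4.65, the one-sided
normal quantile that keeps the family-wise false-candidate rate below about
one per 10⁶ noise frames) or empirically from a trace's own pre-stimulus
first differences (`estimate_derivative_threshold`). Candidates above the
derivative threshold are merged within a 3-frame refractory window; the
spike window runs until the smoothed trace returns to its pre-onset level;
amplitude is measured on the smoothed trace against a baseline read just
before the rising edge, and screened at 2.5× the trace noise s.d. (smoothing
attenuates a 5 σ spike to roughly 3.5 σ, so 2.5 σ rejects noise while
keeping such spikes); duration is the contiguous time above half-amplitude,
screened against the configured minimum. Onsets within the smoothing
kernel's half-width of the trace edges are not called, since the smoothed
estimate is unsupported there. Under these rules, spikes of amplitude 5× the
noise s.d. are recalled at ≥ 0.95 with precision ≥ 0.95 over hundreds of
traces, and 1000 flat noisy traces yield zero false calls.

ROS percent change averages the 50 frames before the stimulus and the 50
frames before ionomycin; the ratio form makes it exactly invariant to
uniform gain.

## Synthetic data: what is and is not emulated

Generators are pure functions of (parameters, seed) and every stochastic
stage reproduces byte-identical output under a fixed seed.

* **Blinking.** Bursts are geometric-duration runs (mean 3 frames, minimum
  2) of localizations at a fixed point of the aggregate support, with iid
  Gaussian localization error (default 20 nm). No photophysics (no dye
  kinetics, no duty-cycle dependence on intensity) — only the structure the
  temporal grouping relies on: intra-burst gaps ≤ 1 frame, inter-burst gaps
  ≫ 21 ms. Fibrils are line segments, amorphous aggregates isotropic discs;
  fiducials emit every frame at 5× better precision.
* **Detector.** Poisson shot noise plus Gaussian read noise; no EMCCD
  excess-noise factor, no pixel response non-uniformity beyond the optional
  flat-field in the cell pipeline.
* **Spectra.** Gaussian peaks (default FWHM 8 Da) of exactly the state
  weights, plus zero-truncated white noise; no baseline curvature, no
  isotope structure, no deconvolution artefacts.
* **Cell movies.** Non-overlapping sigmoid-profile cells on a jittered grid;
  responders (default 85 % of cells) receive ≥ 1 post-stimulus calcium spike
  (linear rise over 2 frames, exponential decay τ = 10 frames, amplitude
  10 % of baseline = 5× the 2 % trace noise) and a linear ROS ramp sized so
  the rendered readout rises ≈ 18 % by the ionomycin window. No cell motion,
  division, focus drift, or bleaching.

Consequently, passing recovery tests demonstrates that the *analysis* is
correct and unbiased under the stated statistical structure — not that it is
robust to photophysical artefacts, drift, or segmentation errors absent from
the simulations. Problem sizes in the test and acceptance runs (e.g. 4
replicates per fibril length, 10,000-frame streams, 200 + 1000 trace
benchmarks, 26 × 6 state recovery grids) are chosen to give stable
statistics at interactive runtimes.

## Degenerate inputs and tie-breaks

Empty localization tables are valid (empty outputs, not errors); a
header-only file parses to an empty table. Zero-area spectra are an error
for assignment ("no signal to assign") but legal as containers. A
single-pixel skeleton has length 0; a cluster whose bursts land on one grid
point has length 0. Vesicles with F_ionomycin ≤ F_background are excluded
with a reason rather than producing unbounded ratios; influx values outside
[0, 100] % are reported raw with an out-of-range flag, never silently
clipped. Fold changes use efficiency 2 (recorded in output metadata);
housekeeping Cts are averaged arithmetically; every sample must carry all
housekeeping genes.
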