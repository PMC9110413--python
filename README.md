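# tauagg

Quantitative analysis pipelines for characterizing hyperphosphorylated tau
aggregates and their cellular effects, written for researchers who image
amyloid aggregates by single-molecule localization microscopy (SMLM) or
diffraction-limited TIRF, measure phosphorylation stoichiometry by native
mass spectrometry, and read out membrane damage and macrophage activation in
cell assays.

Raw microscopy and MS data for this kind of study are rarely deposited in
analysis-ready form, so the package pairs every analysis stage with a
synthetic-data generator of matched statistical structure and known ground
truth. Every pipeline is validated by recovery: simulate with known truth,
analyze, compare.

## What it computes

**Diffraction-limited morphometry** (`tauagg.dl`). Time-averaged images are
band-pass filtered, blurred, and thresholded at 2 % above the image median;
connected components are particles. A particle's apparent length is the
longest geodesic path of its thinned (one-pixel) skeleton, with axial steps
counting 1 pixel and diagonal steps √2, at 107.2 nm/pixel. Intensities are
corrected per pixel by the signal-to-background ratio

    SBR = (I − background) / background,

summed over the particle (background = image median).

**SMLM burst grouping and cluster lengths** (`tauagg.smlm`). Localizations
from a transiently binding dye are quality-filtered (signal strength ≥ 3,
precision ≤ 30 nm), cleaned of fiducials (sites localized in > 500 frames),
then grouped by staged DBSCAN: spatially (ε = 15 nm, minPts = 3), temporally
within each spatial cluster (ε = 21 ms, ≥ 2 frames) → bursts; burst
centroids are clustered again (ε = 200 nm, ≥ 20 bursts) → aggregates. Each
aggregate's length comes from rastering its burst centroids onto an
8×-refined grid, morphological closing, skeletonization, and the same
8-connectivity geodesic measure. Image resolution is estimated by Fourier
ring correlation with the 1/7 threshold (`tauagg.frc`).

**Phospho-stoichiometry by MCMC** (`tauagg.ms`). A deconvolved native mass
spectrum of a phosphoprotein is modelled as a mixture of states (p, a) on
the mass ladder m(p, a) = M₀ + 80·p + 23·a (p phosphate groups of 80 Da,
a small-ion adducts of 23 Da; M₀ = 39,900 Da for 0N4R tau without its
N-terminal methionine). The posterior weight of a state is the spectral area
in a 10 Da window at its ladder mass (uniform priors, p, a < 50), sampled by
an affine-invariant ensemble sampler (6 chains × 3000 steps, 800 burn-in,
thinned by 100). The marginal over p gives the mean ± s.d. and mode number
of phosphates per molecule.

**Calcium / ROS trace analysis** (`tauagg.cells`). Cells are located by
tracking per-frame local maxima (nearest-neighbour linking; jittery tracks
discarded), frozen at their mean position, and read out as the mean of a
cell-sized disk per frame. Calcium spikes are called from the first
derivative of the smoothed, baseline-normalized trace against a calibrated
threshold with minimum-amplitude and minimum-duration screens. The ROS
readout is 100·(F_final − F_initial)/F_initial between 50-frame windows
before the stimulus and before the ionomycin control.

**Closed-form assays** (`tauagg.assays`). Vesicle calcium influx
100·(F_sample − F_background)/(F_ionomycin − F_background); LDH cytotoxicity
100·(LDH_sample − LDH_spont)/(LDH_max − LDH_spont) after per-well
A490 − A680 correction; and ΔΔCt relative expression, fold = 2^(−ΔΔCt),
against the mean of the GAPDH/18S housekeeping Cts and a buffer-control
reference group.

## Worked example

```bash
python examples/phospho_stoichiometry.py
```

```
peak at 40.7 kDa -> 10 phosphate groups
peak at 41.4 kDa -> 19 phosphate groups

posterior over phosphate count: mode 10, mean 10.04 +/- 0.53
 n_phos   weight
      9 0.118182
     10 0.720455
     11 0.159659
```

The first two lines are direct peak arithmetic: a deconvolved peak 0.8 kDa
(respectively 1.5 kDa) above the 39.9 kDa unmodified mass corresponds to 10
(respectively 19) phosphate groups of 80 Da. The posterior below them is the
MCMC assignment on a simulated spectrum whose dominant state has 10
phosphates: the mode recovers it exactly and the ±0.5 s.d. reflects genuine
ambiguity introduced by 23 Da adducts and peak overlap.

`examples/` holds one script per capability (SMLM lengths, FRC resolution,
diffraction-limited morphometry, calcium/ROS traces, assay formulas), each
printing the numbers it computes and what they mean. A thin CLI (`tauagg
simulate | dl-analyze | smlm-analyze | frc | ms-assign | traces | assay`)
wraps the same functions for batch use.

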