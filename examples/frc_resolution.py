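"""Estimate super-resolution image resolution by Fourier ring correlation.

Simulates a dense localization dataset (four long fibrils, 20 nm
localization precision), splits it into random halves, and reports the
spatial frequency at which the ring correlation drops below 1/7.
"""

from tauagg import frc, synth

aggregates = [synth.Aggregate("segment",
                              (1000.0 + 2000.0 * i, 1000.0 + 1500.0 * i),
                              1500.0, 0.4 + 0.5 * i) for i in range(4)]
truth = synth.GroundTruth(aggregates=aggregates, seed=0)
locs = synth.gen_smlm_stream(truth, synth.EmitterModel(precision_nm=20.0),
                             n_frames=10_000, bursts_per_aggregate=600, seed=0)

result = frc.frc_resolution(locs, pixel_nm=10.0, split_seed=0)
print(f"{len(locs)} localizations, FRC resolution: "
      f"{result.resolution_nm:.1f} nm")
print("\nAt 20 nm localization precision the achievable resolution sits")
print("near the ~2.35 sigma FWHM band (about 45-65 nm); tighter precision")
print("pushes the 1/7 crossing to higher spatial frequency.")
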