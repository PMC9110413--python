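"""Measure super-resolved aggregate lengths from a blinking-emitter stream.

Simulates a 10,000-frame localization stream from one 800 nm fibril and one
amorphous blob (radius 80 nm) plus a fiducial marker, then runs the full
staged pipeline: quality filter, fiducial removal, DBSCAN burst grouping
(15 nm / 3, 21 ms / 2), burst clustering (200 nm / 20), and skeleton-based
length measurement on the 8x-refined grid.
"""

import numpy as np

from tauagg import smlm, synth

truth = synth.GroundTruth(
    aggregates=[
        synth.Aggregate("segment", (2000.0, 2000.0), 800.0, 0.5),
        synth.Aggregate("blob", (6000.0, 5000.0), 80.0),
    ],
    fiducials=[(500.0, 7000.0)],
    seed=42,
)
locs = synth.gen_smlm_stream(
    truth, synth.EmitterModel(precision_nm=20.0),
    n_frames=10_000, bursts_per_aggregate=200, seed=42)
print(f"simulated {len(locs)} localizations over 10,000 frames")

bursts, clusters, table = smlm.analyze_localizations(locs)
print(f"{len(bursts)} bursts grouped into {len(clusters)} clusters")
print(table.to_string(index=False))

fractions = smlm.cluster_size_fractions(table["length_nm"])
print(f"fraction below 500 nm: {fractions['below_500nm']:.2f}")
print("\nThe fibril cluster's length_nm should sit near the true 800 nm;")
print("the blob measures short (its closed footprint skeletonizes to a")
print("stub), which is how fibrillar and amorphous species are told apart.")
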