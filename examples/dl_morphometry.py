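"""Diffraction-limited aggregate morphometry on a rendered TIRF field.

Renders a field with one 2 um fibril and two sub-diffraction blobs at the
camera's 107.2 nm pixel pitch, averages the stack, segments particles at 2 %
over the image median, and reports thinning-based lengths and
signal-to-background-corrected intensities.
"""

from tauagg import dl, synth

truth = synth.GroundTruth(
    aggregates=[
        synth.Aggregate("segment", (2000.0, 8000.0), 2000.0, 0.2),
        synth.Aggregate("blob", (8000.0, 3000.0), 90.0),
        synth.Aggregate("blob", (10_000.0, 9000.0), 70.0),
    ],
    seed=1,
)
stack = synth.render_dl_stack(truth, psf_sigma_nm=150.0,
                              noise=(1.0, 2.0, 20.0), n_frames=100,
                              fov_px=(128, 128), seed=1)
table = dl.analyze_stack(stack)
print(table.round(1).to_string(index=False))

measurements = [dl.ParticleMeasurement(*row) for row in
                table[["length_nm", "total_skeleton_nm",
                       "corrected_intensity", "n_pixels"]].itertuples(index=False)]
summary = dl.field_summary(measurements)
print(f"\n{summary['count']} particles, mean length "
      f"{summary['mean_length_nm']:.0f} nm")
print(f"length histogram over bins {summary['bin_edges_nm']}: "
      f"{summary['histogram']}")
print("\nThe fibril's apparent length comes in below its true 2000 nm")
print("because the 2 % threshold clips its dim ends under noise; the")
print("sub-diffraction blobs skeletonize to (near-)zero length - they are")
print("diffraction-limited spots, and only their intensity is meaningful.")
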