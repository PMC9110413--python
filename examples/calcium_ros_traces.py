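"""Per-cell calcium spike calling and ROS percent change from a dual-channel
movie.

Simulates a 600-frame (1 s/frame) movie of 12 macrophage-like cells, 85 % of
which respond to a stimulus at frame 100 with calcium transients and a slow
ROS ramp; ionomycin is added at frame 550 as the positive control.  Cells are
tracked, disk traces extracted, spikes called from the first derivative, and
the ROS change computed between the 50-frame windows before each addition.
"""

import numpy as np

from tauagg import cells, synth

ca, ros, truth = synth.gen_cell_movie(n_cells=12, n_frames=600,
                                      frame_shape=(180, 180), seed=8)
tracks = cells.track_cells(cells.preprocess(ca), cell_radius_px=10.0)
cells.extract_traces(ca, tracks, smooth_sigma=2.0)
ros_tracks = [cells.CellTrack(t.id, t.position, t.position_sd, t.radius_px)
              for t in tracks]
cells.extract_traces(ros, ros_tracks, smooth_sigma=2.0)

calls = []
for tr in tracks:
    trace = cells.normalize_trace(tr.trace, baseline_frames=50)
    threshold = cells.estimate_derivative_threshold(trace, baseline_frames=50)
    calls.extend(cells.detect_spikes(
        trace, threshold, min_amplitude=2.5 * float(np.std(trace[:50])),
        min_duration=2, smooth_sigma=0, cell_id=tr.id))

frac = cells.responding_fraction(calls, len(tracks), stimulus_frame=100)
ros_changes = [cells.ros_percent_change(t.trace, 100, 550, window=50)
               for t in ros_tracks]
print(f"{len(tracks)} cells tracked, {len(calls)} calcium spikes called")
print(f"responding fraction: {frac:.2f} (simulated truth "
      f"{np.mean(truth.responders):.2f})")
print(f"median ROS change: {np.median(ros_changes):+.1f} %")
print("\nA responding fraction near 0.85 with a ROS rise near +18 % mirrors")
print("the strong macrophage activation phenotype of amorphous aggregates.")
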