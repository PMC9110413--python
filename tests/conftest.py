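import numpy as np
import pytest

from tauagg import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def segment_truth():
    """A single 500 nm fibril, no fiducials."""
    return synth.GroundTruth(
        aggregates=[synth.Aggregate("segment", (2000.0, 2000.0), 500.0, 0.5)],
        seed=7)


def random_localization_table(seed: int, n: int = 300,
                              box_nm: float = 2000.0,
                              frame_interval_ms: float = 20.0):
    """A mixed random table: diffuse scatter plus dense blinking sites.

    Built directly (not via the generators) so that clustering oracle tests
    see arbitrary point configurations, not only generator-shaped ones.
    """
    import pandas as pd

    from tauagg.io import as_localization_table

    rng = np.random.default_rng(seed)
    rows = []
    n_sites = rng.integers(3, 9)
    sites = rng.uniform(0, box_nm, (n_sites, 2))
    while len(rows) < n * 0.7:
        site = sites[rng.integers(0, n_sites)]
        start = int(rng.integers(0, 900))
        for f in range(start, start + int(rng.integers(1, 6))):
            x, y = site + rng.normal(0, 8.0, 2)
            rows.append((f, x, y))
    while len(rows) < n:
        rows.append((int(rng.integers(0, 1000)),
                     rng.uniform(0, box_nm), rng.uniform(0, box_nm)))
    frame, x, y = zip(*rows[:n])
    table = pd.DataFrame({"frame": frame, "x_nm": x, "y_nm": y,
                          "intensity": 1000.0, "precision_nm": 15.0})
    return as_localization_table(table, frame_interval_ms=frame_interval_ms)
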