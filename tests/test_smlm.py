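import numpy as np
import pandas as pd
import pytest

from tauagg import smlm, synth
from tauagg.io import as_localization_table


def table_from(rows):
    """rows of (frame, x, y[, intensity, precision])."""
    recs = []
    for r in rows:
        frame, x, y = r[:3]
        inten = r[3] if len(r) > 3 else 1000.0
        prec = r[4] if len(r) > 4 else 15.0
        recs.append({"frame": frame, "x_nm": x, "y_nm": y,
                     "intensity": inten, "precision_nm": prec})
    return as_localization_table(pd.DataFrame(recs), frame_interval_ms=20.0)


class TestQualityFilter:
    def test_poor_precision_removed(self):
        t = table_from([(0, 0, 0, 1000, 40.0), (1, 0, 0, 1000, 10.0)])
        out = smlm.quality_filter(t)
        assert len(out) == 1 and out.loc[0, "precision_nm"] == 10.0

    def test_all_passing_is_identity(self):
        t = table_from([(0, 0, 0), (1, 5, 5), (2, 9, 9)])
        assert smlm.quality_filter(t).equals(t)

    def test_mixed_table_count(self, rng):
        n, n_bad = 100, 30
        prec = np.full(n, 10.0)
        prec[rng.choice(n, n_bad, replace=False)] = 50.0
        t = table_from([(i, i, i, 1000, p) for i, p in enumerate(prec)])
        assert len(smlm.quality_filter(t)) == n - n_bad


class TestFiducials:
    def test_long_lived_site_flagged_and_removed(self):
        truth = synth.GroundTruth(fiducials=[(300.0, 300.0)], seed=2)
        locs = synth.gen_smlm_stream(truth, n_frames=600)
        fids, cleaned = smlm.detect_fiducials(locs, min_frames=500)
        assert len(fids) == 1
        assert np.hypot(fids[0][0] - 300, fids[0][1] - 300) < 10
        assert cleaned.empty

    def test_short_lived_emitter_retained(self):
        rows = [(f, 100.0, 100.0) for f in range(100)]
        locs = table_from(rows)
        fids, cleaned = smlm.detect_fiducials(locs, min_frames=500)
        assert fids == [] and len(cleaned) == 100

    def test_empty_table(self):
        from tauagg.io import empty_localizations
        fids, cleaned = smlm.detect_fiducials(empty_localizations())
        assert fids == [] and cleaned.empty

    def test_extended_aggregate_not_mistaken_for_fiducial(self):
        # long-lived but spatially extended: must survive fiducial removal
        truth = synth.GroundTruth(
            aggregates=[synth.Aggregate("segment", (1000.0, 1000.0), 800.0)],
            seed=3)
        locs = synth.gen_smlm_stream(truth, n_frames=2000,
                                     bursts_per_aggregate=200)
        _, cleaned = smlm.detect_fiducials(locs, min_frames=500)
        assert len(cleaned) > 0.9 * len(locs)


class TestGroupBursts:
    def test_sparse_pair_yields_no_bursts(self):
        t = table_from([(0, 0.0, 0.0), (0, 100.0, 0.0)])
        assert smlm.group_bursts(t) == []

    def test_five_colocalized_consecutive_frames_one_burst(self):
        t = table_from([(f, 5.0 + f * 0.5, 5.0) for f in range(10, 15)])
        bursts = smlm.group_bursts(t)
        assert len(bursts) == 1 and bursts[0].n_locs == 5
        assert (bursts[0].start_frame, bursts[0].end_frame) == (10, 14)

    def test_same_site_two_epochs_two_bursts(self):
        rows = ([(f, 5.0, 5.0) for f in range(10, 15)]
                + [(f, 5.0, 5.0) for f in range(600, 605)])
        bursts = smlm.group_bursts(table_from(rows))
        assert len(bursts) == 2

    def test_single_frame_localization_removed(self):
        # 3 co-located localizations pass spatial DBSCAN, but the lone frame
        # 50 localization fails the 2-frame temporal minimum
        rows = [(10, 5.0, 5.0), (11, 5.0, 5.0), (50, 5.0, 5.0)]
        bursts = smlm.group_bursts(table_from(rows))
        assert len(bursts) == 1 and bursts[0].n_locs == 2


class TestClusterBursts:
    def make_bursts(self, centers):
        return [smlm.Burst(id=i, member_index=np.array([i]),
                           centroid_nm=tuple(c), start_frame=0, end_frame=1)
                for i, c in enumerate(centers)]

    def test_nineteen_bursts_below_minimum(self):
        bursts = self.make_bursts([(0.0, 0.0)] * 19)
        assert smlm.cluster_bursts(bursts) == []

    def test_twentyfive_in_disc_one_cluster(self, rng):
        centers = rng.uniform(-80, 80, (25, 2))
        clusters = smlm.cluster_bursts(self.make_bursts(centers))
        assert len(clusters) == 1 and clusters[0].n_bursts == 25

    def test_two_groups_one_micron_apart_two_clusters(self, rng):
        a = rng.uniform(-80, 80, (25, 2))
        b = rng.uniform(-80, 80, (25, 2)) + 1000.0
        clusters = smlm.cluster_bursts(self.make_bursts(np.vstack([a, b])))
        assert len(clusters) == 2


class TestClusterLength:
    def run_pipeline(self, locs):
        bursts = smlm.group_bursts(locs)
        clusters = smlm.cluster_bursts(bursts)
        table = smlm.measure_clusters(clusters, bursts)
        return table

    def test_coincident_bursts_zero_length(self):
        bursts = [smlm.Burst(i, np.array([i]), (50.0, 50.0), 0, 1)
                  for i in range(25)]
        cl = smlm.cluster_bursts(bursts)[0]
        smlm.cluster_length(cl, bursts)
        assert cl.length_nm == 0.0

    def test_500nm_segment_recovered(self):
        truth = synth.GroundTruth(
            aggregates=[synth.Aggregate("segment", (2000.0, 2000.0), 500.0,
                                        0.7)], seed=11)
        locs = synth.gen_smlm_stream(truth,
                                     synth.EmitterModel(precision_nm=20.0),
                                     n_frames=10_000, bursts_per_aggregate=125)
        table = self.run_pipeline(locs)
        assert len(table) == 1
        assert table.loc[0, "length_nm"] == pytest.approx(500.0, rel=0.15)

    def test_l_shape_recovers_total_arm_length(self):
        # two arms of 300 and 400 nm meeting at a right angle
        truth = synth.GroundTruth(aggregates=[
            synth.Aggregate("segment", (2000.0, 2000.0), 300.0, 0.0),
            synth.Aggregate("segment", (2300.0, 2000.0), 400.0, np.pi / 2)],
            seed=4)
        locs = synth.gen_smlm_stream(truth,
                                     synth.EmitterModel(precision_nm=15.0),
                                     n_frames=10_000, bursts_per_aggregate=90)
        table = self.run_pipeline(locs)
        assert len(table) == 1
        assert table.loc[0, "length_nm"] == pytest.approx(700.0, rel=0.15)


class TestRendering:
    def test_counts_conserved(self, rng):
        t = table_from([(i, rng.uniform(0, 500), rng.uniform(0, 500))
                        for i in range(200)])
        for px in (10.0, 20.0):
            counts, _ = smlm.render_superres(t, pixel_nm=px)
            assert counts.sum() == 200

    def test_single_localization_single_pixel(self):
        t = table_from([(0, 35.0, 35.0)])
        counts, _ = smlm.render_superres(t, pixel_nm=10.0)
        assert counts.sum() == 1 and (counts > 0).sum() == 1

    def test_cluster_labels_present(self):
        rows = [(f, 5.0, 5.0) for f in range(10, 15)]
        t = table_from(rows * 5)  # enough locs for grouping
        bursts = smlm.group_bursts(t)
        clusters = smlm.cluster_bursts(bursts, min_bursts=1)
        _, labels = smlm.render_superres(t, pixel_nm=10.0, clusters=clusters,
                                         bursts=bursts)
        assert labels.max() == 1


class TestSizeFractions:
    def test_two_thirds_below_500(self):
        out = smlm.cluster_size_fractions([190.0, 280.0, 1450.0])
        assert out["below_500nm"] == pytest.approx(2 / 3)
        assert sum(out["partition"]) == pytest.approx(1.0)

    def test_all_below(self):
        assert smlm.cluster_size_fractions([100, 200])["below_500nm"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            smlm.cluster_size_fractions([])
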