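"""Minimum-distance computation and regime segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimerlens.config import AnalysisConfig
from dimerlens.geometry import min_image
from dimerlens.kinetics import (
    DistanceSeries,
    count_dissociations,
    distance_heatmap,
    distance_series,
    min_distance,
    segment_regimes,
)

from conftest import make_point_receptors


def brute_force_min_distance(a, b, box):
    best = np.inf
    for p in a:
        for q in b:
            d = p - q
            d = d - box * np.round(d / box)
            best = min(best, float(np.sqrt((d * d).sum())))
    return best


class TestMinDistance:
    def test_direct_distance(self):
        traj, top = make_point_receptors([(1, 1, 1)], [(2, 1, 1)])
        assert min_distance(traj.frame(0), top) == pytest.approx(1.0)

    def test_minimum_image_across_boundary(self):
        traj, top = make_point_receptors([(0.2, 1, 1)], [(9.9, 1, 1)])
        assert min_distance(traj.frame(0), top) == pytest.approx(0.3)

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(11)
        box = np.array([7.0, 9.0, 5.0])
        for _ in range(20):
            a = rng.uniform(-5, 15, size=(25, 3))
            b = rng.uniform(-5, 15, size=(25, 3))
            traj, top = make_point_receptors(a.tolist(), b.tolist(), box=tuple(box))
            got = min_distance(traj.frame(0), top)
            assert got == pytest.approx(
                brute_force_min_distance(a, b, box), abs=1e-9
            )

    @given(
        shift=st.tuples(
            st.integers(-3, 3), st.integers(-3, 3), st.integers(-3, 3)
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_translation_by_box_vectors_invariant(self, shift):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 10, size=(8, 3))
        b = rng.uniform(0, 10, size=(8, 3))
        box = np.array([10.0, 10.0, 10.0])
        traj, top = make_point_receptors(a.tolist(), b.tolist())
        base = min_distance(traj.frame(0), top)
        traj2, top2 = make_point_receptors(
            (a + np.array(shift) * box).tolist(), b.tolist()
        )
        assert min_distance(traj2.frame(0), top2) == pytest.approx(base, abs=1e-9)

    def test_loop_beads_excluded(self):
        # the loop bead is closest but must not contribute
        traj, top = make_point_receptors(
            [(1, 1, 1), (4.9, 1, 1)],
            [(5, 1, 1)],
            residues1=[(48, "I"), (250, "loop")],
            residues2=[(48, "I")],
        )
        assert min_distance(traj.frame(0), top) == pytest.approx(4.0)

    def test_distance_series_matches_per_frame(self, reference_runs):
        _, traj, top, _, _ = reference_runs["popc_0"]
        series = distance_series(traj, top)
        for fi in (0, 350, 1000):
            assert series.min_distance[fi] == pytest.approx(
                min_distance(traj.frame(fi), top), abs=1e-12
            )


def series(distances, dt=1.0):
    d = np.asarray(distances, dtype=float)
    return DistanceSeries(times=np.arange(len(d)) * dt, min_distance=d)


class TestSegmentation:
    def test_all_monomer(self):
        seg = segment_regimes(series([2.0] * 50))
        assert seg.intervals == [(0, 49, "monomer")]
        assert seg.dimer_events == []

    def test_single_transient_definition_case(self):
        d = [2.0] * 10 + [0.4] * 491 + [2.0] * 100
        seg = segment_regimes(series(d))
        assert seg.dimer_intervals() == [(10, 500, "transient")]

    def test_stable_runs_to_final_frame(self):
        d = [2.0] * 10 + [0.4] * 200
        seg = segment_regimes(series(d))
        assert seg.dimer_intervals() == [(10, 209, "stable")]

    def test_short_contact_is_grazing(self):
        # dwell below cut-off is long enough to open but closes too soon
        d = [2.0] * 10 + [0.4] * 20 + [2.0] * 100
        seg = segment_regimes(series(d))
        assert seg.dimer_events == []
        assert seg.intervals == [(0, 129, "monomer")]

    def test_sub_minimum_dwell_never_opens(self):
        d = [2.0] * 10 + [0.4] * 4 + [2.0] * 10
        seg = segment_regimes(series(d))
        assert seg.dimer_events == []

    def test_intermediate_distances_continue_dimer(self):
        # excursions into (0.5, 1.5] do not close an open dimer
        d = [0.4] * 120 + [1.2] * 50 + [0.4] * 120 + [2.0] * 50
        seg = segment_regimes(series(d))
        assert seg.dimer_intervals() == [(0, 289, "transient")]

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0.2, 3.0, size=400)
        s = series(d)
        a = segment_regimes(s)
        b = segment_regimes(s)
        assert a.intervals == b.intervals and a.dimer_events == b.dimer_events

    def test_hysteresis_boundary_distances(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(0.2, 2.5, size=2000)
        cfg = AnalysisConfig()
        seg = segment_regimes(series(d), cfg)
        for s_, e_, cls in seg.dimer_intervals():
            assert all(d[s_ : s_ + cfg.min_dimer_frames] < cfg.dimer_cutoff)
            if e_ + 1 < len(d):
                assert d[e_ + 1] > cfg.dissociation_threshold

    def test_partition_and_alternation(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(0.2, 2.5, size=1500)
        seg = segment_regimes(series(d))
        spans = [(s, e) for s, e, _ in seg.intervals]
        assert spans[0][0] == 0 and spans[-1][1] == 1499
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 == e1 + 1
        labels = [lab for _, _, lab in seg.intervals]
        assert all(a != b for a, b in zip(labels, labels[1:]))


class TestEventCountsAndHeatmap:
    def test_zero_events(self):
        seg = segment_regimes(series([2.0] * 20))
        assert count_dissociations([seg])["total"] == 0

    def test_sum_over_segmentations(self):
        segs = []
        for n in (2, 0, 1):
            d = []
            for _ in range(n):
                d += [0.4] * 150 + [2.0] * 20
            d += [2.0] * 30
            segs.append(segment_regimes(series(d)))
        out = count_dissociations(segs)
        assert out["total"] == 3

    def test_constant_series_in_lowest_bin(self):
        hm = distance_heatmap([series([0.3] * 40)])
        assert hm.iloc[0]["<0.5"] == 40
        assert hm.iloc[0].drop("<0.5").sum() == 0

    def test_ramp_passes_through_bins_in_order(self):
        d = np.linspace(0.0, 6.0, 200)
        hm = distance_heatmap([series(d)])
        counts = hm.iloc[0]
        assert (counts > 0).all()

    def test_frame_count_conserved_per_row(self):
        rng = np.random.default_rng(4)
        lst = [series(rng.uniform(0, 8, size=n)) for n in (50, 77)]
        hm = distance_heatmap(lst)
        assert hm.sum(axis=1).tolist() == [50, 77]
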