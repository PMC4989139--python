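"""The planted-scenario generator: determinism, validity, fidelity."""

import numpy as np
import pytest

from dimerlens.config import AnalysisConfig
from dimerlens.kinetics import distance_series, segment_regimes
from dimerlens.synthetic import (
    DimerInterval,
    GenerationError,
    LipidHotspot,
    PlantedScenario,
    build_receptor_template,
    generate_trajectory,
    reference_scenarios,
)
from dimerlens.topology import SystemTopology


class TestTemplate:
    def test_deterministic_for_a_seed(self):
        a = build_receptor_template(5)
        b = build_receptor_template(5)
        assert np.array_equal(a.positions, b.positions)

    def test_different_seeds_differ(self):
        assert not np.array_equal(
            build_receptor_template(1).positions, build_receptor_template(2).positions
        )

    def test_helix_sectors_pairwise_disjoint(self):
        tpl = build_receptor_template(0)
        angles = sorted(tpl.helix_angles.values())
        gaps = np.diff(angles + [angles[0] + 360.0])
        assert (gaps > 2 * 180.0 / 7.0 - 1e-9).all()

    def test_anchor_residues_on_expected_helices(self):
        tpl = build_receptor_template(0)
        rec = tpl.records
        assert rec.loc[tpl.bead_index(48), "helix_label"] == "I"
        assert rec.loc[tpl.bead_index(164), "helix_label"] == "IV"
        assert rec.loc[tpl.bead_index(167), "helix_label"] == "IV"
        # the 164-167 hinge is vertical: the planted-angle construction needs it
        p = tpl.positions
        assert np.allclose(
            p[tpl.bead_index(164)][:2], p[tpl.bead_index(167)][:2]
        )

    def test_each_helix_has_at_least_three_backbone_beads(self):
        tpl = build_receptor_template(3)
        counts = (
            tpl.records[tpl.records["bead_role"] == "backbone"]
            .groupby("helix_label")
            .size()
        )
        assert (counts.drop("loop") >= 3).all()


class TestScenarioValidation:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(GenerationError, match="ordered"):
            PlantedScenario(
                n_frames=500,
                dimer_intervals=[
                    DimerInterval(10, 200, ("I", "I")),
                    DimerInterval(150, 300, ("I", "I")),
                ],
            )

    def test_stable_must_reach_final_frame(self):
        with pytest.raises(GenerationError, match="last frame"):
            PlantedScenario(
                n_frames=500,
                dimer_intervals=[DimerInterval(10, 200, ("I", "I"), stable=True)],
            )

    def test_hotspot_occupancy_bounds(self):
        with pytest.raises(GenerationError, match="occupancy"):
            PlantedScenario(
                n_frames=500, lipid_hotspots=[LipidHotspot(1, 48, "CHOL", 1.2)]
            )

    def test_chol_hotspot_without_cholesterol_unsatisfiable(self):
        scenario = PlantedScenario(
            n_frames=200,
            cholesterol_fraction=0.0,
            lipid_hotspots=[LipidHotspot(1, 48, "CHOL", 0.5)],
        )
        with pytest.raises(GenerationError, match="not enough CHOL"):
            generate_trajectory(scenario)

    def test_hotspot_run_longer_than_any_interval_unsatisfiable(self):
        scenario = PlantedScenario(
            n_frames=600,
            cholesterol_fraction=9.0,
            dimer_intervals=[DimerInterval(100, 499, ("I", "I"))],
            lipid_hotspots=[LipidHotspot(1, 48, "CHOL", 0.9, "monomer")],
        )
        # monomer frames total 200 but split 100 + 100: a 180-frame run cannot fit
        with pytest.raises(GenerationError, match="run"):
            generate_trajectory(scenario)

    def test_yaml_round_trip(self, tmp_path):
        sc = reference_scenarios()[2]
        p = tmp_path / "sc.yaml"
        sc.to_yaml(p)
        back = PlantedScenario.from_yaml(p)
        assert back == sc


class TestGeneration:
    def test_bit_identical_regeneration(self):
        sc = PlantedScenario(
            n_frames=120,
            cholesterol_fraction=9.0,
            dimer_intervals=[DimerInterval(40, 119, ("I", "I"), stable=True)],
            seed=99,
        )
        t1, _, g1 = generate_trajectory(sc)
        t2, _, g2 = generate_trajectory(sc)
        assert np.array_equal(t1.coords, t2.coords)
        assert g1 == g2

    def test_topology_passes_validation(self, reference_runs):
        for name, (_, _, top, _, _) in reference_runs.items():
            assert isinstance(top, SystemTopology)
            assert top.receptor_ids == [1, 2]

    def test_no_interval_scenario_stays_monomeric(self):
        sc = PlantedScenario(n_frames=400, seed=5)
        traj, top, _ = generate_trajectory(sc)
        d = distance_series(traj, top).min_distance
        assert (d > 1.0).mean() >= 0.99

    def test_full_occupancy_hotspot_limit(self):
        sc = PlantedScenario(
            n_frames=200,
            cholesterol_fraction=30.0,
            lipid_hotspots=[LipidHotspot(1, 48, "CHOL", 1.0, "monomer")],
            seed=17,
        )
        traj, top, truth = generate_trajectory(sc)
        cfg = AnalysisConfig()
        from dimerlens.lipids import residue_occupancy

        prof = residue_occupancy(traj, top, [(0, 199)], "CHOL", cfg, 1, "monomer")
        assert prof.values.loc[48] == 1.0

    def test_transient_shorter_than_dwell_minimum_rejected(self):
        sc = PlantedScenario(
            n_frames=400,
            dimer_intervals=[DimerInterval(100, 149, ("I", "I"))],
            dt=1.0,
        )
        cfg = AnalysisConfig(min_transient_duration=100.0)
        with pytest.raises(GenerationError, match="min_transient_duration"):
            generate_trajectory(sc, cfg)


class TestReferenceScenarios:
    def test_four_compositions(self):
        scs = reference_scenarios()
        assert len(scs) == 4
        assert [s.cholesterol_fraction for s in scs] == [0.0, 9.0, 30.0, 50.0]

    def test_pure_popc_scenario_has_no_cholesterol(self, reference_runs):
        _, _, top, _, _ = reference_runs["popc_0"]
        assert top.lipid_molecules("CHOL") == []

    def test_each_runs_within_bead_and_frame_budget(self):
        for sc in reference_scenarios():
            assert sc.n_frames <= 5000
            traj_beads = 2 * build_receptor_template(sc.seed).n_beads + (
                3 * sc.n_popc + 2 * sc.n_chol
            )
            assert traj_beads <= 5000

    def test_grazing_approaches_dip_without_dimerizing(self, reference_runs, config):
        _, traj, top, truth, seg = reference_runs["popc_0"]
        d = distance_series(traj, top).min_distance
        for g in truth["grazing_frames"]:
            assert d[g] < 1.0
            assert d[g] > config.dimer_cutoff
        # grazing frames are monomer in the recovered segmentation
        labels = seg.frame_labels()
        assert all(labels[g] == "monomer" for g in truth["grazing_frames"])
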