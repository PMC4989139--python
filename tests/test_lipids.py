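"""Lipid occupancy (longest contact run) and bilayer-thickness mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimerlens.config import AnalysisConfig
from dimerlens.lipids import (
    OccupancyProfile,
    average_profiles,
    longest_contact_run,
    residue_occupancy,
    thickness_map,
)
from dimerlens.topology import BEAD_COLUMNS, SystemTopology
from dimerlens.trajectory import Trajectory

HELIX_DEFS = {
    "I": (37, 62), "II": (74, 98), "III": (110, 132), "IV": (153, 175),
    "V": (192, 217), "VI": (346, 371), "VII": (379, 403),
}


def brute_force_longest_run(flags):
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


@given(st.lists(st.booleans(), max_size=200))
@settings(max_examples=60, deadline=None)
def test_longest_run_matches_brute_force(flags):
    assert longest_contact_run(np.array(flags, dtype=bool)) == brute_force_longest_run(
        flags
    )


def contact_plan_system(plan: np.ndarray, cutoff: float = 0.6):
    """One single-residue receptor pair and one CHOL whose contact state per
    frame follows ``plan`` exactly (True = within cutoff)."""
    n = len(plan)
    rows = []
    for bead_id, (mol, kind, rid, res, role, helix) in enumerate(
        [
            (1, "receptor", 1, 48, "backbone", "I"),
            (2, "receptor", 2, 48, "backbone", "I"),
            (3, "CHOL", None, None, "other", None),
            (4, "CHOL", None, None, "other", None),
        ]
    ):
        rows.append(
            {
                "bead_id": bead_id, "molecule_id": mol, "molecule_kind": kind,
                "receptor_id": rid, "residue_index": res, "bead_role": role,
                "helix_label": helix,
            }
        )
    top = SystemTopology(
        beads=pd.DataFrame(rows, columns=BEAD_COLUMNS), helix_definitions=HELIX_DEFS
    )
    coords = np.zeros((n, 4, 3))
    coords[:, 0] = [2.0, 2.0, 2.0]  # receptor 1 residue 48
    coords[:, 1] = [8.0, 8.0, 2.0]  # receptor 2, far away
    lipid_x = np.where(plan, 2.3, 5.0)
    coords[:, 2, 0] = lipid_x
    coords[:, 2, 1] = 2.0
    coords[:, 2, 2] = 2.0
    coords[:, 3] = coords[:, 2] + [0.0, 0.0, 0.4]
    traj = Trajectory(
        times=np.arange(n, dtype=float),
        boxes=np.tile([12.0, 12.0, 8.0], (n, 1)),
        coords=coords,
    )
    return traj, top


class TestOccupancy:
    def test_always_in_contact_gives_one(self):
        traj, top = contact_plan_system(np.ones(50, dtype=bool))
        prof = residue_occupancy(traj, top, [(0, 49)], "CHOL")
        assert prof.values.loc[48] == 1.0

    def test_alternating_contact_gives_one_over_length(self):
        plan = np.zeros(50, dtype=bool)
        plan[::2] = True
        traj, top = contact_plan_system(plan)
        prof = residue_occupancy(traj, top, [(0, 49)], "CHOL")
        assert prof.values.loc[48] == pytest.approx(1.0 / 50.0)

    def test_matches_run_length_oracle_on_random_plan(self):
        rng = np.random.default_rng(13)
        plan = rng.random(1000) < 0.5
        traj, top = contact_plan_system(plan)
        prof = residue_occupancy(traj, top, [(0, 999)], "CHOL")
        assert prof.values.loc[48] == pytest.approx(
            brute_force_longest_run(plan) / 1000.0
        )

    def test_runs_do_not_bridge_interval_gaps(self):
        plan = np.ones(40, dtype=bool)
        traj, top = contact_plan_system(plan)
        prof = residue_occupancy(traj, top, [(0, 19), (20, 39)], "CHOL")
        assert prof.values.loc[48] == pytest.approx(20.0 / 40.0)

    def test_extending_a_run_never_decreases_occupancy(self):
        rng = np.random.default_rng(3)
        plan = rng.random(300) < 0.4
        traj, top = contact_plan_system(plan)
        base = residue_occupancy(traj, top, [(0, 299)], "CHOL").values.loc[48]
        runs = np.flatnonzero(plan)
        plan2 = plan.copy()
        plan2[min(runs.max() + 1, 299)] = True
        traj2, top2 = contact_plan_system(plan2)
        ext = residue_occupancy(traj2, top2, [(0, 299)], "CHOL").values.loc[48]
        assert ext >= base

    def test_zero_lipids_warns_and_zeroes(self):
        traj, top = contact_plan_system(np.ones(10, dtype=bool))
        with pytest.warns(UserWarning, match="no POPC"):
            prof = residue_occupancy(traj, top, [(0, 9)], "POPC")
        assert (prof.values == 0).all()

    def test_planted_hotspot_recovered(self, reference_runs, config):
        _, traj, top, truth, seg = reference_runs["chol_9"]
        mono = [(s, e) for s, e, lab in seg.intervals if lab == "monomer"]
        hs = [h for h in truth["hotspots"] if h["regime"] == "monomer"][0]
        prof = residue_occupancy(
            traj, top, mono, hs["lipid_kind"], config,
            receptor_id=hs["receptor_id"], regime="monomer",
        )
        regime_len = sum(e - s + 1 for s, e in mono)
        assert prof.values.loc[hs["residue_index"]] == pytest.approx(
            hs["planted_occupancy"], abs=1.0 / regime_len
        )

    def test_average_profiles(self):
        a = OccupancyProfile(
            values=pd.Series({48: 0.8, 50: 0.2}), regime="monomer",
            lipid_kind="CHOL", receptor_id=1,
        )
        b = OccupancyProfile(
            values=pd.Series({48: 0.4, 50: 0.0}), regime="monomer",
            lipid_kind="CHOL", receptor_id=2,
        )
        mean = average_profiles([a, b])
        assert mean.values.loc[48] == pytest.approx(0.6)
        assert mean.receptor_id is None


class TestThickness:
    def test_flat_bilayer_is_unity(self, reference_runs, config):
        _, traj, top, _, seg = reference_runs["popc_0"]
        mono = [(s, e) for s, e, lab in seg.intervals if lab == "monomer"]
        tmap = thickness_map(traj, top, mono, config, receptor_id=1)
        g = tmap.grid.to_numpy()
        assert np.nanmax(np.abs(g - 1.0)) <= 1e-9

    def test_planted_sector_deformation(self, reference_runs, config):
        _, traj, top, _, seg = reference_runs["chol_30"]
        mono = [(s, e) for s, e, lab in seg.intervals if lab == "monomer"]
        tmap = thickness_map(traj, top, mono, config, receptor_id=1)
        g = tmap.grid.to_numpy()
        xs = tmap.grid.index.to_numpy(dtype=float)
        gx, gy = np.meshgrid(xs, tmap.grid.columns.to_numpy(dtype=float), indexing="ij")
        ang = np.degrees(np.arctan2(gy, gx))
        rr = np.hypot(gx, gy)
        # helix I faces +x in the body frame
        sector = (np.abs(ang) <= 12) & (rr > 0.8) & (rr < 1.9) & np.isfinite(g)
        assert sector.sum() > 0
        assert np.nanmax(g[sector]) == pytest.approx(1.10, abs=0.02)

    def test_farfield_mean_is_unity(self, reference_runs, config):
        _, traj, top, _, seg = reference_runs["chol_30"]
        mono = [(s, e) for s, e, lab in seg.intervals if lab == "monomer"]
        tmap = thickness_map(traj, top, mono, config, receptor_id=1)
        assert tmap.farfield_cells_mean(config.farfield_min_distance) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_scaling_z_leaves_normalized_map_unchanged(self, reference_runs, config):
        _, traj, top, _, seg = reference_runs["popc_0"]
        mono = [(s, e) for s, e, lab in seg.intervals if lab == "monomer"][:1]
        base = thickness_map(traj, top, mono, config, receptor_id=1)
        scaled = Trajectory(
            times=traj.times,
            boxes=traj.boxes * [1.0, 1.0, 2.0],
            coords=traj.coords * [1.0, 1.0, 2.0],
            label=traj.label,
            composition=traj.composition,
        )
        doubled = thickness_map(scaled, top, mono, config, receptor_id=1)
        assert doubled.farfield_thickness == pytest.approx(
            2.0 * base.farfield_thickness
        )
        pd.testing.assert_frame_equal(doubled.grid, base.grid)

    def test_leaflets_never_flip_in_synthetic_data(self, reference_runs):
        _, traj, top, _, _ = reference_runs["chol_9"]
        phos = top.phosphate_indices()
        z = traj.coords[:, phos, 2]
        sign = np.sign(z - np.median(z, axis=1, keepdims=True))
        assert (sign == sign[0]).all()
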