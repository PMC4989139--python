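"""Rotational-angle computation, orientation densities and conformers."""

import numpy as np
import pandas as pd
import pytest

from dimerlens.config import AnalysisConfig
from dimerlens.geometry import dihedral, rotation_about_axis
from dimerlens.orientation import (
    ConformerRegions,
    assign_conformer,
    default_regions,
    orientation_density,
    orientation_series,
    rotation_angle,
    OrientationSeries,
)

from conftest import make_point_receptors

P1, P2, P3, P4 = (
    np.array([0.0, 0.0, 0.0]),
    np.array([1.0, 0.0, 0.0]),
    np.array([1.0, 1.0, 0.0]),
    np.array([1.0, 1.0, 1.0]),
)


class TestDihedral:
    def test_canonical_staircase_is_plus_ninety(self):
        assert dihedral(P1, P2, P3, P4) == pytest.approx(90.0, abs=1e-9)

    def test_coplanar_cases(self):
        # fourth point in the first plane: opposite side of the hinge -> 180
        assert abs(dihedral(P1, P2, P3, np.array([2.0, 2.0, 0.0]))) == pytest.approx(
            180.0, abs=1e-9
        )
        # same side as p1 -> cis, angle zero
        assert dihedral(P1, P2, P3, np.array([0.0, 0.5, 0.0])) == pytest.approx(
            0.0, abs=1e-9
        )

    @pytest.mark.parametrize("delta", [30.0, -30.0, 90.0, -90.0, 170.0])
    def test_rotation_about_hinge_shifts_angle_by_delta(self, delta):
        axis = P3 - P2
        p4r = P3 + rotation_about_axis(axis, delta) @ (P4 - P3)
        got = dihedral(P1, P2, P3, p4r)
        assert (got - 90.0 - delta) % 360.0 == pytest.approx(0.0, abs=1e-6) or (
            got - 90.0 - delta
        ) % 360.0 == pytest.approx(360.0, abs=1e-6)

    def test_collinear_points_degenerate(self):
        assert np.isnan(
            dihedral(P1, P2, np.array([2.0, 0.0, 0.0]), P4)
        )

    def test_periodic_split_molecule(self):
        box = np.array([5.0, 5.0, 5.0])
        shifted = P4 + np.array([5.0, 0.0, 0.0])
        assert dihedral(P1, P2, P3, shifted, box=box) == pytest.approx(90.0, abs=1e-9)


def _angle_system(extra_rotation=0.0):
    """Two receptors with the four angle-defining backbone beads each."""
    r1 = [(2.0, 2.0, 1.0), (3.0, 2.0, 1.0), (3.0, 2.0, 1.6)]
    base2 = np.array([(6.0, 2.4, 1.0), (5.0, 2.4, 1.0), (5.0, 2.4, 1.6)])
    if extra_rotation:
        rot = rotation_about_axis([0, 0, 1.0], extra_rotation)
        centre = np.array([5.5, 2.4, 1.3])
        base2 = (base2 - centre) @ rot.T + centre
    residues = [(48, "I"), (164, "IV"), (167, "IV")]
    return make_point_receptors(
        r1, [tuple(p) for p in base2], residues1=residues, residues2=residues
    )


class TestRotationAngle:
    def test_exchange_symmetry(self):
        traj, top = _angle_system(extra_rotation=25.0)
        t1 = rotation_angle(traj.frame(0), top, 1)
        t2 = rotation_angle(traj.frame(0), top, 2)
        # swap receptor identities in the topology
        swapped = top.beads.copy()
        swapped["receptor_id"] = swapped["receptor_id"].map({1: 2, 2: 1})
        from dimerlens.topology import SystemTopology

        top_sw = SystemTopology(beads=swapped, helix_definitions=top.helix_definitions)
        s1 = rotation_angle(traj.frame(0), top_sw, 1)
        s2 = rotation_angle(traj.frame(0), top_sw, 2)
        assert s1 == pytest.approx(t2, abs=1e-9)
        assert s2 == pytest.approx(t1, abs=1e-9)

    def test_rigid_body_invariance(self):
        traj, top = _angle_system(extra_rotation=40.0)
        base = (
            rotation_angle(traj.frame(0), top, 1),
            rotation_angle(traj.frame(0), top, 2),
        )
        rot = rotation_about_axis([0, 0, 1.0], 73.0)
        coords = traj.coords[0] @ rot.T + np.array([1.3, 0.7, 0.2])
        traj.coords[0] = coords
        moved = (
            rotation_angle(traj.frame(0), top, 1),
            rotation_angle(traj.frame(0), top, 2),
        )
        assert moved[0] == pytest.approx(base[0], abs=1e-9)
        assert moved[1] == pytest.approx(base[1], abs=1e-9)

    def test_recovers_planted_angles(self, reference_runs):
        _, traj, top, truth, _ = reference_runs["chol_30"]
        stable = [iv for iv in truth["dimer_intervals"] if iv["stable"]][0]
        mid = (stable["start"] + stable["end"]) // 2
        assert rotation_angle(traj.frame(mid), top, 1) == pytest.approx(30.0, abs=1e-6)
        assert rotation_angle(traj.frame(mid), top, 2) == pytest.approx(-45.0, abs=1e-6)


class TestDensity:
    def test_single_frame_single_bin(self):
        s = OrientationSeries(frames=[0], theta1=[0.0], theta2=[0.0])
        density = orientation_density([s])
        vals = density.to_numpy()
        assert vals.sum() == pytest.approx(1.0, abs=1e-12)
        assert (vals > 0).sum() == 1

    def test_normalization_any_bin_width(self):
        rng = np.random.default_rng(0)
        s = OrientationSeries(
            frames=np.arange(500),
            theta1=rng.uniform(-179, 180, 500),
            theta2=rng.uniform(-179, 180, 500),
        )
        for width in (5.0, 10.0, 30.0):
            cfg = AnalysisConfig(angle_bin_width=width)
            assert orientation_density([s], cfg).to_numpy().sum() == pytest.approx(
                1.0, abs=1e-12
            )

    def test_modal_bin_at_planted_orientation(self, reference_runs, config):
        _, traj, top, _, seg = reference_runs["chol_30"]
        series = orientation_series(traj, top, seg, config)
        density = orientation_density([series], config)
        i, j = np.unravel_index(np.argmax(density.to_numpy()), density.shape)
        t1c, t2c = density.index[i], density.columns[j]
        half = config.angle_bin_width / 2
        assert abs(t1c - 30.0) <= half
        assert abs(t2c - (-45.0)) <= half

    def test_equalized_subsampling_is_seeded(self):
        rng = np.random.default_rng(1)
        mk = lambda comp, n: OrientationSeries(
            frames=np.arange(n),
            theta1=rng.uniform(-90, 90, n),
            theta2=rng.uniform(-90, 90, n),
            composition=comp,
        )
        series = [mk(0.0, 50), mk(0.0, 50), mk(9.0, 50)]
        cfg = AnalysisConfig(seed=42)
        a = orientation_density(series, cfg, equalize=True)
        b = orientation_density(series, cfg, equalize=True)
        pd.testing.assert_frame_equal(a, b)


class TestConformers:
    def test_origin_maps_to_A(self):
        assert assign_conformer(0.0, 0.0, default_regions()) == "A"

    def test_inside_and_outside(self):
        regions = default_regions()
        assert assign_conformer(150.0, 150.0, regions) == "B"
        assert assign_conformer(150.0, 0.0, regions) == "C"
        assert assign_conformer(40.0, -40.0, regions) == "A'"
        assert assign_conformer(85.0, 85.0, regions) == "unassigned"

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ConformerRegions(
                regions={
                    "A": [(-20.0, 20.0, -20.0, 20.0)],
                    "B": [(-10.0, 30.0, -10.0, 30.0)],
                }
            )

    def test_regions_yaml_round_trip(self, tmp_path):
        regions = default_regions()
        p = tmp_path / "regions.yaml"
        regions.to_yaml(p)
        back = ConformerRegions.from_yaml(p)
        assert back.regions == regions.regions
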