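"""Shared fixtures: packaged scenarios generated once per session, plus
small hand-built systems for unit-level geometry tests."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from dimerlens.config import AnalysisConfig
from dimerlens.kinetics import distance_series, segment_regimes
from dimerlens.synthetic import generate_trajectory, reference_scenarios
from dimerlens.topology import BEAD_COLUMNS, SystemTopology
from dimerlens.trajectory import Trajectory

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def reference_runs(config):
    """name -> (scenario, trajectory, topology, ground_truth, segmentation)."""
    runs = {}
    for scenario in reference_scenarios():
        traj, top, truth = generate_trajectory(scenario, config)
        seg = segment_regimes(distance_series(traj, top), config)
        runs[scenario.name] = (scenario, traj, top, truth, seg)
    return runs


def make_point_receptors(
    coords1: list[tuple[float, float, float]],
    coords2: list[tuple[float, float, float]],
    box=(10.0, 10.0, 10.0),
    residues1=None,
    residues2=None,
) -> tuple[Trajectory, SystemTopology]:
    """Two receptors made of individually placed beads, one frame.

    Residues default to helix-I backbone beads (residue 48, 49, ...).
    ``residuesN`` entries may be (residue_index, helix_label) tuples.
    """
    helix_definitions = {
        "I": (37, 62),
        "II": (74, 98),
        "III": (110, 132),
        "IV": (153, 175),
        "V": (192, 217),
        "VI": (346, 371),
        "VII": (379, 403),
    }
    rows = []
    coords = []
    bead_id = 0
    for rid, (pts, residues) in enumerate(
        [(coords1, residues1), (coords2, residues2)], start=1
    ):
        residues = residues or [(48, "I")] * len(pts)
        for (x, y, z), (res, helix) in zip(pts, residues):
            rows.append(
                {
                    "bead_id": bead_id,
                    "molecule_id": rid,
                    "molecule_kind": "receptor",
                    "receptor_id": rid,
                    "residue_index": res,
                    "bead_role": "backbone",
                    "helix_label": helix,
                }
            )
            coords.append([x, y, z])
            bead_id += 1
    top = SystemTopology(
        beads=pd.DataFrame(rows, columns=BEAD_COLUMNS),
        helix_definitions=helix_definitions,
    )
    traj = Trajectory(
        times=np.array([0.0]),
        boxes=np.array([box], dtype=float),
        coords=np.array([coords], dtype=float),
    )
    return traj, top
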