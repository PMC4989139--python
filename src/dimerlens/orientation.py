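"""Rotational orientation of the two receptors in the dimer regime.

The relative orientation of a receptor pair is described by two angles:
``theta1`` is the rotational angle of receptor 1 relative to receptor 2
and ``theta2`` the converse. Each is the signed four-point dihedral over
the backbone beads of residues 48, 164 and 167 of the subject receptor
and residue 167 of the other receptor (48-164-167-167'), i.e. the angle
between the plane fixed by helix I and helix IV of the subject and the
plane containing the partner's helix-IV anchor, hinged on the subject's
164-167 axis. The convention is right-handed with range (-180, 180];
minimum-image displacements make the inter-receptor leg periodicity
safe.

Orientation statistics are 2-D population densities over
``(theta1, theta2)`` restricted to dimer-regime frames, with optional
seeded subsampling so that membrane compositions contributing unequal
numbers of simulations are compared on equal footing. Populated regions
can be mapped to named conformers (A, B, C, A') through axis-aligned
rectangles supplied as configuration; the default regions are a
calibration on synthetic data in which (0, 0) — the symmetric homodimer
— falls in conformer A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig
from .geometry import dihedral
from .kinetics import RegimeSegmentation
from .topology import SystemTopology
from .trajectory import Frame, Trajectory

__all__ = [
    "OrientationSeries",
    "ConformerRegions",
    "rotation_angle",
    "orientation_series",
    "orientation_density",
    "assign_conformer",
    "default_regions",
]


@dataclass
class OrientationSeries:
    """Per-dimer-frame (theta1, theta2) for one trajectory."""

    frames: np.ndarray  # frame indices within the trajectory
    theta1: np.ndarray  # degrees, (-180, 180]
    theta2: np.ndarray
    label: str = ""
    composition: float = 0.0
    n_simulations: int = 1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.theta1 = np.asarray(self.theta1, dtype=float)
        self.theta2 = np.asarray(self.theta2, dtype=float)
        if not (len(self.frames) == len(self.theta1) == len(self.theta2)):
            raise ValueError("frames, theta1 and theta2 must have equal lengths")
        for th in (self.theta1, self.theta2):
            finite = th[np.isfinite(th)]
            if finite.size and (np.any(finite <= -180.0) or np.any(finite > 180.0)):
                raise ValueError("angles must lie in (-180, 180]")

    def __len__(self) -> int:
        return len(self.frames)


def rotation_angle(
    frame: Frame,
    topology: SystemTopology,
    subject: int,
    angle_residues: tuple[int, int, int] = (48, 164, 167),
) -> float:
    """Rotational angle (degrees) of ``subject`` relative to the partner.

    Returns NaN when the defining beads are collinear (degenerate plane).
    """
    other = 2 if subject == 1 else 1
    r_a, r_hinge1, r_hinge2 = angle_residues
    p1 = frame.coords[topology.backbone_bead(subject, r_a)]
    p2 = frame.coords[topology.backbone_bead(subject, r_hinge1)]
    p3 = frame.coords[topology.backbone_bead(subject, r_hinge2)]
    p4 = frame.coords[topology.backbone_bead(other, r_hinge2)]
    return dihedral(p1, p2, p3, p4, box=frame.box)


def orientation_series(
    trajectory: Trajectory,
    topology: SystemTopology,
    segmentation: RegimeSegmentation,
    config: AnalysisConfig | None = None,
) -> OrientationSeries:
    """theta1/theta2 on every dimer-regime frame of a trajectory."""
    config = config or AnalysisConfig()
    dimer_frames: list[int] = []
    for s, e, _ in segmentation.dimer_intervals():
        dimer_frames.extend(range(s, e + 1))
    idx = np.asarray(dimer_frames, dtype=int)
    th1 = np.empty(len(idx))
    th2 = np.empty(len(idx))
    for k, fi in enumerate(idx):
        fr = trajectory.frame(int(fi))
        th1[k] = rotation_angle(fr, topology, 1, config.angle_residues)
        th2[k] = rotation_angle(fr, topology, 2, config.angle_residues)
    return OrientationSeries(
        frames=idx,
        theta1=th1,
        theta2=th2,
        label=trajectory.label,
        composition=trajectory.composition,
    )


def _angle_bins(width: float) -> np.ndarray:
    n = int(round(360.0 / width))
    return np.linspace(-180.0, 180.0, n + 1)


def orientation_density(
    series_list: list[OrientationSeries],
    config: AnalysisConfig | None = None,
    equalize: bool = False,
) -> pd.DataFrame:
    """Normalized 2-D (theta1, theta2) population density.

    With ``equalize=True`` the contributing series are grouped by
    composition and each group is randomly subsampled (seeded by
    ``config.seed``) to the size of the smallest group, so compositions
    with unequal numbers of contributing simulations carry equal weight.

    Rows are theta1 bin centres, columns theta2 bin centres; the density
    sums to 1 (or is all-zero, with a warning, if no dimer frames exist).
    """
    config = config or AnalysisConfig()
    if not series_list:
        raise ValueError("need at least one orientation series")
    chosen = list(series_list)
    if equalize:
        rng = np.random.default_rng(config.seed)
        groups: dict[float, list[OrientationSeries]] = {}
        for s in series_list:
            groups.setdefault(s.composition, []).append(s)
        smallest = min(len(g) for g in groups.values())
        chosen = []
        for comp in sorted(groups):
            g = groups[comp]
            pick = rng.choice(len(g), size=smallest, replace=False)
            chosen.extend(g[int(i)] for i in sorted(pick))

    edges = _angle_bins(config.angle_bin_width)
    centres = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros((len(centres), len(centres)))
    total = 0
    for s in chosen:
        ok = np.isfinite(s.theta1) & np.isfinite(s.theta2)
        if not ok.any():
            continue
        # bin membership treats -180 as equivalent to +180 (same circle point)
        h, _, _ = np.histogram2d(s.theta1[ok], s.theta2[ok], bins=[edges, edges])
        hist += h
        total += int(ok.sum())
    if total == 0:
        warnings.warn("no dimer-regime frames: orientation density is empty")
    else:
        hist /= hist.sum()
    df = pd.DataFrame(hist, index=np.round(centres, 6), columns=np.round(centres, 6))
    df.index.name = "theta1"
    df.columns.name = "theta2"
    return df


# -- conformer regions -------------------------------------------------


@dataclass
class ConformerRegions:
    """Axis-aligned rectangles labelling regions of (theta1, theta2) space.

    Containment is half-open (``lo <= x < hi``) so rectangles sharing an
    edge do not double-assign; overlapping interiors are a configuration
    error.
    """

    regions: dict[str, list[tuple[float, float, float, float]]]
    # each rectangle is (theta1_lo, theta1_hi, theta2_lo, theta2_hi)

    def __post_init__(self) -> None:
        rects = []
        for label, rect_list in self.regions.items():
            for r in rect_list:
                lo1, hi1, lo2, hi2 = r
                if not (-180.0 <= lo1 < hi1 <= 180.0 and -180.0 <= lo2 < hi2 <= 180.0):
                    raise ValueError(f"region {label}: rectangle {r} outside domain")
                rects.append((label, r))
        for i, (la, ra) in enumerate(rects):
            for lb, rb in rects[i + 1 :]:
                if ra[0] < rb[1] and rb[0] < ra[1] and ra[2] < rb[3] and rb[2] < ra[3]:
                    raise ValueError(
                        f"conformer regions overlap: {la} {ra} and {lb} {rb}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConformerRegions":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        regions = {
            label: [tuple(float(v) for v in rect) for rect in rect_list]
            for label, rect_list in doc.items()
        }
        return cls(regions=regions)

    def to_yaml(self, path: str | Path) -> None:
        doc = {k: [list(r) for r in v] for k, v in self.regions.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_regions() -> ConformerRegions:
    """Packaged calibration rectangles for conformers A, B, C and A'.

    A is the symmetric homodimer around (0, 0); A' is the flexible ring
    around it; B the site-2 homointerface quadrant; C the two
    hetero-interface quadrants mixing sites 1 and 2.
    """
    return ConformerRegions(
        regions={
            "A": [(-25.0, 25.0, -25.0, 25.0)],
            "A'": [
                (-60.0, -25.0, -60.0, 60.0),
                (25.0, 60.0, -60.0, 60.0),
                (-25.0, 25.0, -60.0, -25.0),
                (-25.0, 25.0, 25.0, 60.0),
            ],
            "B": [(100.0, 180.0, 100.0, 180.0)],
            "C": [(100.0, 180.0, -60.0, 60.0), (-60.0, 60.0, 100.0, 180.0)],
        }
    )


def assign_conformer(
    theta1: float, theta2: float, regions: ConformerRegions
) -> str:
    """Label of the unique region containing the point, else 'unassigned'."""
    if not (np.isfinite(theta1) and np.isfinite(theta2)):
        return "unassigned"
    for label, rect_list in regions.regions.items():
        for lo1, hi1, lo2, hi2 in rect_list:
            if lo1 <= theta1 < hi1 and lo2 <= theta2 < hi2:
                return label
    return "unassigned"
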