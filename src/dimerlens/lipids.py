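"""Residue-wise lipid occupancy and bilayer-thickness mapping.

*Maximum occupancy* of a lipid species at a residue is the longest
normalized time a single lipid molecule stays continuously associated
with that residue: for each molecule, the longest run of consecutive
regime frames with any lipid bead within ``lipid_contact_cutoff``
(0.6 nm) of any residue bead, divided by the regime length in frames.
Runs do not bridge separate regime intervals, and a single frame out of
cutoff breaks a run (gap tolerance zero, configurable upstream of this
definition by preprocessing the contact series).

The *normalized bilayer thickness map* is computed in the body frame of
a chosen receptor: each frame is translated so the receptor's TM-bead
centroid is at the origin and rotated so the centroid-to-helix-I axis
points along +x. Phosphate beads are assigned to leaflets by the sign of
z relative to the per-frame phosphate median; thickness per planar grid
cell is (mean upper z) - (mean lower z) over all samples, normalized by
the far-field thickness measured from phosphates at least
``farfield_min_distance`` from every receptor bead. Phosphates within
that distance of the *other* receptor are excluded so the neighbour's
deformation is not attributed to the subject's surroundings. Values > 1
indicate local thickening (positive hydrophobic mismatch), < 1 local
thinning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, HELIX_LABELS
from .geometry import min_image
from .topology import SystemTopology, TopologyError
from .trajectory import Trajectory

__all__ = [
    "OccupancyProfile",
    "ThicknessMap",
    "longest_contact_run",
    "residue_occupancy",
    "average_profiles",
    "thickness_map",
]


@dataclass
class OccupancyProfile:
    """Residue index -> maximum normalized occupancy, for one regime."""

    values: pd.Series  # index residue_index, values in [0, 1]
    regime: str  # "monomer" | "dimer"
    lipid_kind: str  # "CHOL" | "POPC"
    receptor_id: int | None = None  # None = averaged over receptors
    normalization: str = "regime_length"

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.any((v < 0) | (v > 1.0 + 1e-12)):
            raise ValueError("occupancy values must lie in [0, 1]")

    def normalized_to_max(self) -> "OccupancyProfile":
        peak = float(self.values.max())
        vals = self.values / peak if peak > 0 else self.values
        return OccupancyProfile(
            values=vals,
            regime=self.regime,
            lipid_kind=self.lipid_kind,
            receptor_id=self.receptor_id,
            normalization=self.normalization + "+profile_max",
        )


def longest_contact_run(contact: np.ndarray) -> int:
    """Length of the longest run of True in a boolean series."""
    contact = np.asarray(contact, dtype=bool)
    if contact.size == 0:
        return 0
    padded = np.concatenate([[0], contact.astype(np.int8), [0]])
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max()) if starts.size else 0


def _contact_tensor(
    trajectory: Trajectory,
    frames: np.ndarray,
    residue_beads: list[np.ndarray],
    lipid_beads: list[np.ndarray],
    cutoff: float,
) -> np.ndarray:
    """Boolean (n_frames, n_residues, n_lipids) contact tensor."""
    res_idx = np.concatenate(residue_beads)
    res_ptr = np.cumsum([0] + [len(b) for b in residue_beads])
    lip_idx = np.concatenate(lipid_beads)
    lip_ptr = np.cumsum([0] + [len(b) for b in lipid_beads])
    out = np.zeros((len(frames), len(residue_beads), len(lipid_beads)), dtype=bool)
    cut2 = cutoff * cutoff
    for k, fi in enumerate(frames):
        d = min_image(
            trajectory.coords[fi, res_idx][:, None, :]
            - trajectory.coords[fi, lip_idx][None, :, :],
            trajectory.boxes[fi],
        )
        close = (d * d).sum(axis=-1) < cut2
        # reduce bead-level contacts to residue x molecule
        by_res = np.logical_or.reduceat(close, res_ptr[:-1], axis=0)
        out[k] = np.logical_or.reduceat(by_res, lip_ptr[:-1], axis=1)
    return out


def residue_occupancy(
    trajectory: Trajectory,
    topology: SystemTopology,
    regime_intervals: list[tuple[int, int]],
    lipid_kind: str,
    config: AnalysisConfig | None = None,
    receptor_id: int = 1,
    regime: str = "monomer",
) -> OccupancyProfile:
    """Maximum lipid occupancy per residue of one receptor, one regime.

    ``regime_intervals`` are inclusive frame ranges (e.g. the monomer or
    dimer intervals of a segmentation); occupancy is normalized by their
    total length. Runs are evaluated within each interval separately.
    """
    config = config or AnalysisConfig()
    if not regime_intervals:
        raise ValueError("regime intervals must be non-empty")
    res = topology.residue_table(receptor_id)
    lipids = topology.lipid_molecules(lipid_kind)
    regime_len = sum(e - s + 1 for s, e in regime_intervals)
    if not lipids:
        warnings.warn(f"no {lipid_kind} molecules in topology: occupancy is zero")
        values = pd.Series(0.0, index=res["residue_index"].to_numpy())
        values.index.name = "residue_index"
        return OccupancyProfile(
            values=values, regime=regime, lipid_kind=lipid_kind, receptor_id=receptor_id
        )
    residue_beads = res["bead_indices"].to_list()
    lipid_beads = [b for _, b in lipids]
    best = np.zeros((len(residue_beads), len(lipid_beads)), dtype=int)
    for s, e in regime_intervals:
        frames = np.arange(s, e + 1)
        contact = _contact_tensor(
            trajectory, frames, residue_beads, lipid_beads, config.lipid_contact_cutoff
        )
        # longest run per (residue, molecule) within this interval
        padded = np.zeros((contact.shape[0] + 2,) + contact.shape[1:], dtype=np.int8)
        padded[1:-1] = contact
        edges = np.diff(padded, axis=0)
        for r in range(contact.shape[1]):
            for m in range(contact.shape[2]):
                starts = np.flatnonzero(edges[:, r, m] == 1)
                if starts.size:
                    ends = np.flatnonzero(edges[:, r, m] == -1)
                    run = int((ends - starts).max())
                    if run > best[r, m]:
                        best[r, m] = run
    occupancy = best.max(axis=1) / regime_len
    values = pd.Series(occupancy, index=res["residue_index"].to_numpy())
    values.index.name = "residue_index"
    return OccupancyProfile(
        values=values, regime=regime, lipid_kind=lipid_kind, receptor_id=receptor_id
    )


def average_profiles(profiles: list[OccupancyProfile]) -> OccupancyProfile:
    """Average occupancy profiles (e.g. the two receptors, many runs)."""
    if not profiles:
        raise ValueError("need at least one profile")
    regimes = {p.regime for p in profiles}
    kinds = {p.lipid_kind for p in profiles}
    if len(regimes) > 1 or len(kinds) > 1:
        raise ValueError("cannot average profiles across regimes or lipid kinds")
    stacked = pd.concat([p.values for p in profiles], axis=1)
    values = stacked.mean(axis=1)
    values.index.name = "residue_index"
    return OccupancyProfile(
        values=values,
        regime=profiles[0].regime,
        lipid_kind=profiles[0].lipid_kind,
        receptor_id=None,
        normalization=profiles[0].normalization + f"+mean_of_{len(profiles)}",
    )


@dataclass
class ThicknessMap:
    """Normalized bilayer thickness on a body-frame planar grid."""

    grid: pd.DataFrame  # rows = x bin centres, cols = y bin centres; NaN = no data
    farfield_thickness: float  # nm, raw
    receptor_id: int
    n_samples: pd.DataFrame | None = None
    footprint_xy: np.ndarray | None = None  # body-frame receptor bead positions

    def farfield_cells_mean(
        self, min_distance: float, footprint_xy: np.ndarray | None = None
    ) -> float:
        """Mean over cells farther than ``min_distance`` from the footprint."""
        if footprint_xy is None:
            footprint_xy = self.footprint_xy
        if footprint_xy is None:
            raise ValueError("no receptor footprint available")
        xs = self.grid.index.to_numpy(dtype=float)
        ys = self.grid.columns.to_numpy(dtype=float)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        cells = np.stack([gx.ravel(), gy.ravel()], axis=1)
        d = np.sqrt(
            ((cells[:, None, :] - footprint_xy[None, :, :]) ** 2).sum(axis=-1)
        ).min(axis=1)
        vals = self.grid.to_numpy().ravel()
        far = (d > min_distance) & np.isfinite(vals)
        if not far.any():
            raise ValueError("no sampled far-field cells")
        return float(vals[far].mean())


def thickness_map(
    trajectory: Trajectory,
    topology: SystemTopology,
    regime_intervals: list[tuple[int, int]],
    config: AnalysisConfig | None = None,
    receptor_id: int = 1,
) -> ThicknessMap:
    """Receptor-centred normalized bilayer thickness over monomer frames."""
    config = config or AnalysisConfig()
    if not regime_intervals:
        raise ValueError("regime intervals must be non-empty")
    phos = topology.phosphate_indices()
    if phos.size == 0:
        raise TopologyError("no POPC phosphate beads in topology")
    subj = topology.receptor_beads(receptor_id, tm_only=True)
    helix_mask = (
        (topology.beads["molecule_kind"] == "receptor")
        & (topology.beads["receptor_id"] == receptor_id)
        & (topology.beads["helix_label"] == "I")
    )
    helix1 = np.flatnonzero(helix_mask.to_numpy())
    others = [r for r in topology.receptor_ids if r != receptor_id]
    other_beads = (
        np.concatenate([topology.receptor_beads(r) for r in others])
        if others
        else np.empty(0, dtype=int)
    )

    half = config.map_extent
    nbin = int(np.ceil(2 * half / config.grid_bin))
    edges = -half + config.grid_bin * np.arange(nbin + 1)
    sum_up = np.zeros((nbin, nbin))
    cnt_up = np.zeros((nbin, nbin), dtype=int)
    sum_lo = np.zeros((nbin, nbin))
    cnt_lo = np.zeros((nbin, nbin), dtype=int)
    far_up_sum = far_lo_sum = 0.0
    far_up_n = far_lo_n = 0
    footprint: np.ndarray | None = None

    for s, e in regime_intervals:
        for fi in range(s, e + 1):
            box = trajectory.boxes[fi]
            coords = trajectory.coords[fi]
            # periodicity-safe centroid: average displacements from one bead
            ref = coords[subj[0]]
            sub = ref + min_image(coords[subj] - ref, box)
            centroid = sub.mean(axis=0)
            axis = min_image(coords[helix1] - centroid, box).mean(axis=0)[:2]
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                continue
            c, sn = axis[0] / norm, axis[1] / norm
            rot = np.array([[c, sn], [-sn, c]])  # maps axis -> +x
            if footprint is None:
                footprint = min_image(sub - centroid, box)[:, :2] @ rot.T

            p = coords[phos]
            rel = min_image(p - centroid, box)
            z = p[:, 2]
            leaflet_up = z - np.median(z) > 0
            xy = rel[:, :2] @ rot.T

            # subject-distance (xy) of each phosphate to the receptor beads
            drel = min_image(p[:, None, :] - coords[subj][None, :, :], box)
            d_subj = np.sqrt((drel[:, :, :2] ** 2).sum(axis=-1)).min(axis=1)
            if other_beads.size:
                dother = min_image(p[:, None, :] - coords[other_beads][None, :, :], box)
                d_other = np.sqrt((dother[:, :, :2] ** 2).sum(axis=-1)).min(axis=1)
            else:
                d_other = np.full(len(p), np.inf)
            keep = d_other > config.farfield_min_distance
            far = keep & (d_subj > config.farfield_min_distance)

            far_up_sum += z[far & leaflet_up].sum()
            far_up_n += int((far & leaflet_up).sum())
            far_lo_sum += z[far & ~leaflet_up].sum()
            far_lo_n += int((far & ~leaflet_up).sum())

            inside = (
                keep
                & (xy[:, 0] >= edges[0])
                & (xy[:, 0] < edges[-1])
                & (xy[:, 1] >= edges[0])
                & (xy[:, 1] < edges[-1])
            )
            bx = np.floor((xy[inside, 0] - edges[0]) / config.grid_bin).astype(int)
            by = np.floor((xy[inside, 1] - edges[0]) / config.grid_bin).astype(int)
            up_in = leaflet_up[inside]
            zin = z[inside]
            np.add.at(sum_up, (bx[up_in], by[up_in]), zin[up_in])
            np.add.at(cnt_up, (bx[up_in], by[up_in]), 1)
            np.add.at(sum_lo, (bx[~up_in], by[~up_in]), zin[~up_in])
            np.add.at(cnt_lo, (bx[~up_in], by[~up_in]), 1)

    if far_up_n == 0 or far_lo_n == 0:
        raise ValueError(
            "one leaflet has no far-field phosphate samples; cannot normalize"
        )
    t_far = far_up_sum / far_up_n - far_lo_sum / far_lo_n
    if t_far <= 0:
        raise ValueError(f"non-positive far-field thickness {t_far:.3f} nm")

    with np.errstate(invalid="ignore", divide="ignore"):
        thickness = sum_up / cnt_up - sum_lo / cnt_lo
    thickness[(cnt_up == 0) | (cnt_lo == 0)] = np.nan
    centres = np.round(0.5 * (edges[:-1] + edges[1:]), 6)
    grid = pd.DataFrame(thickness / t_far, index=centres, columns=centres)
    grid.index.name = "x"
    grid.columns.name = "y"
    samples = pd.DataFrame(
        np.minimum(cnt_up, cnt_lo), index=centres, columns=centres
    )
    return ThicknessMap(
        grid=grid,
        farfield_thickness=float(t_far),
        receptor_id=receptor_id,
        n_samples=samples,
        footprint_xy=footprint,
    )
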