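"""Synthetic coarse-grain trajectories with fully known ground truth.

The generator is kinematic, not a physics engine: two rigid seven-helix
bead assemblies diffuse in the plane of a periodic bilayer patch, and
dimerization events, interface helices, relative rotational angles,
lipid residence hot-spots and bilayer-thickness deformations are
*planted* by construction. Every downstream analysis therefore has an
exact recovery target, which matters more here than physical realism.

Receptor model
    Seven helix clusters (four backbone beads each, one sidechain bead)
    on a ring, one outward-facing angular sector per helix; two
    intracellular-loop beads inside the ring. Residue numbering follows
    the UniProt P08908 transmembrane assignments so that residue 48 sits
    on helix I and residues 164/167 on helix IV, the anchors of the
    rotational-angle definition. The 164-167 backbone axis is vertical
    by construction, which makes the relation between receptor pose and
    the planted dihedral angles closed-form and lets scenarios request
    explicit (theta1, theta2) values.

Bilayer model
    POPC molecules are three vertically stacked beads (phosphate,
    glycerol, tail), cholesterol two beads, each assigned permanently to
    one leaflet. Phosphate z follows a radial deformation field around
    each receptor: inside a helix's angular sector the leaflet offset is
    scaled by that helix's planted thickness multiplier, decaying to the
    flat value well inside the far-field distance.

Events
    Outside planted dimer intervals the receptors random-walk with a
    minimum-separation floor that keeps the bead-bead minimum distance
    above the monomer threshold, apart from planted sub-dimer grazing
    approaches (excursions to 0.65-0.85 nm shorter than the dimer dwell
    minimum). Inside an interval the receptors are placed so that the
    planted helix pair — and only that pair — is in contact below the
    dimer cutoff at the planted rotational angles; transient intervals
    end with an immediate separation beyond the dissociation threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig, HELIX_LABELS
from .geometry import min_image
from .topology import BEAD_COLUMNS, SystemTopology
from .trajectory import Trajectory

__all__ = [
    "GenerationError",
    "ReceptorTemplate",
    "DimerInterval",
    "LipidHotspot",
    "PlantedScenario",
    "build_receptor_template",
    "generate_trajectory",
    "reference_scenarios",
]

BILAYER_HALF_THICKNESS = 2.0  # nm; flat leaflet |z - centre| of the phosphates
FIELD_PLATEAU = 2.0  # nm; deformation fully applied within this radius
FIELD_DECAY_END = 2.8  # nm; deformation zero beyond (inside the far field)
SECTOR_HALF_WIDTH = 180.0 / 7.0  # degrees per helix sector
POPC_DEPTHS = {"PO4": 1.0, "GL1": 0.55, "C2A": 0.15}  # fraction of leaflet offset
CHOL_DEPTHS = {"ROH": 0.8, "R1": 0.35}
HOTSPOT_PIN_OFFSET = 0.25  # nm, planted lipid-to-residue contact distance
HOTSPOT_KEEPOUT = 1.2  # nm, planted out-of-run lipid-to-residue distance

# helix residue quartets (P08908 numbering); second residue carries a sidechain
HELIX_RESIDUES = {
    "I": (46, 48, 50, 52),
    "II": (85, 87, 89, 91),
    "III": (115, 117, 119, 121),
    "IV": (161, 164, 167, 170),
    "V": (200, 202, 204, 206),
    "VI": (352, 354, 356, 358),
    "VII": (385, 387, 389, 391),
}
HELIX_DEFINITIONS = {
    "I": (37, 62),
    "II": (74, 98),
    "III": (110, 132),
    "IV": (153, 175),
    "V": (192, 217),
    "VI": (346, 371),
    "VII": (379, 403),
}
LOOP_RESIDUES = (250, 252)  # third intracellular loop
RESIDUE_Z = (-0.45, -0.15, 0.15, 0.45)  # backbone stack within a helix rod


class GenerationError(ValueError):
    pass


def _wrap_angle(a):
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def _azimuth(v) -> float:
    return float(np.degrees(np.arctan2(v[1], v[0])))


@dataclass
class ReceptorTemplate:
    """Rigid bead assembly of one receptor in its body frame."""

    positions: np.ndarray  # (n_beads, 3), centred on the ring axis
    records: pd.DataFrame  # residue_index, helix_label, bead_role per bead
    helix_angles: dict[str, float]  # outward sector centre per helix, degrees
    helix_xy: dict[str, np.ndarray]  # body-frame xy of each helix rod
    radial_extent: float  # nm, max planar bead radius

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def bead_index(self, residue: int, role: str = "backbone") -> int:
        df = self.records
        idx = np.flatnonzero(
            ((df["residue_index"] == residue) & (df["bead_role"] == role)).to_numpy()
        )
        if idx.size != 1:
            raise GenerationError(f"template lacks a unique {role} bead for {residue}")
        return int(idx[0])

    @property
    def hinge_azimuth(self) -> float:
        """Template azimuth of the residue-48 -> residue-164 planar leg."""
        return _azimuth(self.helix_xy["IV"] - self.helix_xy["I"])


def build_receptor_template(seed: int = 0, ring_radius: float = 1.4) -> ReceptorTemplate:
    """Seven helix rods on a ring with per-helix seeded placement jitter."""
    rng = np.random.default_rng(seed)
    positions = []
    records = []
    helix_angles = {}
    helix_xy = {}
    for k, helix in enumerate(HELIX_LABELS):
        alpha = k * 360.0 / 7.0
        helix_angles[helix] = alpha
        jitter = rng.uniform(-0.03, 0.03, size=2)
        centre = ring_radius * np.array(
            [np.cos(np.radians(alpha)), np.sin(np.radians(alpha))]
        ) + jitter
        helix_xy[helix] = centre
        outward = centre / np.linalg.norm(centre)
        tangent = np.array([-outward[1], outward[0]])
        for ri, (residue, z) in enumerate(zip(HELIX_RESIDUES[helix], RESIDUE_Z)):
            positions.append([centre[0], centre[1], z])
            records.append(
                {"residue_index": residue, "helix_label": helix, "bead_role": "backbone"}
            )
            if ri == 1:  # sidechain bead on the outward face
                sc = centre + 0.18 * outward
                positions.append([sc[0], sc[1], z])
                records.append(
                    {
                        "residue_index": residue,
                        "helix_label": helix,
                        "bead_role": "sidechain",
                    }
                )
            elif ri in (0, 2):  # tangential sidechains widen the contact face
                sign = -1.0 if ri == 0 else 1.0
                sc = centre + 0.10 * outward + sign * 0.22 * tangent
                positions.append([sc[0], sc[1], z])
                records.append(
                    {
                        "residue_index": residue,
                        "helix_label": helix,
                        "bead_role": "sidechain",
                    }
                )
    for residue in LOOP_RESIDUES:
        ang = rng.uniform(0, 360)
        positions.append(
            [0.5 * np.cos(np.radians(ang)), 0.5 * np.sin(np.radians(ang)), -0.6]
        )
        records.append(
            {"residue_index": residue, "helix_label": "loop", "bead_role": "backbone"}
        )
    pos = np.asarray(positions)
    return ReceptorTemplate(
        positions=pos,
        records=pd.DataFrame(records),
        helix_angles=helix_angles,
        helix_xy=helix_xy,
        radial_extent=float(np.sqrt((pos[:, :2] ** 2).sum(axis=1)).max()),
    )


# -- scenario description ----------------------------------------------


@dataclass
class DimerInterval:
    start: int
    end: int  # inclusive frame index
    helix_pair: tuple[str, str]  # (receptor-1 helix, receptor-2 helix)
    theta1: float | None = None  # requested angle; None = whatever facing gives
    theta2: float | None = None
    stable: bool = False


@dataclass
class LipidHotspot:
    receptor_id: int
    residue_index: int
    lipid_kind: str  # "CHOL" | "POPC"
    target_occupancy: float
    regime: str = "monomer"  # regime whose length normalizes the occupancy


@dataclass
class PlantedScenario:
    name: str = "scenario"
    n_frames: int = 1000
    dt: float = 1.0  # ns between stored frames
    box: tuple[float, float, float] = (14.0, 14.0, 9.0)
    cholesterol_fraction: float = 0.0  # mole % of lipids
    dimer_intervals: list[DimerInterval] = field(default_factory=list)
    lipid_hotspots: list[LipidHotspot] = field(default_factory=list)
    thickness_field: dict[tuple[int, str], float] = field(default_factory=dict)
    diffusion_coefficient: float = 0.04  # nm^2/ns, receptor in-plane walk
    lipid_diffusion_coefficient: float = 0.045  # nm^2/ns
    n_popc: int = 64
    grazing_frames: list[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_frames < 2:
            raise GenerationError("scenario needs at least two frames")
        if self.dt <= 0:
            raise GenerationError("dt must be positive")
        if not 0.0 <= self.cholesterol_fraction < 100.0:
            raise GenerationError("cholesterol_fraction must lie in [0, 100)")
        prev_end = -1
        for k, iv in enumerate(self.dimer_intervals):
            if iv.start <= prev_end:
                raise GenerationError("dimer intervals must be ordered, non-overlapping")
            if iv.end < iv.start or iv.end >= self.n_frames:
                raise GenerationError(f"interval {k} has invalid bounds")
            if iv.start - prev_end < 12 and prev_end >= 0:
                raise GenerationError(
                    f"interval {k} starts before the previous dissociation completes"
                )
            for h in iv.helix_pair:
                if h not in HELIX_LABELS:
                    raise GenerationError(f"unknown helix {h} in interval {k}")
            if iv.stable and iv.end != self.n_frames - 1:
                raise GenerationError("a stable interval must extend to the last frame")
            if iv.stable and k != len(self.dimer_intervals) - 1:
                raise GenerationError("a stable interval must be the last interval")
            prev_end = iv.end
        for hs in self.lipid_hotspots:
            if not 0.0 <= hs.target_occupancy <= 1.0:
                raise GenerationError("target occupancy must lie in [0, 1]")
            if hs.lipid_kind not in ("CHOL", "POPC"):
                raise GenerationError(f"unknown lipid kind {hs.lipid_kind}")
            if hs.regime not in ("monomer", "dimer"):
                raise GenerationError(f"unknown hotspot regime {hs.regime}")
        for (rid, helix), mult in self.thickness_field.items():
            if helix not in HELIX_LABELS or rid not in (1, 2):
                raise GenerationError(f"bad thickness field key ({rid}, {helix})")
            if mult <= 0:
                raise GenerationError("thickness multipliers must be positive")
        for g in self.grazing_frames:
            for iv in self.dimer_intervals:
                if iv.start - 4 <= g <= iv.end + 12:
                    raise GenerationError(
                        f"grazing frame {g} collides with a dimer interval"
                    )
            if not 0 <= g < self.n_frames:
                raise GenerationError(f"grazing frame {g} out of range")

    @property
    def n_chol(self) -> int:
        f = self.cholesterol_fraction / 100.0
        return int(round(self.n_popc * f / (1.0 - f))) if f > 0 else 0

    # scenario <-> YAML, for the CLI
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dimer_intervals"] = [dataclasses.asdict(iv) for iv in self.dimer_intervals]
        d["lipid_hotspots"] = [dataclasses.asdict(h) for h in self.lipid_hotspots]
        d["thickness_field"] = [
            [rid, helix, mult] for (rid, helix), mult in self.thickness_field.items()
        ]
        d["box"] = list(self.box)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedScenario":
        d = dict(d)
        d["box"] = tuple(d.get("box", (14.0, 14.0, 9.0)))
        d["dimer_intervals"] = [
            DimerInterval(**{**iv, "helix_pair": tuple(iv["helix_pair"])})
            for iv in d.get("dimer_intervals", [])
        ]
        d["lipid_hotspots"] = [LipidHotspot(**h) for h in d.get("lipid_hotspots", [])]
        d["thickness_field"] = {
            (int(rid), helix): float(mult)
            for rid, helix, mult in d.get("thickness_field", [])
        }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlantedScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# -- topology assembly -------------------------------------------------


def _build_topology(scenario: PlantedScenario, tpl: ReceptorTemplate) -> SystemTopology:
    rows = []
    bead_id = 0
    mol_id = 0
    for rid in (1, 2):
        mol_id += 1
        for _, rec in tpl.records.iterrows():
            rows.append(
                {
                    "bead_id": bead_id,
                    "molecule_id": mol_id,
                    "molecule_kind": "receptor",
                    "receptor_id": rid,
                    "residue_index": int(rec["residue_index"]),
                    "bead_role": rec["bead_role"],
                    "helix_label": rec["helix_label"],
                }
            )
            bead_id += 1
    for _ in range(scenario.n_popc):
        mol_id += 1
        for name, role in (("PO4", "phosphate"), ("GL1", "other"), ("C2A", "other")):
            rows.append(
                {
                    "bead_id": bead_id,
                    "molecule_id": mol_id,
                    "molecule_kind": "POPC",
                    "receptor_id": None,
                    "residue_index": None,
                    "bead_role": role,
                    "helix_label": None,
                }
            )
            bead_id += 1
    for _ in range(scenario.n_chol):
        mol_id += 1
        for name in ("ROH", "R1"):
            rows.append(
                {
                    "bead_id": bead_id,
                    "molecule_id": mol_id,
                    "molecule_kind": "CHOL",
                    "receptor_id": None,
                    "residue_index": None,
                    "bead_role": "other",
                    "helix_label": None,
                }
            )
            bead_id += 1
    beads = pd.DataFrame(rows, columns=BEAD_COLUMNS)
    return SystemTopology(beads=beads, helix_definitions=dict(HELIX_DEFINITIONS))


def gro_skeleton(topology: SystemTopology) -> pd.DataFrame:
    """Residue/atom naming for GRO output of a generated system."""
    names = {"backbone": "BB", "sidechain": "SC1", "phosphate": "PO4"}
    rows = []
    other_counter: dict[int, int] = {}
    for _, row in topology.beads.iterrows():
        kind = row["molecule_kind"]
        if kind == "receptor":
            resname = f"REC{int(row['receptor_id'])}"
            atom = names[row["bead_role"]]
        else:
            resname = kind
            if row["bead_role"] == "phosphate":
                atom = "PO4"
            else:
                c = other_counter.get(int(row["molecule_id"]), 0) + 1
                other_counter[int(row["molecule_id"])] = c
                atom = f"L{c}"
        rows.append(
            {"resid": int(row["molecule_id"]), "resname": resname, "atomname": atom}
        )
    return pd.DataFrame(rows)


# -- receptor pose solving ---------------------------------------------


def _rot2(phi_deg: float) -> np.ndarray:
    t = np.radians(phi_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


def _world_beads(
    tpl: ReceptorTemplate, centre_xy: np.ndarray, phi: float
) -> np.ndarray:
    xy = tpl.positions[:, :2] @ _rot2(phi).T + centre_xy
    return np.column_stack([xy, tpl.positions[:, 2]])


def _pair_min_distances(
    tpl: ReceptorTemplate, b1: np.ndarray, b2: np.ndarray
) -> dict[tuple[str, str], float]:
    """Min bead distance per (helix_R1, helix_R2) pair (no PBC; local poses)."""
    labels = tpl.records["helix_label"].to_numpy()
    out = {}
    d = np.sqrt(((b1[:, None, :] - b2[None, :, :]) ** 2).sum(axis=-1))
    for ha in HELIX_LABELS:
        ia = labels == ha
        for hb in HELIX_LABELS:
            ib = labels == hb
            out[(ha, hb)] = float(d[np.ix_(ia, ib)].min())
    return out


def _min_bead_distance(
    tpl: ReceptorTemplate,
    centre: np.ndarray,
    u: np.ndarray,
    sep: float,
    phi1: float,
    phi2: float,
    pair: tuple[str, str] | None = None,
) -> float:
    """Minimum inter-receptor bead distance, optionally for one helix pair."""
    b1 = _world_beads(tpl, centre - 0.5 * sep * u, phi1)
    b2 = _world_beads(tpl, centre + 0.5 * sep * u, phi2)
    if pair is not None:
        labels = tpl.records["helix_label"].to_numpy()
        b1 = b1[labels == pair[0]]
        b2 = b2[labels == pair[1]]
    d = np.sqrt(((b1[:, None, :] - b2[None, :, :]) ** 2).sum(axis=-1))
    return float(d.min())


def _solve_separation(
    tpl: ReceptorTemplate,
    centre: np.ndarray,
    u: np.ndarray,
    phi1: float,
    phi2: float,
    target: float,
    pair: tuple[str, str] | None = None,
) -> float:
    lo, hi = 0.5, 10.0
    for _ in range(70):
        mid = 0.5 * (lo + hi)
        if _min_bead_distance(tpl, centre, u, mid, phi1, phi2, pair) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _planar_theta(
    tpl: ReceptorTemplate,
    c1: np.ndarray,
    phi1: float,
    c2: np.ndarray,
    phi2: float,
) -> tuple[float, float]:
    """Closed-form (theta1, theta2) for vertical 164-167 hinges.

    With the helix-IV backbone axis parallel to z, the four-point
    dihedral reduces to planar azimuths: theta = az(leg to the partner's
    167 bead) - az(subject's 48->164 leg) - 180, wrapped to (-180, 180].
    """
    a = tpl.hinge_azimuth
    q1 = tpl.helix_xy["IV"] @ _rot2(phi1).T + c1
    q2 = tpl.helix_xy["IV"] @ _rot2(phi2).T + c2
    b3 = q2 - q1
    th1 = _wrap_angle(_azimuth(b3) - (a + phi1) - 180.0)
    th2 = _wrap_angle(_azimuth(-b3) - (a + phi2) - 180.0)
    return float(th1), float(th2)


def _solve_pose(
    tpl: ReceptorTemplate,
    centre: np.ndarray,
    u: np.ndarray,
    interval: DimerInterval,
    contact_target: float,
    config: AnalysisConfig,
) -> tuple[np.ndarray, float, np.ndarray, float, float, float]:
    """Place both receptors so the planted pair alone is in contact.

    Returns (centre1, phi1, centre2, phi2, theta1, theta2).
    """
    ha, hb = interval.helix_pair
    az_u = _azimuth(u)
    a = tpl.hinge_azimuth
    labels = tpl.records["helix_label"].to_numpy()
    beads_a = tpl.positions[labels == ha]
    beads_b = tpl.positions[labels == hb]

    if (interval.theta1 is None) != (interval.theta2 is None):
        raise GenerationError(
            "planted angles must be given for both receptors or neither"
        )
    if interval.theta1 is None:
        # facing placement: each planted helix points straight at the other
        phi1 = az_u - tpl.helix_angles[ha]
        phi2 = _wrap_angle(az_u + 180.0) - tpl.helix_angles[hb]
        sep = _solve_separation(
            tpl, centre, u, phi1, phi2, contact_target, pair=interval.helix_pair
        )
        c1 = centre - 0.5 * sep * u
        c2 = centre + 0.5 * sep * u
    else:
        # gauge phi1 = 0: the requested angles fix the azimuth of the
        # 167 -> 167' leg (beta) and receptor 2's rotation outright;
        # the one remaining unknown is the slide distance L along beta
        beta = a + 180.0 + interval.theta1
        phi2g = beta - a - interval.theta2
        e_beta = np.array([np.cos(np.radians(beta)), np.sin(np.radians(beta))])
        q1 = tpl.helix_xy["IV"]
        rot2g = _rot2(phi2g)
        wa = np.column_stack([beads_a[:, :2], beads_a[:, 2]])
        wb_body = np.column_stack([beads_b[:, :2] @ rot2g.T, beads_b[:, 2]])

        def pair_dist(L: float) -> float:
            c2g = q1 + L * e_beta - rot2g @ tpl.helix_xy["IV"]
            wb = wb_body + np.array([c2g[0], c2g[1], 0.0])
            d = wa[:, None, :] - wb[None, :, :]
            return float(np.sqrt((d * d).sum(axis=-1)).min())

        grid = np.arange(0.0, 8.0, 0.02)
        vals = np.array([pair_dist(L) for L in grid])
        k = int(np.argmin(vals))
        if vals[k] > contact_target:
            raise GenerationError(
                f"helix pair {interval.helix_pair} cannot reach "
                f"{contact_target} nm at theta=({interval.theta1}, "
                f"{interval.theta2}); closest approach {vals[k]:.3f} nm"
            )
        lo, hi = grid[k], 8.0
        for _ in range(70):
            mid = 0.5 * (lo + hi)
            if pair_dist(mid) < contact_target:
                lo = mid
            else:
                hi = mid
        L = 0.5 * (lo + hi)
        c1g = np.zeros(2)
        c2g = q1 + L * e_beta - rot2g @ tpl.helix_xy["IV"]
        # rotate the gauge solution so the receptors meet along u, and
        # centre it on the requested midpoint
        eta = az_u - _azimuth(c2g - c1g)
        rot_eta = _rot2(eta)
        midg = 0.5 * (c1g + c2g)
        c1 = centre + rot_eta @ (c1g - midg)
        c2 = centre + rot_eta @ (c2g - midg)
        phi1 = eta
        phi2 = phi2g + eta
    b1 = _world_beads(tpl, c1, phi1)
    b2 = _world_beads(tpl, c2, phi2)
    dists = _pair_min_distances(tpl, b1, b2)
    planted = dists[(ha, hb)]
    if planted >= config.dimer_cutoff:
        raise GenerationError(
            f"planted pair {interval.helix_pair} not in contact "
            f"({planted:.3f} nm) at theta=({interval.theta1}, {interval.theta2})"
        )
    others = {k: v for k, v in dists.items() if k != (ha, hb)}
    closest_other = min(others.values())
    if closest_other < config.contact_cutoff + 0.03:
        bad = min(others, key=others.get)
        raise GenerationError(
            f"geometrically unsatisfiable interval: helix pair {bad} "
            f"({closest_other:.3f} nm) would also satisfy the contact cut-off "
            f"alongside {interval.helix_pair}"
        )
    th1, th2 = _planar_theta(tpl, c1, phi1, c2, phi2)
    if interval.theta1 is not None and abs(_wrap_angle(th1 - interval.theta1)) > 1e-6:
        raise GenerationError("theta1 placement did not converge")
    if interval.theta2 is not None and abs(_wrap_angle(th2 - interval.theta2)) > 1e-6:
        raise GenerationError("theta2 placement did not converge")
    return c1, _wrap_angle(phi1), c2, _wrap_angle(phi2), th1, th2


# -- receptor driving --------------------------------------------------


def _drive_receptors(
    scenario: PlantedScenario,
    tpl: ReceptorTemplate,
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Frame-by-frame receptor centres (xy) and z-rotations.

    Returns ``centres`` with shape (n_frames, 2, 2), ``phis`` with shape
    (n_frames, 2) and the planted-interval ground-truth records
    (realized angles included).
    """
    n = scenario.n_frames
    box_xy = np.asarray(scenario.box[:2])
    sigma = np.sqrt(2.0 * scenario.diffusion_coefficient * scenario.dt)
    sigma_phi = 4.0  # degrees per frame during free diffusion
    d_floor = 2.0 * tpl.radial_extent + 1.1  # keeps min bead distance > 1 nm
    contact_target = 0.45  # nm planted interface distance, below the cut-off

    centres = np.zeros((n, 2, 2))
    phis = np.zeros((n, 2))
    x1 = np.array([box_xy[0] * 0.3, box_xy[1] * 0.5])
    x2 = np.array([box_xy[0] * 0.7, box_xy[1] * 0.5])
    p1 = float(rng.uniform(-180, 180))
    p2 = float(rng.uniform(-180, 180))

    # schedule: frame -> (mode, payload)
    interval_at = {}
    exit_at = {}
    truth: list[dict] = []
    for iv in scenario.dimer_intervals:
        for f in range(iv.start, iv.end + 1):
            interval_at[f] = iv
        if not iv.stable:
            for k in range(1, 9):
                if iv.end + k < n:
                    exit_at[iv.end + k] = k
    graze_at = {}
    for g in sorted(scenario.grazing_frames):
        duration = int(rng.integers(1, 3))
        target = float(rng.uniform(0.65, 0.85))
        for k in range(duration):
            if g + k < n and (g + k) not in interval_at:
                graze_at[g + k] = target

    pose: dict | None = None
    for f in range(n):
        iv = interval_at.get(f)
        if iv is not None:
            if pose is None or pose["interval"] is not iv:
                mid = x1 + 0.5 * min_image(x2 - x1, box_xy)
                u = min_image(x2 - x1, box_xy)
                nu = np.linalg.norm(u)
                u = u / nu if nu > 1e-9 else np.array([1.0, 0.0])
                c1, f1, c2, f2, th1, th2 = _solve_pose(
                    tpl, mid, u, iv, contact_target, config
                )
                pose = {
                    "interval": iv,
                    "c1": c1,
                    "c2": c2,
                    "phi1": f1,
                    "phi2": f2,
                    "u": u,
                    "mid": mid,
                }
                duration_ns = (iv.end - iv.start + 1) * scenario.dt
                if not iv.stable and duration_ns < config.min_transient_duration:
                    raise GenerationError(
                        f"transient interval at frame {iv.start} lasts "
                        f"{duration_ns:g} ns < min_transient_duration "
                        f"({config.min_transient_duration:g} ns)"
                    )
                truth.append(
                    {
                        "start": iv.start,
                        "end": iv.end,
                        "helix_pair": list(iv.helix_pair),
                        "stable": iv.stable,
                        "theta1": th1,
                        "theta2": th2,
                    }
                )
            x1, x2 = pose["c1"].copy(), pose["c2"].copy()
            p1, p2 = pose["phi1"], pose["phi2"]
        elif f in exit_at:
            k = exit_at[f]
            assert pose is not None
            mid, u = pose["mid"], pose["u"]
            if k == 1:  # immediate dissociation beyond the 1.5 nm criterion
                sep = _solve_separation(tpl, mid, u, p1, p2, 1.62)
            else:
                sep = np.linalg.norm(min_image(x2 - x1, box_xy)) + 0.45
            x1 = mid - 0.5 * sep * u
            x2 = mid + 0.5 * sep * u
        elif f in graze_at:
            u = min_image(x2 - x1, box_xy)
            nu = np.linalg.norm(u)
            u = u / nu if nu > 1e-9 else np.array([1.0, 0.0])
            mid = x1 + 0.5 * min_image(x2 - x1, box_xy)
            sep = _solve_separation(tpl, mid, u, p1, p2, graze_at[f])
            x1 = mid - 0.5 * sep * u
            x2 = mid + 0.5 * sep * u
        else:
            if f > 0:
                x1 = x1 + rng.normal(0.0, sigma, size=2)
                x2 = x2 + rng.normal(0.0, sigma, size=2)
                p1 = _wrap_angle(p1 + rng.normal(0.0, sigma_phi))
                p2 = _wrap_angle(p2 + rng.normal(0.0, sigma_phi))
                d = min_image(x2 - x1, box_xy)
                nd = np.linalg.norm(d)
                if nd < d_floor:  # reflect off the separation floor
                    u = d / nd if nd > 1e-9 else np.array([1.0, 0.0])
                    x2 = x1 + d + (d_floor - nd + 0.05) * u
        centres[f, 0] = x1
        centres[f, 1] = x2
        phis[f, 0] = p1
        phis[f, 1] = p2
    return centres, phis, truth


# -- lipid placement ---------------------------------------------------


def _field_multiplier(
    xy: np.ndarray,
    centres: np.ndarray,
    phis: np.ndarray,
    tpl: ReceptorTemplate,
    thickness_field: dict[tuple[int, str], float],
    box_xy: np.ndarray,
) -> np.ndarray:
    """Local thickness multiplier at planar points, all frames at once.

    ``xy`` has shape (n_frames, n_points, 2). Contributions from the two
    receptors are combined by the largest absolute deviation from 1, so
    overlapping identical fields do not stack.
    """
    n_f, n_p = xy.shape[:2]
    dev = np.zeros((n_f, n_p))
    for rid in (1, 2):
        entries = [
            (helix, mult)
            for (r, helix), mult in thickness_field.items()
            if r == rid and mult != 1.0
        ]
        if not entries:
            continue
        rel = min_image(xy - centres[:, rid - 1][:, None, :], box_xy)
        rr = np.sqrt((rel**2).sum(axis=-1))
        ang = np.degrees(np.arctan2(rel[..., 1], rel[..., 0])) - phis[:, rid - 1][:, None]
        g = np.clip((FIELD_DECAY_END - rr) / (FIELD_DECAY_END - FIELD_PLATEAU), 0.0, 1.0)
        for helix, mult in entries:
            in_sector = (
                np.abs(_wrap_angle(ang - tpl.helix_angles[helix])) <= SECTOR_HALF_WIDTH
            )
            contrib = (mult - 1.0) * g * in_sector
            take = np.abs(contrib) > np.abs(dev)
            dev = np.where(take, contrib, dev)
    return 1.0 + dev


def _monomer_intervals(scenario: PlantedScenario) -> list[tuple[int, int]]:
    out = []
    prev = 0
    for iv in scenario.dimer_intervals:
        if iv.start > prev:
            out.append((prev, iv.start - 1))
        prev = iv.end + 1
    if prev < scenario.n_frames:
        out.append((prev, scenario.n_frames - 1))
    return out


def _plan_hotspots(
    scenario: PlantedScenario, rng: np.random.Generator
) -> list[dict]:
    """Assign a dedicated lipid molecule and a contact run to each hotspot."""
    monomer = _monomer_intervals(scenario)
    dimer = [(iv.start, iv.end) for iv in scenario.dimer_intervals]
    counts = {"POPC": scenario.n_popc, "CHOL": scenario.n_chol}
    used: dict[str, int] = {"POPC": 0, "CHOL": 0}
    plans = []
    for hs in scenario.lipid_hotspots:
        if used[hs.lipid_kind] >= counts[hs.lipid_kind]:
            raise GenerationError(
                f"not enough {hs.lipid_kind} molecules for all hotspots"
            )
        mol_index = used[hs.lipid_kind]  # index within molecules of that kind
        used[hs.lipid_kind] += 1
        intervals = monomer if hs.regime == "monomer" else dimer
        if not intervals:
            raise GenerationError(f"no {hs.regime} frames for hotspot {hs}")
        regime_len = sum(e - s + 1 for s, e in intervals)
        k = int(round(hs.target_occupancy * regime_len))
        host = max(intervals, key=lambda se: se[1] - se[0])
        host_len = host[1] - host[0] + 1
        if k > host_len:
            raise GenerationError(
                f"hotspot target {hs.target_occupancy} needs a {k}-frame run but "
                f"the longest {hs.regime} interval has {host_len} frames"
            )
        slack = host_len - k
        offset = int(rng.integers(0, slack + 1)) if slack > 0 else 0
        run = (host[0] + offset, host[0] + offset + k - 1) if k > 0 else None
        plans.append(
            {
                "hotspot": hs,
                "mol_index": mol_index,
                "run": run,
                "run_frames": k,
                "regime_len": regime_len,
                "occupancy": k / regime_len,
            }
        )
    return plans


# -- trajectory assembly -----------------------------------------------


def generate_trajectory(
    scenario: PlantedScenario, config: AnalysisConfig | None = None
) -> tuple[Trajectory, SystemTopology, dict]:
    """Generate a trajectory realizing a planted scenario.

    Returns the trajectory, its topology and a JSON-serializable ground
    truth record (planted intervals with realized angles, hotspot runs
    and occupancies, thickness multipliers, grazing frames).
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(scenario.seed)
    tpl = build_receptor_template(scenario.seed)
    topology = _build_topology(scenario, tpl)
    n = scenario.n_frames
    box = np.asarray(scenario.box, dtype=float)
    box_xy = box[:2]
    zc = box[2] / 2.0

    centres, phis, interval_truth = _drive_receptors(scenario, tpl, config, rng)
    plans = _plan_hotspots(scenario, rng)

    # receptor bead coordinates, all frames at once
    t = np.radians(phis)  # (n, 2)
    cos, sin = np.cos(t), np.sin(t)
    tx, ty, tz = tpl.positions[:, 0], tpl.positions[:, 1], tpl.positions[:, 2]
    rec_coords = []
    for r in range(2):
        x = cos[:, r, None] * tx - sin[:, r, None] * ty + centres[:, r, 0][:, None]
        y = sin[:, r, None] * tx + cos[:, r, None] * ty + centres[:, r, 1][:, None]
        z = zc + np.broadcast_to(tz, (n, tpl.n_beads))
        rec_coords.append(np.stack([x, y, z], axis=-1))

    # lipid molecules: id order is POPC block then CHOL block
    n_popc, n_chol = scenario.n_popc, scenario.n_chol
    n_lip = n_popc + n_chol
    leaflet = np.ones(n_lip)  # +1 upper, -1 lower; alternate within each kind
    leaflet[np.flatnonzero(np.arange(n_popc) % 2 == 1)] = -1.0
    leaflet[n_popc + np.flatnonzero(np.arange(n_chol) % 2 == 1)] = -1.0

    # hotspot molecules live in the leaflet nearest their target residue
    res_bead_of: list[tuple[int, int]] = []  # (receptor index, template bead)
    for plan in plans:
        hs = plan["hotspot"]
        bead = tpl.bead_index(hs.residue_index)
        mol = plan["mol_index"] + (n_popc if hs.lipid_kind == "CHOL" else 0)
        plan["mol"] = mol
        plan["tpl_bead"] = bead
        leaflet[mol] = 1.0 if tpl.positions[bead, 2] > 0 else -1.0
        res_bead_of.append((hs.receptor_id - 1, bead))

    sigma_lip = np.sqrt(2.0 * scenario.lipid_diffusion_coefficient * scenario.dt)
    start_xy = rng.uniform(0.0, 1.0, size=(n_lip, 2)) * box_xy
    steps = rng.normal(0.0, sigma_lip, size=(n, n_lip, 2))
    steps[0] = 0.0
    lip_xy = start_xy[None, :, :] + np.cumsum(steps, axis=0)

    # keep hotspot lipids clear of their residue outside the planted run
    for plan in plans:
        hs = plan["hotspot"]
        mol = plan["mol"]
        r_idx, bead = hs.receptor_id - 1, plan["tpl_bead"]
        res_xy = rec_coords[r_idx][:, bead, :2]
        rel = min_image(lip_xy[:, mol] - res_xy, box_xy)
        dist = np.sqrt((rel**2).sum(axis=1))
        run = plan["run"]
        outside = np.ones(n, dtype=bool)
        if run is not None:
            outside[run[0] : run[1] + 1] = False
        fix = outside & (dist < HOTSPOT_KEEPOUT)
        if fix.any():
            u = rel[fix]
            nu = np.linalg.norm(u, axis=1, keepdims=True)
            u = np.where(nu > 1e-9, u / np.maximum(nu, 1e-9), [[1.0, 0.0]])
            lip_xy[fix, mol] = res_xy[fix] + HOTSPOT_KEEPOUT * u

    # phosphate-level thickness multiplier per molecule, then bead z values
    mult = _field_multiplier(
        lip_xy, centres, phis, tpl, scenario.thickness_field, box_xy
    )
    offset = BILAYER_HALF_THICKNESS * mult * leaflet[None, :]  # (n, n_lip)
    depth_sets = [POPC_DEPTHS] * n_popc + [CHOL_DEPTHS] * n_chol
    lip_coords = np.empty((n, sum(len(d) for d in depth_sets), 3))
    b = 0
    for m, depths in enumerate(depth_sets):
        for frac in depths.values():
            lip_coords[:, b, 0] = lip_xy[:, m, 0]
            lip_coords[:, b, 1] = lip_xy[:, m, 1]
            lip_coords[:, b, 2] = zc + frac * offset[:, m]
            b += 1
    mol_bead_start = np.cumsum([0] + [len(d) for d in depth_sets])

    # pin hotspot molecules to their residue during the planted run
    for plan in plans:
        run = plan["run"]
        if run is None:
            continue
        hs = plan["hotspot"]
        mol = plan["mol"]
        r_idx, bead = hs.receptor_id - 1, plan["tpl_bead"]
        fsl = slice(run[0], run[1] + 1)
        res_pos = rec_coords[r_idx][fsl, bead]  # (k, 3)
        centre_xy = centres[fsl, r_idx]
        u = min_image(res_pos[:, :2] - centre_xy, box_xy)
        nu = np.linalg.norm(u, axis=1, keepdims=True)
        u = np.where(nu > 1e-9, u / np.maximum(nu, 1e-9), [[1.0, 0.0]])
        contact_xy = res_pos[:, :2] + HOTSPOT_PIN_OFFSET * u
        beads = range(mol_bead_start[mol], mol_bead_start[mol + 1])
        depths = list(depth_sets[mol].values())
        deepest = int(np.argmin(depths))
        for j, gb in enumerate(beads):
            lip_coords[fsl, gb, 0] = contact_xy[:, 0]
            lip_coords[fsl, gb, 1] = contact_xy[:, 1]
            if j == deepest:
                lip_coords[fsl, gb, 2] = res_pos[:, 2]
            else:
                lip_coords[fsl, gb, 2] = zc + depths[j] * offset[fsl, mol]

    coords = np.concatenate([rec_coords[0], rec_coords[1], lip_coords], axis=1)
    coords = coords - box[None, None, :] * np.floor(coords / box[None, None, :])
    times = np.arange(n) * scenario.dt
    traj = Trajectory(
        times=times,
        boxes=np.broadcast_to(box, (n, 3)).copy(),
        coords=coords,
        label=scenario.name,
        composition=scenario.cholesterol_fraction,
    )

    ground_truth = {
        "name": scenario.name,
        "seed": scenario.seed,
        "composition": scenario.cholesterol_fraction,
        "n_frames": n,
        "dt_ns": scenario.dt,
        "dimer_intervals": interval_truth,
        "n_transient": sum(1 for iv in scenario.dimer_intervals if not iv.stable),
        "n_stable": sum(1 for iv in scenario.dimer_intervals if iv.stable),
        "monomer_intervals": [list(se) for se in _monomer_intervals(scenario)],
        "grazing_frames": sorted(scenario.grazing_frames),
        "hotspots": [
            {
                "receptor_id": p["hotspot"].receptor_id,
                "residue_index": p["hotspot"].residue_index,
                "lipid_kind": p["hotspot"].lipid_kind,
                "regime": p["hotspot"].regime,
                "target_occupancy": p["hotspot"].target_occupancy,
                "planted_occupancy": p["occupancy"],
                "run": list(p["run"]) if p["run"] else None,
                "molecule_index": p["mol"],
            }
            for p in plans
        ],
        "thickness_field": [
            [rid, helix, mult_]
            for (rid, helix), mult_ in scenario.thickness_field.items()
        ],
    }
    return traj, topology, ground_truth


# -- packaged reference scenarios --------------------------------------


def reference_scenarios(seed: int = 7) -> list[PlantedScenario]:
    """Four deterministic scenarios mirroring the studied bilayer
    compositions (0, 9, 30 and 50 mole % cholesterol).

    Each is small enough to run end-to-end in minutes yet exercises every
    analysis stage: grazing approaches, transient and stable dimers with
    known interfaces and angles, lipid residence hot-spots and a planted
    bilayer-thickness deformation.
    """
    return [
        PlantedScenario(
            name="popc_0",
            n_frames=1600,
            cholesterol_fraction=0.0,
            dimer_intervals=[
                DimerInterval(300, 449, ("IV", "I")),
                DimerInterval(900, 1599, ("I", "I"), theta1=0.0, theta2=0.0, stable=True),
            ],
            lipid_hotspots=[LipidHotspot(1, 204, "POPC", 0.5, "monomer")],
            grazing_frames=[100, 600, 700],
            seed=seed * 1000 + 11,
        ),
        PlantedScenario(
            name="chol_9",
            n_frames=1800,
            cholesterol_fraction=9.0,
            dimer_intervals=[
                DimerInterval(250, 399, ("I", "I")),
                DimerInterval(1100, 1799, ("I", "I"), stable=True),
            ],
            lipid_hotspots=[
                LipidHotspot(1, 164, "CHOL", 0.6, "monomer"),
                LipidHotspot(1, 48, "CHOL", 0.8, "dimer"),
                LipidHotspot(2, 48, "CHOL", 0.8, "dimer"),
            ],
            grazing_frames=[700],
            seed=seed * 1000 + 22,
        ),
        PlantedScenario(
            name="chol_30",
            n_frames=1800,
            cholesterol_fraction=30.0,
            dimer_intervals=[
                DimerInterval(300, 449, ("IV", "V")),
                DimerInterval(
                    1200, 1799, ("I", "VII"), theta1=30.0, theta2=-45.0, stable=True
                ),
            ],
            lipid_hotspots=[LipidHotspot(1, 356, "CHOL", 0.7, "monomer")],
            thickness_field={(1, "I"): 1.10, (2, "I"): 1.10},
            grazing_frames=[800],
            seed=seed * 1000 + 33,
        ),
        PlantedScenario(
            name="chol_50",
            n_frames=2000,
            cholesterol_fraction=50.0,
            dimer_intervals=[
                DimerInterval(150, 299, ("I", "I")),
                DimerInterval(450, 599, ("I", "I")),
                DimerInterval(750, 899, ("I", "I")),
                DimerInterval(1050, 1199, ("IV", "V")),
                DimerInterval(1500, 1999, ("V", "V"), stable=True),
            ],
            lipid_hotspots=[LipidHotspot(1, 48, "CHOL", 0.3, "monomer")],
            grazing_frames=[50, 1300, 1350],
            seed=seed * 1000 + 44,
        ),
    ]
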