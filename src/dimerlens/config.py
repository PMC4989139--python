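"""Analysis configuration shared by every pipeline stage.

The defaults encode the distance criteria used throughout the analyses:
receptors closer than ``dimer_cutoff`` (0.5 nm minimum bead distance
between transmembrane segments) are in the dimer regime, dissociation is
declared when the minimum distance exceeds ``dissociation_threshold``
(1.5 nm), and distances above ``monomer_threshold`` (1 nm) characterise
freely diffusing monomers. Contact maps use ``contact_cutoff`` (0.5 nm)
for residue-residue contacts and lipid occupancy uses
``lipid_contact_cutoff`` (0.6 nm, configurable because contact-based
residence definitions vary between studies). The interface occupancy
score keeps only helices with normalized occupancy >= 0.7 and interface
probability >= 0.7.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]

HELIX_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII")


@dataclass
class AnalysisConfig:
    dimer_cutoff: float = 0.5  # nm, opens a dimer interval
    monomer_threshold: float = 1.0  # nm, monomer regime characterisation
    dissociation_threshold: float = 1.5  # nm, closes a dimer interval
    contact_cutoff: float = 0.5  # nm, residue-residue interface contacts
    lipid_contact_cutoff: float = 0.6  # nm, lipid-residue occupancy contacts
    min_dimer_frames: int = 5  # consecutive sub-cutoff frames to open a dimer
    min_transient_duration: float = 100.0  # ns, shorter closed contacts are grazing
    angle_bin_width: float = 10.0  # degrees, orientation histograms
    grid_bin: float = 0.2  # nm, thickness-map cell size
    farfield_min_distance: float = 3.0  # nm, unperturbed-bilayer cutoff
    occupancy_threshold: float = 0.7  # normalized occupancy filter (score)
    interface_probability_threshold: float = 0.7  # interface filter (score)
    seed: int = 0
    # angle-defining backbone residues: two on helix IV (hinge), one on helix I
    angle_residues: tuple[int, int, int] = (48, 164, 167)
    map_extent: float = 5.0  # nm, half-width of the body-frame thickness map

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.dimer_cutoff < self.monomer_threshold < self.dissociation_threshold):
            raise ValueError(
                "require dimer_cutoff < monomer_threshold < dissociation_threshold, "
                f"got {self.dimer_cutoff}, {self.monomer_threshold}, "
                f"{self.dissociation_threshold}"
            )
        for name in (
            "dimer_cutoff",
            "monomer_threshold",
            "dissociation_threshold",
            "contact_cutoff",
            "lipid_contact_cutoff",
            "angle_bin_width",
            "grid_bin",
            "farfield_min_distance",
            "map_extent",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("occupancy_threshold", "interface_probability_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_dimer_frames < 1:
            raise ValueError("min_dimer_frames must be >= 1")
        if self.min_transient_duration < 0:
            raise ValueError("min_transient_duration must be >= 0")
        if len(self.angle_residues) != 3:
            raise ValueError("angle_residues must name exactly three residues")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["angle_residues"] = list(self.angle_residues)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown AnalysisConfig keys: {sorted(unknown)}")
        data = dict(data)
        if "angle_residues" in data:
            data["angle_residues"] = tuple(data["angle_residues"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)
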