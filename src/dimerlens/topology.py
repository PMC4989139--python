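"""System topology: the bead-level frame of reference for every analysis.

A :class:`SystemTopology` maps each bead of a coarse-grain system to its
molecule (receptor, POPC or cholesterol), and for receptor beads to a
receptor id (1 or 2), a residue index (UniProt P08908 numbering for the
serotonin 1A receptor) and a transmembrane-helix label I..VII or
``loop``. Helix definitions are inclusive residue ranges.

Validation enforces the structural facts the downstream analyses depend
on: each POPC carries exactly one phosphate bead (bilayer thickness), and
the rotational-angle definition requires residue 48 on helix I and
residues 164 and 167 on helix IV.

Topologies are read from a TSV file (``#helix LABEL LO HI`` comment lines
followed by a tab-separated bead table) or an equivalent JSON document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import HELIX_LABELS

__all__ = ["SystemTopology", "TopologyError", "read_topology", "write_topology"]

BEAD_COLUMNS = [
    "bead_id",
    "molecule_id",
    "molecule_kind",
    "receptor_id",
    "residue_index",
    "bead_role",
    "helix_label",
]

MOLECULE_KINDS = {"receptor", "POPC", "CHOL"}
BEAD_ROLES = {"backbone", "sidechain", "phosphate", "other"}
# residues whose helix placement the rotational-angle definition relies on
ANGLE_ANCHORS = {48: "I", 164: "IV", 167: "IV"}


class TopologyError(ValueError):
    """A topology record violates a structural invariant."""


@dataclass
class SystemTopology:
    beads: pd.DataFrame
    helix_definitions: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.beads = self.beads.reset_index(drop=True)
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        df = self.beads
        missing = [c for c in BEAD_COLUMNS if c not in df.columns]
        if missing:
            raise TopologyError(f"bead table missing columns: {missing}")
        bad_kind = set(df["molecule_kind"]) - MOLECULE_KINDS
        if bad_kind:
            raise TopologyError(f"unknown molecule kinds: {sorted(bad_kind)}")
        bad_role = set(df["bead_role"]) - BEAD_ROLES
        if bad_role:
            raise TopologyError(f"unknown bead roles: {sorted(bad_role)}")

        self._validate_helix_definitions()
        rec = df[df["molecule_kind"] == "receptor"]
        if len(rec):
            self._validate_receptors(rec)
        self._validate_popc(df)

    def _validate_helix_definitions(self) -> None:
        for label, (lo, hi) in self.helix_definitions.items():
            if label not in HELIX_LABELS:
                raise TopologyError(f"unknown helix label in definitions: {label}")
            if lo > hi:
                raise TopologyError(f"helix {label} has empty range ({lo}, {hi})")
        labels = list(self.helix_definitions)
        for i, a in enumerate(labels):
            lo_a, hi_a = self.helix_definitions[a]
            for b in labels[i + 1 :]:
                lo_b, hi_b = self.helix_definitions[b]
                if lo_a <= hi_b and lo_b <= hi_a:
                    raise TopologyError(
                        f"helix ranges overlap: {a} ({lo_a}-{hi_a}) and "
                        f"{b} ({lo_b}-{hi_b})"
                    )
        for residue, helix in ANGLE_ANCHORS.items():
            if helix not in self.helix_definitions:
                raise TopologyError(f"helix {helix} missing from definitions")
            lo, hi = self.helix_definitions[helix]
            if not lo <= residue <= hi:
                raise TopologyError(
                    f"residue {residue} must lie in helix {helix} "
                    f"({lo}-{hi}); the rotational-angle definition depends on it"
                )

    def _validate_receptors(self, rec: pd.DataFrame) -> None:
        if rec["receptor_id"].isna().any():
            bad = rec[rec["receptor_id"].isna()]["bead_id"].tolist()
            raise TopologyError(f"receptor beads without receptor_id: {bad[:5]}")
        ids = set(int(i) for i in rec["receptor_id"].unique())
        if not ids <= {1, 2}:
            raise TopologyError(f"receptor_id values must be 1 or 2, got {sorted(ids)}")
        if rec["residue_index"].isna().any():
            bad = rec[rec["residue_index"].isna()]["bead_id"].tolist()
            raise TopologyError(f"receptor beads without residue_index: {bad[:5]}")
        for _, row in rec.iterrows():
            label = row["helix_label"]
            residue = int(row["residue_index"])
            expected = self.helix_of_residue(residue)
            if label != expected:
                raise TopologyError(
                    f"bead {row['bead_id']}: residue {residue} labelled "
                    f"{label!r} but helix definitions place it in {expected!r}"
                )

    def _validate_popc(self, df: pd.DataFrame) -> None:
        popc = df[df["molecule_kind"] == "POPC"]
        if not len(popc):
            return
        counts = (
            popc.assign(is_p=popc["bead_role"] == "phosphate")
            .groupby("molecule_id")["is_p"]
            .sum()
        )
        bad = counts[counts != 1]
        if len(bad):
            mol = int(bad.index[0])
            raise TopologyError(
                f"POPC molecule {mol} has {int(bad.iloc[0])} phosphate beads "
                "(exactly one required)"
            )

    # -- queries ------------------------------------------------------

    def helix_of_residue(self, residue: int) -> str:
        for label, (lo, hi) in self.helix_definitions.items():
            if lo <= residue <= hi:
                return label
        return "loop"

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def receptor_ids(self) -> list[int]:
        rec = self.beads[self.beads["molecule_kind"] == "receptor"]
        return sorted(int(i) for i in rec["receptor_id"].unique())

    def require_two_receptors(self) -> None:
        if self.receptor_ids != [1, 2]:
            raise TopologyError(
                f"dimer analyses need receptors 1 and 2; found {self.receptor_ids}"
            )

    def receptor_beads(self, receptor_id: int, tm_only: bool = False) -> np.ndarray:
        """Positional indices of a receptor's beads (optionally TM only)."""
        df = self.beads
        mask = (df["molecule_kind"] == "receptor") & (df["receptor_id"] == receptor_id)
        if tm_only:
            mask &= df["helix_label"].isin(HELIX_LABELS)
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise TopologyError(f"receptor {receptor_id} has no matching beads")
        return idx

    def backbone_bead(self, receptor_id: int, residue: int) -> int:
        df = self.beads
        mask = (
            (df["molecule_kind"] == "receptor")
            & (df["receptor_id"] == receptor_id)
            & (df["residue_index"] == residue)
            & (df["bead_role"] == "backbone")
        )
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size != 1:
            raise TopologyError(
                f"receptor {receptor_id} residue {residue}: expected exactly one "
                f"backbone bead, found {idx.size}"
            )
        return int(idx[0])

    def residue_table(self, receptor_id: int) -> pd.DataFrame:
        """One row per residue: residue_index, helix_label, bead indices."""
        cache = self.__dict__.setdefault("_residue_table_cache", {})
        if receptor_id in cache:
            return cache[receptor_id]
        df = self.beads
        mask = (df["molecule_kind"] == "receptor") & (df["receptor_id"] == receptor_id)
        sub = df[mask]
        rows = []
        for residue, grp in sub.groupby("residue_index"):
            rows.append(
                {
                    "residue_index": int(residue),
                    "helix_label": grp["helix_label"].iloc[0],
                    "bead_indices": np.asarray(grp.index, dtype=int),
                }
            )
        table = pd.DataFrame(rows).sort_values("residue_index").reset_index(drop=True)
        cache[receptor_id] = table
        return table

    def lipid_molecules(self, kind: str) -> list[tuple[int, np.ndarray]]:
        """(molecule_id, bead positional indices) for every lipid of ``kind``."""
        df = self.beads
        sub = df[df["molecule_kind"] == kind]
        return [
            (int(mol), np.asarray(grp.index, dtype=int))
            for mol, grp in sub.groupby("molecule_id")
        ]

    def phosphate_indices(self) -> np.ndarray:
        df = self.beads
        mask = (df["molecule_kind"] == "POPC") & (df["bead_role"] == "phosphate")
        return np.flatnonzero(mask.to_numpy())


# -- file formats ------------------------------------------------------


def read_topology(path: str | Path) -> SystemTopology:
    """Read a topology from TSV (``#helix`` header lines) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        beads = pd.DataFrame(doc["beads"], columns=BEAD_COLUMNS)
        helices = {k: (int(v[0]), int(v[1])) for k, v in doc["helix_definitions"].items()}
    else:
        helices = {}
        rows = []
        header: list[str] | None = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith("#helix"):
                    parts = line.split()
                    if len(parts) != 4:
                        raise TopologyError(
                            f"{path}:{lineno}: malformed helix definition {line!r}"
                        )
                    helices[parts[1]] = (int(parts[2]), int(parts[3]))
                    continue
                if line.startswith("#"):
                    continue
                fields = line.split("\t")
                if header is None:
                    header = fields
                    continue
                rows.append(dict(zip(header, fields)))
        if header is None:
            raise TopologyError(f"{path}: no bead table found")
        beads = pd.DataFrame(rows, columns=header)
    return SystemTopology(beads=_coerce_beads(beads), helix_definitions=helices)


def _coerce_beads(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("bead_id", "molecule_id"):
        df[col] = df[col].astype(int)
    for col in ("receptor_id", "residue_index"):
        df[col] = pd.to_numeric(df[col].replace({"": None, "-": None, "NA": None}))
    df["helix_label"] = df["helix_label"].replace({"": None, "-": None, "NA": None})
    return df


def write_topology(topology: SystemTopology, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "helix_definitions": {
                k: list(v) for k, v in topology.helix_definitions.items()
            },
            "beads": json.loads(
                topology.beads[BEAD_COLUMNS].to_json(orient="records")
            ),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
        return
    with open(path, "w") as fh:
        for label, (lo, hi) in topology.helix_definitions.items():
            fh.write(f"#helix {label} {lo} {hi}\n")
        fh.write("\t".join(BEAD_COLUMNS) + "\n")
        for _, row in topology.beads.iterrows():
            vals = []
            for col in BEAD_COLUMNS:
                v = row[col]
                if pd.isna(v):
                    vals.append("-")
                elif col in ("bead_id", "molecule_id", "receptor_id", "residue_index"):
                    vals.append(str(int(v)))
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")
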