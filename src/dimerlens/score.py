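"""Interface occupancy score: lipid occupancy coupled to the dimer interface.

The score asks whether a lipid species (cholesterol, POPC) that dwells
on a transmembrane helix does so *at* the dimer interface or away from
it. Per receptor, each helix gets the maximum residue occupancy over its
residues in the dimer regime, normalized by the receptor's highest helix
value. Each helix also has a probability of occurring at the dimer
interface (fraction of stable-dimer frames in which it participates in
an interface contact). The matrix entry ``(h_occ, h_int)`` is the
product of the normalized occupancy of ``h_occ`` and the interface
probability of ``h_int``; diagonal entries therefore report lipid
occupancy at interface helices and off-diagonal entries occupancy away
from the interface. To suppress noise, entries are zeroed unless the
interface probability is at least 0.7 and the normalized occupancy at
least 0.7 (both configurable); the filters act on the product matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, HELIX_LABELS
from .lipids import OccupancyProfile
from .topology import SystemTopology, TopologyError

__all__ = [
    "InterfaceOccupancyMatrix",
    "helix_occupancy",
    "interface_occupancy_matrix",
]


@dataclass
class InterfaceOccupancyMatrix:
    matrix: pd.DataFrame  # rows = helix with occupancy, cols = helix at interface
    lipid_kind: str
    composition: float
    occupancy_threshold: float
    interface_probability_threshold: float

    def diagonal_dominant(self) -> bool:
        m = self.matrix.to_numpy()
        diag = np.diag(m)
        off = m - np.diag(diag)
        return bool(diag.max() > off.max())


def helix_occupancy(
    profile: OccupancyProfile, topology: SystemTopology, normalize: bool = True
) -> pd.Series:
    """Per-helix maximum residue occupancy, normalized to the receptor max.

    Loop residues are ignored; each helix must own at least one residue
    of the profile.
    """
    receptor = profile.receptor_id if profile.receptor_id is not None else 1
    out = {}
    for helix in HELIX_LABELS:
        lo, hi = topology.helix_definitions[helix]
        residues = [r for r in profile.values.index if lo <= r <= hi]
        if not residues:
            raise TopologyError(f"helix {helix} has no residues in the profile")
        out[helix] = float(profile.values.loc[residues].max())
    series = pd.Series(out, name=f"occupancy_{profile.lipid_kind}_R{receptor}")
    if normalize:
        peak = series.max()
        if peak > 0:
            series = series / peak
    return series


def interface_occupancy_matrix(
    helix_occ: pd.Series,
    interface_prob: pd.Series,
    config: AnalysisConfig | None = None,
    lipid_kind: str = "CHOL",
    composition: float = 0.0,
) -> InterfaceOccupancyMatrix:
    """Product-and-threshold interface occupancy score matrix.

    ``helix_occ`` is the normalized per-helix occupancy (values in
    [0, 1], max 1 for the receptor); ``interface_prob`` the per-helix
    interface probability. Entries failing either threshold are exactly
    zero.
    """
    config = config or AnalysisConfig()
    occ = helix_occ.reindex(list(HELIX_LABELS))
    prob = interface_prob.reindex(list(HELIX_LABELS))
    if occ.isna().any() or prob.isna().any():
        raise ValueError("occupancy and probability must cover helices I..VII")
    m = np.outer(occ.to_numpy(), prob.to_numpy())
    keep = np.outer(
        occ.to_numpy() >= config.occupancy_threshold,
        prob.to_numpy() >= config.interface_probability_threshold,
    )
    m = np.where(keep, m, 0.0)
    matrix = pd.DataFrame(m, index=list(HELIX_LABELS), columns=list(HELIX_LABELS))
    matrix.index.name = "helix_occupancy"
    matrix.columns.name = "helix_interface"
    return InterfaceOccupancyMatrix(
        matrix=matrix,
        lipid_kind=lipid_kind,
        composition=composition,
        occupancy_threshold=config.occupancy_threshold,
        interface_probability_threshold=config.interface_probability_threshold,
    )
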