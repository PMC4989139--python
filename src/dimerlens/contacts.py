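"""Helix-helix dimer interfaces and normalized 7x7 contact maps.

A residue of receptor 1 and a residue of receptor 2 are in contact when
any pair of their beads is within ``contact_cutoff`` (0.5 nm,
minimum-image). A helix pair (hA, hB) is at the interface of a frame
when at least one residue contact joins them; contacts involving loop
residues are tallied in a side table and excluded from the 7x7 maps.

Two aggregate maps are produced:

* the *stable* map pools long-lived dimers (no subsequent dissociation):
  each event contributes its per-helix-pair fraction of interface frames
  weighted by the event's duration relative to its trajectory length,
  and the summed matrix is normalized to its maximum so the dominant
  interface scores 1;
* the *transient* map pools short-lived dimers that later dissociate:
  each event contributes its per-pair interface fraction weighted by the
  association period, normalized to the maximum total so that, e.g., a
  pair seen in one of four equal transients scores 1/3 of a pair seen in
  three.

Raw (unnormalized) accumulators are kept on the result so alternative
normalizations can be applied post hoc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, HELIX_LABELS
from .geometry import min_image
from .kinetics import RegimeSegmentation
from .topology import SystemTopology
from .trajectory import Frame, Trajectory

__all__ = [
    "HelixContactMap",
    "interface_helices",
    "event_interface_sets",
    "stable_contact_map",
    "transient_contact_map",
    "helix_interface_probability",
]


@dataclass
class HelixContactMap:
    """Normalized helix-pair population at the dimer interface."""

    matrix: pd.DataFrame  # 7x7, rows = receptor-1 helix, cols = receptor-2 helix
    kind: str  # "stable" | "transient"
    composition: float = 0.0
    raw: pd.DataFrame | None = None  # unnormalized accumulator
    loop_contacts: pd.DataFrame | None = None  # side table incl. loop residues

    def symmetrized(self) -> pd.DataFrame:
        """Receptor-order-free map: max of the matrix and its transpose."""
        m = self.matrix
        return pd.DataFrame(
            np.maximum(m.to_numpy(), m.to_numpy().T), index=m.index, columns=m.columns
        )


def _empty_map() -> pd.DataFrame:
    df = pd.DataFrame(
        np.zeros((7, 7)), index=list(HELIX_LABELS), columns=list(HELIX_LABELS)
    )
    df.index.name = "helix_R1"
    df.columns.name = "helix_R2"
    return df


def interface_helices(
    frame: Frame,
    topology: SystemTopology,
    config: AnalysisConfig | None = None,
) -> tuple[set[tuple[str, str]], list[tuple[str, str]]]:
    """Helix pairs at the dimer interface of one frame.

    Returns ``(helix_pairs, side_pairs)`` where ``helix_pairs`` are
    (receptor-1 helix, receptor-2 helix) labels I..VII and ``side_pairs``
    records contacts that involve loop residues on either side.
    """
    config = config or AnalysisConfig()
    topology.require_two_receptors()
    res1 = topology.residue_table(1)
    res2 = topology.residue_table(2)
    idx1 = np.concatenate(res1["bead_indices"].to_list())
    idx2 = np.concatenate(res2["bead_indices"].to_list())
    lab1 = np.concatenate(
        [[h] * len(b) for h, b in zip(res1["helix_label"], res1["bead_indices"])]
    )
    lab2 = np.concatenate(
        [[h] * len(b) for h, b in zip(res2["helix_label"], res2["bead_indices"])]
    )
    d = min_image(
        frame.coords[idx1][:, None, :] - frame.coords[idx2][None, :, :], frame.box
    )
    close = np.sqrt((d * d).sum(axis=-1)) < config.contact_cutoff
    pairs: set[tuple[str, str]] = set()
    side: set[tuple[str, str]] = set()
    ii, jj = np.nonzero(close)
    for a, b in zip(lab1[ii], lab2[jj]):
        if a in HELIX_LABELS and b in HELIX_LABELS:
            pairs.add((a, b))
        else:
            side.add((a, b))
    return pairs, sorted(side)


def event_interface_sets(
    trajectory: Trajectory,
    topology: SystemTopology,
    interval: tuple[int, int],
    config: AnalysisConfig | None = None,
) -> list[set[tuple[str, str]]]:
    """Per-frame interface helix-pair sets over a dimer interval."""
    s, e = interval
    return [
        interface_helices(trajectory.frame(i), topology, config)[0]
        for i in range(s, e + 1)
    ]


def _pair_fractions(per_frame: list[set[tuple[str, str]]]) -> pd.DataFrame:
    acc = _empty_map()
    for pairs in per_frame:
        for a, b in pairs:
            acc.loc[a, b] += 1.0
    if per_frame:
        acc /= len(per_frame)
    return acc


def _loop_side_table(
    trajectory: Trajectory,
    topology: SystemTopology,
    intervals: list[tuple[int, int]],
    config: AnalysisConfig,
) -> pd.DataFrame:
    counts: dict[tuple[str, str], int] = {}
    for s, e in intervals:
        for i in range(s, e + 1):
            _, side = interface_helices(trajectory.frame(i), topology, config)
            for pair in side:
                counts[pair] = counts.get(pair, 0) + 1
    rows = [
        {"label_R1": a, "label_R2": b, "frames": n} for (a, b), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["label_R1", "label_R2", "frames"])


def stable_contact_map(
    data: list[tuple[Trajectory, RegimeSegmentation]],
    topology: SystemTopology,
    config: AnalysisConfig | None = None,
    composition: float | None = None,
) -> HelixContactMap:
    """Normalized contact map pooled over long-lived stable dimers.

    Each stable event contributes its per-pair fraction of interface
    frames weighted by (event duration / trajectory length); the pooled
    matrix is scaled so its maximum is 1. With zero stable events an
    all-zero map is returned with a warning.
    """
    config = config or AnalysisConfig()
    acc = _empty_map()
    loops = []
    n_events = 0
    comp = composition
    for traj, seg in data:
        comp = traj.composition if comp is None else comp
        stable = [(s, e) for s, e, _ in seg.dimer_intervals("stable")]
        for s, e in stable:
            per_frame = event_interface_sets(traj, topology, (s, e), config)
            weight = (e - s + 1) / len(traj)
            acc += weight * _pair_fractions(per_frame)
            n_events += 1
        if stable:
            loops.append(_loop_side_table(traj, topology, stable, config))
    raw = acc.copy()
    if n_events == 0:
        warnings.warn("no stable dimer events: stable contact map is empty")
        matrix = acc
    else:
        peak = acc.to_numpy().max()
        matrix = acc / peak if peak > 0 else acc
    side = (
        pd.concat(loops, ignore_index=True)
        if loops
        else pd.DataFrame(columns=["label_R1", "label_R2", "frames"])
    )
    return HelixContactMap(
        matrix=matrix,
        kind="stable",
        composition=comp if comp is not None else 0.0,
        raw=raw,
        loop_contacts=side,
    )


def transient_contact_map(
    data: list[tuple[Trajectory, RegimeSegmentation]],
    topology: SystemTopology,
    config: AnalysisConfig | None = None,
    composition: float | None = None,
) -> HelixContactMap:
    """Normalized contact map pooled over transient (dissociating) dimers.

    Each transient event contributes its per-pair interface fraction
    weighted by the association period (ns); the pooled matrix is
    normalized by its maximum total, so equal-duration events give map
    values proportional to the number of transient instances per pair.
    """
    config = config or AnalysisConfig()
    acc = _empty_map()
    loops = []
    n_events = 0
    comp = composition
    for traj, seg in data:
        comp = traj.composition if comp is None else comp
        dt = traj.dt
        transients = [(s, e) for s, e, _ in seg.dimer_intervals("transient")]
        for s, e in transients:
            per_frame = event_interface_sets(traj, topology, (s, e), config)
            duration_ns = (e - s + 1) * dt
            acc += duration_ns * _pair_fractions(per_frame)
            n_events += 1
        if transients:
            loops.append(_loop_side_table(traj, topology, transients, config))
    raw = acc.copy()
    if n_events == 0:
        warnings.warn("no transient dimer events: transient contact map is empty")
        matrix = acc
    else:
        peak = acc.to_numpy().max()
        matrix = acc / peak if peak > 0 else acc
    side = (
        pd.concat(loops, ignore_index=True)
        if loops
        else pd.DataFrame(columns=["label_R1", "label_R2", "frames"])
    )
    return HelixContactMap(
        matrix=matrix,
        kind="transient",
        composition=comp if comp is not None else 0.0,
        raw=raw,
        loop_contacts=side,
    )


def helix_interface_probability(
    data: list[tuple[Trajectory, RegimeSegmentation]],
    topology: SystemTopology,
    config: AnalysisConfig | None = None,
    kind: str = "stable",
    receptor: int | None = None,
) -> pd.Series:
    """Per-helix probability of being at the dimer interface.

    The probability is the fraction of pooled ``kind``-dimer frames in
    which the helix participates in at least one interface pair, on the
    side of ``receptor`` (1 or 2), or on either side when ``receptor``
    is None.
    """
    config = config or AnalysisConfig()
    counts = pd.Series(0.0, index=list(HELIX_LABELS))
    n_frames = 0
    for traj, seg in data:
        for s, e, _ in seg.dimer_intervals(kind):
            for pairs in event_interface_sets(traj, topology, (s, e), config):
                present: set[str] = set()
                for a, b in pairs:
                    if receptor in (None, 1):
                        present.add(a)
                    if receptor in (None, 2):
                        present.add(b)
                for h in present:
                    counts[h] += 1.0
                n_frames += 1
    if n_frames == 0:
        warnings.warn(f"no {kind} dimer frames: interface probabilities are zero")
        return counts
    out = counts / n_frames
    out.name = f"p_interface_{kind}" + ("" if receptor is None else f"_R{receptor}")
    return out
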