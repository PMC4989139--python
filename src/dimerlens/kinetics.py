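"""Dimer/monomer regime detection from inter-receptor minimum distances.

The per-frame observable is the minimum minimum-image distance between
the transmembrane-helix beads of receptor 1 and receptor 2 (loop beads
are excluded so that flexible intracellular loops cannot masquerade as
dimer contacts). Segmentation uses hysteresis: a dimer interval opens at
the first of ``min_dimer_frames`` consecutive frames below
``dimer_cutoff`` (0.5 nm) and closes at the first frame above
``dissociation_threshold`` (1.5 nm). Intermediate distances continue the
current regime. A dimer interval that survives to the final frame is a
long-lived *stable* dimer; a closed interval lasting at least
``min_transient_duration`` is a *transient* dimer (one dissociation
event); shorter closed contacts are grazing approaches and are folded
back into the monomer regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .geometry import min_image, pairwise_min_distance
from .topology import SystemTopology
from .trajectory import Frame, Trajectory

__all__ = [
    "DistanceSeries",
    "RegimeSegmentation",
    "min_distance",
    "distance_series",
    "segment_regimes",
    "count_dissociations",
    "distance_heatmap",
    "HEATMAP_BINS",
]

# Fig-1-style distance classes (nm); right-open bins, last bin unbounded
HEATMAP_BINS = (0.0, 0.5, 1.0, 2.0, 4.0, np.inf)
HEATMAP_LABELS = ("<0.5", "0.5-1", "1-2", "2-4", ">4")


@dataclass
class DistanceSeries:
    """Per-frame minimum TM-TM inter-receptor distance (nm)."""

    times: np.ndarray
    min_distance: np.ndarray
    label: str = ""
    composition: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.min_distance = np.asarray(self.min_distance, dtype=float)
        if len(self.times) != len(self.min_distance):
            raise ValueError("times and min_distance must have equal lengths")
        if np.any(self.min_distance < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RegimeSegmentation:
    """Alternating monomer/dimer intervals partitioning a trajectory.

    ``intervals`` holds inclusive frame ranges ``(start, end, label)``;
    ``dimer_events`` maps interval indices to ``stable``/``transient``.
    """

    intervals: list[tuple[int, int, str]]
    dimer_events: list[tuple[int, str]]
    label: str = ""
    composition: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.intervals[-1][1] + 1 if self.intervals else 0

    def frame_labels(self) -> np.ndarray:
        out = np.empty(self.n_frames, dtype=object)
        for s, e, lab in self.intervals:
            out[s : e + 1] = lab
        return out

    def dimer_intervals(self, kind: str | None = None) -> list[tuple[int, int, str]]:
        """(start, end, class) of dimer events, optionally one class only."""
        out = []
        for idx, cls in self.dimer_events:
            s, e, _ = self.intervals[idx]
            if kind is None or cls == kind:
                out.append((s, e, cls))
        return out


def min_distance(
    frame: Frame, topology: SystemTopology, tm_only: bool = True
) -> float:
    """Minimum minimum-image distance between the two receptors' beads."""
    topology.require_two_receptors()
    idx1 = topology.receptor_beads(1, tm_only=tm_only)
    idx2 = topology.receptor_beads(2, tm_only=tm_only)
    return pairwise_min_distance(frame.coords[idx1], frame.coords[idx2], frame.box)


def distance_series(
    trajectory: Trajectory,
    topology: SystemTopology,
    tm_only: bool = True,
    chunk: int = 256,
) -> DistanceSeries:
    """Vectorised per-frame minimum TM-TM distance over a trajectory."""
    topology.require_two_receptors()
    idx1 = topology.receptor_beads(1, tm_only=tm_only)
    idx2 = topology.receptor_beads(2, tm_only=tm_only)
    n = len(trajectory)
    out = np.empty(n)
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        a = trajectory.coords[s:e, idx1]
        b = trajectory.coords[s:e, idx2]
        d = a[:, :, None, :] - b[:, None, :, :]
        d = min_image(d, trajectory.boxes[s:e, None, None, :])
        out[s:e] = np.sqrt((d * d).sum(axis=-1)).min(axis=(1, 2))
    return DistanceSeries(
        times=trajectory.times,
        min_distance=out,
        label=trajectory.label,
        composition=trajectory.composition,
    )


def segment_regimes(
    series: DistanceSeries, config: AnalysisConfig | None = None
) -> RegimeSegmentation:
    """Hysteresis segmentation of a distance series into regimes."""
    config = config or AnalysisConfig()
    d = series.min_distance
    n = len(d)
    if n == 0:
        raise ValueError("cannot segment an empty distance series")
    dt = float(np.median(np.diff(series.times))) if n > 1 else 0.0

    labels = np.zeros(n, dtype=bool)  # True = dimer frame
    raw_events: list[tuple[int, int, bool]] = []  # (start, end, reached_end)
    in_dimer = False
    below_run = 0
    start = -1
    for i in range(n):
        if not in_dimer:
            if d[i] < config.dimer_cutoff:
                below_run += 1
                if below_run >= config.min_dimer_frames:
                    in_dimer = True
                    start = i - below_run + 1
            elif d[i] > config.dissociation_threshold:
                below_run = 0
            else:
                # intermediate distances neither extend nor reset hysteresis;
                # a sub-cutoff run must be consecutive to open an interval
                below_run = 0
        else:
            if d[i] > config.dissociation_threshold:
                raw_events.append((start, i - 1, False))
                in_dimer = False
                below_run = 0
    if in_dimer:
        raw_events.append((start, n - 1, True))

    events: list[tuple[int, int, str]] = []
    for s, e, reached_end in raw_events:
        if reached_end:
            events.append((s, e, "stable"))
            continue
        duration_ns = (e - s + 1) * dt
        if duration_ns >= config.min_transient_duration:
            events.append((s, e, "transient"))
        # else: grazing contact, folded into the monomer regime
    for s, e, _ in events:
        labels[s : e + 1] = True

    intervals: list[tuple[int, int, str]] = []
    dimer_events: list[tuple[int, str]] = []
    ev_iter = iter(events)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        lab = "dimer" if labels[i] else "monomer"
        intervals.append((i, j, lab))
        if lab == "dimer":
            s, e, cls = next(ev_iter)
            assert (s, e) == (i, j)
            dimer_events.append((len(intervals) - 1, cls))
        i = j + 1
    return RegimeSegmentation(
        intervals=intervals,
        dimer_events=dimer_events,
        label=series.label,
        composition=series.composition,
    )


def count_dissociations(
    segmentations: list[RegimeSegmentation],
) -> dict[str, int | dict[float, int]]:
    """Total transient (closed) dimer events, overall and per composition."""
    per_comp: dict[float, int] = {}
    total = 0
    for seg in segmentations:
        n = sum(1 for _, cls in seg.dimer_events if cls == "transient")
        total += n
        per_comp[seg.composition] = per_comp.get(seg.composition, 0) + n
    return {"total": total, "per_composition": per_comp}


def distance_heatmap(series_list: list[DistanceSeries]) -> pd.DataFrame:
    """Per-simulation frame counts in the five Fig-1-style distance classes."""
    if not series_list:
        raise ValueError("need at least one distance series")
    rows = {}
    for k, series in enumerate(series_list):
        name = series.label or f"sim{k}"
        counts, _ = np.histogram(series.min_distance, bins=HEATMAP_BINS)
        rows[name] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(HEATMAP_LABELS))
    df.index.name = "simulation"
    return df


def binned_distance_classes(series: DistanceSeries) -> np.ndarray:
    """Per-frame distance class index (0 = closest bin)."""
    return np.clip(
        np.digitize(series.min_distance, HEATMAP_BINS[1:-1]), 0, len(HEATMAP_LABELS) - 1
    )
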