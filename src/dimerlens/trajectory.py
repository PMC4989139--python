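"""Trajectory containers and GRO-format I/O.

Frames hold bead coordinates in nm in an orthorhombic periodic box, in
the bead order of the companion :class:`~dimerlens.topology.SystemTopology`.
Multi-frame trajectories are stored as concatenated GRO blocks (title,
atom count, fixed-column atom records, box line); triclinic boxes are
rejected because every analysis here relies on component-wise
minimum-image arithmetic.

An optional XTC fast path is provided through MDAnalysis when that
package is available; GRO remains the canonical text format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Frame", "Trajectory", "GroParseError", "read_gro", "write_gro", "read_xtc"]


class GroParseError(ValueError):
    pass


@dataclass
class Frame:
    """One stored frame: time (ns), box (nm, orthorhombic) and coordinates."""

    time: float
    box: np.ndarray  # (3,)
    coords: np.ndarray  # (n_beads, 3)

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.box.shape != (3,):
            raise ValueError("box must be three orthorhombic lengths")
        if np.any(self.box <= 0):
            raise ValueError(f"box lengths must be > 0, got {self.box}")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_beads, 3)")


@dataclass
class Trajectory:
    """Time-ordered frames of one simulation.

    ``composition`` is the cholesterol mole percentage of the bilayer
    (0, 9, 30 or 50 in the reference scenarios; any value is accepted).
    """

    times: np.ndarray  # (n_frames,) ns
    boxes: np.ndarray  # (n_frames, 3) nm
    coords: np.ndarray  # (n_frames, n_beads, 3) nm
    label: str = ""
    composition: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.times) != len(self.coords) or len(self.boxes) != len(self.coords):
            raise ValueError("times, boxes and coords must have equal frame counts")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Nominal inter-frame spacing in ns (median of stored intervals)."""
        if len(self.times) < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), box=self.boxes[i], coords=self.coords[i])

    @classmethod
    def from_frames(
        cls, frames: list[Frame], label: str = "", composition: float = 0.0
    ) -> "Trajectory":
        if not frames:
            raise ValueError("cannot build a trajectory from zero frames")
        return cls(
            times=np.array([f.time for f in frames]),
            boxes=np.stack([f.box for f in frames]),
            coords=np.stack([f.coords for f in frames]),
            label=label,
            composition=composition,
        )


# -- GRO parsing -------------------------------------------------------


def _parse_box_line(line: str, lineno: int) -> np.ndarray:
    parts = line.split()
    if len(parts) not in (3, 9):
        raise GroParseError(f"line {lineno}: malformed box line {line.strip()!r}")
    vals = [float(p) for p in parts]
    if len(vals) == 9 and any(abs(v) > 1e-12 for v in vals[3:]):
        raise GroParseError(
            f"line {lineno}: triclinic box not supported (off-diagonal "
            "components present); analyses assume an orthorhombic cell"
        )
    box = np.array(vals[:3])
    if np.any(box <= 0):
        raise GroParseError(f"line {lineno}: box lengths must be positive, got {box}")
    return box


def _parse_time(title: str) -> float | None:
    if "t=" in title:
        try:
            return float(title.split("t=")[-1].split()[0])
        except (ValueError, IndexError):
            return None
    return None


def read_gro(path: str | Path) -> tuple[pd.DataFrame, list[Frame]]:
    """Read a (possibly multi-frame, concatenated) GRO file.

    Returns a topology skeleton — one record per bead of the first frame
    with ``resid``, ``resname`` and ``atomname`` — and the list of frames
    in file order. Coordinates are in nm. Frames without a parsable
    ``t=`` tag in the title are numbered sequentially.
    """
    path = Path(path)
    frames: list[Frame] = []
    skeleton: pd.DataFrame | None = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)
    frame_no = 0
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i].rstrip("\n")
        if i + 1 >= n_lines:
            raise GroParseError(f"line {i + 1}: truncated frame (missing atom count)")
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError:
            raise GroParseError(
                f"line {i + 2}: malformed atom count {lines[i + 1].strip()!r}"
            ) from None
        first_atom = i + 2
        box_line = first_atom + n_atoms
        if box_line >= n_lines:
            raise GroParseError(
                f"line {first_atom + 1}: truncated frame (declared {n_atoms} atoms, "
                f"file ends after {n_lines - first_atom} atom lines)"
            )
        records = []
        coords = np.empty((n_atoms, 3))
        for k in range(n_atoms):
            line = lines[first_atom + k]
            if len(line) < 44:
                raise GroParseError(
                    f"line {first_atom + k + 1}: atom record too short "
                    f"(frame declared {n_atoms} atoms)"
                )
            try:
                coords[k, 0] = float(line[20:28])
                coords[k, 1] = float(line[28:36])
                coords[k, 2] = float(line[36:44])
            except ValueError:
                raise GroParseError(
                    f"line {first_atom + k + 1}: unparsable coordinates in "
                    f"{line.rstrip()!r}"
                ) from None
            if skeleton is None:
                records.append(
                    {
                        "resid": int(line[0:5]),
                        "resname": line[5:10].strip(),
                        "atomname": line[10:15].strip(),
                    }
                )
        box = _parse_box_line(lines[box_line], box_line + 1)
        if skeleton is None:
            skeleton = pd.DataFrame(records)
        elif n_atoms != len(skeleton):
            raise GroParseError(
                f"line {i + 2}: frame has {n_atoms} atoms but first frame "
                f"had {len(skeleton)}"
            )
        t = _parse_time(title)
        frames.append(Frame(time=frame_no if t is None else t, box=box, coords=coords))
        frame_no += 1
        i = box_line + 1
    if skeleton is None:
        raise GroParseError("file contains no frames")
    return skeleton, frames


def write_gro(
    trajectory: Trajectory,
    skeleton: pd.DataFrame,
    path: str | Path,
    title: str = "dimerlens",
) -> None:
    """Write a trajectory as concatenated GRO frames (3-decimal precision)."""
    if len(skeleton) != trajectory.n_beads:
        raise ValueError(
            f"skeleton has {len(skeleton)} beads, trajectory {trajectory.n_beads}"
        )
    resids = skeleton["resid"].to_numpy()
    resnames = skeleton["resname"].tolist()
    atomnames = skeleton["atomname"].tolist()
    n = trajectory.n_beads
    chunks: list[str] = []
    for fi in range(len(trajectory)):
        xyz = trajectory.coords[fi]
        box = trajectory.boxes[fi]
        lines = [f"{title} t= {trajectory.times[fi]:.4f}", f"{n:5d}"]
        for k in range(n):
            lines.append(
                f"{int(resids[k]) % 100000:5d}{resnames[k]:<5.5s}"
                f"{atomnames[k]:>5.5s}{(k + 1) % 100000:5d}"
                f"{xyz[k, 0]:8.3f}{xyz[k, 1]:8.3f}{xyz[k, 2]:8.3f}"
            )
        lines.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}")
        chunks.append("\n".join(lines))
    Path(path).write_text("\n".join(chunks) + "\n")


def read_xtc(gro_path: str | Path, xtc_path: str | Path) -> list[Frame]:
    """Optional XTC fast path via MDAnalysis (GRO supplies the bead order)."""
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "XTC reading requires MDAnalysis; convert to multi-frame GRO "
            "(e.g. `gmx trjconv -o traj.gro`) to use the text path"
        ) from exc
    u = mda.Universe(str(gro_path), str(xtc_path))
    frames = []
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None or abs(dims[3] - 90) > 1e-6 or abs(dims[4] - 90) > 1e-6 or abs(
            dims[5] - 90
        ) > 1e-6:
            raise GroParseError("triclinic XTC boxes are not supported")
        frames.append(
            Frame(
                time=float(ts.time) / 1000.0,  # ps -> ns
                box=np.array(dims[:3]) / 10.0,  # A -> nm
                coords=u.atoms.positions / 10.0,
            )
        )
    return frames
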