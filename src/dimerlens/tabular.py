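"""Labelled-matrix TSV output with JSON metadata side-cars.

Every numeric matrix the pipeline emits (contact maps, densities,
occupancy tables, thickness grids) goes through :func:`write_matrix` so
that row/column labels travel with the values and the full analysis
configuration is recorded next to each file. NaN entries are written as
``NA`` and survive a round-trip through :func:`read_matrix`.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["write_matrix", "read_matrix"]


def write_matrix(
    matrix: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    path = Path(path)
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label=matrix.index.name or "row")
    if metadata is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        with open(sidecar, "w") as fh:
            json.dump(metadata, fh, indent=1, sort_keys=True, default=str)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index.name = None if df.index.name == "row" else df.index.name
    # restore numeric labels where possible so round-trips are exact
    for axis in ("index", "columns"):
        labels = getattr(df, axis)
        try:
            converted = labels.astype(float)
            if (converted == converted.astype(int)).all():
                converted = converted.astype(int)
            setattr(df, axis, converted)
        except (ValueError, TypeError):
            pass
    return df
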