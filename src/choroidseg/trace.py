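"""Layer-boundary traces.

A boundary trace stores one real-valued row position per image column and
optionally the fitted polynomial it came from.  Row indices grow downward
(row 0 is the top of the B-scan), so "anatomically lower" always means a
larger row value.  All modules share this convention and 0-based indexing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


def round_half_up(values):
    """Round to nearest integer with .5 rounding away from zero-up.

    Used whenever a real-valued trace is turned into pixel row indices;
    numpy's banker's rounding would make the rasterization depend on parity.
    """
    return np.floor(np.asarray(values, dtype=float) + 0.5).astype(int)


@dataclass
class BoundaryTrace:
    """A layer curve: one row value per column x = 0..W-1.

    Parameters
    ----------
    rows : array of float, shape (W,)
        Row position of the boundary in each column.
    poly : numpy.polynomial.Polynomial, optional
        The fitted polynomial the rows were evaluated from, kept so that
        downstream steps (thickness profiling) can evaluate the curve at
        non-integer positions.
    """

    rows: np.ndarray
    poly: object | None = field(default=None, repr=False)

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 1:
            raise ValueError("trace rows must be one-dimensional")

    @property
    def width(self) -> int:
        return self.rows.size

    def __call__(self, x):
        """Evaluate the trace at (possibly non-integer) column positions."""
        if self.poly is not None:
            return self.poly(np.asarray(x, dtype=float))
        return np.interp(np.asarray(x, dtype=float), np.arange(self.width), self.rows)

    def pixel_rows(self) -> np.ndarray:
        """Integer row per column (half-up rounding)."""
        return round_half_up(self.rows)

    @classmethod
    def from_polynomial(cls, poly, width: int) -> "BoundaryTrace":
        x = np.arange(width, dtype=float)
        return cls(rows=poly(x), poly=poly)

    @classmethod
    def constant(cls, row: float, width: int) -> "BoundaryTrace":
        return cls(rows=np.full(width, float(row)))

    # ---- serialization ----------------------------------------------------

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write (x, row) pairs; polynomial coefficients go to a JSON sidecar."""
        path = Path(path)
        arr = np.column_stack([np.arange(self.width), self.rows])
        np.savetxt(path, arr, fmt="%d,%.6f", header="x,row", comments="")
        if sidecar and self.poly is not None:
            meta = {
                "coef": list(map(float, self.poly.coef)),
                "domain": list(map(float, getattr(self.poly, "domain", [0, self.width - 1]))),
            }
            path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path) -> "BoundaryTrace":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        trace = cls(rows=arr[:, 1])
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            trace.poly = np.polynomial.Polynomial(meta["coef"], domain=meta["domain"])
        return trace
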