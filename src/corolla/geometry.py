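"""Petal trait measurement: area A, length L, width W from an outline.

L is the extent of the outline along a length axis, W the maximum extent
perpendicular to it, and A the shoelace area of the outline.  Because the
petal fits inside the L x W rectangle oriented along that axis, the
Montgomery ratio A/(L*W) always lies in (0, 1]: pi/4 for an ellipse, 1
for a rectangle.

Two length-axis conventions are supported:

``principal``
    Major axis of the outline's second moments of area.  Default;
    needs no landmarks and is rotation/translation invariant.
``landmarks``
    Base-to-apex axis through two user-supplied points, for bilaterally
    symmetric petals whose symmetry axis is known.

For petals with a concave (notched) apex, L is still the axis extent of
the outline — the notch is not bridged.  This mirrors the measurement
convention used for such petals in practice and inflates the Montgomery
ratio, since the real bounding rectangle of an un-notched petal would be
longer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .boundary import BoundaryPolygon

__all__ = [
    "AxisSpec",
    "PetalRecord",
    "polygon_area",
    "measure_petal",
    "read_petal_table",
    "write_petal_table",
]

PETAL_COLUMNS = ["species", "flower_id", "petal_id", "A", "L", "W"]


@dataclass(frozen=True)
class AxisSpec:
    """How to orient the length axis of a petal outline."""

    mode: Literal["principal", "landmarks"] = "principal"
    base: tuple[float, float] | None = None
    apex: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("principal", "landmarks"):
            raise ValueError(f"unknown axis mode {self.mode!r}")
        if self.mode == "landmarks" and (self.base is None or self.apex is None):
            raise ValueError("landmarks mode requires both base and apex points")


@dataclass(frozen=True)
class PetalRecord:
    """One petal's measured traits with its grouping labels.

    A, L, W are in cm^2 / cm / cm.  Invariants: all positive and
    A <= L*W (the petal fits its oriented bounding rectangle).
    """

    species: str
    flower_id: str
    petal_id: str
    A: float
    L: float
    W: float

    def __post_init__(self) -> None:
        if not self.species or not self.flower_id:
            raise ValueError("species and flower_id must be nonempty")
        if self.A <= 0 or self.L <= 0 or self.W <= 0:
            raise ValueError(
                f"petal {self.petal_id!r}: A, L, W must all be positive")
        if self.A > self.L * self.W * (1 + 1e-9):
            raise ValueError(
                f"petal {self.petal_id!r}: A={self.A} exceeds L*W="
                f"{self.L * self.W} (petal cannot exceed its bounding box)")

    @property
    def aspect_ratio(self) -> float:
        """Width-to-length ratio W/L (petal shape index)."""
        return self.W / self.L

    @property
    def montgomery_ratio(self) -> float:
        """A/(L*W), the per-petal proportionality; in (0, 1]."""
        return self.A / (self.L * self.W)


def polygon_area(polygon: BoundaryPolygon) -> float:
    """Absolute shoelace area of the closed outline (cm^2)."""
    a = polygon.area
    if a == 0.0:  # pragma: no cover - BoundaryPolygon forbids this
        raise ValueError("zero area: degenerate (collinear) polygon")
    return a


def _moments(v: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Area, centroid and central second-moment matrix of a polygon."""
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    c = x * y1 - x1 * y
    area = 0.5 * c.sum()
    cx = ((x + x1) * c).sum() / (6.0 * area)
    cy = ((y + y1) * c).sum() / (6.0 * area)
    sxx = ((x * x + x * x1 + x1 * x1) * c).sum() / 12.0 - area * cx * cx
    syy = ((y * y + y * y1 + y1 * y1) * c).sum() / 12.0 - area * cy * cy
    sxy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * c).sum() / 24.0 \
        - area * cx * cy
    return float(area), np.array([cx, cy]), np.array([[sxx, sxy], [sxy, syy]])


def _longest_diameter_axis(v: np.ndarray) -> np.ndarray:
    """Direction of the farthest vertex pair (on the convex hull)."""
    from scipy.spatial import ConvexHull

    hull = v[ConvexHull(v).vertices]
    d = hull[:, None, :] - hull[None, :, :]
    dist2 = (d ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(dist2), dist2.shape)
    axis = hull[i] - hull[j]
    return axis / np.linalg.norm(axis)


def measure_petal(
    polygon: BoundaryPolygon,
    axis: AxisSpec = AxisSpec(),
    species: str = "unknown",
    flower_id: str = "f1",
    petal_id: str | None = None,
) -> PetalRecord:
    """Measure A, L, W of one petal outline.

    L is the caliper extent of the outline projected on the length axis,
    W the caliper extent perpendicular to it, A the shoelace area.

    Raises
    ------
    ValueError
        If landmark points coincide.  A degenerate principal axis
        (isotropic second moments, e.g. a square or circle) falls back
        to the longest-diameter axis with a warning instead.
    """
    v = polygon.vertices
    if axis.mode == "landmarks":
        base = np.asarray(axis.base, dtype=float)
        apex = np.asarray(axis.apex, dtype=float)
        u = apex - base
        norm = np.linalg.norm(u)
        if norm == 0:
            raise ValueError("landmark base and apex coincide")
        lo, hi = v.min(axis=0), v.max(axis=0)
        for name, p in (("base", base), ("apex", apex)):
            if np.any(p < lo - 1e-9) or np.any(p > hi + 1e-9):
                raise ValueError(f"{name} point lies outside the outline's "
                                 "bounding box")
        u = u / norm
    else:
        _, _, m = _moments(v)
        evals, evecs = np.linalg.eigh(m)
        spread = evals[1] - evals[0]
        if spread <= 1e-9 * max(evals[1], 1e-300):
            warnings.warn(
                "principal axis degenerate (isotropic second moments); "
                "falling back to longest-diameter axis", stacklevel=2)
            u = _longest_diameter_axis(v)
        else:
            u = evecs[:, 1]  # eigenvector of the larger moment
    t = v @ u
    w = v @ np.array([-u[1], u[0]])
    L = float(t.max() - t.min())
    W = float(w.max() - w.min())
    A = polygon_area(polygon)
    return PetalRecord(
        species=species,
        flower_id=flower_id,
        petal_id=petal_id if petal_id is not None else (polygon.label or "p1"),
        A=A, L=L, W=W,
    )


def write_petal_table(petals: list[PetalRecord], path: str | Path) -> None:
    """Write per-petal measurements as CSV (A in cm^2, L and W in cm)."""
    df = pd.DataFrame([p.__dict__ for p in petals], columns=PETAL_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# units: A cm^2, L cm, W cm\n")
        df.to_csv(fh, index=False)


def read_petal_table(path: str | Path) -> list[PetalRecord]:
    """Read per-petal measurements from CSV.

    This is also the ingest point for externally measured petal tables
    (columns ``species,flower_id,petal_id,A,L,W``; ``#`` comment lines
    and extra columns are ignored).
    """
    df = pd.read_csv(path, comment="#")
    missing = set(PETAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"petal table missing columns: {sorted(missing)}")
    return [
        PetalRecord(str(r.species), str(r.flower_id), str(r.petal_id),
                    float(r.A), float(r.L), float(r.W))
        for r in df.itertuples(index=False)
    ]
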