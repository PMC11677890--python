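"""Binary silhouette images and petal boundary polygons.

A scanned petal sheet arrives as a binary raster: foreground pixels are
petal, background is scanner bed.  Each connected foreground region is
traced into a closed outline polygon with sub-pixel marching-squares
contouring, and pixel coordinates are converted to centimetres using the
scan resolution (``cm = px * 2.54 / dpi``).

Coordinate convention: ``x = column * scale`` and
``y = (image_height - row) * scale``, so y increases upward as on a bench,
not downward as in raster storage.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage import measure

__all__ = [
    "BinaryImage",
    "BoundaryPolygon",
    "TracingError",
    "trace_boundaries",
    "read_image",
    "read_boundary_file",
    "write_boundary_file",
]

#: centimetres per inch; fixes the px -> cm conversion 2.54 / dpi
CM_PER_INCH = 2.54

#: components smaller than this many pixels are treated as scanner noise
DEFAULT_MIN_PIXELS = 100


class TracingError(ValueError):
    """Raised when an image or boundary file cannot yield valid polygons."""


@dataclass
class BinaryImage:
    """A thresholded raster with a known scan resolution.

    Parameters
    ----------
    pixels : ndarray of bool, shape (rows, cols)
        True marks foreground (petal) pixels.
    dpi : float
        Scan resolution in dots per inch; must be positive. 600 dpi is the
        typical flatbed setting for petal scans.
    """

    pixels: np.ndarray
    dpi: float = 600.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixel grid must be 2-D")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")

    @property
    def scale(self) -> float:
        """Centimetres per pixel."""
        return CM_PER_INCH / self.dpi

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BoundaryPolygon:
    """Ordered outline of one petal in physical units (cm).

    The ring is stored open (first vertex not repeated); closure is
    implicit.  Invariants enforced at construction: at least three
    distinct vertices, a simple (non-self-intersecting) ring, nonzero
    area.  Orientation is normalised to counter-clockwise so the signed
    shoelace area is positive.
    """

    vertices: np.ndarray
    label: str = ""
    touches_border: bool = False
    _shapely: _ShapelyPolygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"object {self.label!r}: vertices must be (n, 2)")
        # drop an explicit closing vertex and collapse consecutive duplicates
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        keep = np.ones(len(v), dtype=bool)
        keep[1:] = np.any(np.diff(v, axis=0) != 0.0, axis=1)
        v = v[keep]
        if len(np.unique(v, axis=0)) < 3:
            raise TracingError(
                f"object {self.label!r}: fewer than 3 distinct vertices"
            )
        ring = _ShapelyPolygon(v)
        if ring.area == 0.0:
            raise TracingError(f"object {self.label!r}: zero area (degenerate)")
        if not ring.is_valid:
            raise TracingError(f"object {self.label!r}: self-intersecting outline")
        # normalise to counter-clockwise (positive signed area)
        if _signed_area(v) < 0:
            v = v[::-1]
        self.vertices = v
        self._shapely = _ShapelyPolygon(v)

    @property
    def shapely(self) -> _ShapelyPolygon:
        return self._shapely

    @property
    def area(self) -> float:
        """Enclosed (shoelace) area, in the square of the vertex unit."""
        return self._shapely.area

    @property
    def perimeter(self) -> float:
        return self._shapely.length

    def translated(self, dx: float, dy: float) -> "BoundaryPolygon":
        return BoundaryPolygon(self.vertices + [dx, dy], label=self.label,
                               touches_border=self.touches_border)

    def rotated(self, angle_rad: float) -> "BoundaryPolygon":
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        rot = np.array([[c, -s], [s, c]])
        return BoundaryPolygon(self.vertices @ rot.T, label=self.label,
                               touches_border=self.touches_border)


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def trace_boundaries(
    image: BinaryImage,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    label_prefix: str = "petal",
) -> list[BoundaryPolygon]:
    """Trace every connected foreground region into an outline polygon.

    Regions are found with 8-connectivity (diagonal neighbours join, so
    thin petal tips stay attached), contoured at the 0.5 level with
    marching squares for sub-pixel placement, and scaled to centimetres.
    Only the outer contour of each region is kept: petal silhouettes are
    simply connected, so interior holes are scanning artefacts.

    Parameters
    ----------
    image : BinaryImage
    min_pixels : int
        Regions with fewer foreground pixels are dropped (scanner noise).
    label_prefix : str
        Polygons are labelled ``{prefix}_{i}`` in region-label order.

    Returns
    -------
    list of BoundaryPolygon
        One counter-clockwise polygon per retained region, in cm.
        Regions that touch the image border get ``touches_border=True``
        and a warning, since part of the petal may be cut off.

    Raises
    ------
    TracingError
        If the image has no foreground at all, or no region survives the
        size filter ("no objects found").
    """
    px = image.pixels
    if not px.any():
        raise TracingError("no objects found: image has no foreground pixels")
    labels, n_regions = measure.label(px, connectivity=2, return_num=True)
    nrows = px.shape[0]
    scale = image.scale
    out: list[BoundaryPolygon] = []
    for i in range(1, n_regions + 1):
        mask = labels == i
        npix = int(mask.sum())
        if npix < min_pixels:
            continue
        touches = bool(
            mask[0, :].any() or mask[-1, :].any()
            or mask[:, 0].any() or mask[:, -1].any()
        )
        # pad so the 0.5-level contour closes even at the border
        padded = np.pad(mask, 1).astype(float)
        contours = measure.find_contours(padded, level=0.5)
        if not contours:  # pragma: no cover - padded mask always contours
            continue
        # outer rings share one orientation, interior holes the opposite;
        # keep the outers (petals are simply connected, holes are noise).
        # An 8-connected region joined only at pixel corners yields one
        # ring per lobe — each becomes its own polygon.
        rings = []
        for ring in contours:
            rows = ring[:, 0] - 1.0  # undo padding
            cols = ring[:, 1] - 1.0
            xy = np.column_stack([cols * scale, (nrows - rows) * scale])
            rings.append((xy, _signed_area(xy[:-1] if len(xy) > 1 else xy)))
        outer_sign = np.sign(max(rings, key=lambda r: abs(r[1]))[1])
        for xy, signed in rings:
            if np.sign(signed) != outer_sign:
                continue  # hole inside the silhouette
            if abs(signed) < min_pixels * scale * scale:
                continue  # saddle-point sliver
            poly = BoundaryPolygon(xy, label=f"{label_prefix}_{len(out) + 1}",
                                   touches_border=touches)
            if touches:
                warnings.warn(
                    f"{poly.label}: region touches the image border; the "
                    "outline may be truncated", stacklevel=2)
            out.append(poly)
    if not out:
        raise TracingError(
            f"no objects found: all regions below min_pixels={min_pixels}")
    return out


def read_image(path: str | Path, dpi: float | None = None) -> BinaryImage:
    """Load a PNG/BMP/TIFF raster as a binary image.

    Pixels above half the dtype range count as foreground; if the scan is
    dark-on-light (most foreground pixels along the border), polarity is
    flipped automatically.  ``dpi`` overrides any metadata; defaults to
    600 when neither is available.
    """
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    fg = arr > (arr.max() + arr.min()) / 2.0 if arr.dtype != bool else arr
    border = np.concatenate([fg[0, :], fg[-1, :], fg[:, 0], fg[:, -1]])
    if border.mean() > 0.5:
        fg = ~fg
    if dpi is None:
        meta = iio.immeta(path)
        dpi = float(meta.get("dpi", (600,))[0]) if meta.get("dpi") else 600.0
    return BinaryImage(fg, dpi=dpi)


def read_boundary_file(path: str | Path) -> list[BoundaryPolygon]:
    """Read outline polygons from a delimited text file.

    The file must have a header row naming columns ``object_id``, ``x``,
    ``y`` (comma- or tab-separated; extra columns ignored).  Vertices are
    grouped by ``object_id`` in file order; consecutive duplicate
    vertices are collapsed.

    Raises
    ------
    TracingError
        If an object has fewer than 3 distinct vertices, naming it.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise TracingError(f"{path.name}: empty file")
    delim = "\t" if "\t" in lines[0] else ","
    reader = csv.DictReader(lines, delimiter=delim)
    cols = {c.strip().lower(): c for c in reader.fieldnames or []}
    for need in ("object_id", "x", "y"):
        if need not in cols:
            raise TracingError(f"{path.name}: missing column {need!r}")
    groups: dict[str, list[tuple[float, float]]] = {}
    for row in reader:
        oid = row[cols["object_id"]].strip()
        groups.setdefault(oid, []).append(
            (float(row[cols["x"]]), float(row[cols["y"]])))
    if not groups:
        raise TracingError(f"{path.name}: no vertex rows")
    return [BoundaryPolygon(np.array(pts), label=oid)
            for oid, pts in groups.items()]


def write_boundary_file(
    polygons: list[BoundaryPolygon], path: str | Path, delimiter: str = ","
) -> None:
    """Write polygons as ``object_id,x,y`` rows (units: cm, y up)."""
    with open(path, "w", newline="") as fh:
        fh.write("# units: cm; y increases upward" + "\n")
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["object_id", "x", "y"])
        for poly in polygons:
            for x, y in poly.vertices:
                writer.writerow([poly.label, repr(float(x)), repr(float(y))])
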