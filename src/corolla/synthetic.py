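"""Synthetic two-species petal datasets with known ground truth.

The generator emulates the structure of a two-species petal study: each
species contributes a set of flowers, each flower a handful of petals,
and each petal a bilaterally symmetric outline whose area, length and
width are known exactly by construction.  Observed petal areas carry
multiplicative lognormal noise (areas are positive and their scatter
grows with size, which is why the scaling models are fitted after log
transformation).

Outline family: half-width profile along the length axis

    w(x) = (W/2) * f(x/L),   f(t) = t^p1 (1-t)^p2 / max f,

so the outline always has axis extent exactly L and maximum width
exactly W.  ``p1 > p2`` gives an obovate petal (widest toward the apex),
``p1 = p2`` a symmetric rounded petal.  An optional apex notch removes a
wedge of depth ``notch_depth * L`` at the tip without shortening the
measured length — the two notch lobes still reach x = L — which lowers
the enclosed area and therefore raises the apparent Montgomery ratio of
the bounding rectangle, the signature of concave-apex petals.

Because f is scale-free, the shape-determined proportionality
k = A/(L*W) is one number per species; the generator reports it as
ground truth.  A ``shape_drift`` knob makes petal shape vary with flower
size, which breaks the isometric (slope 1) structure and produces a
power-law exponent alpha != 1 that the PLE can recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely

from .aggregate import FlowerSummary, aggregate_flowers
from .boundary import BinaryImage, BoundaryPolygon, CM_PER_INCH
from .geometry import PetalRecord

__all__ = [
    "SpeciesConfig",
    "SyntheticConfig",
    "SyntheticDataset",
    "make_outline",
    "generate_dataset",
    "rasterize",
    "mh_like",
    "pk_like",
    "default_config",
]


def make_outline(
    L: float,
    W: float,
    p1: float,
    p2: float,
    notch_depth: float = 0.0,
    n_vertices: int = 256,
    label: str = "petal",
) -> BoundaryPolygon:
    """Construct a bilaterally symmetric petal outline on [0, L].

    Parameters
    ----------
    L, W : float
        Target length (axis extent) and maximum width, cm.
    p1, p2 : float
        Half-width profile exponents; the widest station sits at
        t* = p1/(p1+p2) of the length.
    notch_depth : float
        Apex notch depth as a fraction of L, in [0, 0.3).  The notch
        wedge reaches from the tip back to (1 - notch_depth) L; its
        shoulder starts at (1 - 2*notch_depth) L, which must lie apical
        of the widest station so W is preserved.
    n_vertices : int
        Approximate vertex budget for the outline (>= 16).

    Returns
    -------
    BoundaryPolygon with axis extent exactly L and perpendicular extent
    exactly W by construction.
    """
    if L <= 0 or W <= 0:
        raise ValueError("L and W must be positive")
    if p1 <= 0 or p2 <= 0:
        raise ValueError("profile exponents p1, p2 must be positive")
    if not 0.0 <= notch_depth < 0.3:
        raise ValueError("notch_depth must lie in [0, 0.3)")
    if n_vertices < 16:
        raise ValueError("need at least 16 vertices")
    t_star = p1 / (p1 + p2)
    t_cut = 1.0 - 2.0 * notch_depth
    if notch_depth > 0 and t_star > t_cut - 1e-9:
        raise ValueError("notch overlaps the widest station; reduce "
                         "notch_depth or move the profile peak basally")
    f_max = t_star ** p1 * (1.0 - t_star) ** p2

    m = max(n_vertices // 2, 8)
    ts = np.unique(np.concatenate([np.linspace(0.0, t_cut, m), [t_star]]))
    ts = ts[(ts > 0.0) & (ts < 1.0)]
    w = 0.5 * W * ts ** p1 * (1.0 - ts) ** p2 / f_max
    x = ts * L

    lower = np.column_stack([x, -w])
    upper = np.column_stack([x[::-1], w[::-1]])
    if notch_depth == 0.0:
        verts = np.vstack([[0.0, 0.0], lower, [L, 0.0], upper])
    else:
        y_lobe = 0.5 * w[-1]
        apex = np.array([
            [L, -y_lobe],
            [(1.0 - notch_depth) * L, 0.0],
            [L, y_lobe],
        ])
        verts = np.vstack([[0.0, 0.0], lower, apex, upper])
    return BoundaryPolygon(verts, label=label)


@dataclass(frozen=True)
class SpeciesConfig:
    """Generative parameters for one species-like population.

    Lengths are lognormal with the given arithmetic mean and sd (cm);
    W/L is Gaussian (truncated below at 0.05).  ``sigma_log_area`` is
    the sd of the additive Gaussian noise on ln(area), i.e. lognormal
    multiplicative noise on area.  ``shape_drift`` couples the profile
    exponent p2 to flower size (see module docstring); 0 keeps the
    isometric slope-1 structure exact.
    """

    name: str
    n_flowers: int
    petal_count: tuple[int, int]          # inclusive (min, max)
    length_mean: float                    # cm
    length_sd: float                      # cm
    ratio_mean: float                     # target W/L
    ratio_sd: float
    p1: float
    p2: float
    notch_depth: float = 0.0
    sigma_log_area: float = 0.03
    shape_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.n_flowers < 1:
            raise ValueError("n_flowers must be >= 1")
        if self.petal_count[0] < 1 or self.petal_count[1] < self.petal_count[0]:
            raise ValueError("petal_count must be (min, max) with min >= 1")
        if min(self.length_sd, self.ratio_sd, self.sigma_log_area) < 0:
            raise ValueError("sds must be nonnegative")
        if self.length_mean <= 0 or self.ratio_mean <= 0:
            raise ValueError("length_mean and ratio_mean must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    """A full two-(or more-)species simulated study.  ``seed`` is
    mandatory: every dataset must be reproducible."""

    species: tuple[SpeciesConfig, ...]
    seed: int
    n_vertices: int = 256

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required (reproducibility is "
                             "mandatory)")
        if not self.species:
            raise ValueError("at least one species config required")


@dataclass
class SyntheticDataset:
    """Generated data plus the ground truth that produced it."""

    petals: list[PetalRecord]
    flowers: list[FlowerSummary]
    #: noise-free area of each petal, parallel to ``petals``
    true_areas: list[float]
    #: per-species ground truth: shape-determined k, noise sd, counts
    truth: dict[str, dict]
    config: SyntheticConfig = field(repr=False, default=None)

    def noise_free_petals(self) -> list[PetalRecord]:
        """The same petals with their exact (noise-free) areas."""
        return [
            PetalRecord(p.species, p.flower_id, p.petal_id, a, p.L, p.W)
            for p, a in zip(self.petals, self.true_areas)
        ]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a reproducible synthetic petal dataset.

    Flower size is a lognormal random effect: 80% of the length variance
    sits between flowers and 20% between petals within a flower, so
    petals of one flower are realistically similar in size.  Each
    petal's noise-free area comes from its constructed outline; the
    observed area multiplies it by exp(eps), eps ~ N(0, sigma^2).
    """
    rng = np.random.default_rng(config.seed)
    petals: list[PetalRecord] = []
    true_areas: list[float] = []
    truth: dict[str, dict] = {}
    for sp in config.species:
        cv2 = (sp.length_sd / sp.length_mean) ** 2
        s2 = math.log1p(cv2)                       # lognormal log-variance
        mu = math.log(sp.length_mean) - s2 / 2.0
        s_between = math.sqrt(0.8 * s2)
        s_within = math.sqrt(0.2 * s2)
        ratios_k: list[float] = []
        for i in range(sp.n_flowers):
            fid = f"{sp.name}_f{i + 1:03d}"
            center = rng.normal(mu, s_between)
            p2_eff = sp.p2 * math.exp(sp.shape_drift * (center - mu))
            n_p = int(rng.integers(sp.petal_count[0], sp.petal_count[1] + 1))
            for j in range(n_p):
                L = float(np.exp(rng.normal(center, s_within)))
                ratio = max(float(rng.normal(sp.ratio_mean, sp.ratio_sd)),
                            0.05)
                W = ratio * L
                outline = make_outline(L, W, sp.p1, p2_eff, sp.notch_depth,
                                       config.n_vertices)
                a_true = outline.area
                a_obs = a_true * math.exp(rng.normal(0.0, sp.sigma_log_area))
                petals.append(PetalRecord(sp.name, fid, f"p{j + 1}",
                                          a_obs, L, W))
                true_areas.append(a_true)
                ratios_k.append(a_true / (L * W))
        truth[sp.name] = {
            "k": float(np.mean(ratios_k)),
            "sigma_log_area": sp.sigma_log_area,
            "alpha_structure": 1.0 if sp.shape_drift == 0.0 else None,
            "n_petals": len(ratios_k),
            "n_flowers": sp.n_flowers,
        }
    flowers = aggregate_flowers(petals)
    return SyntheticDataset(petals=petals, flowers=flowers,
                            true_areas=true_areas, truth=truth, config=config)


def rasterize(
    polygon: BoundaryPolygon,
    dpi: float = 600.0,
    margin_px: int = 2,
    max_canvas_px: int = 8000,
) -> BinaryImage:
    """Render an outline polygon (cm) to a binary raster.

    A pixel is foreground iff its centre falls inside the polygon.
    The canvas is the polygon's bounding box plus a small margin; a
    polygon needing more than ``max_canvas_px`` pixels on a side is
    refused rather than silently producing a huge image.
    """
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    scale = CM_PER_INCH / dpi
    minx, miny, maxx, maxy = polygon.shapely.bounds
    ncols = int(math.ceil((maxx - minx) / scale)) + 2 * margin_px
    nrows = int(math.ceil((maxy - miny) / scale)) + 2 * margin_px
    if max(nrows, ncols) > max_canvas_px:
        raise ValueError(
            f"polygon needs a {nrows}x{ncols} canvas at {dpi} dpi, above "
            f"the {max_canvas_px} px limit")
    xs = minx + (np.arange(ncols) - margin_px + 0.5) * scale
    ys = maxy + (margin_px - np.arange(nrows) - 0.5) * scale  # row 0 on top
    gx, gy = np.meshgrid(xs, ys)
    geom = polygon.shapely
    shapely.prepare(geom)
    mask = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(gx.shape)
    return BinaryImage(mask, dpi=dpi)


def mh_like(**overrides) -> SpeciesConfig:
    """Preset: many-petalled species with narrow obovate petals.

    Illustrative numbers, not measurements: ~60 flowers of 11-12 petals,
    petal length ~1.6 cm, W/L ~ 0.55, widest toward the apex (p1 > p2),
    no apex notch.  Exponents stay near 1 so the tips are blunt, as real
    petals are (exponents far above 1 would give cusp-like tips thinner
    than a scan pixel).  Shape-determined k ~ 0.66.
    """
    base = dict(name="mh_like", n_flowers=60, petal_count=(11, 12),
                length_mean=1.6, length_sd=0.16, ratio_mean=0.55,
                ratio_sd=0.04, p1=1.2, p2=0.8, notch_depth=0.0,
                sigma_log_area=0.03)
    base.update(overrides)
    return SpeciesConfig(**base)


def pk_like(**overrides) -> SpeciesConfig:
    """Preset: five-petalled species with broad rounded petals and a
    concave (notched) apex.  Illustrative numbers: ~63 flowers of 5
    petals, petal length ~1.5 cm, W/L ~ 0.95, symmetric rounded profile
    (p1 = p2 < 1), notch depth 5% of L.  Shape-determined k ~ 0.7.
    """
    base = dict(name="pk_like", n_flowers=63, petal_count=(5, 5),
                length_mean=1.5, length_sd=0.15, ratio_mean=0.95,
                ratio_sd=0.06, p1=0.7, p2=0.7, notch_depth=0.05,
                sigma_log_area=0.03)
    base.update(overrides)
    return SpeciesConfig(**base)


def default_config(seed: int, **kwargs) -> SyntheticConfig:
    """Two-species study at the default scale (~690 + ~315 petals)."""
    return SyntheticConfig(species=(mh_like(), pk_like()), seed=seed,
                           **kwargs)
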