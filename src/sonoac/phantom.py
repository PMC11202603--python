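"""Randomized abdominal soft-tissue phantoms with known liver attenuation.

Each phantom is a 2-D imaging plane: a stack of 6-10 superficial layers
(skin, fat, muscle) confined to the top 30 mm, a large elliptical liver with
semi-axes of 50-80 mm, up to 9 circular vessel-like inclusions inside the
liver, and an "other abdominal tissue" background.  Every tissue class draws
its speed of sound, attenuation coefficient (AC) and density uniformly from
the published abdominal ranges (see :data:`TISSUE_PROPERTY_RANGES`).  The
liver AC draw is recorded as the regression ground truth.

Sub-wavelength scatterers (fewer than 10 per wavelength-by-wavelength unit
area, densities 800-1200 kg/m^3) provide the speckle from which attenuation
is read out acoustically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "TISSUE_PROPERTY_RANGES",
    "TISSUE_LABELS",
    "PhantomSpec",
    "TissueMap",
    "sample_phantom",
    "warp_axial_grid",
    "homogeneous_phantom",
    "check_property_containment",
]

# Integer codes for the label map.
TISSUE_LABELS = {
    "other": 0,
    "liver": 1,
    "vessel": 2,
    "muscle": 3,
    "fat": 4,
    "skin": 5,
}
LABEL_NAMES = {v: k for k, v in TISSUE_LABELS.items()}

# Acoustic property ranges per tissue class:
# (speed of sound m/s, attenuation dB/cm/MHz, density kg/m^3).
TISSUE_PROPERTY_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "liver": {"sos": (1500.0, 1600.0), "ac": (0.0, 1.0), "density": (1050.0, 1150.0)},
    "vessel": {"sos": (1500.0, 1600.0), "ac": (0.0, 0.5), "density": (1050.0, 1150.0)},
    "muscle": {"sos": (1500.0, 1650.0), "ac": (0.0, 1.5), "density": (1000.0, 1200.0)},
    "fat": {"sos": (1400.0, 1500.0), "ac": (0.0, 0.5), "density": (800.0, 950.0)},
    "skin": {"sos": (1500.0, 1700.0), "ac": (0.0, 1.0), "density": (1100.0, 1150.0)},
    "other": {"sos": (1450.0, 1650.0), "ac": (0.0, 1.5), "density": (850.0, 1150.0)},
}


def _copy_ranges() -> dict:
    return {k: {p: tuple(v) for p, v in d.items()} for k, d in TISSUE_PROPERTY_RANGES.items()}


@dataclass
class PhantomSpec:
    """Sampling law for one phantom family.

    Geometry is given in millimetres on an axial-by-lateral cell grid.
    Defaults follow the published phantom recipe: liver semi-axes 50-80 mm,
    fewer than 10 vessel objects of radius 3-50 mm, 6-10 layers in the top
    30 mm, and fewer than 10 scatterers per wavelength^2 unit area with
    densities 800-1200 kg/m^3.
    """

    grid_shape: tuple[int, int] = (400, 200)  # (axial, lateral) cells
    cell_size: float = 0.2  # mm
    liver_radius_range: tuple[float, float] = (50.0, 80.0)  # mm, both semi-axes
    vessel_count_max: int = 10  # exclusive upper bound
    vessel_radius_range: tuple[float, float] = (3.0, 50.0)  # mm
    layer_count_range: tuple[int, int] = (6, 10)  # inclusive
    layer_zone_depth: float = 30.0  # mm
    scatterer_count_max_per_unit_area: int = 10  # exclusive upper bound
    scatterer_density_range: tuple[float, float] = (800.0, 1200.0)  # kg/m^3
    property_ranges: dict = field(default_factory=_copy_ranges)
    probe_curvature_radius: Optional[float] = 60.0  # mm; None = flat array
    world_extent_mm: tuple[float, float] = (180.0, 240.0)  # full phantom (axial, lateral)
    unit_area_frequency_mhz: float = 3.0  # wavelength reference for scatterer unit area
    unit_area_sos: float = 1550.0  # m/s, median liver speed of sound
    seed: int = 0

    def __post_init__(self) -> None:
        for name, pair in (
            ("liver_radius_range", self.liver_radius_range),
            ("vessel_radius_range", self.vessel_radius_range),
            ("layer_count_range", self.layer_count_range),
            ("scatterer_density_range", self.scatterer_density_range),
        ):
            if not pair[0] <= pair[1]:
                raise ConfigurationError(f"{name} must be ordered low <= high, got {pair}")
        for tissue, ranges in self.property_ranges.items():
            for prop, (lo, hi) in ranges.items():
                if lo > hi:
                    raise ConfigurationError(
                        f"property range {tissue}.{prop} not ordered: ({lo}, {hi})"
                    )
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if self.vessel_count_max < 1 or self.scatterer_count_max_per_unit_area < 1:
            raise ConfigurationError("exclusive count bounds must be >= 1")
        depth, width = self.extent_mm
        if self.liver_radius_range[0] > max(depth, width):
            raise ConfigurationError(
                f"grid extent {depth:.0f}x{width:.0f} mm cannot contain the minimum "
                f"liver semi-axis {self.liver_radius_range[0]:.0f} mm"
            )
        if depth <= self.layer_zone_depth:
            raise ConfigurationError("grid depth must exceed the superficial layer zone")

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(axial depth, lateral width) of the grid in mm."""
        return (self.grid_shape[0] * self.cell_size, self.grid_shape[1] * self.cell_size)

    @property
    def unit_area_wavelength_mm(self) -> float:
        return self.unit_area_sos / (self.unit_area_frequency_mhz * 1e6) * 1e3


@dataclass
class TissueMap:
    """One realized phantom: property grids, scatterers and ground truth.

    ``scatterers`` is an (N, 3) array of (axial mm, lateral mm, density
    kg/m^3); lateral coordinates are centred on the probe axis.
    ``liver_ac_truth`` is the attenuation coefficient (dB/cm/MHz) assigned
    to every liver-labelled cell.
    """

    sos_map: np.ndarray
    ac_map: np.ndarray
    density_map: np.ndarray
    label_map: np.ndarray
    scatterers: np.ndarray
    liver_ac_truth: float
    seed: int
    cell_size: float
    meta: dict = field(default_factory=dict)

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (
            self.label_map.shape[0] * self.cell_size,
            self.label_map.shape[1] * self.cell_size,
        )

    def axial_mm(self) -> np.ndarray:
        """Cell-centre axial coordinates (depth below the probe face)."""
        return (np.arange(self.label_map.shape[0]) + 0.5) * self.cell_size

    def lateral_mm(self) -> np.ndarray:
        """Cell-centre lateral coordinates, centred on the probe axis."""
        n = self.label_map.shape[1]
        return (np.arange(n) + 0.5 - n / 2) * self.cell_size


def _sample_properties(rng: np.random.Generator, ranges: dict[str, tuple[float, float]]):
    return tuple(rng.uniform(*ranges[p]) for p in ("sos", "ac", "density"))


def sample_phantom(spec: PhantomSpec) -> TissueMap:
    """Draw one phantom reproducibly from ``spec`` (geometry, properties, speckle).

    The same spec and seed always produce a bit-identical phantom.  Shapes are
    rasterized in precedence order other < liver < vessel < layers, so
    superficial layers always win in the top 30 mm.
    """
    rng = np.random.default_rng(spec.seed)
    nz, nx = spec.grid_shape
    depth, width = spec.extent_mm
    z = (np.arange(nz) + 0.5)[:, None] * spec.cell_size  # (nz, 1) mm
    x = ((np.arange(nx) + 0.5) - nx / 2)[None, :] * spec.cell_size  # (1, nx) mm

    label = np.zeros((nz, nx), dtype=np.int8)
    sos = np.empty((nz, nx))
    ac = np.empty((nz, nx))
    rho = np.empty((nz, nx))

    # Background: other abdominal tissue.
    s, a, d = _sample_properties(rng, spec.property_ranges["other"])
    sos[:], ac[:], rho[:] = s, a, d

    # Liver ellipse; both semi-axes drawn from the published 50-80 mm range.
    ax_lat = rng.uniform(*spec.liver_radius_range)
    ax_axi = rng.uniform(*spec.liver_radius_range)
    cx = rng.uniform(-0.15, 0.15) * width
    cz = spec.layer_zone_depth + rng.uniform(0.25, 0.60) * ax_axi
    liver_mask = ((x - cx) / ax_lat) ** 2 + ((z - cz) / ax_axi) ** 2 <= 1.0
    liver_sos, liver_ac, liver_rho = _sample_properties(rng, spec.property_ranges["liver"])
    label[liver_mask] = TISSUE_LABELS["liver"]
    sos[liver_mask], ac[liver_mask], rho[liver_mask] = liver_sos, liver_ac, liver_rho

    # Vessel-like inclusions: 0..vessel_count_max-1 circles at arbitrary
    # locations in the full phantom world (large enough to hold the liver
    # ellipse); the imaged grid crops them, so only some intersect the view.
    n_vessels = int(rng.integers(0, spec.vessel_count_max))
    world_z, world_x = spec.world_extent_mm
    vessels = []
    for _ in range(n_vessels):
        r = rng.uniform(*spec.vessel_radius_range)
        vx = rng.uniform(-world_x / 2, world_x / 2)
        vz = rng.uniform(spec.layer_zone_depth, world_z)
        mask = (x - vx) ** 2 + (z - vz) ** 2 <= r**2
        vs, va, vd = _sample_properties(rng, spec.property_ranges["vessel"])
        label[mask] = TISSUE_LABELS["vessel"]
        sos[mask], ac[mask], rho[mask] = vs, va, vd
        vessels.append({"center_mm": (float(vz), float(vx)), "radius_mm": float(r)})

    # Superficial layers: skin on top, then a random fat/muscle stack filling
    # exactly the 30 mm layer zone.
    n_layers = int(rng.integers(spec.layer_count_range[0], spec.layer_count_range[1] + 1))
    weights = rng.random(n_layers) + 0.3  # keeps every layer > ~1 cell thick
    thickness = weights / weights.sum() * spec.layer_zone_depth
    boundaries = np.concatenate([[0.0], np.cumsum(thickness)])
    layer_records = []
    for i in range(n_layers):
        tissue = "skin" if i == 0 else ("fat" if rng.uniform() < 0.5 else "muscle")
        ls, la, ld = _sample_properties(rng, spec.property_ranges[tissue])
        mask = (z >= boundaries[i]) & (z < boundaries[i + 1]) & np.ones_like(x, dtype=bool)
        label[mask] = TISSUE_LABELS[tissue]
        sos[mask], ac[mask], rho[mask] = ls, la, ld
        layer_records.append({"tissue": tissue, "top_mm": float(boundaries[i]),
                              "bottom_mm": float(boundaries[i + 1])})

    # Speckle scatterers: a per-phantom count (strictly below the bound) is
    # placed uniformly inside every wavelength-by-wavelength unit cell.
    lam = spec.unit_area_wavelength_mm
    n_per_unit = int(rng.integers(1, spec.scatterer_count_max_per_unit_area))
    n_uz, n_ux = int(np.ceil(depth / lam)), int(np.ceil(width / lam))
    cell_z = np.repeat(np.arange(n_uz), n_ux * n_per_unit) * lam
    cell_x = np.tile(np.repeat(np.arange(n_ux), n_per_unit), n_uz) * lam
    n_scat = cell_z.size
    jitter = 1.0 - 1e-9  # keep each scatterer strictly inside its unit cell
    sz = cell_z + rng.random(n_scat) * lam * jitter
    sx = cell_x + rng.random(n_scat) * lam * jitter - width / 2
    inside = (sz < depth) & (np.abs(sx) < width / 2)
    sdens = rng.uniform(*spec.scatterer_density_range, size=n_scat)
    scatterers = np.column_stack([sz[inside], sx[inside], sdens[inside]])

    meta = {
        "liver_semi_axes_mm": (float(ax_axi), float(ax_lat)),
        "liver_center_mm": (float(cz), float(cx)),
        "n_vessels": n_vessels,
        "vessels": vessels,
        "n_layers": n_layers,
        "layers": layer_records,
        "scatterers_per_unit_area": n_per_unit,
        "unit_area_wavelength_mm": lam,
        "warped": False,
    }
    return TissueMap(
        sos_map=sos, ac_map=ac, density_map=rho, label_map=label,
        scatterers=scatterers, liver_ac_truth=float(liver_ac),
        seed=spec.seed, cell_size=spec.cell_size, meta=meta,
    )


def warp_axial_grid(tmap: TissueMap, curvature_radius: Optional[float]) -> TissueMap:
    """Warp the phantom so superficial layers follow a convex probe face.

    Each lateral column is shifted deeper by the probe sagitta
    ``delta(x) = R - sqrt(R^2 - x^2)`` (periodic shift: the sliver leaving the
    deep edge re-enters above the probe face).  This conserves per-class cell
    counts exactly, leaves the centre column untouched, and places the warped
    top boundary on a circle of radius ``R``.  ``None`` (or non-positive /
    infinite R) is the flat-array sentinel and returns the input unchanged.
    """
    if curvature_radius is None or not np.isfinite(curvature_radius) or curvature_radius <= 0:
        return tmap
    R = float(curvature_radius)
    nz, nx = tmap.label_map.shape
    xs = tmap.lateral_mm()
    half_width = tmap.extent_mm[1] / 2
    if R < half_width:
        raise ConfigurationError(
            f"curvature radius {R:.1f} mm smaller than the lateral half-extent "
            f"{half_width:.1f} mm"
        )
    sagitta = R - np.sqrt(R**2 - xs**2)  # mm, per column
    shift = np.round(sagitta / tmap.cell_size).astype(int)  # cells

    rows = (np.arange(nz)[:, None] - shift[None, :]) % nz
    cols = np.broadcast_to(np.arange(nx)[None, :], (nz, nx))

    def roll(arr: np.ndarray) -> np.ndarray:
        return arr[rows, cols]

    scat = tmap.scatterers.copy()
    if scat.size:
        sag_at = np.interp(scat[:, 1], xs, sagitta)
        scat[:, 0] = (scat[:, 0] + sag_at) % tmap.extent_mm[0]

    meta = dict(tmap.meta)
    meta.update({"warped": True, "curvature_radius_mm": R})
    return replace(
        tmap,
        sos_map=roll(tmap.sos_map),
        ac_map=roll(tmap.ac_map),
        density_map=roll(tmap.density_map),
        label_map=roll(tmap.label_map),
        scatterers=scat,
        meta=meta,
    )


def homogeneous_phantom(
    ac_db_cm_mhz: float,
    sos: float = 1540.0,
    density: float = 1050.0,
    grid_shape: tuple[int, int] = (400, 200),
    cell_size: float = 0.2,
    scatterers_per_unit: int = 5,
    unit_area_frequency_mhz: float = 3.0,
    seed: int = 0,
) -> TissueMap:
    """Uniform single-tissue speckle phantom with a prescribed attenuation.

    Calibration/oracle input: closed-form attenuation checks and the
    spectral-log-difference estimator both assume a homogeneous medium.
    Pass ``scatterers_per_unit=0`` for a scatterer-free medium (point targets
    can then be injected by assigning ``scatterers`` directly).
    """
    rng = np.random.default_rng(seed)
    nz, nx = grid_shape
    depth, width = nz * cell_size, nx * cell_size
    lam = (sos / (unit_area_frequency_mhz * 1e6)) * 1e3
    if scatterers_per_unit > 0:
        n_uz, n_ux = int(np.ceil(depth / lam)), int(np.ceil(width / lam))
        cz = np.repeat(np.arange(n_uz), n_ux * scatterers_per_unit) * lam
        cxx = np.tile(np.repeat(np.arange(n_ux), scatterers_per_unit), n_uz) * lam
        sz = cz + rng.random(cz.size) * lam
        sx = cxx + rng.random(cz.size) * lam - width / 2
        keep = (sz < depth) & (np.abs(sx) < width / 2)
        dens = rng.uniform(800.0, 1200.0, size=cz.size)
        scat = np.column_stack([sz[keep], sx[keep], dens[keep]])
    else:
        scat = np.empty((0, 3))
    return TissueMap(
        sos_map=np.full(grid_shape, float(sos)),
        ac_map=np.full(grid_shape, float(ac_db_cm_mhz)),
        density_map=np.full(grid_shape, float(density)),
        label_map=np.full(grid_shape, TISSUE_LABELS["liver"], dtype=np.int8),
        scatterers=scat,
        liver_ac_truth=float(ac_db_cm_mhz),
        seed=seed,
        cell_size=cell_size,
        meta={"homogeneous": True},
    )


def check_property_containment(tmap: TissueMap, property_ranges: dict | None = None) -> int:
    """Count cells whose (SoS, AC, density) fall outside their label's range.

    Returns 0 for a law-abiding phantom; used by the Monte-Carlo bound checks.
    """
    ranges = property_ranges or TISSUE_PROPERTY_RANGES
    bad = 0
    for name, code in TISSUE_LABELS.items():
        mask = tmap.label_map == code
        if not mask.any():
            continue
        r = ranges[name]
        for grid, prop in ((tmap.sos_map, "sos"), (tmap.ac_map, "ac"), (tmap.density_map, "density")):
            vals = grid[mask]
            lo, hi = r[prop]
            bad += int(np.count_nonzero((vals < lo) | (vals > hi)))
    return bad
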