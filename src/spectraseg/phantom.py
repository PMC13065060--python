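"""Synthetic multi-energy phantom simulator.

Emulates the acquisition geometry of a cylindrical 100 mm phantom with
eight 10 mm insert rods (one central, seven on a ring) scanned with an
F-bin photon-counting detector: every rod traverses all axial slices, each
slice carries F registered energy-bin images, and the ground-truth label
map marks rod interiors with the material's class id (background = 0
everywhere else, including the water-filled phantom bulk).

The forward model is deliberately simple — reconstructed-intensity domain,
not projection physics: voxel intensity in bin f is the material's mean
attenuation ``mu[f]`` times a smooth multiplicative radial bias field
(a cupping / beam-hardening stand-in) plus zero-mean Gaussian noise whose
per-bin standard deviation scales with the inverse square root of the bin
width (narrow bins collect fewer photons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .materials import MaterialSpec, default_materials

__all__ = [
    "PhantomLayout",
    "AcquisitionParams",
    "SpectralVolume",
    "LabelVolume",
    "make_layouts",
    "render_scan",
    "CoverageError",
]

#: Confusable quartet placed in every layout by default (see make_layouts).
ALWAYS_INCLUDE_DEFAULT = ("HA100", "HA200", "I5", "I10")


class CoverageError(ValueError):
    """Raised when full material coverage is requested but impossible."""


@dataclass(frozen=True)
class SpectralVolume:
    """Per-scan 4-D intensity array (Z slices, F bins, H, W) with metadata."""

    values: np.ndarray
    bin_edges_keV: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        edges = np.asarray(self.bin_edges_keV, dtype=float)
        if v.ndim != 4:
            raise ValueError("values must be (Z, F, H, W)")
        if v.shape[1] != len(edges) - 1:
            raise ValueError("F must equal len(bin_edges) - 1")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite intensities")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "bin_edges_keV", edges)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class LabelVolume:
    """Integer class map (Z, H, W), values 0..12, aligned with a SpectralVolume."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("labels must be (Z, H, W)")
        if lab.min() < 0 or lab.max() > 12:
            raise ValueError("labels must be in 0..12")
        object.__setattr__(self, "labels", lab.astype(np.uint8))


@dataclass(frozen=True)
class PhantomLayout:
    """Rod positions (mm, phantom-centered) and the material at each position.

    ``assignment`` maps position index (0 = central, 1..7 = ring) to a
    MaterialSpec; unassigned positions are simply absent from the map.
    """

    phantom_diameter_mm: float = 100.0
    rod_diameter_mm: float = 10.0
    positions: tuple = ()
    assignment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = tuple((float(x), float(y)) for x, y in self.positions)
        object.__setattr__(self, "positions", pos)
        if len(pos) != 8:
            raise ValueError("a layout has exactly 8 rod positions")
        r_rod = self.rod_diameter_mm / 2.0
        r_ph = self.phantom_diameter_mm / 2.0
        for i, (x, y) in enumerate(pos):
            if math.hypot(x, y) + r_rod > r_ph + 1e-9:
                raise ValueError(f"rod position {i} crosses the phantom boundary")
        for i in range(8):
            for j in range(i + 1, 8):
                d = math.dist(pos[i], pos[j])
                if d < self.rod_diameter_mm - 1e-9:
                    raise ValueError(f"rods {i} and {j} overlap")

    def materials(self) -> list[MaterialSpec]:
        return [self.assignment[k] for k in sorted(self.assignment)]


def standard_positions(phantom_diameter_mm: float = 100.0,
                       ring_radius_frac: float = 0.325) -> tuple:
    """One central position plus 7 equally spaced on a ring."""
    r = ring_radius_frac * phantom_diameter_mm
    pos = [(0.0, 0.0)]
    for k in range(7):
        a = 2.0 * math.pi * k / 7.0
        pos.append((r * math.cos(a), r * math.sin(a)))
    return tuple(pos)


@dataclass(frozen=True)
class AcquisitionParams:
    """Scan geometry, spectral binning and noise model parameters.

    ``voxel_size_mm=None`` derives the voxel pitch from a field of view of
    1.3x the phantom diameter divided by ``image_size`` (0.1 mm at 1300
    voxels, matching high-resolution photon-counting reconstructions of a
    100 mm object).
    """

    bin_edges_keV: tuple = (7.0, 12.0, 15.0, 18.0, 21.0, 120.0)
    voxel_size_mm: float | None = None
    n_slices: int = 100
    image_size: int = 512
    noise_sigma0: float = 0.005
    bias_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.bin_edges_keV)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly ascending")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        for name in ("noise_sigma0", "bias_amplitude"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        object.__setattr__(self, "bin_edges_keV", edges)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges_keV) - 1

    def resolved_voxel_size(self, phantom_diameter_mm: float) -> float:
        if self.voxel_size_mm is not None:
            return float(self.voxel_size_mm)
        return 1.3 * phantom_diameter_mm / self.image_size

    @property
    def bin_widths(self) -> np.ndarray:
        e = np.asarray(self.bin_edges_keV)
        return e[1:] - e[:-1]

    def bin_sigmas(self) -> np.ndarray:
        """Per-bin noise SD: sigma0 * sqrt(w_ref / w_f), w_ref = widest bin."""
        w = self.bin_widths
        return self.noise_sigma0 * np.sqrt(w.max() / w)


def make_layouts(n_scans: int,
                 materials: list[MaterialSpec] | None = None,
                 rng_seed: int = 0,
                 ensure_coverage: bool = True,
                 always_include: tuple = ALWAYS_INCLUDE_DEFAULT,
                 phantom_diameter_mm: float = 100.0,
                 rod_diameter_mm: float = 10.0) -> list[PhantomLayout]:
    """Draw ``n_scans`` rod assignments, deterministically in ``rng_seed``.

    Every layout fills all 8 positions with distinct materials.  Materials
    named in ``always_include`` appear in every scan (default: the two
    engineered HA/iodine confusable pairs, so the hard case is probed in
    whichever scan is held out); the remaining positions rotate through the
    other materials so that, when ``ensure_coverage`` is set, every material
    of the table appears in at least one scan.

    Raises
    ------
    CoverageError
        If coverage is requested but 8 * n_scans < len(materials).
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if materials is None:
        materials = default_materials()
    n_mat = len(materials)
    if ensure_coverage and 8 * n_scans < n_mat:
        raise CoverageError(
            f"cannot cover {n_mat} materials with {n_scans} scans of 8 rods")
    by_name = {m.name: m for m in materials}
    fixed = [by_name[n] for n in always_include if n in by_name]
    others = [m for m in materials if m.name not in set(always_include)]
    n_free = 8 - len(fixed)
    if n_free < 0:
        raise ValueError("always_include larger than the 8 rod positions")

    rng = np.random.default_rng(rng_seed)
    positions = standard_positions(phantom_diameter_mm)
    layouts = []
    for s in range(n_scans):
        if others and n_free > 0:
            if n_free <= len(others):
                # rotate through non-fixed materials for cross-scan coverage
                idx = [(s * n_free + j) % len(others) for j in range(n_free)]
                chosen = fixed + [others[i] for i in sorted(set(idx))]
            else:
                chosen = fixed + list(others)
        else:
            chosen = list(fixed)
        chosen = chosen[:8]
        order = rng.permutation(len(chosen))
        assignment = {int(p): chosen[k] for p, k in enumerate(order)}
        layouts.append(PhantomLayout(phantom_diameter_mm, rod_diameter_mm,
                                     positions, assignment))
    if ensure_coverage:
        seen = {m.name for lay in layouts for m in lay.assignment.values()}
        missing = [m for m in materials if m.name not in seen]
        if missing:  # fill remaining free slots deterministically
            raise CoverageError(
                f"coverage shortfall for materials {[m.name for m in missing]}")
    return layouts


def _radial_bias(acq: AcquisitionParams, layout: PhantomLayout,
                 xx_mm: np.ndarray, yy_mm: np.ndarray) -> np.ndarray:
    """Multiplicative cupping field: 1 - A*(1 - (r/R)^2) inside the phantom."""
    r2 = (xx_mm ** 2 + yy_mm ** 2) / (layout.phantom_diameter_mm / 2.0) ** 2
    return 1.0 - acq.bias_amplitude * np.clip(1.0 - r2, 0.0, None)


def render_scan(layout: PhantomLayout, acq: AcquisitionParams,
                ) -> tuple[SpectralVolume, LabelVolume]:
    """Rasterize one scan: (Z, F, H, W) intensities and (Z, H, W) labels.

    Rods traverse the full Z extent, so every slice shows the same geometry;
    slices differ only in their noise realization.  Labels use a
    voxel-center inclusion test against each rod disk; the phantom bulk is
    rendered with water intensity but labeled background (water is a class
    only where a water rod is placed).
    """
    F = acq.n_bins
    n = acq.image_size
    vox = acq.resolved_voxel_size(layout.phantom_diameter_mm)
    # voxel-center coordinates in mm, image centered on the phantom axis
    coords = (np.arange(n) - (n - 1) / 2.0) * vox
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    r_ph = layout.phantom_diameter_mm / 2.0
    inside = xx ** 2 + yy ** 2 <= r_ph ** 2

    for m in layout.assignment.values():
        if len(m.mu) != F:
            raise ValueError("material signature length differs from F")
    from .materials import MU_WATER  # water-filled phantom bulk
    if len(MU_WATER) == F:
        water_mu = MU_WATER
    else:  # non-default binning: flat water filler
        water_mu = np.full(F, float(MU_WATER.mean()))

    label2d = np.zeros((n, n), dtype=np.uint8)
    mean2d = np.zeros((F, n, n), dtype=np.float64)
    mean2d[:, inside] = np.asarray(water_mu)[:, None]
    r_rod = layout.rod_diameter_mm / 2.0
    for pos_idx, mat in layout.assignment.items():
        cx, cy = layout.positions[pos_idx]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_rod ** 2
        label2d[mask] = mat.class_id
        mean2d[:, mask] = mat.mu[:, None]

    mean2d *= _radial_bias(acq, layout, xx, yy)[None, :, :]

    rng = np.random.default_rng(acq.seed)
    sigmas = acq.bin_sigmas()
    values = np.empty((acq.n_slices, F, n, n), dtype=np.float32)
    for z in range(acq.n_slices):
        noise = rng.standard_normal((F, n, n)) * sigmas[:, None, None]
        values[z] = (mean2d + noise).astype(np.float32)
    labels = np.broadcast_to(label2d, (acq.n_slices, n, n)).copy()
    vol = SpectralVolume(values, np.asarray(acq.bin_edges_keV), vox)
    return vol, LabelVolume(labels)
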