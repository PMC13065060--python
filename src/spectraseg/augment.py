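"""Training-time augmentations for multi-energy slices.

The central one is the grid-puzzle permutation: a slice is partitioned into
a g x g grid and the tiles are shuffled with a single permutation applied
identically to *all* energy bins and to the label map.  This destroys
global geometry (rod contours, ring layout) while leaving every voxel's
spectral vector paired with its label, forcing the classifier to rely on
energy-dependent attenuation rather than shape priors.  Flips/rotations act
in-plane only (the energy axis is never touched), and intensity jitter is a
single multiplicative gain shared across bins plus i.i.d. Gaussian noise —
a per-bin gain would corrupt the spectral signature the model must learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AugmentParams", "PuzzleRecord",
    "grid_puzzle", "invert_grid_puzzle",
    "spatial_flips_rots", "intensity_jitter", "augment_sample",
]


@dataclass(frozen=True)
class AugmentParams:
    """Augmentation configuration; all of it is inert unless ``train_mode``."""

    g_max: int = 10
    enable_flips: bool = True
    enable_rot90: bool = True
    brightness_range: tuple = (0.9, 1.1)
    noise_sigma: float = 0.01
    train_mode: bool = True

    def __post_init__(self) -> None:
        if self.g_max < 1:
            raise ValueError("g_max must be >= 1")
        lo, hi = self.brightness_range
        if lo > hi:
            raise ValueError("brightness_range must satisfy lo <= hi")


@dataclass(frozen=True)
class PuzzleRecord:
    """Everything needed to invert a grid-puzzle application exactly."""

    g: int
    tile_h: int
    tile_w: int
    permutation: np.ndarray  # tile k of the output came from tile perm[k]


def _tiles_view(arr: np.ndarray, g: int, th: int, tw: int) -> np.ndarray:
    """(..., g*th, g*tw) region -> (..., g, g, th, tw) tile view."""
    lead = arr.shape[:-2]
    v = arr[..., : g * th, : g * tw]
    v = v.reshape(*lead, g, th, g, tw)
    return np.moveaxis(v, -2, -3)  # (..., g, g, th, tw)


def _apply_tile_perm(arr: np.ndarray, rec: PuzzleRecord) -> np.ndarray:
    g, th, tw = rec.g, rec.tile_h, rec.tile_w
    out = arr.copy()
    tiles = _tiles_view(arr, g, th, tw).reshape(*arr.shape[:-2], g * g, th, tw)
    shuffled = tiles[..., rec.permutation, :, :]
    blk = shuffled.reshape(*arr.shape[:-2], g, g, th, tw)
    blk = np.moveaxis(blk, -3, -2).reshape(*arr.shape[:-2], g * th, g * tw)
    out[..., : g * th, : g * tw] = blk
    return out


def grid_puzzle(image_slice: np.ndarray, label_slice: np.ndarray, g: int,
                rng: np.random.Generator,
                ) -> tuple[np.ndarray, np.ndarray, PuzzleRecord]:
    """Permute g*g equal tiles, identically across bins and labels.

    The top-left ``g*floor(H/g) x g*floor(W/g)`` region is tiled; any
    remainder border (when H or W is not divisible by g) stays in place.
    ``g=1`` is the identity.  Returns the permuted image (F, H, W), labels
    (H, W), and a :class:`PuzzleRecord` that inverts the operation exactly.
    """
    F_, H, W = image_slice.shape
    if label_slice.shape != (H, W):
        raise ValueError("label shape does not match image")
    if g < 1 or g > min(H, W):
        raise ValueError(f"grid size g={g} invalid for a {H}x{W} slice")
    th, tw = H // g, W // g
    if g == 1:
        rec = PuzzleRecord(1, th, tw, np.arange(1))
        return image_slice.copy(), label_slice.copy(), rec
    perm = rng.permutation(g * g)
    rec = PuzzleRecord(g, th, tw, perm)
    return (_apply_tile_perm(image_slice, rec),
            _apply_tile_perm(label_slice, rec), rec)


def invert_grid_puzzle(image_slice: np.ndarray, label_slice: np.ndarray,
                       rec: PuzzleRecord) -> tuple[np.ndarray, np.ndarray]:
    """Undo :func:`grid_puzzle` bit-exactly using the recorded permutation."""
    inv = np.empty_like(rec.permutation)
    inv[rec.permutation] = np.arange(len(rec.permutation))
    rec_inv = PuzzleRecord(rec.g, rec.tile_h, rec.tile_w, inv)
    return _apply_tile_perm(image_slice, rec_inv), _apply_tile_perm(label_slice, rec_inv)


def spatial_flips_rots(image_slice: np.ndarray, label_slice: np.ndarray,
                       rng: np.random.Generator,
                       flips: bool = True, rots: bool = True,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Random in-plane flips and quarter-turns, identical across energy bins."""
    img, lab = image_slice, label_slice
    if flips:
        if rng.random() < 0.5:
            img, lab = img[..., ::-1, :], lab[..., ::-1, :]
        if rng.random() < 0.5:
            img, lab = img[..., :, ::-1], lab[..., :, ::-1]
    if rots:
        if img.shape[-1] != img.shape[-2]:
            raise ValueError("90-degree rotations require H == W")
        k = int(rng.integers(0, 4))
        img = np.rot90(img, k, axes=(-2, -1))
        lab = np.rot90(lab, k, axes=(-2, -1))
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


def intensity_jitter(image_slice: np.ndarray, rng: np.random.Generator,
                     params: AugmentParams) -> np.ndarray:
    """Global gain a ~ U(brightness_range) plus i.i.d. N(0, noise_sigma) noise."""
    lo, hi = params.brightness_range
    a = rng.uniform(lo, hi)
    out = a * image_slice
    if params.noise_sigma > 0:
        out = out + rng.normal(0.0, params.noise_sigma, size=image_slice.shape)
    return out.astype(image_slice.dtype, copy=False)


def augment_sample(image_slice: np.ndarray, label_slice: np.ndarray,
                   params: AugmentParams, rng: np.random.Generator,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Full training-time pipeline; exact identity when ``train_mode`` is off.

    Order: grid puzzle (g drawn uniformly from 1..g_max, applied when g>1),
    then flips/rotations, then intensity jitter.
    """
    if not params.train_mode:
        return image_slice, label_slice
    g = int(rng.integers(1, params.g_max + 1))
    if g > 1:
        image_slice, label_slice, _ = grid_puzzle(image_slice, label_slice, g, rng)
    image_slice, label_slice = spatial_flips_rots(
        image_slice, label_slice, rng,
        flips=params.enable_flips, rots=params.enable_rot90)
    image_slice = intensity_jitter(image_slice, rng, params)
    return image_slice, label_slice
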