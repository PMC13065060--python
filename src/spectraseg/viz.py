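"""Overlay rendering and slice-error band plots.

The overlay backdrop is the mean over energy bins, min-max windowed per
slice; labels are alpha-blended with a fixed 13-color palette (background
transparent), so the same label always gets the same color in every
figure.  Overlays are written with PIL and are byte-identical for
identical inputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["CLASS_PALETTE", "render_overlay", "render_error_band_plot"]

#: RGB palette per class id; index 0 (background) is transparent.
CLASS_PALETTE = {
    0: None,
    1: (141, 211, 199),   # HA50
    2: (255, 255, 179),   # HA100
    3: (190, 186, 218),   # HA200
    4: (251, 128, 114),   # HA400
    5: (128, 177, 211),   # HA800
    6: (253, 180, 98),    # I5
    7: (179, 222, 105),   # I10
    8: (252, 205, 229),   # I15
    9: (217, 217, 217),   # adipose
    10: (188, 128, 189),  # liver
    11: (204, 235, 197),  # lung
    12: (255, 237, 111),  # water
}


def render_overlay(spectral_slice: np.ndarray, label_map: np.ndarray,
                   path, alpha: float = 0.5) -> Path:
    """Blend a label map over the bin-averaged grayscale slice; write PNG."""
    from PIL import Image

    if spectral_slice.shape[-2:] != label_map.shape:
        raise ValueError("label map not aligned with slice")
    gray = spectral_slice.mean(axis=0).astype(np.float64)
    lo, hi = gray.min(), gray.max()
    gray = (gray - lo) / (hi - lo) if hi > lo else np.zeros_like(gray)
    rgb = np.repeat((gray * 255).astype(np.uint8)[..., None], 3, axis=-1)
    for cid, color in CLASS_PALETTE.items():
        if color is None:
            continue
        mask = label_map == cid
        if mask.any():
            blended = (1 - alpha) * rgb[mask] + alpha * np.asarray(color)
            rgb[mask] = blended.astype(np.uint8)
    path = Path(path)
    Image.fromarray(rgb).save(path, format="PNG")
    return path


def render_error_band_plot(series_record: dict, path, title: str = "",
                           ) -> Path:
    """Plot e = 1 - Dice per slice with its mean and +/-1.96 SD band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    slices = np.asarray(series_record["slices"])
    errors = np.asarray(series_record["errors"])
    if errors.size == 0:
        raise ValueError("empty error series")
    mean = series_record["mean"]
    hw = series_record["half_width"]
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.plot(slices, errors, ".", ms=4, color="0.4", label="per-slice error")
    ax.axhline(mean, color="C0", lw=2, label="mean")
    ax.fill_between(slices, mean - hw, mean + hw, color="C0", alpha=0.2,
                    label="mean ± 1.96 SD")
    ax.set_xlabel("test slice index")
    ax.set_ylabel("e = 1 − Dice")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
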