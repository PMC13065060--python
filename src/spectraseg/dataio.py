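"""On-disk formats: per-scan array containers, dataset manifests, NIfTI export.

The native container for one scan is a compressed ``.npz`` archive with keys

========== ======================= =========================================
key        dtype / shape           meaning
========== ======================= =========================================
image      float32 (Z, F, H, W)    per-bin reconstructed intensities
labels     uint8   (Z, H, W)       voxel class map, 0 = background
bin_edges  float64 (F+1,)          energy-bin edges in keV
voxel_size float64 scalar          in-plane voxel pitch in mm
scan_id    str                     scan identifier
========== ======================= =========================================

The dataset manifest is a JSON file recording the material table, every
layout, the acquisition parameters and all per-scan seeds — enough to
regenerate the arrays bit-identically (`regenerate_scan`).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .materials import MaterialSpec, default_materials
from .phantom import (AcquisitionParams, LabelVolume, PhantomLayout,
                      SpectralVolume, make_layouts, render_scan)

__all__ = [
    "save_scan", "load_scan", "simulate_dataset", "load_manifest",
    "regenerate_scan", "export_nifti",
]

MANIFEST_NAME = "manifest.json"


def save_scan(path: str | Path, vol: SpectralVolume, lab: LabelVolume,
              scan_id: str) -> None:
    path = Path(path)
    try:
        np.savez_compressed(
            path,
            image=vol.values.astype(np.float32),
            labels=lab.labels,
            bin_edges=np.asarray(vol.bin_edges_keV, dtype=np.float64),
            voxel_size=np.float64(vol.voxel_size_mm),
            scan_id=np.str_(scan_id),
        )
    except OSError as exc:
        raise OSError(f"cannot write scan container {path}: {exc}") from exc


def load_scan(path: str | Path) -> tuple[SpectralVolume, LabelVolume, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scan container not found: {path}")
    with np.load(path, allow_pickle=False) as z:
        vol = SpectralVolume(z["image"], z["bin_edges"], float(z["voxel_size"]))
        lab = LabelVolume(z["labels"])
        scan_id = str(z["scan_id"])
    return vol, lab, scan_id


def _scan_seed(base_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=[int(base_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _layout_record(layout: PhantomLayout) -> dict:
    return {
        "phantom_diameter_mm": layout.phantom_diameter_mm,
        "rod_diameter_mm": layout.rod_diameter_mm,
        "positions": [list(p) for p in layout.positions],
        "assignment": {str(k): m.name for k, m in layout.assignment.items()},
    }


def _layout_from_record(rec: dict, materials: list[MaterialSpec]) -> PhantomLayout:
    by_name = {m.name: m for m in materials}
    return PhantomLayout(
        rec["phantom_diameter_mm"], rec["rod_diameter_mm"],
        tuple(tuple(p) for p in rec["positions"]),
        {int(k): by_name[v] for k, v in rec["assignment"].items()},
    )


def simulate_dataset(n_scans: int, acq: AcquisitionParams,
                     out_dir: str | Path,
                     materials: list[MaterialSpec] | None = None,
                     **layout_kwargs) -> dict:
    """Render ``n_scans`` phantom scans into ``out_dir`` and write a manifest.

    Returns the manifest dictionary.  ``n_scans=0`` writes an empty manifest
    and no scan files.  All randomness derives from ``acq.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if materials is None:
        materials = default_materials()
    layouts = make_layouts(n_scans, materials, rng_seed=acq.seed,
                           **layout_kwargs) if n_scans else []

    manifest: dict = {
        "format_version": 1,
        "acquisition": asdict(acq),
        "materials": [
            {"name": m.name, "class_id": m.class_id,
             "concentration": m.concentration, "unit": m.unit,
             "mu": [float(v) for v in m.mu]}
            for m in materials
        ],
        "scans": [],
    }
    for i, layout in enumerate(layouts):
        scan_id = f"scan_{i:03d}"
        seed = _scan_seed(acq.seed, i)
        vol, lab = render_scan(layout, _with_seed(acq, seed))
        fname = f"{scan_id}.npz"
        save_scan(out_dir / fname, vol, lab, scan_id)
        manifest["scans"].append({
            "scan_id": scan_id, "file": fname, "seed": seed,
            "layout": _layout_record(layout),
        })
    with open(out_dir / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _with_seed(acq: AcquisitionParams, seed: int) -> AcquisitionParams:
    from dataclasses import replace
    return replace(acq, seed=seed)


def load_manifest(path: str | Path) -> dict:
    path = Path(path)
    if path.is_dir():
        path = path / MANIFEST_NAME
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    with open(path) as fh:
        return json.load(fh)


def _materials_from_manifest(manifest: dict) -> list[MaterialSpec]:
    return [MaterialSpec(m["name"], m["class_id"], m["concentration"],
                         m["unit"], np.asarray(m["mu"]))
            for m in manifest["materials"]]


def regenerate_scan(manifest: dict, scan_id: str,
                    ) -> tuple[SpectralVolume, LabelVolume]:
    """Re-render one scan from its manifest record (bit-identical contract)."""
    rec = next((s for s in manifest["scans"] if s["scan_id"] == scan_id), None)
    if rec is None:
        raise KeyError(f"scan {scan_id!r} not in manifest")
    materials = _materials_from_manifest(manifest)
    acq_kwargs = dict(manifest["acquisition"])
    acq_kwargs["bin_edges_keV"] = tuple(acq_kwargs["bin_edges_keV"])
    acq = AcquisitionParams(**acq_kwargs)
    layout = _layout_from_record(rec["layout"], materials)
    return render_scan(layout, _with_seed(acq, rec["seed"]))


def export_nifti(vol: SpectralVolume, lab: LabelVolume, out_dir: str | Path,
                 scan_id: str) -> list[Path]:
    """Write one 3-D NIfTI per energy bin plus one label file."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    s = float(vol.voxel_size_mm)
    affine = np.diag([s, s, s, 1.0])
    written = []
    for f in range(vol.n_bins):
        # (Z, H, W) -> (W, H, Z) so in-plane axes are the NIfTI i,j axes
        data = np.transpose(vol.values[:, f], (2, 1, 0)).astype(np.float32)
        p = out_dir / f"{scan_id}_bin{f}.nii"
        nib.save(nib.Nifti1Image(data, affine), str(p))
        written.append(p)
    lab_data = np.transpose(lab.labels, (2, 1, 0)).astype(np.uint8)
    p = out_dir / f"{scan_id}_labels.nii"
    nib.save(nib.Nifti1Image(lab_data, affine), str(p))
    written.append(p)
    return written
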