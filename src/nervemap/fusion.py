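"""Stacking registered per-ring density maps into a 3-D volume.

Slices are ordered apex -> base along Z (slice index 1 = apex), spaced at
the ring thickness (4 mm here). Slices missing from the reference data are
filled by linear interpolation between the nearest present neighbours;
terminal gaps copy the nearest slice. Volumes round-trip through NIfTI
with the correct spacing in the affine. Out-of-tissue voxels use a -1
sentinel (valid densities are >= 0).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "build_volume", "interpolate_missing", "save_nifti", "load_nifti", "FILL_VALUE"]

FILL_VALUE = -1.0


@dataclass
class Volume3D:
    """Z x H x W scalar volume, apex -> base along Z.

    spacing is (dz, dy, dx) in mm; provenance holds one source label per
    slice (a ring id, or "interpolated").
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a Z x H x W grid with Z >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
        if not self.provenance:
            self.provenance = ["" for _ in range(self.voxels.shape[0])]
        if len(self.provenance) != self.voxels.shape[0]:
            raise ValueError("provenance length must equal the slice count")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def slice_means(self, ignore_fill: bool = True) -> np.ndarray:
        """Mean density per slice, excluding fill voxels by default."""
        out = np.empty(self.n_slices)
        for z in range(self.n_slices):
            sl = self.voxels[z]
            valid = sl != FILL_VALUE if ignore_fill else np.ones_like(sl, bool)
            out[z] = sl[valid].mean() if valid.any() else np.nan
        return out


def build_volume(
    slices: list[np.ndarray],
    dz: float = 4.0,
    in_plane_spacing: float = 1.0,
    provenance: list[str] | None = None,
) -> Volume3D:
    """Stack registered density grids apex -> base at spacing ``dz`` mm."""
    if not slices:
        raise ValueError("need at least one slice")
    shapes = {np.asarray(s).shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"all slices must share one shape, got {sorted(shapes)}")
    vox = np.stack([np.asarray(s, dtype=np.float64) for s in slices], axis=0)
    return Volume3D(
        voxels=vox,
        spacing=(float(dz), float(in_plane_spacing), float(in_plane_spacing)),
        provenance=list(provenance) if provenance else [f"slice_{i + 1}" for i in range(len(slices))],
    )


def interpolate_missing(volume: Volume3D, missing: list[int]) -> Volume3D:
    """Fill missing slices from their neighbours to keep the volume
    spatially continuous.

    Interior missing slices are linearly interpolated between the nearest
    non-missing neighbours (inverse-distance weights); terminal missing
    slices copy the nearest non-missing slice. Provenance of filled slices
    is marked "interpolated".
    """
    missing_set = set(int(m) for m in missing)
    z_all = range(volume.n_slices)
    present = [z for z in z_all if z not in missing_set]
    if not present:
        raise ValueError("cannot interpolate: all slices are missing")
    if not missing_set:
        return volume
    vox = volume.voxels.copy()
    prov = list(volume.provenance)
    for z in sorted(missing_set):
        below = [p for p in present if p < z]
        above = [p for p in present if p > z]
        if below and above:
            lo, hi = below[-1], above[0]
            w_hi = (z - lo) / (hi - lo)
            vox[z] = (1.0 - w_hi) * vox[lo] + w_hi * vox[hi]
        elif below:
            vox[z] = vox[below[-1]]
        else:
            vox[z] = vox[above[0]]
        prov[z] = "interpolated"
    return Volume3D(voxels=vox, spacing=volume.spacing, provenance=prov)


def save_nifti(volume: Volume3D, path: str | os.PathLike) -> None:
    """Write the volume as NIfTI (x, y, z data order, spacing in the
    affine) plus a provenance sidecar JSON next to it."""
    path = os.fspath(path)
    dz, dy, dx = volume.spacing
    data = np.transpose(volume.voxels, (2, 1, 0))  # (W, H, Z) -> x, y, z
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), path)
    sidecar = path
    for ext in (".nii.gz", ".nii"):
        if sidecar.endswith(ext):
            sidecar = sidecar[: -len(ext)]
            break
    with open(sidecar + "_provenance.json", "w") as fh:
        json.dump({"slices": volume.provenance}, fh, indent=1)


def load_nifti(path: str | os.PathLike) -> Volume3D:
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    vox = np.transpose(data, (2, 1, 0))
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
    path = os.fspath(path)
    sidecar = path
    for ext in (".nii.gz", ".nii"):
        if sidecar.endswith(ext):
            sidecar = sidecar[: -len(ext)]
            break
    prov: list[str] = []
    if os.path.exists(sidecar + "_provenance.json"):
        with open(sidecar + "_provenance.json") as fh:
            prov = json.load(fh)["slices"]
    return Volume3D(voxels=vox, spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])), provenance=prov)
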