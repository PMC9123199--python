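"""Volume I/O and intensity conditioning for the network.

EPI magnitude volumes are carried as :class:`Volume` (a 3D float32 grid plus
voxel size and affine).  Before entering the generator every volume is
min-max normalized to [-1, 1],

    A_hat = 2 * (A - m) / d,    m = (max + min) / 2,    d = max - min,

and the (m, d) pair is kept so predictions can be mapped back to the input
intensity frame.  For presentation and for all similarity metrics, volumes
in [-1, 1] are rescaled to [0, 1] by ``0.5 * x + 0.5``.

Stride-2 encoders need every axis divisible by ``2**depth``;
:func:`fit_to_network_grid` zero-pads symmetrically (extra voxel on the
trailing side) and records the padding so the inverse crop is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "NormalizedVolume",
    "ConstantVolumeError",
    "normalize_minmax",
    "denormalize",
    "rescale_display",
    "fit_to_network_grid",
    "crop_to_original",
    "read_volume",
    "write_volume",
]


class ConstantVolumeError(ValueError):
    """Raised when a volume has zero intensity range (d = 0)."""


def _default_affine(voxel_size):
    aff = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    return aff


@dataclass
class Volume:
    """A real-valued 3D image with voxel geometry.

    Parameters
    ----------
    data : ndarray
        3D array of finite intensities; stored as float32.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    affine : ndarray, optional
        4x4 voxel-to-world matrix, carried through unchanged.
    """

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = None

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=np.float32)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite voxels")
        self.data = arr
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class NormalizedVolume:
    """A volume mapped to [-1, 1] with its inversion parameters (m, d)."""

    data: np.ndarray
    m: float
    d: float
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = None

    def __post_init__(self):
        if self.d <= 0:
            raise ConstantVolumeError("normalization range d must be positive")


def normalize_minmax(vol: Volume) -> NormalizedVolume:
    """Min-max normalize a volume to [-1, 1].

    Raises
    ------
    ConstantVolumeError
        If the volume is constant (max == min), where the map is undefined.
    """
    a = vol.data
    lo = float(a.min())
    hi = float(a.max())
    d = hi - lo
    if d <= 0:
        raise ConstantVolumeError(
            "cannot normalize a constant volume (max == min)"
        )
    m = (hi + lo) / 2.0
    out = (2.0 * (a.astype(np.float64) - m) / d).astype(np.float32)
    return NormalizedVolume(out, m=m, d=d, voxel_size=vol.voxel_size,
                            affine=vol.affine)


def denormalize(nv: NormalizedVolume) -> Volume:
    """Invert :func:`normalize_minmax` using the stored (m, d)."""
    a = nv.data.astype(np.float64) * nv.d / 2.0 + nv.m
    return Volume(a.astype(np.float32), voxel_size=nv.voxel_size,
                  affine=nv.affine)


def rescale_display(nv) -> Volume:
    """Map a [-1, 1] volume to the [0, 1] display range (0.5 * x + 0.5)."""
    if isinstance(nv, NormalizedVolume):
        data, vs, aff = nv.data, nv.voxel_size, nv.affine
    else:
        data, vs, aff = np.asarray(nv.data), nv.voxel_size, nv.affine
    return Volume(0.5 * data + 0.5, voxel_size=vs, affine=aff)


def _pad_amounts(shape, depth):
    mult = 2 ** depth
    pads = []
    for n in shape:
        target = int(np.ceil(n / mult) * mult)
        total = target - n
        before = total // 2
        after = total - before  # trailing side rounded up
        pads.append((before, after))
    return tuple(pads)


def fit_to_network_grid(vol: Volume, depth: int):
    """Zero-pad each axis to the next multiple of ``2**depth``.

    Returns the padded volume and the per-axis ``(before, after)`` padding,
    which :func:`crop_to_original` inverts exactly.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    pads = _pad_amounts(vol.shape, depth)
    out = np.pad(vol.data, pads, mode="constant")
    return Volume(out, voxel_size=vol.voxel_size, affine=vol.affine), pads


def crop_to_original(vol: Volume, pads) -> Volume:
    """Remove padding recorded by :func:`fit_to_network_grid`."""
    sl = tuple(
        slice(b, n - a if a else n)
        for (b, a), n in zip(pads, vol.shape)
    )
    return Volume(vol.data[sl], voxel_size=vol.voxel_size, affine=vol.affine)


def read_volume(path) -> Volume:
    """Read a NIfTI-1 volume.  Non-finite voxels are rejected."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise IOError(f"{path}: volume contains non-finite voxels")
    zooms = img.header.get_zooms()[:3]
    return Volume(data, voxel_size=tuple(float(z) for z in zooms),
                  affine=img.affine)


def write_volume(vol: Volume, path) -> None:
    """Write a volume as NIfTI-1, recording voxel size in the header."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def write_sidecar(path, payload: dict) -> None:
    """Write a JSON sidecar next to a volume (m, d, padding, spec, ...)."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_sidecar(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
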