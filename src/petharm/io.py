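"""NIfTI-1 volume I/O and the in-memory volume container.

All processing in this package happens on the voxel lattice of
spatially normalized (template-space) images.  The rotational part of a
file's affine is therefore ignored for computation and only carried
through on write; voxel spacing is taken from the header zooms.

Axis convention: axes 0 and 1 span the transaxial (XY) plane, axis 2 is
the axial (Z) direction.  The loader maps the file's i, j, k axes
directly onto 0, 1, 2 and never reorients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "read_volume", "write_volume", "MIN_DIM"]

#: Minimum voxels per axis; local-statistics windows (11^3) must fit.
MIN_DIM = 12


@dataclass
class VolumeGrid:
    """A 3D scalar intensity field on a regular voxel lattice.

    Parameters
    ----------
    data
        3D array of finite intensities (arbitrary activity units).
        Stored internally as float64.
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm, all strictly positive.
    origin_note
        Free-text provenance tag (e.g. the source filename or the
        simulation recipe).
    affine
        Optional 4x4 affine from the source file, kept only for
        pass-through on write; never used in computation.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin_note: str = ""
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < MIN_DIM:
            raise ValueError(
                f"all dimensions must be >= {MIN_DIM} voxels, got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, note: str | None = None) -> "VolumeGrid":
        """A new grid on the same lattice with replaced intensities."""
        return VolumeGrid(
            data=data,
            spacing=self.spacing,
            origin_note=self.origin_note if note is None else note,
            affine=self.affine,
        )

    def same_geometry(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, rtol=0, atol=1e-6
        )


def read_volume(path: str | Path) -> VolumeGrid:
    """Load a NIfTI-1 volume (.nii or .nii.gz) into a :class:`VolumeGrid`.

    4D files with a singleton trailing dimension are squeezed to 3D.
    Raises on missing files, non-3D content, non-finite voxels or
    degenerate header spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D content, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any((not np.isfinite(z)) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: zero/negative voxel spacing in header: {zooms}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    return VolumeGrid(
        data=data,
        spacing=tuple(float(z) for z in zooms),
        origin_note=str(path),
        affine=np.asarray(img.affine, dtype=np.float64),
    )


def write_volume(v: VolumeGrid, path: str | Path) -> None:
    """Write a :class:`VolumeGrid` as a 32-bit float NIfTI-1 file.

    Intensities are relative activity; storing them as float32 keeps
    round-trip error below 1e-6 relative, which is far below any
    physically meaningful precision here.  Spacing is written exactly.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    affine = v.affine if v.affine is not None else np.diag([*v.spacing, 1.0])
    img = nib.Nifti1Image(v.data.astype(np.float32), affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))
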