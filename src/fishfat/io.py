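"""Image-stack containers, acquisition geometry and on-disk formats.

A CHESS fat/water acquisition consists of two magnitude image stacks, one
per chemically selective excitation, sharing one acquisition geometry but
each recorded with its own receiver gain.  Stacks are stored as multi-page
TIFF (one page per axial slice) or NIfTI, selected by file extension, with
a JSON metadata sidecar carrying everything the quantification chain needs
(field of view, matrix, slice geometry, channel label, receiver gain).

Array convention: axis 0 is the axial slice index, axis 1 the image row
(y), axis 2 the image column (x); indexing is 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "ChannelStack",
    "voxel_volume",
    "read_stack",
    "write_stack",
    "sidecar_path",
]

CHANNELS = ("fat", "water")

#: Exact key set of the JSON sidecar written next to every stack.
SIDECAR_KEYS = (
    "channel",
    "fov_mm",
    "matrix",
    "n_slices",
    "slice_thickness_mm",
    "receiver_gain",
    "seed",
    "sigma_truth",
)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Axial multi-slice acquisition geometry.

    Parameters
    ----------
    fov_mm
        In-plane field of view ``(x, y)`` in millimetres.
    matrix
        In-plane acquisition matrix ``(nx, ny)``.
    n_slices
        Number of axial slices.
    slice_thickness_mm
        Slice thickness in millimetres.
    """

    fov_mm: tuple[float, float]
    matrix: tuple[int, int]
    n_slices: int
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "fov_mm", tuple(float(v) for v in self.fov_mm))
        object.__setattr__(self, "matrix", tuple(int(v) for v in self.matrix))
        if len(self.fov_mm) != 2 or len(self.matrix) != 2:
            raise ValueError("fov_mm and matrix must each have two components")
        if any(v <= 0 for v in self.fov_mm):
            raise ValueError(f"field of view must be positive, got {self.fov_mm}")
        if any(v <= 0 for v in self.matrix):
            raise ValueError(f"matrix must be positive, got {self.matrix}")
        if self.n_slices <= 0:
            raise ValueError(f"n_slices must be positive, got {self.n_slices}")
        if self.slice_thickness_mm <= 0:
            raise ValueError(
                f"slice_thickness_mm must be positive, got {self.slice_thickness_mm}"
            )

    @property
    def pixel_size_mm(self) -> tuple[float, float]:
        """In-plane voxel edge lengths ``(dx, dy)`` in mm."""
        return (self.fov_mm[0] / self.matrix[0], self.fov_mm[1] / self.matrix[1])

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape ``(n_slices, ny, nx)``."""
        return (self.n_slices, self.matrix[1], self.matrix[0])

    @property
    def slab_depth_mm(self) -> float:
        """Axial extent covered by the slice stack, in mm."""
        return self.n_slices * self.slice_thickness_mm

    def voxel_volume_mm3(self) -> float:
        dx, dy = self.pixel_size_mm
        return dx * dy * self.slice_thickness_mm

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable voxel-center coordinates (z, y, x), origin at the
        geometric center of the imaged slab."""
        dx, dy = self.pixel_size_mm
        dz = self.slice_thickness_mm
        z = (np.arange(self.n_slices) + 0.5) * dz - self.slab_depth_mm / 2
        y = (np.arange(self.matrix[1]) + 0.5) * dy - self.fov_mm[1] / 2
        x = (np.arange(self.matrix[0]) + 0.5) * dx - self.fov_mm[0] / 2
        return (
            z[:, None, None],
            y[None, :, None],
            x[None, None, :],
        )


def voxel_volume(geometry: AcquisitionGeometry) -> float:
    """Volume of one voxel in mm^3: ``(fov_x/nx) * (fov_y/ny) * thickness``.

    For the printed zebrafish protocol (16 x 16 mm field of view, 128 x 128
    matrix, 0.5 mm slices) this is 7.8125e-3 mm^3, i.e. 7.81 in units of
    1e-3 mm^3.
    """
    return geometry.voxel_volume_mm3()


@dataclass
class ChannelStack:
    """One magnitude image stack (fat or water channel) with its metadata.

    Intensities are non-negative magnitude values in arbitrary scanner
    units; ``receiver_gain`` is the amplification the scanner applied to
    this channel and must be divided out before channels are compared.
    """

    channel: str
    data: np.ndarray
    receiver_gain: float
    geometry: AcquisitionGeometry
    seed: int | None = None
    sigma_truth: float | None = None

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        self.data = np.asarray(self.data)
        if self.data.shape != self.geometry.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match geometry "
                f"shape {self.geometry.shape}"
            )
        if np.any(self.data < 0):
            raise ValueError("magnitude intensities must be non-negative")
        if not self.receiver_gain > 0:
            raise ValueError(f"receiver gain must be positive, got {self.receiver_gain}")

    def with_data(self, data: np.ndarray, **changes) -> "ChannelStack":
        """Copy of this stack with new voxel data (and optional field changes)."""
        return ChannelStack(
            channel=changes.get("channel", self.channel),
            data=data,
            receiver_gain=changes.get("receiver_gain", self.receiver_gain),
            geometry=self.geometry,
            seed=self.seed,
            sigma_truth=self.sigma_truth,
        )


def sidecar_path(path: str | Path) -> Path:
    """Path of the JSON sidecar belonging to a stack file."""
    path = Path(path)
    return path.with_name(path.name + ".json")


def _sidecar_dict(stack: ChannelStack) -> dict:
    geom = stack.geometry
    return {
        "channel": stack.channel,
        "fov_mm": list(geom.fov_mm),
        "matrix": list(geom.matrix),
        "n_slices": geom.n_slices,
        "slice_thickness_mm": geom.slice_thickness_mm,
        "receiver_gain": stack.receiver_gain,
        "seed": stack.seed,
        "sigma_truth": stack.sigma_truth,
    }


def write_stack(stack: ChannelStack, path: str | Path) -> tuple[Path, Path]:
    """Write a stack plus its JSON sidecar; format chosen by extension.

    ``.tif``/``.tiff`` writes one TIFF page per axial slice; ``.nii`` /
    ``.nii.gz`` writes a NIfTI volume with the voxel sizes in the affine.
    Returns the (stack path, sidecar path) actually written.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, stack.data)
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        dx, dy = stack.geometry.pixel_size_mm
        affine = np.diag([dx, dy, stack.geometry.slice_thickness_mm, 1.0])
        # NIfTI stores x fastest: transpose (slice, y, x) -> (x, y, slice).
        img = nib.Nifti1Image(np.ascontiguousarray(stack.data.T), affine)
        nib.save(img, path)
    else:
        raise ValueError(
            f"unsupported stack format {path.name!r}; use .tif/.tiff or .nii/.nii.gz"
        )
    side = sidecar_path(path)
    side.write_text(json.dumps(_sidecar_dict(stack), indent=1))
    return path, side


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> ChannelStack:
    """Read a stack written by :func:`write_stack`.

    The sidecar defaults to ``<path>.json``.  All sidecar keys are
    required; a missing key raises ``ValueError`` naming it, and a sidecar
    whose geometry disagrees with the array shape is rejected.
    """
    path = Path(path)
    side = Path(sidecar) if sidecar is not None else sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not side.exists():
        raise FileNotFoundError(f"sidecar not found: {side}")
    meta = json.loads(side.read_text())
    for key in SIDECAR_KEYS:
        if key not in meta:
            raise ValueError(f"sidecar {side} is missing required key {key!r}")

    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        data = tifffile.imread(path)
        if data.ndim == 2:  # single-slice stack
            data = data[None]
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asanyarray(nib.load(path).dataobj).T
    else:
        raise ValueError(f"unsupported stack format {path.name!r}")

    geometry = AcquisitionGeometry(
        fov_mm=tuple(meta["fov_mm"]),
        matrix=tuple(meta["matrix"]),
        n_slices=meta["n_slices"],
        slice_thickness_mm=meta["slice_thickness_mm"],
    )
    if data.shape != geometry.shape:
        raise ValueError(
            f"stack shape {data.shape} does not match sidecar geometry {geometry.shape}"
        )
    return ChannelStack(
        channel=meta["channel"],
        data=data,
        receiver_gain=meta["receiver_gain"],
        geometry=geometry,
        seed=meta["seed"],
        sigma_truth=meta["sigma_truth"],
    )
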