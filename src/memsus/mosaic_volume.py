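"""Volumetric stacking, Gaussian-apodized mosaicking, MIP and slicing.

B-mode frames acquired at successive elevational (Y) stage positions stack
into a local volume; local volumes acquired at successive lateral (X)
stage positions merge into one seam-free global volume.  Each local volume
is weighted along X by a Gaussian window centered on the tile,
``w(x) = exp(-(x - x_c)^2 / (2 sigma^2))`` with ``sigma = sigma_frac *
tile_width``, and the global voxel is the weight-normalized sum of the
contributing tiles.  The X extent of the mosaic obeys
``width + (n - 1) * step``: six 10 mm tiles at 4 mm steps span 30 mm, four
13 mm tiles at 4 mm steps span 25 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scan_convert import BModeImage

__all__ = [
    "LocalVolume",
    "GlobalVolume",
    "stack_local",
    "merge_mosaic",
    "seam_metric",
    "mip",
    "slice_volume",
]

_AXES = {"X": 0, "Y": 1, "Z": 2}
_PLANES = {"XY": 2, "XZ": 1, "YZ": 0}  # plane -> axis whose index is fixed


@dataclass
class LocalVolume:
    """One stage-position acquisition: voxels[ix, iy, iz] in dB."""

    voxels: np.ndarray
    voxel_spacing: tuple[float, float, float]
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3-D (X, Y, Z)")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size along each axis, m (voxel count x spacing)."""
        return tuple(
            n * s for n, s in zip(self.voxels.shape, self.voxel_spacing)
        )

    @property
    def x_center(self) -> float:
        return self.offset[0] + self.extent[0] / 2.0


@dataclass
class GlobalVolume:
    """Apodization-merged mosaic with provenance."""

    voxels: np.ndarray
    voxel_spacing: tuple[float, float, float]
    offset: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(
            n * s for n, s in zip(self.voxels.shape, self.voxel_spacing)
        )


def stack_local(frames: list[BModeImage], y_step: float) -> LocalVolume:
    """Stack B-mode frames into constant-Y slabs at ``index * y_step``."""
    if not frames:
        raise ValueError("need at least one frame")
    if y_step <= 0:
        raise ValueError("y_step must be positive")
    shape = frames[0].pixels.shape
    spacing = frames[0].pixel_spacing
    origin = frames[0].origin
    for f in frames[1:]:
        if f.pixels.shape != shape or f.pixel_spacing != spacing:
            raise ValueError("all frames must share one grid")
    voxels = np.stack([f.pixels for f in frames], axis=1)
    return LocalVolume(
        voxels=voxels,
        voxel_spacing=(spacing[0], y_step, spacing[1]),
        offset=(origin[0], 0.0, origin[1]),
    )


def _check_lattice(locals_: list[LocalVolume]) -> None:
    spacing = locals_[0].voxel_spacing
    for lv in locals_[1:]:
        if not np.allclose(lv.voxel_spacing, spacing, rtol=1e-9):
            raise ValueError("local volumes must share one voxel spacing")
    base = np.asarray(locals_[0].offset)
    for lv in locals_[1:]:
        steps = (np.asarray(lv.offset) - base) / np.asarray(spacing)
        if not np.allclose(steps, np.round(steps), atol=1e-6):
            raise ValueError(
                "local-volume offsets must lie on the voxel lattice "
                f"(offending offset {lv.offset})"
            )


def merge_mosaic(
    locals_: list[LocalVolume],
    sigma_frac: float = 0.25,
    window: str = "gaussian",
) -> GlobalVolume:
    """Merge lattice-aligned local volumes into one global mosaic.

    window='gaussian'
        Each tile is weighted along X by a Gaussian of sigma
        ``sigma_frac * tile X-width`` centered on the tile; global voxels
        are the weight-normalized sums.  Large ``sigma_frac`` approaches
        plain averaging in the overlaps.
    window='cut'
        Hard abutment: each voxel taken from the tile whose X center is
        nearest (the seam-prone reference against which apodization is
        judged).
    """
    if not locals_:
        raise ValueError("need at least one local volume")
    if window not in ("gaussian", "cut"):
        raise ValueError("window must be 'gaussian' or 'cut'")
    _check_lattice(locals_)
    spacing = locals_[0].voxel_spacing
    dx, dy, dz = spacing

    # Gap check along X: union of tile intervals must be contiguous.
    intervals = sorted(
        (lv.offset[0], lv.offset[0] + lv.extent[0]) for lv in locals_
    )
    reach = intervals[0][1]
    for lo, hi in intervals[1:]:
        if lo > reach + dx / 2.0:
            raise ValueError(
                f"disjoint local volumes: gap in X between {reach * 1e3:.3f} "
                f"and {lo * 1e3:.3f} mm"
            )
        reach = max(reach, hi)

    origin = tuple(min(lv.offset[k] for lv in locals_) for k in range(3))
    top = tuple(
        max(lv.offset[k] + lv.extent[k] for lv in locals_) for k in range(3)
    )
    shape = tuple(
        int(round((top[k] - origin[k]) / spacing[k])) for k in range(3)
    )

    acc = np.zeros(shape)
    wsum3 = np.zeros(shape)  # weights vary along X but coverage is 3-D
    x_axis = origin[0] + (np.arange(shape[0]) + 0.5) * dx

    if window == "cut":
        centers = np.array([lv.x_center for lv in locals_])

    for i, lv in enumerate(locals_):
        i0 = tuple(
            int(round((lv.offset[k] - origin[k]) / spacing[k])) for k in range(3)
        )
        sl = tuple(
            slice(i0[k], i0[k] + lv.voxels.shape[k]) for k in range(3)
        )
        xs = x_axis[sl[0]]
        if window == "gaussian":
            sigma = sigma_frac * lv.extent[0]
            w = np.exp(-((xs - lv.x_center) ** 2) / (2.0 * sigma**2))
        else:
            # weight 1 where this tile's center is the nearest, else 0
            dist = np.abs(xs - lv.x_center)
            others = np.min(
                np.abs(xs[:, None] - np.delete(centers, i)[None, :]), axis=1
            ) if len(locals_) > 1 else np.full_like(xs, np.inf)
            w = (dist <= others).astype(float)
        acc[sl] += w[:, None, None] * lv.voxels
        wsum3[sl] += np.broadcast_to(w[:, None, None], lv.voxels.shape)

    with np.errstate(invalid="ignore", divide="ignore"):
        voxels = np.where(wsum3 > 0, acc / np.maximum(wsum3, 1e-300), 0.0)

    return GlobalVolume(
        voxels=voxels,
        voxel_spacing=spacing,
        offset=origin,
        provenance={
            "tile_offsets_m": [list(lv.offset) for lv in locals_],
            "sigma_frac": sigma_frac,
            "window": window,
        },
    )


def seam_metric(
    vol: GlobalVolume, seam_positions: list[float]
) -> float:
    """Mean |dV/dx| (dB per voxel) within +/-1 voxel of the seam planes."""
    dx = vol.voxel_spacing[0]
    grad = np.abs(np.diff(vol.voxels, axis=0))
    nx = grad.shape[0]
    sel = []
    for x in seam_positions:
        ix = int(round((x - vol.offset[0]) / dx))
        if not 0 <= ix < vol.voxels.shape[0]:
            raise ValueError(f"seam position {x * 1e3:.3f} mm outside the volume")
        lo, hi = max(ix - 1, 0), min(ix + 1, nx)
        sel.append(grad[lo:hi])
    if not sel:
        raise ValueError("no seam positions given")
    return float(np.concatenate(sel, axis=0).mean())


def mip(vol: GlobalVolume | LocalVolume, axis: str = "Z") -> np.ndarray:
    """Maximum intensity projection along X, Y or Z."""
    try:
        ax = _AXES[axis.upper()]
    except KeyError:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    return vol.voxels.max(axis=ax)


def slice_volume(
    vol: GlobalVolume | LocalVolume, plane: str, index: int
) -> np.ndarray:
    """Extract one orthogonal plane (XY, XZ or YZ) at ``index``."""
    try:
        ax = _PLANES[plane.upper()]
    except KeyError:
        raise ValueError(f"plane must be one of {sorted(_PLANES)}, got {plane!r}")
    n = vol.voxels.shape[ax]
    if not 0 <= index < n:
        raise IndexError(f"index {index} out of range [0, {n}) for plane {plane}")
    return np.take(vol.voxels, index, axis=ax)
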