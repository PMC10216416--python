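"""Geometry preprocessing: isotropic resampling, VOI extraction, slice-stack standardization.

Conventions used throughout the package:

* voxel arrays are indexed ``[x, y, z]`` with physical spacing in mm per axis;
* voxel indices are 0-based; bounding boxes are inclusive index ranges;
* intensities are Hounsfield units (HU) and are never rescaled on the
  hand-crafted feature path — only the CNN path applies a display window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .errors import ConfigurationError, EmptySegmentationError

#: Soft-tissue display window (HU) used to normalize CNN inputs to [0, 1].
DEFAULT_WINDOW = (-160.0, 240.0)

#: Target z-slice count for the standardized stack (median node z-extent).
DEFAULT_Z_SLICES = 10

#: Canonical backbone input scale.
DEFAULT_XY_SIZE = (224, 224)


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical geometry.

    Attributes
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Intensities in HU (or a binary mask cast to a numeric dtype).
    spacing : tuple of float
        Voxel edge lengths in mm per axis.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ConfigurationError("ImageVolume requires a 3D voxel array")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"spacing must be positive, got {self.spacing}")
        # NaN is permitted (out-of-mask sentinel in derived feature maps);
        # infinities never are.
        if np.isinf(self.voxels).any():
            raise ConfigurationError("ImageVolume intensities must not be infinite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class NodeVOI:
    """A node cropped to its mask bounding box, with provenance.

    ``image.voxels`` and ``mask`` share shape and spacing.  Out-of-mask voxels
    may carry a fill value (CNN path) or the original background (hand-crafted
    path, where features only ever touch in-mask voxels).
    """

    image: ImageVolume
    mask: np.ndarray
    patient_id: str | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.image.voxels.shape:
            raise ConfigurationError("mask and image shapes differ")
        if not self.mask.any():
            raise EmptySegmentationError("NodeVOI mask is empty")

    @property
    def in_mask_values(self) -> np.ndarray:
        """Flat array of the in-mask intensities (HU)."""
        return self.image.voxels[self.mask]


@dataclass
class SliceStack:
    """Fixed-shape normalized slice stack fed to the deep extractor.

    ``slices`` has shape ``(n_slices, height, width)`` with values in
    ``intensity_range`` (default [0, 1]).  ``support``, when present, is a
    same-shaped boolean array marking the node's spatial support on the
    canvas; pooled deep features are averaged over it so that the node's
    area on the canvas does not leak into every feature.
    """

    slices: np.ndarray
    intensity_range: tuple[float, float] = (0.0, 1.0)
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3:
            raise ConfigurationError("SliceStack requires (n_slices, h, w)")
        if self.support is not None:
            self.support = np.asarray(self.support).astype(bool)
            if self.support.shape != self.slices.shape:
                raise ConfigurationError("support and slices shapes differ")


def resample_isotropic(
    volume: ImageVolume, target_spacing_mm: float, is_mask: bool = False
) -> ImageVolume:
    """Resample a volume to isotropic voxels of edge ``target_spacing_mm``.

    The output grid has ``round(size * spacing / target)`` voxels per axis.
    Images are linearly interpolated; masks use nearest-neighbour so they stay
    strictly binary.  Intensities are never rescaled.
    """
    if target_spacing_mm <= 0:
        raise ConfigurationError("target spacing must be positive")
    spacing = np.asarray(volume.spacing, dtype=float)
    if np.allclose(spacing, target_spacing_mm):
        return ImageVolume(volume.voxels.copy(), (target_spacing_mm,) * 3, volume.origin)
    zoom = spacing / target_spacing_mm
    order = 0 if is_mask else 1
    data = volume.voxels.astype(bool) if is_mask else volume.voxels.astype(float)
    out = ndimage.zoom(data, zoom, order=order, mode="nearest", prefilter=False)
    if is_mask:
        out = out.astype(bool)
    return ImageVolume(out, (target_spacing_mm,) * 3, volume.origin)


def mask_bounding_box(mask: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Inclusive per-axis index ranges of the nonzero extent of ``mask``."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptySegmentationError("cannot compute the bounding box of an empty mask")
    bbox = []
    for axis in range(mask.ndim):
        proj = mask.any(axis=tuple(a for a in range(mask.ndim) if a != axis))
        nz = np.flatnonzero(proj)
        bbox.append((int(nz[0]), int(nz[-1])))
    return tuple(bbox)


def extract_voi(
    volume: ImageVolume,
    mask: np.ndarray,
    fill_value: float | None = None,
    patient_id: str | None = None,
    label: int | None = None,
) -> NodeVOI:
    """Crop to the tight bounding box of ``mask``.

    When ``fill_value`` is given, out-of-mask voxels inside the box are
    replaced by it; otherwise they keep the original background.  In-mask
    voxels are never altered.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume.voxels.shape:
        raise ConfigurationError("mask grid does not match the volume grid")
    bbox = mask_bounding_box(mask)
    sl = tuple(slice(lo, hi + 1) for lo, hi in bbox)
    sub = volume.voxels[sl].astype(float).copy()
    sub_mask = mask[sl]
    if fill_value is not None:
        sub[~sub_mask] = float(fill_value)
    origin = tuple(
        o + lo * s for o, (lo, _), s in zip(volume.origin, bbox, volume.spacing)
    )
    return NodeVOI(
        image=ImageVolume(sub, volume.spacing, origin),
        mask=sub_mask,
        patient_id=patient_id,
        label=label,
    )


def standardize_stack(
    voi: NodeVOI,
    z_slices: int = DEFAULT_Z_SLICES,
    xy_size: tuple[int, int] = DEFAULT_XY_SIZE,
    window: tuple[float, float] = DEFAULT_WINDOW,
    fill: str = "mean",
    xy_mode: str = "pad",
) -> SliceStack:
    """Turn a VOI into a fixed-shape normalized slice stack.

    The z-axis is linearly resampled to ``z_slices`` planes, each plane is
    brought to ``xy_size``, and intensities are clipped to ``window`` then
    affinely mapped to [0, 1].

    Out-of-mask voxels are replaced first.  ``fill="mean"`` (default) uses
    the in-mask mean, which removes the artificial node-versus-background
    step: convolutional band-pass features then respond to the tissue
    texture inside the node rather than to the silhouette of the
    segmentation.  ``fill="window-min"`` keeps the hard silhouette
    (background maps to exactly 0).

    ``xy_mode`` controls the in-plane standardization:

    * ``"pad"`` (default) — center the plane on the fixed canvas at its
      native resolution (downscaling only planes that exceed it).  The
      spatial frequency content of the texture is then comparable across
      nodes of different sizes, which a frozen filter bank needs;
    * ``"resize"`` — stretch every plane to the canvas, the conventional
      CNN input standardization (scale information is lost and the texture
      spectrum shifts with node size).
    """
    if z_slices < 1:
        raise ConfigurationError("z_slices must be >= 1")
    lo, hi = window
    if hi <= lo:
        raise ConfigurationError("window must satisfy high > low")
    if fill not in ("mean", "window-min"):
        raise ConfigurationError(f"unknown fill mode: {fill}")
    if xy_mode not in ("pad", "resize"):
        raise ConfigurationError(f"unknown xy_mode: {xy_mode}")
    vol = voi.image.voxels.astype(float).copy()
    fill_value = float(vol[voi.mask].mean()) if fill == "mean" else lo
    vol[~voi.mask] = fill_value
    nx, ny, nz = vol.shape
    if min(nx, ny, nz) < 1:
        raise ConfigurationError("degenerate zero-extent VOI")

    def _standardize(volume: np.ndarray, background: float) -> np.ndarray:
        # z first, then in-plane, matching the two-stage standardization
        vz = resize(volume, (nx, ny, z_slices), order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
        planes = np.full((z_slices, xy_size[0], xy_size[1]), background,
                         dtype=float)
        for k in range(z_slices):
            plane = vz[:, :, k]
            if (xy_mode == "resize" or plane.shape[0] > xy_size[0]
                    or plane.shape[1] > xy_size[1]):
                scale = min(xy_size[0] / plane.shape[0],
                            xy_size[1] / plane.shape[1])
                target = (
                    xy_size
                    if xy_mode == "resize"
                    else (max(1, int(plane.shape[0] * scale)),
                          max(1, int(plane.shape[1] * scale)))
                )
                plane = resize(plane, target, order=1, mode="edge",
                               anti_aliasing=False, preserve_range=True)
            ox = (xy_size[0] - plane.shape[0]) // 2
            oy = (xy_size[1] - plane.shape[1]) // 2
            planes[k, ox:ox + plane.shape[0], oy:oy + plane.shape[1]] = plane
        return planes

    out = _standardize(vol, fill_value)
    out = (np.clip(out, lo, hi) - lo) / (hi - lo)
    support = _standardize(voi.mask.astype(float), 0.0) > 0.5
    return SliceStack(slices=out, intensity_range=(0.0, 1.0), support=support)


def preprocess_node(
    volume: ImageVolume,
    mask: np.ndarray,
    target_spacing_mm: float = 1.0,
    patient_id: str | None = None,
    label: int | None = None,
) -> NodeVOI:
    """Resample image and mask to isotropic spacing, then crop to the node.

    The image is resampled with mask-weighted (normalized-convolution)
    linear interpolation: in-mask output voxels average only in-mask input
    intensities.  Plain linear interpolation would blend the air background
    (−1000 HU) into every boundary voxel the resampled mask still covers,
    and those partial-volume values would dominate all in-mask statistics.
    """
    mask = np.asarray(mask).astype(bool)
    w_iso = resample_isotropic(
        ImageVolume(mask.astype(float), volume.spacing, volume.origin),
        target_spacing_mm,
    )
    masked = np.where(mask, volume.voxels, 0.0)
    num_iso = resample_isotropic(
        ImageVolume(masked, volume.spacing, volume.origin), target_spacing_mm
    )
    w = w_iso.voxels
    bg = float(volume.voxels[~mask].min()) if (~mask).any() else 0.0
    img_iso = ImageVolume(
        np.where(w > 1e-6, num_iso.voxels / np.maximum(w, 1e-6), bg),
        (target_spacing_mm,) * 3,
        volume.origin,
    )
    mask_iso = resample_isotropic(
        ImageVolume(mask.astype(np.uint8), volume.spacing, volume.origin),
        target_spacing_mm,
        is_mask=True,
    )
    m = mask_iso.voxels.astype(bool)
    if not m.any():
        # Tiny nodes can vanish under nearest-neighbour downsampling; keep the
        # voxel nearest the native mask centroid so the node survives.
        centroid = np.array(ndimage.center_of_mass(mask.astype(float)))
        scale = np.asarray(volume.spacing) / target_spacing_mm
        idx = np.clip(
            np.round(centroid * scale).astype(int), 0, np.array(m.shape) - 1
        )
        m[tuple(idx)] = True
    return extract_voi(img_iso, m, patient_id=patient_id, label=label)
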