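"""IBSI-style hand-crafted radiomics: first-order, 3D shape, and GLCM texture.

All features are computed strictly over in-mask voxels.  Estimators are the
population (biased) forms: variance divides by N, skewness is Fisher's g1,
kurtosis is Pearson's beta2 (3 for a normal).  Texture features discretize
intensities with a fixed bin width anchored at the in-mask minimum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from .errors import ConfigurationError, EmptySegmentationError
from .preprocessing import ImageVolume, NodeVOI

#: The 13 unique 3D direction offsets (half of the 26-neighbourhood).
GLCM_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off > (0, 0, 0)
)

VOXEL_MAP_SENTINEL = np.nan


@dataclass(frozen=True)
class DiscretizationConfig:
    """Fixed-bin-width intensity discretization for texture features."""

    bin_width: float = 25.0  # HU

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be positive")

    def discretize(self, values: np.ndarray) -> np.ndarray:
        """0-based bin indices, anchored at the minimum of ``values``."""
        return np.floor((values - values.min()) / self.bin_width).astype(int)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def compute_first_order(
    voi: NodeVOI, disc: DiscretizationConfig = DiscretizationConfig()
) -> dict[str, float]:
    """First-order statistics of the in-mask intensity distribution."""
    x = voi.in_mask_values.astype(float)
    if x.size == 0:
        raise EmptySegmentationError("no in-mask voxels")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population
    sd = np.sqrt(var)
    centered = x - mean
    if sd > 0:
        skew = float((centered**3).mean() / sd**3)
        kurt = float((centered**4).mean() / sd**4)
    else:
        skew, kurt = 0.0, 0.0
    bins = disc.discretize(x)
    counts = np.bincount(bins).astype(float)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    return {
        "firstorder.mean": mean,
        "firstorder.median": float(np.median(x)),
        "firstorder.minimum": float(x.min()),
        "firstorder.maximum": float(x.max()),
        "firstorder.range": float(x.max() - x.min()),
        "firstorder.variance": var,
        "firstorder.skewness": skew,
        "firstorder.kurtosis": kurt,
        "firstorder.energy": float((x**2).sum()),
        "firstorder.rms": float(np.sqrt((x**2).mean())),
        "firstorder.p10": float(p10),
        "firstorder.p90": float(p90),
        "firstorder.iqr": float(p75 - p25),
        "firstorder.entropy": _entropy_bits(counts / n),
    }


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (N, 3) of in-mask voxels with at least one 6-neighbour outside."""
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    return np.argwhere(mask & ~eroded)


def compute_shape(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """3D shape descriptors of a binary mask on a (possibly anisotropic) grid.

    Volume is voxel-counted; surface area comes from a marching-cubes boundary
    mesh; the maximum 3D diameter is the largest pairwise distance between
    boundary voxels (via their convex hull); axis lengths derive from the
    eigen-decomposition of the physical in-mask coordinate covariance
    (lengths 4*sqrt(lambda), the full extent of the matched ellipsoid).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptySegmentationError("empty mask")
    sp = np.asarray(spacing, dtype=float)
    n_vox = int(mask.sum())
    volume = n_vox * float(np.prod(sp))

    padded = np.pad(mask.astype(float), 2)
    if n_vox > 1:
        # Lightly smooth the binary indicator before meshing: the raw 0/1 field
        # yields a faceted marching-cubes surface that overestimates area by
        # ~9% on a digital ball; sigma=0.8 voxels brings it within ~1%.
        from scipy import ndimage

        smoothed = ndimage.gaussian_filter(padded, sigma=0.8)
        if smoothed.max() <= 0.5:  # tiny mask smoothed away: mesh the raw field
            smoothed = padded
        verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=tuple(sp))
        area = float(measure.mesh_surface_area(verts, faces))
    else:
        # a single voxel: use its box surface
        area = float(2.0 * (sp[0] * sp[1] + sp[1] * sp[2] + sp[0] * sp[2]))
    sphericity = float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)

    boundary = _boundary_voxels(mask)
    pts = boundary * sp
    if len(pts) >= 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    max_diam = float(pdist(pts).max()) if len(pts) > 1 else 0.0

    coords = np.argwhere(mask) * sp
    cov = np.cov(coords, rowvar=False, bias=True) if n_vox > 1 else np.zeros((3, 3))
    eig = np.sort(np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0.0, None))[::-1]
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0
    return {
        "shape.volume_mm3": volume,
        "shape.surface_area_mm2": area,
        "shape.sphericity": sphericity,
        "shape.max_diameter_mm": max_diam,
        "shape.major_axis_mm": float(major),
        "shape.minor_axis_mm": float(minor),
        "shape.least_axis_mm": float(least),
        "shape.elongation": elongation,
        "shape.flatness": flatness,
    }


def _glcm_matrix(
    bins: np.ndarray,
    mask: np.ndarray,
    offsets: tuple[tuple[int, int, int], ...],
    distance: int,
) -> np.ndarray:
    """Symmetric co-occurrence matrix over in-mask voxel pairs, sum-normalized."""
    levels = int(bins[mask].max()) + 1
    grid = np.zeros(mask.shape, dtype=int)
    grid[mask] = bins[mask] if bins.shape == mask.shape else 0
    glcm = np.zeros((levels, levels), dtype=float)
    n_pairs = 0
    for off in offsets:
        off = tuple(int(o) * distance for o in off)
        src = tuple(
            slice(max(0, -o), min(s, s - o)) for o, s in zip(off, mask.shape)
        )
        dst = tuple(
            slice(max(0, o), min(s, s + o)) for o, s in zip(off, mask.shape)
        )
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        i = grid[src][valid]
        j = grid[dst][valid]
        np.add.at(glcm, (i, j), 1.0)
        np.add.at(glcm, (j, i), 1.0)  # symmetric accumulation
        n_pairs += 2 * valid.sum()
    if n_pairs == 0:
        raise EmptySegmentationError("no valid in-mask voxel pairs for the GLCM")
    return glcm / glcm.sum()


def compute_glcm(
    voi: NodeVOI,
    disc: DiscretizationConfig = DiscretizationConfig(),
    distance: int = 1,
    offsets: tuple[tuple[int, int, int], ...] = GLCM_OFFSETS,
) -> dict[str, float]:
    """Gray-level co-occurrence texture features.

    The co-occurrence matrix is accumulated symmetrically over the given
    direction offsets at ``distance`` voxels, restricted to pairs where both
    voxels are in-mask, then normalized to sum 1.
    """
    if voi.mask.sum() < 2:
        raise EmptySegmentationError("GLCM needs at least 2 in-mask voxels")
    full_bins = np.zeros(voi.mask.shape, dtype=int)
    full_bins[voi.mask] = disc.discretize(voi.in_mask_values)
    P = _glcm_matrix(full_bins, voi.mask, offsets, distance)
    levels = P.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    px = P.sum(axis=1)
    mu = float((np.arange(levels) * px).sum())
    sigma2 = float(((np.arange(levels) - mu) ** 2 * px).sum())
    diff2 = (i - j) ** 2
    if sigma2 > 0:
        corr = float(((i - mu) * (j - mu) * P).sum() / sigma2)
    else:
        corr = 1.0  # constant region: perfectly correlated by convention
    return {
        "glcm.joint_energy": float((P**2).sum()),
        "glcm.joint_entropy": _entropy_bits(P.ravel()),
        "glcm.contrast": float((diff2 * P).sum()),
        "glcm.idm": float((P / (1.0 + diff2)).sum()),
        "glcm.correlation": corr,
    }


FIRST_ORDER_NAMES = tuple(
    compute_first_order(
        NodeVOI(ImageVolume(np.zeros((2, 2, 2)), (1, 1, 1)), np.ones((2, 2, 2), bool))
    )
)
GLCM_NAMES = ("glcm.joint_energy", "glcm.joint_entropy", "glcm.contrast",
              "glcm.idm", "glcm.correlation")


def compute_voxel_map(
    voi: NodeVOI,
    feature_name: str,
    kernel_radius: int = 2,
    disc: DiscretizationConfig = DiscretizationConfig(),
) -> ImageVolume:
    """Voxel-based feature map: the feature recomputed on the cubic
    neighbourhood of each in-mask voxel (intersected with the mask).

    Out-of-mask voxels carry NaN.  Used for spatial interpretation of what a
    feature responds to, mirroring voxel-based extraction.
    """
    if feature_name in FIRST_ORDER_NAMES:
        kind = "firstorder"
    elif feature_name in GLCM_NAMES:
        kind = "glcm"
    else:
        raise ConfigurationError(f"unknown voxel-map feature: {feature_name}")
    shape = voi.mask.shape
    out = np.full(shape, VOXEL_MAP_SENTINEL, dtype=float)
    r = int(kernel_radius)
    for idx in np.argwhere(voi.mask):
        sl = tuple(slice(max(0, c - r), min(s, c + r + 1)) for c, s in zip(idx, shape))
        sub_mask = voi.mask[sl]
        sub_img = voi.image.voxels[sl]
        sub = NodeVOI(ImageVolume(sub_img, voi.image.spacing), sub_mask)
        if kind == "firstorder":
            out[tuple(idx)] = compute_first_order(sub, disc)[feature_name]
        else:
            if sub_mask.sum() < 2:
                continue
            try:
                out[tuple(idx)] = compute_glcm(sub, disc)[feature_name]
            except EmptySegmentationError:
                continue
    return ImageVolume(out, voi.image.spacing, voi.image.origin)


def assemble_handcrafted(
    voi: NodeVOI, disc: DiscretizationConfig = DiscretizationConfig()
) -> dict[str, float]:
    """First-order + shape + GLCM blocks concatenated in a stable order."""
    vec: dict[str, float] = {}
    vec.update(compute_first_order(voi, disc))
    vec.update(compute_shape(voi.mask, voi.image.spacing))
    vec.update(compute_glcm(voi, disc))
    return vec


def select_features(vector: dict[str, float], prefixes: tuple[str, ...]) -> dict[str, float]:
    """Subset a feature vector by namespace prefix (e.g. firstorder, shape)."""
    return {k: v for k, v in vector.items() if k.split(".")[0] in prefixes}
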