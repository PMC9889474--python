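"""Compact radiomics feature catalogue: first-order, shape, GLCM and GLRLM.

The catalogue is deliberately small and fully specified (no filtered-image
or wavelet variants): 16 first-order, 12 shape, 6 co-occurrence and 6
run-length features.  Texture matrices are computed over the 13 unique 3D
unit offsets at distance 1, restricted to voxel pairs/runs lying entirely
inside the mask, and feature values are averaged across offsets, which
makes them invariant to translation and axis permutation.

Feature names follow ``<timepoint>__<region>__<family>__<feature>``, e.g.
``F0__peri5__glcm__contrast``; the timepoint tag becomes ``delta`` for
per-day change features downstream.

Discretization uses a fixed number of equal-width bins over the in-region
intensity range (default 32), so texture features are invariant to affine
intensity shifts while first-order location statistics (mean, percentiles)
shift equivariantly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import measure as skmeasure

from .grid import BinaryMask, RegionSet, VoxelGrid

__all__ = [
    "OFFSETS_13",
    "DiscretizedRegion",
    "discretize",
    "first_order_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "extract_all",
    "FIRST_ORDER_NAMES",
    "SHAPE_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "catalogue_size",
]

#: The 13 unique direction offsets of the 26-neighbourhood (one per
#: antipodal pair; the first nonzero component is positive).
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0) or (dx == 0 and ((dy, dz) > (0, 0)))
)
assert len(OFFSETS_13) == 13

FIRST_ORDER_NAMES = (
    "mean", "median", "variance", "skewness", "kurtosis", "energy", "rms",
    "entropy", "uniformity", "minimum", "maximum", "range", "p10", "p90",
    "iqr", "mad",
)
SHAPE_NAMES = (
    "voxel_volume_mm3", "mesh_volume_mm3", "surface_area_mm2",
    "surface_to_volume", "sphericity", "compactness", "max_diameter_mm",
    "major_axis_mm", "minor_axis_mm", "least_axis_mm", "elongation",
    "flatness",
)
GLCM_NAMES = ("contrast", "dissimilarity", "energy", "homogeneity", "entropy", "correlation")
GLRLM_NAMES = ("sre", "lre", "gln", "rln", "run_percentage", "run_entropy")


def catalogue_size() -> dict[str, int]:
    """Fixed per-family feature counts of the catalogue."""
    return {
        "first_order": len(FIRST_ORDER_NAMES),
        "shape": len(SHAPE_NAMES),
        "glcm": len(GLCM_NAMES),
        "glrlm": len(GLRLM_NAMES),
    }


@dataclass
class DiscretizedRegion:
    """Integer gray levels of the in-mask voxels on the cropped grid.

    ``levels`` holds 0 outside the mask and values in ``[1, n_levels]``
    inside; ``edges`` are the (strictly increasing) bin edges.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    edges: np.ndarray


def _crop(mask: np.ndarray, *arrays: np.ndarray, pad: int = 1):
    """Crop arrays to the mask bounding box (plus pad) to keep texture loops small."""
    idx = np.nonzero(mask)
    lo = [max(int(i.min()) - pad, 0) for i in idx]
    hi = [min(int(i.max()) + pad + 1, s) for i, s in zip(idx, mask.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return tuple(a[sl] for a in (mask, *arrays))


def discretize(grid: VoxelGrid, mask: BinaryMask, n_bins: int = 32) -> DiscretizedRegion:
    """Fixed-bin-number, equal-width discretization over the in-region range."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    m = np.asarray(mask.values, dtype=bool)
    if not m.any():
        raise ValueError("cannot discretize an empty mask")
    m, v = _crop(m, np.asarray(grid.values, dtype=float))
    vals = v[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(m.shape, dtype=np.int32)
    if hi <= lo:
        levels[m] = 1
        edges = np.array([lo, lo + 1.0])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        lv = np.floor((vals - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
        levels[m] = np.clip(lv, 1, n_bins)
    return DiscretizedRegion(levels=levels, mask=m, n_levels=n_bins, edges=edges)


# --------------------------------------------------------------------------
# first order
# --------------------------------------------------------------------------

def first_order_features(
    grid: VoxelGrid, mask: BinaryMask, n_bins: int = 32
) -> dict[str, float]:
    """Intensity statistics of in-region voxels.

    Entropy (natural log) and uniformity are computed on the discretized
    histogram.  Skewness and excess kurtosis are flagged missing (NaN) for
    single-voxel or constant regions where they are undefined.
    """
    m = np.asarray(mask.values, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    v = np.asarray(grid.values, dtype=float)[m]
    disc = discretize(grid, mask, n_bins)
    p = np.bincount(disc.levels[disc.mask])[1:].astype(float)
    p = p[p > 0] / p.sum()
    var = float(v.var())
    degenerate = v.size < 2 or var == 0.0
    q75, q25 = np.percentile(v, [75, 25])
    return {
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "variance": var,
        "skewness": float(stats.skew(v)) if not degenerate else np.nan,
        "kurtosis": float(stats.kurtosis(v)) if not degenerate else np.nan,
        "energy": float(np.sum(v**2)),
        "rms": float(np.sqrt(np.mean(v**2))),
        "entropy": float(-(p * np.log(p)).sum()),
        "uniformity": float((p**2).sum()),
        "minimum": float(v.min()),
        "maximum": float(v.max()),
        "range": float(v.max() - v.min()),
        "p10": float(np.percentile(v, 10)),
        "p90": float(np.percentile(v, 90)),
        "iqr": float(q75 - q25),
        "mad": float(np.mean(np.abs(v - v.mean()))),
    }


# --------------------------------------------------------------------------
# shape
# --------------------------------------------------------------------------

def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return abs(float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum())) / 6.0


def shape_features(mask: BinaryMask) -> dict[str, float]:
    """Mesh- and PCA-based shape descriptors of the tumor mask.

    Surface area and mesh volume come from a marching-cubes surface;
    ``sphericity = pi^(1/3) (6V)^(2/3) / A`` equals 1 for a perfect ball.
    Axis lengths are ``4 sqrt(eigenvalue)`` of the voxel-coordinate
    covariance (the exact relation for a solid ellipsoid).  Mesh features
    are flagged missing for degenerate (planar or < 8 voxel) masks.
    """
    m = np.asarray(mask.values, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    spacing = mask.spacing_mm
    n = int(m.sum())
    voxvol = float(np.prod(spacing))
    out: dict[str, float] = dict.fromkeys(SHAPE_NAMES, np.nan)
    out["voxel_volume_mm3"] = n * voxvol

    coords = np.argwhere(m) * spacing
    # maximum 3D diameter via the convex hull of voxel centers
    try:
        from scipy.spatial import ConvexHull

        hull_pts = coords[ConvexHull(coords).vertices] if len(coords) > 4 else coords
    except Exception:
        hull_pts = coords
    d2 = np.sum((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2, axis=-1)
    out["max_diameter_mm"] = float(np.sqrt(d2.max()))

    if n >= 4:
        centered = coords - coords.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(centered.T)))[::-1]
        eig = np.clip(eig, 0, None)
        out["major_axis_mm"] = 4.0 * float(np.sqrt(eig[0]))
        out["minor_axis_mm"] = 4.0 * float(np.sqrt(eig[1]))
        out["least_axis_mm"] = 4.0 * float(np.sqrt(eig[2]))
        if eig[0] > 0:
            out["elongation"] = float(np.sqrt(eig[1] / eig[0]))
            out["flatness"] = float(np.sqrt(eig[2] / eig[0]))

    if n >= 8:
        # marching cubes on the raw binary mask inflates surface area with
        # staircase facets (~10% for digital balls); a light Gaussian smooth
        # of the indicator field before isosurfacing suppresses them
        from scipy.ndimage import gaussian_filter

        padded = gaussian_filter(np.pad(m, 2).astype(float), 0.8)
        try:
            verts, faces, _, _ = skmeasure.marching_cubes(padded, level=0.5, spacing=spacing)
            area = float(skmeasure.mesh_surface_area(verts, faces))
            vol = _mesh_volume(verts, faces)
            out["mesh_volume_mm3"] = vol
            out["surface_area_mm2"] = area
            if vol > 0 and area > 0:
                out["surface_to_volume"] = area / vol
                out["sphericity"] = float(np.pi ** (1 / 3) * (6 * vol) ** (2 / 3) / area)
                out["compactness"] = float(vol / (np.sqrt(np.pi) * area**1.5))
        except (ValueError, RuntimeError):
            pass  # degenerate surface: mesh features stay missing
    return out


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def _offset_slices(shape, off):
    src, dst = [], []
    for s, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, s - o))
            dst.append(slice(o, s))
        else:
            src.append(slice(-o, s))
            dst.append(slice(0, s + o))
    return tuple(src), tuple(dst)


def glcm_features(disc: DiscretizedRegion) -> dict[str, float]:
    """Gray-level co-occurrence features, averaged over the 13 offsets.

    Each offset's matrix counts level pairs with both voxels in the mask,
    is symmetrized and normalized; correlation is missing (NaN) when fewer
    than two levels are occupied (zero marginal variance).
    """
    L, m = disc.levels, disc.mask
    K = int(disc.levels.max())
    if K < 1:
        raise ValueError("empty discretized region")
    idx = np.arange(1, K + 1, dtype=float)
    per_offset = {name: [] for name in GLCM_NAMES}
    any_pairs = False
    for off in OFFSETS_13:
        s, d = _offset_slices(L.shape, off)
        a, b = L[s], L[d]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        any_pairs = True
        counts = np.bincount(
            (a[valid].astype(np.int64) - 1) * K + (b[valid].astype(np.int64) - 1),
            minlength=K * K,
        ).reshape(K, K).astype(float)
        P = counts + counts.T
        P /= P.sum()
        i = idx[:, None]
        j = idx[None, :]
        px = P.sum(axis=1)
        mu = float((idx * px).sum())
        sig2 = float(((idx - mu) ** 2 * px).sum())
        nz = P > 0
        per_offset["contrast"].append(float((P * (i - j) ** 2).sum()))
        per_offset["dissimilarity"].append(float((P * np.abs(i - j)).sum()))
        per_offset["energy"].append(float((P**2).sum()))
        per_offset["homogeneity"].append(float((P / (1.0 + (i - j) ** 2)).sum()))
        per_offset["entropy"].append(float(-(P[nz] * np.log(P[nz])).sum()))
        if sig2 > 0:
            corr = float(((i - mu) * (j - mu) * P).sum() / sig2)
            per_offset["correlation"].append(corr)
    if not any_pairs:
        raise ValueError("no valid co-occurrence pairs inside the mask")
    return {
        name: (float(np.mean(vals)) if vals else np.nan)
        for name, vals in per_offset.items()
    }


# --------------------------------------------------------------------------
# GLRLM
# --------------------------------------------------------------------------

def _shift_plane(plane: np.ndarray, dy: int, dz: int) -> np.ndarray:
    """Shift a 2D array by (dy, dz), filling vacated cells with 0."""
    out = np.zeros_like(plane)
    sy = slice(max(dy, 0), plane.shape[0] + min(dy, 0))
    ty = slice(max(-dy, 0), plane.shape[0] + min(-dy, 0))
    sz = slice(max(dz, 0), plane.shape[1] + min(dz, 0))
    tz = slice(max(-dz, 0), plane.shape[1] + min(-dz, 0))
    out[sy, sz] = plane[ty, tz]
    return out


def _run_length_matrix(L: np.ndarray, off: tuple[int, int, int], max_len: int) -> np.ndarray:
    """Run-length matrix for one direction; rows = levels 1..K, cols = lengths 1..max_len.

    Runs are maximal sequences of equal-level in-mask voxels along ``off``;
    computed by a backward recurrence on the run length from each voxel.
    """
    K = int(L.max())
    axes = [k for k in range(3) if off[k] != 0]
    scan = axes[0]
    # orient so the scan component is +1
    if off[scan] < 0:
        off = tuple(-o for o in off)
    arr = np.moveaxis(L, scan, 0)
    rest = tuple(o for k, o in enumerate(off) if k != scan)
    nx = arr.shape[0]
    length = np.zeros_like(arr)
    # length[x] = 1 + length[x+1] shifted by the transverse offset, where levels match
    for x in range(nx - 1, -1, -1):
        cur = arr[x]
        length[x] = (cur > 0).astype(arr.dtype)
        if x + 1 < nx:
            nxt_lvl = _shift_plane(arr[x + 1], -rest[0], -rest[1])
            nxt_len = _shift_plane(length[x + 1], -rest[0], -rest[1])
            cont = (cur > 0) & (nxt_lvl == cur)
            length[x] = np.where(cont, 1 + nxt_len, length[x])
    # run starts: voxels whose predecessor is absent or a different level
    starts = arr > 0
    prev = np.zeros_like(arr)
    prev[1:] = arr[:-1]
    for x in range(nx):
        if x == 0:
            continue
        prev[x] = _shift_plane(arr[x - 1], rest[0], rest[1])
    starts &= prev != arr
    lv = arr[starts].astype(np.int64)
    ln = length[starts].astype(np.int64)
    R = np.zeros((K, max_len), dtype=float)
    np.add.at(R, (lv - 1, np.clip(ln, 1, max_len) - 1), 1.0)
    return R


def glrlm_features(disc: DiscretizedRegion) -> dict[str, float]:
    """Gray-level run-length features, averaged over the 13 directions."""
    L, m = disc.levels, disc.mask
    n_vox = int(m.sum())
    if n_vox == 0:
        raise ValueError("empty discretized region")
    max_len = max(L.shape)
    per_dir = {name: [] for name in GLRLM_NAMES}
    jj = np.arange(1, max_len + 1, dtype=float)
    for off in OFFSETS_13:
        R = _run_length_matrix(L, off, max_len)
        n_runs = R.sum()
        if n_runs == 0:
            continue
        row = R.sum(axis=1)
        col = R.sum(axis=0)
        p = R[R > 0] / n_runs
        per_dir["sre"].append(float((col / jj**2).sum() / n_runs))
        per_dir["lre"].append(float((col * jj**2).sum() / n_runs))
        per_dir["gln"].append(float((row**2).sum() / n_runs))
        per_dir["rln"].append(float((col**2).sum() / n_runs))
        per_dir["run_percentage"].append(float(n_runs / n_vox))
        per_dir["run_entropy"].append(float(-(p * np.log(p)).sum()))
    return {
        name: (float(np.mean(vals)) if vals else np.nan)
        for name, vals in per_dir.items()
    }


# --------------------------------------------------------------------------
# full extraction
# --------------------------------------------------------------------------

def extract_all(
    grid: VoxelGrid,
    regions: RegionSet,
    timepoint_tag: str,
    n_bins: int = 32,
) -> dict[str, float]:
    """Extract the full catalogue for one scan.

    First-order, GLCM and GLRLM features are computed per region (tumor,
    peri5, peri10); shape features only for the tumor (the rings are shells
    whose geometry is derived from the tumor contour).  Per-feature failures
    are recorded as NaN rather than aborting the scan.
    """
    out: dict[str, float] = {}

    def _put(region: str, family: str, values: dict[str, float]) -> None:
        for k, v in values.items():
            out[f"{timepoint_tag}__{region}__{family}__{k}"] = v

    for region_name, mask in regions:
        try:
            disc = discretize(grid, mask, n_bins)
            _put(region_name, "first_order", first_order_features(grid, mask, n_bins))
            _put(region_name, "glcm", glcm_features(disc))
            _put(region_name, "glrlm", glrlm_features(disc))
        except ValueError:
            for fam, names in (
                ("first_order", FIRST_ORDER_NAMES),
                ("glcm", GLCM_NAMES),
                ("glrlm", GLRLM_NAMES),
            ):
                _put(region_name, fam, dict.fromkeys(names, np.nan))
    try:
        _put("tumor", "shape", shape_features(regions.tumor))
    except ValueError:
        _put("tumor", "shape", dict.fromkeys(SHAPE_NAMES, np.nan))
    return out
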