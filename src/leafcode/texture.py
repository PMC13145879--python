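"""Texture and filter-bank descriptors of the masked leaf surface.

Families: gray-level co-occurrence statistics (GLCM), uniform local
binary patterns (LBP), an orientation-histogram gradient summary (HOG),
a 12-filter Gabor bank, Canny edge density, first/second-order edge
operators (Sobel, Scharr, Prewitt, Laplacian) and radial Fourier power
fractions.  Together with the color and Hu shape features they form a
105-value vector per image.

Every family is computed strictly over the leaf mask: pair counting,
neighborhoods and summary statistics never touch sheet pixels, and
convolutional families (HOG, Gabor, Canny, Fourier) first replace the
background with the masked mean so that no background value can leak
through a filter support.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.feature import canny as _canny
from skimage.feature import local_binary_pattern
from skimage.filters import gabor_kernel
from skimage.transform import resize

from .color_shape import (
    COLOR_FEATURE_NAMES,
    HU_FEATURE_NAMES,
    color_shape_features,
)
from .imgio import LeafManifestEntry, to_gray

# ---------------------------------------------------------------- parameters

GLCM_LEVELS = 16
GLCM_DISTANCES = (1, 2, 4)
# (row, col) steps for angles 0, 45, 90, 135 degrees at unit distance
GLCM_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

LBP_P = 8
LBP_R = 1

HOG_SIZE = 128
HOG_CELL = 16
HOG_BINS = 9
HOG_EPS = 1e-6

GABOR_THETAS = (0, 45, 90, 135)          # degrees
GABOR_FREQS = (0.05, 0.15, 0.30)         # cycles/pixel
GABOR_SIGMA_FACTOR = 0.56                # sigma = 0.56 / frequency

CANNY_SIGMA = 1.0
CANNY_PCT = (70, 90)

FOURIER_SIZE = 128
FOURIER_BINS = 8

GLCM_FEATURE_NAMES = (
    "glcm_contrast", "glcm_dissimilarity", "glcm_homogeneity",
    "glcm_energy", "glcm_correlation", "glcm_asm",
)
LBP_FEATURE_NAMES = tuple(f"lbp_{i}" for i in range(10))
HOG_FEATURE_NAMES = tuple(f"hog_mean_{i}" for i in range(1, 10)) + tuple(
    f"hog_std_{i}" for i in range(1, 10)
)
GABOR_FEATURE_NAMES = tuple(
    f"gabor_o{t}_f{int(round(f * 100)):03d}_{stat}"
    for t in GABOR_THETAS
    for f in GABOR_FREQS
    for stat in ("mean", "std")
)
EDGE_FEATURE_NAMES = tuple(
    f"{op}_{stat}"
    for op in ("sobel", "scharr", "prewitt", "laplacian")
    for stat in ("mean", "std", "energy")
)
FOURIER_FEATURE_NAMES = tuple(f"fourier_f{i}" for i in range(1, 9)) + (
    "fourier_centroid",
)

#: the full, ordered column contract of one feature vector
FEATURE_NAMES: tuple[str, ...] = (
    COLOR_FEATURE_NAMES
    + HU_FEATURE_NAMES
    + GLCM_FEATURE_NAMES
    + LBP_FEATURE_NAMES
    + HOG_FEATURE_NAMES
    + GABOR_FEATURE_NAMES
    + ("canny_edge_density",)
    + EDGE_FEATURE_NAMES
    + FOURIER_FEATURE_NAMES
)

EXTRACTOR_PARAMS = {
    "glcm_levels": GLCM_LEVELS,
    "glcm_distances": list(GLCM_DISTANCES),
    "glcm_angles_deg": [0, 45, 90, 135],
    "lbp_p": LBP_P,
    "lbp_r": LBP_R,
    "hog_size": HOG_SIZE,
    "hog_cell": HOG_CELL,
    "hog_bins": HOG_BINS,
    "gabor_thetas_deg": list(GABOR_THETAS),
    "gabor_freqs": list(GABOR_FREQS),
    "gabor_sigma_factor": GABOR_SIGMA_FACTOR,
    "canny_sigma": CANNY_SIGMA,
    "canny_threshold_percentiles": list(CANNY_PCT),
    "fourier_size": FOURIER_SIZE,
    "fourier_bins": FOURIER_BINS,
}


def masked_fill(gray: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace background with the masked mean (neutral fill for filters)."""
    if not mask.any():
        raise ValueError("empty leaf mask")
    out = np.where(mask, gray, gray[mask].mean())
    return out.astype(np.float64)


# ------------------------------------------------------------------- GLCM


def quantize_gray(gray: np.ndarray, mask: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Min–max quantization of masked pixels into ``levels`` equal-width
    bins, with occupied bins compacted to consecutive ranks.

    Compaction makes a two-tone image land on *adjacent* levels, so the
    co-occurrence statistics of, e.g., a binary checkerboard match a
    direct pair enumeration over its raw values.
    """
    vals = gray[mask]
    mn, mx = float(vals.min()), float(vals.max())
    if mx == mn:
        return np.zeros(gray.shape, dtype=np.intp)
    q = np.floor((gray - mn) / (mx - mn) * levels).astype(np.intp)
    np.clip(q, 0, levels - 1, out=q)
    occupied = np.unique(q[mask])
    remap = np.zeros(levels, dtype=np.intp)
    remap[occupied] = np.arange(occupied.size)
    return remap[np.clip(q, 0, levels - 1)]


def _cooccurrence(q: np.ndarray, mask: np.ndarray, dr: int, dc: int, levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one offset; pairs
    must have both pixels inside the mask."""
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if not valid.any():
        return np.zeros((levels, levels))
    counts = np.bincount(
        a[valid] * levels + b[valid], minlength=levels * levels
    ).reshape(levels, levels)
    p = counts + counts.T
    return p / p.sum()


def _glcm_stats(p: np.ndarray) -> dict[str, float]:
    levels = p.shape[0]
    i = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    d = ii - jj
    contrast = float((p * d**2).sum())
    dissim = float((p * np.abs(d)).sum())
    homog = float((p / (1.0 + d**2)).sum())
    asm = float((p**2).sum())
    marg = p.sum(axis=1)
    mu = float((i * marg).sum())
    var = float(((i - mu) ** 2 * marg).sum())
    if var <= 0:
        corr = 1.0
    else:
        corr = float(((ii * jj * p).sum() - mu**2) / var)
    return {
        "glcm_contrast": contrast,
        "glcm_dissimilarity": dissim,
        "glcm_homogeneity": homog,
        "glcm_energy": float(np.sqrt(asm)),
        "glcm_correlation": corr,
        "glcm_asm": asm,
    }


def glcm_features(
    gray: np.ndarray,
    mask: np.ndarray,
    distances: tuple[int, ...] = GLCM_DISTANCES,
    levels: int = GLCM_LEVELS,
) -> dict[str, float]:
    """Haralick-style statistics averaged over the offset family
    distances x angles {0, 45, 90, 135} degrees."""
    if not mask.any():
        raise ValueError("empty leaf mask")
    q = quantize_gray(gray, mask, levels)
    nlev = int(q[mask].max()) + 1
    per_offset = []
    for d in distances:
        for dr, dc in GLCM_DIRECTIONS:
            p = _cooccurrence(q, mask, dr * d, dc * d, nlev)
            if p.sum() > 0:
                per_offset.append(_glcm_stats(p))
    if not per_offset:
        raise ValueError("no valid pixel pairs for any GLCM offset")
    return {
        k: float(np.mean([s[k] for s in per_offset])) for k in GLCM_FEATURE_NAMES
    }


# -------------------------------------------------------------------- LBP


def lbp_histogram(gray: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Normalized 10-bin uniform LBP histogram (P=8, R=1).

    Codes use bilinearly interpolated circular neighbors with the tie
    rule neighbor >= center -> 1.  Uniform patterns (<= 2 circular
    transitions) map to bins 0..8 by their number of set bits; all
    non-uniform patterns share bin 9.  Only center pixels whose full
    3x3 neighborhood lies inside the mask contribute.
    """
    import warnings

    with warnings.catch_warnings():
        # continuous-valued input is intentional: codes are rank statistics
        warnings.simplefilter("ignore", UserWarning)
        codes = local_binary_pattern(gray, P=LBP_P, R=LBP_R, method="uniform")
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))
    if not interior.any():
        raise ValueError("no interior pixels for LBP after mask erosion")
    hist = np.bincount(codes[interior].astype(np.intp), minlength=LBP_P + 2)
    hist = hist / hist.sum()
    return {f"lbp_{i}": float(v) for i, v in enumerate(hist)}


# -------------------------------------------------------------------- HOG


def _bbox_crop(gray: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return gray[sl], mask[sl]


def _resampled_fill(gray: np.ndarray, mask: np.ndarray, size: int) -> np.ndarray:
    """Mask bounding-box crop, background replaced by the masked mean,
    resampled to a fixed square for size-independent spectral/gradient
    descriptors."""
    g, m = _bbox_crop(gray, mask)
    filled = np.where(m, g, g[m].mean())
    return resize(filled, (size, size), order=1, anti_aliasing=True)


def hog_summary(gray: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Mean and std of the 9 unsigned orientation bins across 16x16
    cells of the 128x128 resampled crop, each cell L2-normalized."""
    im = _resampled_fill(gray, mask, HOG_SIZE)
    gy, gx = np.gradient(im)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), np.pi)  # unsigned, [0, pi)
    bins = np.minimum((ang / np.pi * HOG_BINS).astype(np.intp), HOG_BINS - 1)
    nc = HOG_SIZE // HOG_CELL
    hist = np.zeros((nc, nc, HOG_BINS))
    for b in range(HOG_BINS):
        sel = np.where(bins == b, mag, 0.0)
        hist[:, :, b] = sel.reshape(nc, HOG_CELL, nc, HOG_CELL).sum(axis=(1, 3))
    norms = np.sqrt((hist**2).sum(axis=2) + HOG_EPS**2)
    hist = hist / norms[:, :, None]
    means = hist.mean(axis=(0, 1))
    stds = hist.std(axis=(0, 1))
    out = {f"hog_mean_{i + 1}": float(means[i]) for i in range(HOG_BINS)}
    out.update({f"hog_std_{i + 1}": float(stds[i]) for i in range(HOG_BINS)})
    return out


# ------------------------------------------------------------------ Gabor

_GABOR_KERNELS: dict[tuple[int, float], np.ndarray] = {}


def _gabor_bank() -> dict[tuple[int, float], np.ndarray]:
    if not _GABOR_KERNELS:
        for t in GABOR_THETAS:
            for f in GABOR_FREQS:
                sigma = GABOR_SIGMA_FACTOR / f
                _GABOR_KERNELS[(t, f)] = gabor_kernel(
                    frequency=f, theta=np.deg2rad(t), sigma_x=sigma, sigma_y=sigma
                )
    return _GABOR_KERNELS


def gabor_features(gray: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Masked mean/std of the response magnitude of a 4-orientation x
    3-frequency Gabor bank (sigma matched to frequency)."""
    filled = masked_fill(gray, mask)
    out: dict[str, float] = {}
    for (t, f), kern in _gabor_bank().items():
        # edge-replicate padding: image borders must not ring against
        # the implicit zero padding of a plain convolution
        ph, pw = kern.shape[0] // 2, kern.shape[1] // 2
        padded = np.pad(filled, ((ph, ph), (pw, pw)), mode="edge")
        resp = np.abs(fftconvolve(padded, kern, mode="valid"))
        vals = resp[mask]
        key = f"gabor_o{t}_f{int(round(f * 100)):03d}"
        out[f"{key}_mean"] = float(vals.mean())
        out[f"{key}_std"] = float(vals.std())
    return {k: out[k] for k in GABOR_FEATURE_NAMES}


# ------------------------------------------------------------------ Canny


def canny_density(gray: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of mask pixels marked as Canny edges, with hysteresis
    thresholds at the 70th/90th percentiles of the masked gradient
    magnitude (after Gaussian smoothing, sigma=1)."""
    filled = masked_fill(gray, mask)
    sm = ndimage.gaussian_filter(filled, CANNY_SIGMA)
    grad = np.hypot(ndimage.sobel(sm, axis=0), ndimage.sobel(sm, axis=1))
    gvals = grad[mask]
    if gvals.max() <= 0:
        return 0.0
    low, high = np.percentile(gvals, CANNY_PCT)
    if high <= 0:
        return 0.0
    low = min(low, 0.999 * high)
    edges = _canny(filled, sigma=CANNY_SIGMA, low_threshold=low, high_threshold=high)
    return float((edges & mask).sum() / mask.sum())


# ----------------------------------------------------------- edge filters

EDGE_KERNELS = {
    "sobel": np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float),
    "scharr": np.array([[-3, 0, 3], [-10, 0, 10], [-3, 0, 3]], float),
    "prewitt": np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], float),
}
LAPLACE_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], float)


def edge_filter_features(gray: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Masked mean/std/energy of gradient-magnitude (Sobel, Scharr,
    Prewitt) and |Laplacian| responses, excluding a 1-pixel rim so that
    every 3x3 support lies inside the leaf."""
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))
    if not interior.any():
        raise ValueError("mask interior empty after rim exclusion")
    g = gray.astype(np.float64)
    out: dict[str, float] = {}
    for name, kx in EDGE_KERNELS.items():
        gx = ndimage.correlate(g, kx, mode="nearest")
        gy = ndimage.correlate(g, kx.T, mode="nearest")
        resp = np.hypot(gx, gy)[interior]
        out[f"{name}_mean"] = float(resp.mean())
        out[f"{name}_std"] = float(resp.std())
        out[f"{name}_energy"] = float((resp**2).mean())
    resp = np.abs(ndimage.correlate(g, LAPLACE_KERNEL, mode="nearest"))[interior]
    out["laplacian_mean"] = float(resp.mean())
    out["laplacian_std"] = float(resp.std())
    out["laplacian_energy"] = float((resp**2).mean())
    return out


# ---------------------------------------------------------------- Fourier


def fourier_features(gray: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Radial power fractions f1..f8 (8 equal bins, 0 to Nyquist) and
    the power-weighted spectral centroid (cycles/pixel) of the
    mean-subtracted, background-zeroed 128x128 crop."""
    g, m = _bbox_crop(gray.astype(np.float64), mask)
    filled = np.where(m, g, g[m].mean())  # fill first: resampling must
    g128 = resize(filled, (FOURIER_SIZE, FOURIER_SIZE), order=1,
                  anti_aliasing=True)   # not smear sheet into the leaf
    m128 = resize(m.astype(float), (FOURIER_SIZE, FOURIER_SIZE), order=0) > 0.5
    if not m128.any():
        m128 = np.ones_like(g128, dtype=bool)
    z = np.where(m128, g128 - g128[m128].mean(), 0.0)
    power = np.abs(np.fft.fft2(z)) ** 2
    fy = np.fft.fftfreq(FOURIER_SIZE)
    fx = np.fft.fftfreq(FOURIER_SIZE)
    r = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    in_band = (r > 0) & (r <= 0.5)
    total = power[in_band].sum()
    out = {f"fourier_f{i}": 0.0 for i in range(1, 9)}
    out["fourier_centroid"] = 0.0
    if total <= 0:
        return out
    idx = np.minimum((r[in_band] / 0.5 * FOURIER_BINS).astype(np.intp), FOURIER_BINS - 1)
    frac = np.bincount(idx, weights=power[in_band], minlength=FOURIER_BINS) / total
    for i in range(FOURIER_BINS):
        out[f"fourier_f{i + 1}"] = float(frac[i])
    out["fourier_centroid"] = float((power[in_band] * r[in_band]).sum() / total)
    return out


# ---------------------------------------------------------------- assembly


def assemble_feature_vector(
    entry: LeafManifestEntry | None, img: np.ndarray, mask: np.ndarray
) -> dict[str, float | str]:
    """Concatenate all descriptor families into the 105-value named
    vector, with leaf provenance attached when an entry is given.

    Family failures propagate with the family name prefixed so a batch
    run can attribute the error to a descriptor, not just an image.
    """
    gray = to_gray(img)
    families = (
        ("color_shape", lambda: color_shape_features(img, mask)),
        ("glcm", lambda: glcm_features(gray, mask)),
        ("lbp", lambda: lbp_histogram(gray, mask)),
        ("hog", lambda: hog_summary(gray, mask)),
        ("gabor", lambda: gabor_features(gray, mask)),
        ("canny", lambda: {"canny_edge_density": canny_density(gray, mask)}),
        ("edges", lambda: edge_filter_features(gray, mask)),
        ("fourier", lambda: fourier_features(gray, mask)),
    )
    vec: dict[str, float | str] = {}
    for name, fn in families:
        try:
            vec.update(fn())
        except Exception as exc:
            raise RuntimeError(f"descriptor family {name!r} failed: {exc}") from exc
    ordered: dict[str, float | str] = {k: vec[k] for k in FEATURE_NAMES}
    if entry is not None:
        ordered["leaf_id"] = entry.leaf_id
        ordered["surface"] = entry.surface
        ordered["plant_id"] = entry.plant_id
        ordered["folk_type"] = entry.folk_type
    return ordered
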