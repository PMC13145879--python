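"""Color statistics over leaf pixels and Hu invariant shape moments.

Color descriptors are the per-channel mean and population standard
deviation in three spaces: sRGB (0–255), HSV (hue in degrees with
*circular* statistics, S and V in [0, 1]) and CIELab (D65, L* in
[0, 100]).  Hue is treated circularly because dried leaves sit near the
red/brown end of the wheel where the 0/360 wrap makes arithmetic means
meaningless.

Shape is summarized by the seven Hu moment invariants of the binary
silhouette, log-scaled as ``h'_i = -sign(h_i) * log10(|h_i| + 1e-30)``
so the wildly different magnitudes become comparable features.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import moments_central, moments_hu, moments_normalized

HU_EPS = 1e-30

COLOR_FEATURE_NAMES = (
    "rgb_r_mean", "rgb_r_std", "rgb_g_mean", "rgb_g_std", "rgb_b_mean", "rgb_b_std",
    "hsv_h_circmean", "hsv_h_circstd", "hsv_s_mean", "hsv_s_std",
    "hsv_v_mean", "hsv_v_std",
    "lab_l_mean", "lab_l_std", "lab_a_mean", "lab_a_std", "lab_b_mean", "lab_b_std",
)

HU_FEATURE_NAMES = tuple(f"hu_{i}" for i in range(1, 8))


def _check_mask(img: np.ndarray, mask: np.ndarray) -> None:
    if mask.shape != img.shape[:2]:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("empty leaf mask")


def rgb_stats(img: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Masked mean and population std of the R, G, B channels (0–255)."""
    _check_mask(img, mask)
    px = img[mask].astype(np.float64)
    out: dict[str, float] = {}
    for i, ch in enumerate("rgb"):
        out[f"rgb_{ch}_mean"] = float(px[:, i].mean())
        out[f"rgb_{ch}_std"] = float(px[:, i].std())
    return out


def hsv_stats(img: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Masked HSV statistics; hue uses circular mean/std in degrees.

    The circular mean is the direction of the resultant vector in
    [0, 360); the circular std is ``sqrt(-2 ln R)`` (in degrees), zero
    for perfectly concentrated hue.
    """
    _check_mask(img, mask)
    hsv = rgb2hsv(img)[mask]
    h = hsv[:, 0] * 2.0 * np.pi  # skimage hue is in [0, 1)
    c, s = np.cos(h).mean(), np.sin(h).mean()
    mean_deg = float(np.degrees(np.arctan2(s, c)) % 360.0)
    r = min(float(np.hypot(c, s)), 1.0)
    circ_std = float(np.degrees(np.sqrt(max(-2.0 * np.log(r), 0.0)))) if r > 0 else 180.0
    out = {"hsv_h_circmean": mean_deg, "hsv_h_circstd": circ_std}
    for i, ch in ((1, "s"), (2, "v")):
        out[f"hsv_{ch}_mean"] = float(hsv[:, i].mean())
        out[f"hsv_{ch}_std"] = float(hsv[:, i].std())
    return out


# sRGB (D65) to XYZ; the white point is taken as the matrix row sums so
# that (255,255,255) maps to L*=100, a*=b*=0 exactly
_SRGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_LAB_WHITE = _SRGB2XYZ.sum(axis=1)


def srgb_to_lab(img: np.ndarray) -> np.ndarray:
    """sRGB uint8 -> CIELab (piecewise 2.4-exponent decoding, D65)."""
    c = img.astype(np.float64) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    t = (lin @ _SRGB2XYZ.T) / _LAB_WHITE
    d = 6.0 / 29.0
    f = np.where(t > d**3, np.cbrt(t), t / (3 * d * d) + 4.0 / 29.0)
    lab = np.empty_like(f)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return lab


def lab_stats(img: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Masked mean/std in CIELab (sRGB decoding, D65 white point)."""
    _check_mask(img, mask)
    lab = srgb_to_lab(img)[mask]
    out: dict[str, float] = {}
    for i, ch in enumerate("lab"):
        out[f"lab_{ch}_mean"] = float(lab[:, i].mean())
        out[f"lab_{ch}_std"] = float(lab[:, i].std())
    return out


def hu_moments(mask: np.ndarray) -> dict[str, float]:
    """Log-scaled Hu invariants of the binary silhouette.

    Central moments are taken over the mask treated as a {0,1} image,
    normalized as eta_pq = mu_pq / mu_00^(1+(p+q)/2), combined into the
    seven standard invariants, then log-scaled.  Exact under integer
    translation and 90-degree rotation; scale-invariant up to grid
    discretization.
    """
    if mask.sum() < 8:
        raise ValueError("mask has fewer than 8 pixels; moments unstable")
    m = mask.astype(np.float64)
    mu = moments_central(m)
    eta = moments_normalized(mu)
    hu = moments_hu(eta)
    scaled = -np.sign(hu) * np.log10(np.abs(hu) + HU_EPS)
    return {f"hu_{i + 1}": float(v) for i, v in enumerate(scaled)}


def color_shape_features(img: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """All 18 color statistics plus the 7 Hu invariants, in stable order."""
    out: dict[str, float] = {}
    out.update(rgb_stats(img, mask))
    out.update(hsv_stats(img, mask))
    out.update(lab_stats(img, mask))
    out.update(hu_moments(mask))
    return out
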