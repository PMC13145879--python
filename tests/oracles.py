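"""Brute-force reference implementations used as independent oracles.

Everything here is deliberately written as plain nested loops over
pixels and pairs, sharing no code path with the package's vectorized
implementations.
"""

from __future__ import annotations

import math

import numpy as np

GLCM_DIRECTIONS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def color_stats_reference(img: np.ndarray, mask: np.ndarray):
    """Two-pass per-channel mean and population std over mask pixels."""
    out = {}
    for ci, name in enumerate("rgb"):
        vals = []
        for r in range(img.shape[0]):
            for c in range(img.shape[1]):
                if mask[r, c]:
                    vals.append(float(img[r, c, ci]))
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / len(vals)
        out[f"rgb_{name}_mean"] = mean
        out[f"rgb_{name}_std"] = math.sqrt(var)
    return out


def glcm_reference(
    gray: np.ndarray,
    mask: np.ndarray,
    distances=(1, 2, 4),
    angles=(0, 45, 90, 135),
    levels: int = 16,
):
    """Pair-enumeration GLCM statistics averaged over the offset set.

    Quantization: equal-width bins on the masked min-max range, then
    occupied bins renumbered consecutively.
    """
    vals = [gray[r, c] for r in range(gray.shape[0]) for c in range(gray.shape[1]) if mask[r, c]]
    mn, mx = min(vals), max(vals)
    q = np.zeros(gray.shape, dtype=int)
    if mx > mn:
        for r in range(gray.shape[0]):
            for c in range(gray.shape[1]):
                b = int((gray[r, c] - mn) / (mx - mn) * levels)
                q[r, c] = min(max(b, 0), levels - 1)
    occupied = sorted({q[r, c] for r in range(q.shape[0]) for c in range(q.shape[1]) if mask[r, c]})
    rank = {b: i for i, b in enumerate(occupied)}
    nlev = len(occupied)

    per_offset = []
    h, w = gray.shape
    for d in distances:
        for ang in angles:
            dr, dc = GLCM_DIRECTIONS[ang]
            dr, dc = dr * d, dc * d
            p = np.zeros((nlev, nlev))
            for r in range(h):
                for c in range(w):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                        i, j = rank[q[r, c]], rank[q[r2, c2]]
                        p[i, j] += 1
                        p[j, i] += 1
            if p.sum() == 0:
                continue
            p = p / p.sum()
            contrast = dissim = homog = asm = corr_num = 0.0
            mu = var = 0.0
            marg = p.sum(axis=1)
            for i in range(nlev):
                mu += i * marg[i]
            for i in range(nlev):
                var += (i - mu) ** 2 * marg[i]
            for i in range(nlev):
                for j in range(nlev):
                    contrast += p[i, j] * (i - j) ** 2
                    dissim += p[i, j] * abs(i - j)
                    homog += p[i, j] / (1 + (i - j) ** 2)
                    asm += p[i, j] ** 2
                    corr_num += i * j * p[i, j]
            corr = 1.0 if var <= 0 else (corr_num - mu**2) / var
            per_offset.append(
                {
                    "glcm_contrast": contrast,
                    "glcm_dissimilarity": dissim,
                    "glcm_homogeneity": homog,
                    "glcm_energy": math.sqrt(asm),
                    "glcm_correlation": corr,
                    "glcm_asm": asm,
                }
            )
    keys = per_offset[0].keys()
    return {k: sum(s[k] for s in per_offset) / len(per_offset) for k in keys}


def _bilinear(gray: np.ndarray, r: float, c: float) -> float:
    r0, c0 = int(math.floor(r)), int(math.floor(c))
    dr, dc = r - r0, c - c0
    top = (1 - dc) * gray[r0, c0] + dc * gray[r0, c0 + 1] if dc > 0 else gray[r0, c0]
    if dr == 0:
        return top
    bot = (1 - dc) * gray[r0 + 1, c0] + dc * gray[r0 + 1, c0 + 1] if dc > 0 else gray[r0 + 1, c0]
    return (1 - dr) * top + dr * bot


def lbp_reference(gray: np.ndarray, mask: np.ndarray, p: int = 8, radius: float = 1.0):
    """Per-pixel uniform LBP codes and 10-bin normalized histogram.

    Neighbors at angles 2*pi*k/p sampled with bilinear interpolation;
    a bit is set when neighbor >= center; uniform patterns (<= 2
    circular transitions) bin by popcount, all others share bin p+1.
    """
    h, w = gray.shape
    hist = [0] * (p + 2)
    interior = np.zeros_like(mask)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            interior[r, c] = all(
                mask[r + i, c + j] for i in (-1, 0, 1) for j in (-1, 0, 1)
            )
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            if not interior[r, c]:
                continue
            bits = []
            for k in range(p):
                rr = r - radius * math.sin(2 * math.pi * k / p)
                cc = c + radius * math.cos(2 * math.pi * k / p)
                # snap near-integer coordinates to the grid to avoid
                # interpolation noise at exact lattice points
                rr = round(rr, 8)
                cc = round(cc, 8)
                bits.append(1 if _bilinear(gray, rr, cc) >= gray[r, c] else 0)
            transitions = sum(bits[k] != bits[(k + 1) % p] for k in range(p))
            hist[sum(bits) if transitions <= 2 else p + 1] += 1
    total = sum(hist)
    return [v / total for v in hist]


EDGE_KERNELS = {
    "sobel": [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]],
    "scharr": [[-3, 0, 3], [-10, 0, 10], [-3, 0, 3]],
    "prewitt": [[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]],
}
LAPLACE = [[0, 1, 0], [1, -4, 1], [0, 1, 0]]


def _correlate_at(gray: np.ndarray, kern, r: int, c: int) -> float:
    h, w = gray.shape
    acc = 0.0
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            rr = min(max(r + i, 0), h - 1)  # 'nearest' border
            cc = min(max(c + j, 0), w - 1)
            acc += kern[i + 1][j + 1] * gray[rr, cc]
    return acc


def edge_reference(gray: np.ndarray, mask: np.ndarray):
    """Direct 3x3 convolution loops for the four edge operators."""
    h, w = gray.shape
    interior = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            ok = True
            for i in (-1, 0, 1):
                for j in (-1, 0, 1):
                    rr, cc = r + i, c + j
                    if not (0 <= rr < h and 0 <= cc < w and mask[rr, cc]):
                        ok = False
            if ok:
                interior.append((r, c))
    out = {}
    for name, kx in EDGE_KERNELS.items():
        ky = [list(row) for row in zip(*kx)]
        resp = [
            math.hypot(_correlate_at(gray, kx, r, c), _correlate_at(gray, ky, r, c))
            for r, c in interior
        ]
        mean = sum(resp) / len(resp)
        var = sum((v - mean) ** 2 for v in resp) / len(resp)
        out[f"{name}_mean"] = mean
        out[f"{name}_std"] = math.sqrt(var)
        out[f"{name}_energy"] = sum(v**2 for v in resp) / len(resp)
    resp = [abs(_correlate_at(gray, LAPLACE, r, c)) for r, c in interior]
    mean = sum(resp) / len(resp)
    var = sum((v - mean) ** 2 for v in resp) / len(resp)
    out["laplacian_mean"] = mean
    out["laplacian_std"] = math.sqrt(var)
    out["laplacian_energy"] = sum(v**2 for v in resp) / len(resp)
    return out


def anova_reference(groups):
    """Textbook two-pass sums of squares."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    f = (ssb / df_b) / (ssw / df_w)
    return f, ssb, ssw, df_b, df_w
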