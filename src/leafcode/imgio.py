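"""Manifest and image handling for leaf photographs on herbarium sheets.

Images are plain numpy arrays throughout the package:

* RGB image — ``uint8`` array of shape ``(H, W, 3)``, sRGB, ``H, W >= 32``.
* Leaf mask — boolean array of shape ``(H, W)``, ``True`` on leaf pixels.
* Gray image — ``float64`` array of shape ``(H, W)`` with luminance in [0, 1].

A manifest CSV links each image file to its plant, folk type, leaf and
surface; :func:`read_manifest` validates the relational invariants (one
plant and one folk type per leaf, at most one image per leaf surface)
before anything downstream runs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import measure, morphology, transform
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

SURFACES = ("adaxial", "abaxial")

MANIFEST_COLUMNS = ("image_path", "plant_id", "folk_type", "leaf_id", "surface", "intact")

#: default long-side length of a standardized leaf image, pixels
STANDARD_SIZE = 512

#: minimum fraction of the frame a segmented leaf must occupy
MIN_FOREGROUND_FRACTION = 0.01


class ManifestError(ValueError):
    """A manifest row violates the schema or a relational invariant."""


class SegmentationError(RuntimeError):
    """Leaf/background separation produced no usable foreground."""


@dataclass(frozen=True)
class LeafManifestEntry:
    """One image file and its provenance within the sampling design."""

    image_path: Path
    plant_id: str
    folk_type: str
    leaf_id: str
    surface: str
    intact: bool

    def __post_init__(self) -> None:
        if self.surface not in SURFACES:
            raise ManifestError(
                f"surface must be one of {SURFACES}, got {self.surface!r} "
                f"(leaf {self.leaf_id})"
            )


def _parse_bool(token: str, row: int) -> bool:
    t = token.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ManifestError(f"row {row}: cannot parse intact flag {token!r}")


def read_manifest(path: str | Path) -> list[LeafManifestEntry]:
    """Read and validate a manifest CSV.

    Rows with ``intact=false`` are returned with the flag set, never
    dropped; filtering is the caller's decision.

    Raises
    ------
    ManifestError
        On a missing column, an unknown surface token, a duplicate
        (leaf_id, surface) pair, or a leaf_id mapped to two plants or
        two folk types.  The message names the offending row.
    """
    path = Path(path)
    entries: list[LeafManifestEntry] = []
    seen: dict[tuple[str, str], int] = {}
    leaf_ident: dict[str, tuple[str, str, int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ManifestError(f"manifest {path} lacks columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            surface = row["surface"].strip()
            if surface not in SURFACES:
                raise ManifestError(f"row {i}: unknown surface {surface!r}")
            leaf_id = row["leaf_id"].strip()
            key = (leaf_id, surface)
            if key in seen:
                raise ManifestError(
                    f"row {i}: duplicate (leaf_id, surface) = {key}, "
                    f"first seen at row {seen[key]}"
                )
            seen[key] = i
            ident = (row["plant_id"].strip(), row["folk_type"].strip())
            if leaf_id in leaf_ident:
                prev_plant, prev_type, prev_row = leaf_ident[leaf_id]
                if (prev_plant, prev_type) != ident:
                    raise ManifestError(
                        f"row {i}: leaf {leaf_id!r} mapped to "
                        f"({ident[0]}, {ident[1]}) but row {prev_row} has "
                        f"({prev_plant}, {prev_type})"
                    )
            else:
                leaf_ident[leaf_id] = (*ident, i)
            img_path = Path(row["image_path"])
            if not img_path.is_absolute():
                img_path = path.parent / img_path
            entries.append(
                LeafManifestEntry(
                    image_path=img_path,
                    plant_id=ident[0],
                    folk_type=ident[1],
                    leaf_id=leaf_id,
                    surface=surface,
                    intact=_parse_bool(row["intact"], i),
                )
            )
    return entries


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG/TIFF as an 8-bit sRGB ``(H, W, 3)`` array.

    16-bit sources are rescaled by integer division by 257, grayscale
    is replicated across channels and alpha is discarded.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - annotate with path
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"unsupported image layout {arr.shape} in {path}")
    return np.ascontiguousarray(arr)


def _background_contrast(img: np.ndarray) -> np.ndarray:
    """Channel separating a darker/saturated leaf from a bright sheet.

    B' = 0.5*S + 0.5*(1 - G/255): herbarium sheets are bright and
    unsaturated (low saturation, high green channel -> low B'), dried
    leaves darker and more saturated, whether green or browned (high
    B').  Both terms point the same way, so Otsu sees a bimodal
    channel for green as well as brown leaves.
    """
    s = rgb2hsv(img)[..., 1]
    g = img[..., 1].astype(np.float64) / 255.0
    return 0.5 * s + 0.5 * (1.0 - g)


def segment_leaf(img: np.ndarray) -> np.ndarray:
    """Separate the leaf from the herbarium-sheet background.

    Otsu threshold on the background-contrast channel, then a 3x3
    morphological closing, largest connected component, and interior
    hole filling — dried-leaf cracks must not split the mask.

    Raises
    ------
    SegmentationError
        If the cleaned foreground covers less than 1% of the frame.
    """
    b = _background_contrast(img)
    area = b.size
    if np.ptp(b) < 1e-6:
        raise SegmentationError("image has no leaf/background contrast")
    mask = b > threshold_otsu(b)
    mask = morphology.closing(mask, footprint=np.ones((3, 3), bool))
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise SegmentationError("no foreground component found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()
    mask = ndimage.binary_fill_holes(mask)
    if mask.sum() < MIN_FOREGROUND_FRACTION * area:
        raise SegmentationError(
            f"foreground fraction {mask.sum() / area:.4f} below "
            f"{MIN_FOREGROUND_FRACTION}"
        )
    return mask


def standardize(
    img: np.ndarray, mask: np.ndarray, size: int = STANDARD_SIZE, margin: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Crop to the mask bounding box (+margin) and rescale.

    The longer side becomes ``size``; aspect ratio is preserved, the
    image resampled bilinearly and the mask nearest-neighbor.
    """
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0 = max(int(rows[0]) - margin, 0)
    r1 = min(int(rows[-1]) + margin + 1, mask.shape[0])
    c0 = max(int(cols[0]) - margin, 0)
    c1 = min(int(cols[-1]) + margin + 1, mask.shape[1])
    img_c = img[r0:r1, c0:c1]
    mask_c = mask[r0:r1, c0:c1]
    h, w = mask_c.shape
    if max(h, w) == size:
        return img_c.copy(), mask_c.copy()
    scale = size / max(h, w)
    out_shape = (max(int(round(h * scale)), 1), max(int(round(w * scale)), 1))
    img_r = transform.resize(
        img_c.astype(np.float64), out_shape, order=1, anti_aliasing=scale < 1
    )
    mask_r = (
        transform.resize(mask_c.astype(np.float64), out_shape, order=0) > 0.5
    )
    return np.clip(np.round(img_r), 0, 255).astype(np.uint8), mask_r


def to_gray(img: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance on gamma-encoded sRGB values, scaled to [0, 1]."""
    w = np.array([0.299, 0.587, 0.114])
    return img.astype(np.float64) @ w / 255.0
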