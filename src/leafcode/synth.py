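"""Deterministic synthetic two-surface leaf images.

The generator emulates the sampling design of a ten-class herbarium
study of ayahuasca-vine folk types: 47 plants, 384 leaves, 768
two-surface images, with the per-class plant/leaf counts of the study
it stands in for.  Each class has its own base CIELab color, lamina
shape (aspect, apex taper, margin roughness), surface texture (value
noise) and pinnate venation; the abaxial surface is rendered lighter
with stronger vein contrast, as on real dried leaves.

Two deliberate structures are planted for downstream evaluation:

* ``cabi_like`` and ``quebrador_like`` share base color and texture to
  within the jitter level — a morphologically overlapping pair that a
  classifier should confuse;
* ``hybrid_like``, ``arara_like`` and ``outgroup_like`` sit >= 20 Lab
  dE from every other class — a clearly separable trio.

Sampling is hierarchical: per-plant color offsets are drawn before
per-leaf offsets and are larger, so leaves of one plant resemble each
other more than leaves of different plants in the same class.  All
randomness flows from one integer seed through spawned generators, so
a run is reproducible byte for byte, including the PNGs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.color import lab2rgb

from .imgio import LeafManifestEntry, MANIFEST_COLUMNS

IMAGE_SHAPE = (400, 600)  # rows, cols
BACKGROUND_RGB = (235, 225, 205)
#: leaf-level color offsets are this fraction of the plant-level jitter
LEAF_JITTER_FACTOR = 0.5


@dataclass(frozen=True)
class ClassConfig:
    """Generative parameters of one synthetic folk type."""

    name: str
    n_plants: int
    n_leaves: int
    base_color: tuple[float, float, float]        # Lab
    color_jitter: tuple[float, float, float] = (1.5, 1.5, 1.5)  # plant-level std
    aspect: float = 2.2                           # length / width
    apex_sharpness: float = 1.6                   # superellipse exponent, apex half
    margin_roughness: float = 0.02                # relative margin amplitude
    texture_freq: float = 0.04                    # cycles / pixel
    texture_amp: float = 2.5                      # Lab L* units
    vein_density: float = 3.0                     # laterals per 100 px
    vein_contrast: float = 9.0                    # Lab L* darkening
    abaxial_delta: tuple[float, float] = (6.0, 1.4)  # (L* offset, vein mult)
    damage_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_plants < 1 or self.n_leaves < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.damage_rate <= 1.0:
            raise ValueError("damage_rate must be in [0, 1]")
        if self.texture_amp < 0:
            raise ValueError("texture amplitude must be >= 0")


@dataclass
class SyntheticRecord:
    """One rendered image with its ground truth."""

    image: np.ndarray
    mask: np.ndarray
    entry: LeafManifestEntry
    config: ClassConfig
    seed: int


#: names of the planted overlapping pair and clearly separable trio
OVERLAP_PAIR = ("cabi_like", "quebrador_like")
DISTINCT_TRIO = ("hybrid_like", "arara_like", "outgroup_like")


def default_configs() -> list[ClassConfig]:
    """The ten default classes with the study's (n_plants, n_leaves)
    composition: 47 plants, 384 leaves in total."""
    mk = ClassConfig
    return [
        mk("arara_like", 1, 17, (28.0, 25.0, 8.0), aspect=1.9,
           apex_sharpness=1.3, texture_freq=0.06, texture_amp=3.0,
           vein_density=2.5),
        mk("cabi_like", 4, 30, (45.0, 8.0, 30.0), aspect=2.15,
           apex_sharpness=1.6, texture_freq=0.04, texture_amp=2.5,
           vein_density=3.0),
        mk("caupuri_like", 11, 88, (38.0, 12.0, 26.0), aspect=2.5,
           apex_sharpness=1.9, texture_freq=0.05, texture_amp=2.0,
           vein_density=3.5),
        mk("spruce_like", 1, 31, (52.0, 4.0, 24.0), aspect=2.7,
           apex_sharpness=1.4, texture_freq=0.03, texture_amp=2.0,
           vein_density=2.0),
        mk("ourinho_like", 9, 63, (58.0, 14.0, 40.0), aspect=1.8,
           apex_sharpness=1.5, texture_freq=0.05, texture_amp=3.0,
           vein_density=4.0),
        mk("pajezinho_like", 2, 25, (40.0, -2.0, 14.0), aspect=2.0,
           apex_sharpness=2.1, texture_freq=0.07, texture_amp=2.5,
           vein_density=2.8),
        mk("quebrador_like", 3, 16, (46.5, 8.5, 31.0), aspect=2.1,
           apex_sharpness=1.6, texture_freq=0.04, texture_amp=2.5,
           vein_density=3.0),
        mk("tucunaca_like", 11, 80, (33.0, 2.0, 34.0), aspect=2.35,
           apex_sharpness=1.7, texture_freq=0.045, texture_amp=2.2,
           vein_density=3.2),
        mk("hybrid_like", 3, 18, (70.0, -25.0, 50.0), aspect=2.4,
           apex_sharpness=1.5, texture_freq=0.05, texture_amp=2.5,
           vein_density=3.0),
        mk("outgroup_like", 2, 16, (62.0, -18.0, 18.0), aspect=1.7,
           apex_sharpness=1.2, texture_freq=0.06, texture_amp=2.8,
           vein_density=2.2),
    ]


def _value_noise(shape: tuple[int, int], freq: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean unit-std value noise at the given spatial
    frequency (Gaussian lattice, cubic interpolation)."""
    if freq <= 0:
        return np.zeros(shape)
    lat = (max(int(np.ceil(shape[0] * freq)) + 2, 2),
           max(int(np.ceil(shape[1] * freq)) + 2, 2))
    coarse = rng.standard_normal(lat)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    coords = np.stack([yy * freq, xx * freq])
    fine = ndimage.map_coordinates(coarse, coords, order=3, mode="reflect")
    sd = fine.std()
    return fine / sd if sd > 0 else fine


def _background(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Beige herbarium sheet with a mild vignette and faint grain."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
    shade = 1.0 - 0.12 * r2 / 2.0
    base = np.array(BACKGROUND_RGB, dtype=np.float64)
    img = shade[..., None] * base[None, None, :]
    img += rng.normal(0, 1.2, size=(h, w, 1))
    return img


def render_leaf(
    config: ClassConfig, surface: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Render one leaf on a herbarium-sheet background.

    The silhouette is a superellipse lamina with a sharper apex half
    and a sinusoidal margin perturbation; the fill is the class base
    color plus smooth value noise, with a pinnate vein pattern
    (midrib plus regularly spaced laterals) darkened at the configured
    contrast.  Returns the uint8 RGB image and the boolean ground-truth
    mask.
    """
    if surface not in ("adaxial", "abaxial"):
        raise ValueError(f"unknown surface {surface!r}")
    h, w = IMAGE_SHAPE
    # geometry: half-length a, half-width b, small placement jitter
    a = w * rng.uniform(0.36, 0.41)  # half-length in px (~215-245)
    # leaves of one class vary in outline too: a ~5% multiplicative
    # aspect jitter keeps shape a noisy cue rather than a class label
    aspect = max(config.aspect * (1.0 + rng.normal(0.0, 0.05)), 1.2)
    b = a / aspect
    cy = h / 2 + rng.uniform(-12, 12)
    cx = w / 2 + rng.uniform(-12, 12)
    theta = np.deg2rad(rng.uniform(-8, 8))

    yy, xx = np.mgrid[0:h, 0:w]
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    u = xr / a
    # superellipse exponent: blunter base half, sharper (smaller
    # exponent -> more tapered) apex half
    n_base = 2.0
    n_apex = 2.0 / config.apex_sharpness
    expo = np.where(u >= 0, n_apex, n_base)
    au = np.minimum(np.abs(u), 1.0)
    profile = b * (1.0 - au**expo) ** (1.0 / expo)
    phase = rng.uniform(0, 2 * np.pi)
    profile = profile * (
        1.0 + config.margin_roughness * np.sin(2 * np.pi * 3.0 * u + phase)
    )
    mask = (np.abs(u) < 1.0) & (np.abs(yr) <= profile)
    mask = ndimage.binary_fill_holes(mask)

    # lamina color field in Lab
    lab = np.zeros((h, w, 3))
    base = np.array(config.base_color, dtype=np.float64)
    if surface == "abaxial":
        base = base + np.array([config.abaxial_delta[0], 0.0, 0.0])
    lab[...] = base
    if config.texture_amp > 0 and config.texture_freq > 0:
        lab[..., 0] += config.texture_amp * _value_noise((h, w), config.texture_freq, rng)

    vein_contrast = config.vein_contrast
    if surface == "abaxial":
        vein_contrast *= config.abaxial_delta[1]
    if vein_contrast > 0 and config.vein_density > 0:
        vein = np.zeros((h, w), dtype=bool)
        # midrib along the long axis
        vein |= (np.abs(yr) < 1.3) & (np.abs(u) < 0.97)
        # laterals: lines of constant (xr - |yr| / tan(phi)), spaced
        # 100 / density px along the axis, leaning toward the apex
        spacing = 100.0 / config.vein_density
        slope = 1.0 / np.tan(np.deg2rad(40.0))
        v = xr - np.abs(yr) * slope
        dist = np.abs((v + spacing / 2) % spacing - spacing / 2)
        vein |= dist < 0.7
        vein &= mask
        lab[..., 0] -= vein_contrast * vein
        lab[..., 1] += 0.15 * vein_contrast * vein  # veins slightly browner

    rgb_leaf = np.clip(lab2rgb(lab), 0, 1) * 255.0
    img = _background((h, w), rng)
    img[mask] = rgb_leaf[mask]
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, mask


def apply_damage(
    img: np.ndarray,
    mask: np.ndarray,
    severity: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Remove an apical region of about ``severity`` x mask area.

    The removed pixels are repainted with the local background color
    and the record is flagged not intact.  Severity is limited to
    (0, 0.5] so the leaf never vanishes.
    """
    if not 0.0 < severity <= 0.5:
        raise ValueError("severity must be in (0, 0.5]")
    idx = np.argwhere(mask)
    centroid = idx.mean(axis=0)
    centered = idx - centroid
    # principal axis of the silhouette; apex = far end along it
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    proj = centered @ axis
    if np.abs(proj.max()) < np.abs(proj.min()):
        proj = -proj
    # ragged cut: jitter the projection before thresholding
    proj_j = proj + rng.normal(0, 2.0, size=proj.shape)
    cut = np.quantile(proj_j, 1.0 - severity)
    removed = idx[proj_j > cut]
    bg = np.median(img[~mask], axis=0)
    img = img.copy()
    mask = mask.copy()
    img[removed[:, 0], removed[:, 1]] = bg.astype(img.dtype)
    mask[removed[:, 0], removed[:, 1]] = False
    return img, mask, False


def _plan(
    configs: list[ClassConfig], seed: int
) -> list[tuple[ClassConfig, str, str, np.ndarray, int]]:
    """Deterministic leaf plan: (config, plant_id, leaf_id,
    plant-level Lab offset, per-leaf seed) for every leaf."""
    ss = np.random.SeedSequence(seed)
    class_seqs = ss.spawn(len(configs))
    plan = []
    for config, cseq in zip(configs, class_seqs):
        crng = np.random.default_rng(cseq)
        # leaves per plant, nearly uniform
        base, rem = divmod(config.n_leaves, config.n_plants)
        leaf_counts = [base + (1 if i < rem else 0) for i in range(config.n_plants)]
        jitter = np.array(config.color_jitter)
        leaf_seeds = crng.integers(0, 2**31 - 1, size=config.n_leaves)
        li = 0
        for pi, count in enumerate(leaf_counts):
            plant_id = f"{config.name}_p{pi + 1:02d}"
            offset = crng.normal(0.0, jitter)
            for _ in range(count):
                leaf_id = f"{config.name}_l{li + 1:03d}"
                plan.append((config, plant_id, leaf_id, offset, int(leaf_seeds[li])))
                li += 1
    return plan


def generate_dataset(
    configs: list[ClassConfig] | None = None,
    out_dir: str | Path = "synthetic_leaves",
    seed: int = 0,
    damage_rate_override: float | None = None,
    write_images: bool = True,
) -> Path:
    """Render the full dataset and write PNGs plus the manifest CSV.

    Leaves are assigned to plants nearly uniformly; per-plant color
    offsets are drawn before per-leaf offsets, so plants within a
    class are more similar than plants across classes.  Fully
    deterministic for a given seed.  With ``write_images=False`` only
    the manifest (and parameter sidecar) is written — useful to audit
    the sampling design without paying for rendering.

    Returns the manifest path.
    """
    if configs is None:
        configs = default_configs()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for config, plant_id, leaf_id, offset, leaf_seed in _plan(configs, seed):
        damage_rate = (
            config.damage_rate if damage_rate_override is None else damage_rate_override
        )
        lrng = np.random.default_rng(leaf_seed)
        leaf_off = lrng.normal(0.0, LEAF_JITTER_FACTOR * np.array(config.color_jitter))
        color = tuple(np.array(config.base_color) + offset + leaf_off)
        leaf_cfg = ClassConfig(**{**asdict(config), "base_color": color})
        damaged = lrng.random() < damage_rate
        severity = float(lrng.uniform(0.05, 0.3)) if damaged else 0.0
        for surface in ("adaxial", "abaxial"):
            fname = f"{config.name}_{plant_id.split('_p')[-1]}_{leaf_id.split('_l')[-1]}_{surface}.png"
            if write_images:
                img, mask = render_leaf(leaf_cfg, surface, lrng)
                if damaged:
                    img, mask, _ = apply_damage(img, mask, severity, lrng)
                iio.imwrite(out_dir / fname, img)
            rows.append(
                {
                    "image_path": fname,
                    "plant_id": plant_id,
                    "folk_type": config.name,
                    "leaf_id": leaf_id,
                    "surface": surface,
                    "intact": str(not damaged).lower(),
                }
            )
    manifest = out_dir / "manifest.csv"
    import csv as _csv

    with open(manifest, "w", newline="", encoding="utf-8") as fh:
        writer = _csv.DictWriter(fh, fieldnames=list(MANIFEST_COLUMNS))
        writer.writeheader()
        writer.writerows(rows)
    sidecar = {
        "seed": seed,
        "image_shape": list(IMAGE_SHAPE),
        "background_rgb": list(BACKGROUND_RGB),
        "leaf_jitter_factor": LEAF_JITTER_FACTOR,
        "damage_rate_override": damage_rate_override,
        "classes": [asdict(c) for c in configs],
    }
    with open(out_dir / "generation_params.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2)
    return manifest
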