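"""Seeded synthetic H&E-like slide cohorts.

Real whole-slide cohorts with molecular ground truth are not shippable, so
this module renders parametric stand-ins that keep the statistical structure
the pipeline depends on:

* two tumor texture classes (the binary slide label) that differ in base
  color and in the density of dark elliptical "nucleus" blobs, plus a paler
  background-tissue texture;
* an irregular single-component tumor mask covering 20-70% of the slide;
* spatially correlated within-slide heterogeneity — a smoothed random field
  flips a configurable fraction of in-tumor tiles to the opposite class
  texture in locally coherent patches, which is exactly the noise structure
  a region-correlation model can exploit;
* a global affine color shift per scanner domain, emulating slides digitized
  on different scanner models.

Per-tile ground-truth rendering classes are kept on every record so that
downstream tiling and training stages can be tested against exact oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "TextureParams",
    "SyntheticSpec",
    "SlideRecord",
    "default_textures",
    "default_domains",
    "render_class_texture",
    "generate_slide",
    "generate_cohort",
    "load_cohort",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["slide_id", "image_path", "mask_path", "label", "domain", "seed"]

POS, NEG, BACKGROUND = "POS", "NEG", "background"

# integer codes used in the per-tile ground-truth grid
TILE_BG, TILE_NEG, TILE_POS = -1, 0, 1


@dataclass(frozen=True)
class TextureParams:
    """Parametric texture: base color plus dark elliptical nucleus blobs.

    blob_density is the expected blob count per 64x64-pixel area.
    """

    base_rgb: tuple[float, float, float]
    blob_rgb: tuple[float, float, float]
    blob_density: float
    blob_radius: float
    noise_sigma: float = 0.02


def default_textures() -> dict[str, TextureParams]:
    """Free choices documented in the methods note; H&E-ish hues with the
    positive class darker/more violet and more nucleus-dense."""
    return {
        POS: TextureParams((0.72, 0.56, 0.82), (0.30, 0.22, 0.50), 22.0, 3.0),
        NEG: TextureParams((0.82, 0.64, 0.78), (0.45, 0.30, 0.55), 10.0, 3.0),
        BACKGROUND: TextureParams((0.92, 0.87, 0.90), (0.75, 0.65, 0.78), 3.0, 2.5, 0.015),
    }


def default_domains() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Scanner-domain color transforms (3x3 matrix, RGB offset) on [0,1] RGB."""
    identity = (np.eye(3), np.zeros(3))
    shifted = (
        np.array([[1.06, 0.02, 0.00],
                  [0.01, 0.96, 0.02],
                  [0.00, 0.01, 1.03]]),
        np.array([0.02, -0.015, 0.01]),
    )
    return {"aperio": identity, "ventana": shifted}


@dataclass
class SyntheticSpec:
    slide_px: int = 512
    tile_px: int = 64
    texture_params: dict[str, TextureParams] = field(default_factory=default_textures)
    heterogeneity_rate: float = 0.3
    heterogeneity_smoothness: float = 3.0
    domain_shift: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=default_domains)
    seed: int = 0
    mask_coverage: tuple[float, float] = (0.2, 0.7)
    align_mask_to_tiles: bool = False

    def __post_init__(self):
        if self.slide_px <= 0 or self.tile_px <= 0 or self.slide_px % self.tile_px:
            raise ValueError(
                f"slide_px ({self.slide_px}) must be a positive multiple of "
                f"tile_px ({self.tile_px})")
        if not 0 <= self.heterogeneity_rate < 0.5:
            raise ValueError(
                "heterogeneity_rate must be in [0, 0.5); at >= 0.5 the slide "
                "label would no longer be the majority tile class")

    @property
    def grid_tiles(self) -> int:
        return self.slide_px // self.tile_px


@dataclass
class SlideRecord:
    slide_id: str
    image: np.ndarray          # (H, W, 3) uint8
    tumor_mask: np.ndarray     # (H, W) uint8, 1 = tumor
    label: str                 # POS | NEG
    domain: str
    seed: int
    tile_classes: np.ndarray | None = None   # (Hg, Wg) int8: -1 bg, 0 neg, 1 pos
    tile_inside: np.ndarray | None = None    # (Hg, Wg) bool, tile fully in mask
    tile_flipped: np.ndarray | None = None   # (Hg, Wg) bool

    def __post_init__(self):
        if self.image.shape[:2] != self.tumor_mask.shape:
            raise ValueError("image and tumor_mask differ in height/width")
        if self.tumor_mask.sum() == 0:
            raise ValueError("tumor_mask has no tumor pixels")
        if self.label not in (POS, NEG):
            raise ValueError(f"label must be {POS!r} or {NEG!r}, got {self.label!r}")

    @property
    def y(self) -> int:
        return 1 if self.label == POS else 0


def _apply_domain(img: np.ndarray, domain: str,
                  domains: dict[str, tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    if domain not in domains:
        raise ValueError(f"unknown domain {domain!r}; known: {sorted(domains)}")
    matrix, offset = domains[domain]
    out = img @ np.asarray(matrix, dtype=np.float64).T + np.asarray(offset, dtype=np.float64)
    return np.clip(out, 0.0, 1.0)


def _render_texture_float(params: TextureParams, size_px: int,
                          rng: np.random.Generator):
    """Render one texture patch in [0,1] floats; returns (img, blob list)."""
    img = np.empty((size_px, size_px, 3), dtype=np.float64)
    img[...] = params.base_rgb
    img += rng.normal(0.0, params.noise_sigma, size=img.shape)
    n_blobs = rng.poisson(params.blob_density * (size_px / 64.0) ** 2)
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    blobs = []
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, size_px, size=2)
        ry = params.blob_radius * rng.uniform(0.7, 1.3)
        rx = params.blob_radius * rng.uniform(0.7, 1.3)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        d = (u / rx) ** 2 + (v / ry) ** 2
        alpha = np.clip(1.6 - d, 0.0, 1.0)[..., None]
        img = img * (1 - alpha) + alpha * np.asarray(params.blob_rgb)
        blobs.append((cy, cx, ry, rx, theta))
    return np.clip(img, 0.0, 1.0), blobs


def render_class_texture(class_label: str, size_px: int, domain: str = "aperio",
                         rng: np.random.Generator | int | None = None,
                         textures: dict[str, TextureParams] | None = None,
                         domains: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
                         return_blobs: bool = False):
    """Render one size_px x size_px uint8 RGB texture patch.

    With ``return_blobs=True`` also returns the ground-truth list of rendered
    nucleus blobs as (cy, cx, ry, rx, theta) tuples.
    """
    if size_px < 16:
        raise ValueError("size_px must be >= 16")
    textures = textures or default_textures()
    domains = domains or default_domains()
    if class_label not in textures:
        raise ValueError(
            f"unknown class label {class_label!r}; valid labels: {sorted(textures)}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    img, blobs = _render_texture_float(textures[class_label], size_px, rng)
    img = _apply_domain(img, domain, domains)
    out = np.round(img * 255.0).astype(np.uint8)
    if return_blobs:
        return out, blobs
    return out


def _sample_tumor_mask(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Smoothed-random-field blob: single 4-connected component, no holes,
    coverage within spec.mask_coverage."""
    s = spec.slide_px
    lo, hi = spec.mask_coverage
    four_conn = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    sigma = s / 6.0
    for attempt in range(30):
        target = rng.uniform(lo + 0.05, hi - 0.1)
        g = ndimage.gaussian_filter(rng.standard_normal((s, s)), sigma=sigma)
        mask = g > np.quantile(g, 1.0 - target)
        lab, n = ndimage.label(mask, structure=four_conn)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
        mask = ndimage.binary_fill_holes(mask)
        if spec.align_mask_to_tiles:
            t = spec.tile_px
            gt = spec.grid_tiles
            tile_frac = mask.reshape(gt, t, gt, t).mean(axis=(1, 3))
            tmask = tile_frac >= 0.5
            lab, n = ndimage.label(tmask, structure=four_conn)
            if n == 0:
                continue
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
            tmask = lab == (1 + int(np.argmax(sizes)))
            tmask = ndimage.binary_fill_holes(tmask)
            mask = np.kron(tmask, np.ones((t, t), dtype=bool))
        cov = mask.mean()
        if lo <= cov <= hi and mask.any():
            return mask.astype(np.uint8)
        # widen the field if the blob keeps falling outside the band
        sigma *= 1.15
    raise RuntimeError("could not sample a tumor mask within the coverage band")


def generate_slide(spec: SyntheticSpec, label: str, slide_id: str,
                   rng: np.random.Generator | int | None = None,
                   domain: str = "aperio") -> SlideRecord:
    """Render one synthetic slide with known per-tile ground truth."""
    if label not in (POS, NEG):
        raise ValueError(f"label must be {POS!r} or {NEG!r}")
    seed = rng if isinstance(rng, (int, np.integer)) else spec.seed
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng if rng is not None else spec.seed)
    t, gt = spec.tile_px, spec.grid_tiles
    mask = _sample_tumor_mask(spec, rng)

    tile_sum = mask.reshape(gt, t, gt, t).sum(axis=(1, 3))
    tile_inside = tile_sum == t * t
    tile_overlap = tile_sum > 0

    # spatially correlated heterogeneity field on the tile grid
    f = ndimage.gaussian_filter(rng.standard_normal((gt, gt)),
                                sigma=spec.heterogeneity_smoothness)
    flipped = np.zeros((gt, gt), dtype=bool)
    if spec.heterogeneity_rate > 0 and tile_inside.any():
        thr = np.quantile(f[tile_inside], spec.heterogeneity_rate)
        flipped = tile_inside & (f < thr)

    own = TILE_POS if label == POS else TILE_NEG
    other = TILE_NEG if label == POS else TILE_POS
    tile_classes = np.full((gt, gt), TILE_BG, dtype=np.int8)
    tile_classes[tile_overlap] = own
    tile_classes[flipped] = other

    class_name = {TILE_POS: POS, TILE_NEG: NEG}
    img = np.empty((spec.slide_px, spec.slide_px, 3), dtype=np.float64)
    for r in range(gt):
        for c in range(gt):
            sl = np.s_[r * t:(r + 1) * t, c * t:(c + 1) * t]
            bg, _ = _render_texture_float(spec.texture_params[BACKGROUND], t, rng)
            code = tile_classes[r, c]
            if code == TILE_BG:
                img[sl] = bg
            else:
                fg, _ = _render_texture_float(
                    spec.texture_params[class_name[code]], t, rng)
                m = mask[sl].astype(bool)[..., None]
                img[sl] = np.where(m, fg, bg)
    img = _apply_domain(img, domain, spec.domain_shift)
    return SlideRecord(
        slide_id=slide_id,
        image=np.round(img * 255.0).astype(np.uint8),
        tumor_mask=mask,
        label=label,
        domain=domain,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else spec.seed,
        tile_classes=tile_classes,
        tile_inside=tile_inside,
        tile_flipped=flipped,
    )


def _derive_slide_seeds(cohort_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(cohort_seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def generate_cohort(n_pos: int, n_neg: int, spec: SyntheticSpec,
                    domain: str = "aperio", seed: int = 0,
                    out_dir: str | Path | None = None,
                    id_prefix: str = "s"):
    """Generate a labeled cohort; returns (records, manifest DataFrame).

    Per-slide seeds are derived deterministically from the cohort seed and
    recorded in the manifest, so any single slide can be regenerated
    bit-identically with ``generate_slide(spec, label, sid, its_seed, domain)``.
    When ``out_dir`` is given, images (PNG), masks (0/255 PNG), per-tile
    ground-truth grids (CSV) and ``manifest.csv`` are written there; manifest
    paths are relative to ``out_dir``.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("slide counts must be non-negative")
    if n_pos + n_neg == 0:
        raise ValueError("cohort must contain at least one slide")
    labels = [POS] * n_pos + [NEG] * n_neg
    seeds = _derive_slide_seeds(seed, len(labels))
    records, rows = [], []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, (label, sseed) in enumerate(zip(labels, seeds)):
        sid = f"{id_prefix}{i:03d}"
        rec = generate_slide(spec, label, sid, sseed, domain)
        records.append(rec)
        img_path, mask_path = f"{sid}.png", f"{sid}_mask.png"
        if out is not None:
            Image.fromarray(rec.image).save(out / img_path)
            Image.fromarray((rec.tumor_mask * 255).astype(np.uint8)).save(out / mask_path)
            np.savetxt(out / f"{sid}_tiles.csv", rec.tile_classes, fmt="%d", delimiter=",")
        rows.append({"slide_id": sid, "image_path": img_path, "mask_path": mask_path,
                     "label": label, "domain": domain, "seed": sseed})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return records, manifest


def load_cohort(manifest_path: str | Path) -> list[SlideRecord]:
    """Load slides listed in a manifest table (paths relative to it)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    records = []
    for row in manifest.itertuples():
        image = np.asarray(Image.open(root / row.image_path).convert("RGB"))
        mask = (np.asarray(Image.open(root / row.mask_path).convert("L")) > 127)
        tiles_path = root / f"{row.slide_id}_tiles.csv"
        tiles = None
        if tiles_path.exists():
            tiles = np.loadtxt(tiles_path, dtype=np.int8, delimiter=",", ndmin=2)
        records.append(SlideRecord(
            slide_id=str(row.slide_id), image=image,
            tumor_mask=mask.astype(np.uint8), label=str(row.label),
            domain=str(row.domain), seed=int(row.seed), tile_classes=tiles))
    return records
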