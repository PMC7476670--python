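"""Tumor-masked tiling of slides into labeled, grid-indexed patches.

A slide's tumor region is covered with an axis-aligned, non-overlapping grid
of ``patch_dim``-sized windows anchored (by default) at the top-left corner
of the tumor-mask bounding box. A window is kept as a tumor patch when its
tumor-pixel fraction strictly exceeds the threshold (default 0.9, i.e. the
">90% tumor area" rule); kept windows inherit the slide's weak label and are
resized by area averaging to the working patch size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize_local_mean

from .synthetic import SlideRecord

__all__ = [
    "PatchRecord",
    "PatchGrid",
    "compute_tumor_ratio",
    "resize_patch",
    "tile_slide",
    "save_patches",
    "load_patch_index",
    "PATCH_INDEX_COLUMNS",
]

PATCH_INDEX_COLUMNS = ["slide_id", "grid_row", "grid_col", "path", "label",
                       "tumor_ratio", "native_dim"]


@dataclass
class PatchRecord:
    slide_id: str
    grid_row: int
    grid_col: int
    pixels: np.ndarray          # (resize_to, resize_to, 3) uint8
    label: str                  # inherited slide label, POS | NEG
    native_dim: int             # source window side in px
    tumor_ratio: float

    @property
    def y(self) -> int:
        return 1 if self.label == "POS" else 0


@dataclass
class PatchGrid:
    slide_id: str
    grid_shape: tuple[int, int]
    tumor_cells: np.ndarray                  # (Hg, Wg) uint8, 1 = patch kept
    cell_index: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self):
        if int(self.tumor_cells.sum()) != len(self.cell_index):
            raise ValueError("tumor_cells count disagrees with cell_index")


def compute_tumor_ratio(mask_window: np.ndarray) -> float:
    """Fraction of tumor pixels in a square mask window."""
    w = np.asarray(mask_window)
    if w.size == 0:
        raise ValueError("empty mask window")
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"expected a square window, got shape {w.shape}")
    return float(np.count_nonzero(w)) / w.size


def resize_patch(window: np.ndarray, target: int, allow_upscale: bool = False) -> np.ndarray:
    """Area-average resize of a square RGB window to target x target."""
    n = window.shape[0]
    if window.ndim != 3 or window.shape[0] != window.shape[1]:
        raise ValueError(f"expected a square HxWx3 window, got {window.shape}")
    if n == target:
        return window.copy()
    if n < target and not allow_upscale:
        raise ValueError(
            f"refusing to upscale {n}px window to {target}px (set allow_upscale)")
    out = resize_local_mean(window.astype(np.float64), (target, target, window.shape[2]))
    if np.issubdtype(window.dtype, np.integer):
        return np.round(out).astype(window.dtype)
    return out.astype(window.dtype)


def tile_slide(slide: SlideRecord, patch_dim: int, min_tumor_ratio: float = 0.9,
               resize_to: int = 256, anchor: str = "bbox",
               allow_upscale: bool = False):
    """Tile one slide; returns (PatchGrid, list[PatchRecord]).

    Windows are half-open pixel ranges [r*d, (r+1)*d) x [c*d, (c+1)*d) from
    the anchor (tumor-mask bounding-box corner, or the slide origin with
    ``anchor="slide"``); only full-size windows inside the slide are
    considered, and a window is kept iff tumor_ratio > min_tumor_ratio
    (strict, so a ratio of exactly 0.9 is excluded).
    """
    mask = np.asarray(slide.tumor_mask) != 0
    h, w = mask.shape
    if patch_dim > h or patch_dim > w:
        raise ValueError(f"patch_dim {patch_dim} exceeds slide size {h}x{w}")
    if anchor not in ("bbox", "slide"):
        raise ValueError("anchor must be 'bbox' or 'slide'")
    if not mask.any():
        warnings.warn(f"slide {slide.slide_id}: tumor mask is empty; no patches")
        return PatchGrid(slide.slide_id, (0, 0), np.zeros((0, 0), np.uint8)), []

    if anchor == "bbox":
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        r0, c0 = int(rows[0]), int(cols[0])
        extent = (int(rows[-1]) - r0 + 1, int(cols[-1]) - c0 + 1)
    else:
        r0, c0 = 0, 0
        extent = (h, w)
    grid_shape = (int(np.ceil(extent[0] / patch_dim)),
                  int(np.ceil(extent[1] / patch_dim)))
    tumor_cells = np.zeros(grid_shape, dtype=np.uint8)
    cell_index: dict[tuple[int, int], int] = {}
    patches: list[PatchRecord] = []
    for gr in range(grid_shape[0]):
        y = r0 + gr * patch_dim
        if y + patch_dim > h:
            continue
        for gc in range(grid_shape[1]):
            x = c0 + gc * patch_dim
            if x + patch_dim > w:
                continue
            ratio = compute_tumor_ratio(mask[y:y + patch_dim, x:x + patch_dim])
            if ratio > min_tumor_ratio:
                window = slide.image[y:y + patch_dim, x:x + patch_dim]
                pixels = resize_patch(window, resize_to, allow_upscale=allow_upscale)
                cell_index[(gr, gc)] = len(patches)
                tumor_cells[gr, gc] = 1
                patches.append(PatchRecord(
                    slide_id=slide.slide_id, grid_row=gr, grid_col=gc,
                    pixels=pixels, label=slide.label, native_dim=patch_dim,
                    tumor_ratio=ratio))
    return PatchGrid(slide.slide_id, grid_shape, tumor_cells, cell_index), patches


def save_patches(patches: list[PatchRecord], out_dir: str | Path) -> pd.DataFrame:
    """Persist patches as PNGs named slide_id/r_c.png plus an index table."""
    out = Path(out_dir)
    rows = []
    for p in patches:
        rel = Path(p.slide_id) / f"{p.grid_row}_{p.grid_col}.png"
        (out / p.slide_id).mkdir(parents=True, exist_ok=True)
        Image.fromarray(p.pixels).save(out / rel)
        rows.append({"slide_id": p.slide_id, "grid_row": p.grid_row,
                     "grid_col": p.grid_col, "path": str(rel), "label": p.label,
                     "tumor_ratio": p.tumor_ratio, "native_dim": p.native_dim})
    index = pd.DataFrame(rows, columns=PATCH_INDEX_COLUMNS)
    index.to_csv(out / "patch_index.csv", index=False)
    return index


def load_patch_index(index_path: str | Path) -> list[PatchRecord]:
    index_path = Path(index_path)
    root = index_path.parent
    df = pd.read_csv(index_path)
    patches = []
    for row in df.itertuples():
        pixels = np.asarray(Image.open(root / row.path).convert("RGB"))
        patches.append(PatchRecord(
            slide_id=str(row.slide_id), grid_row=int(row.grid_row),
            grid_col=int(row.grid_col), pixels=pixels, label=str(row.label),
            native_dim=int(row.native_dim), tumor_ratio=float(row.tumor_ratio)))
    return patches
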