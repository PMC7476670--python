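"""Patch transforms for training and evaluation.

Training: a random ``crop_px`` sub-window (default 224 from a 256 patch),
independent horizontal/vertical flips, then color jitter — multiplicative
brightness/contrast/saturation factors drawn uniformly from
``[jitter_low, jitter_high]`` (default 0.6-1.4) and an additive hue rotation
drawn from the same centered range scaled by ``hue_max_shift`` (hue is an
angle, so a multiplicative factor is not meaningful; the additive shift is
the standard library convention and is documented as approximate). The order
of the four color sub-operations is randomized per call.

Evaluation: a deterministic center crop, no color change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv

__all__ = ["AugmentConfig", "sample_augment_params", "train_transform",
           "eval_transform"]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class AugmentConfig:
    crop_px: int = 224
    jitter_low: float = 0.6
    jitter_high: float = 1.4
    flip_prob: float = 0.5
    hue_max_shift: float = 0.1   # fraction of the hue circle at full jitter
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.jitter_low <= 1 <= self.jitter_high):
            raise ValueError("jitter range must satisfy 0 < low <= 1 <= high")
        if not 0 <= self.flip_prob <= 1:
            raise ValueError("flip_prob must be in [0, 1]")


def sample_augment_params(input_side: int, cfg: AugmentConfig,
                          rng: np.random.Generator) -> dict:
    """Draw one set of augmentation parameters (exposed for testability)."""
    if cfg.crop_px > input_side:
        raise ValueError(f"crop_px {cfg.crop_px} exceeds input side {input_side}")
    max_off = input_side - cfg.crop_px
    offset = (int(rng.integers(0, max_off + 1)), int(rng.integers(0, max_off + 1)))
    flip_h = bool(rng.random() < cfg.flip_prob)
    flip_v = bool(rng.random() < cfg.flip_prob)
    factors = {
        "brightness": float(rng.uniform(cfg.jitter_low, cfg.jitter_high)),
        "contrast": float(rng.uniform(cfg.jitter_low, cfg.jitter_high)),
        "saturation": float(rng.uniform(cfg.jitter_low, cfg.jitter_high)),
    }
    hue_shift = float(rng.uniform(cfg.jitter_low - 1.0, cfg.jitter_high - 1.0)
                      * cfg.hue_max_shift)
    order = list(rng.permutation(["brightness", "contrast", "saturation", "hue"]))
    return {"offset": offset, "flip_h": flip_h, "flip_v": flip_v,
            "factors": factors, "hue_shift": hue_shift, "order": order}


def _apply_color_jitter(x: np.ndarray, factors: dict, hue_shift: float,
                        order: list[str]) -> np.ndarray:
    """x in [0,1] float; returns jittered [0,1] float."""
    for op in order:
        if op == "brightness":
            x = x * factors["brightness"]
        elif op == "contrast":
            m = float((np.clip(x, 0, 1) @ _LUMA).mean())
            x = (x - m) * factors["contrast"] + m
        elif op == "saturation":
            g = np.clip(x, 0, 1) @ _LUMA
            x = g[..., None] + (x - g[..., None]) * factors["saturation"]
        elif op == "hue":
            hsv = rgb2hsv(np.clip(x, 0, 1))
            hsv[..., 0] = (hsv[..., 0] + hue_shift) % 1.0
            x = hsv2rgb(hsv)
        x = np.clip(x, 0.0, 1.0)
    return x


def train_transform(patch: np.ndarray, cfg: AugmentConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Random crop + flips + color jitter; dtype preserved."""
    side = patch.shape[0]
    params = sample_augment_params(side, cfg, rng)
    r, c = params["offset"]
    out = patch[r:r + cfg.crop_px, c:c + cfg.crop_px]
    if params["flip_h"]:
        out = out[:, ::-1]
    if params["flip_v"]:
        out = out[::-1, :]
    out = np.ascontiguousarray(out)
    identity_color = (all(f == 1.0 for f in params["factors"].values())
                      and params["hue_shift"] == 0.0)
    if identity_color:
        return out.copy()
    is_int = np.issubdtype(patch.dtype, np.integer)
    x = out.astype(np.float64) / (255.0 if is_int else 1.0)
    x = _apply_color_jitter(x, params["factors"], params["hue_shift"], params["order"])
    if is_int:
        return np.round(x * 255.0).astype(patch.dtype)
    return x.astype(patch.dtype)


def eval_transform(patch: np.ndarray, crop_px: int = 224) -> np.ndarray:
    """Deterministic center crop ((side-crop)//2 offset); no color change."""
    side = patch.shape[0]
    if crop_px > side:
        raise ValueError(f"crop_px {crop_px} exceeds input side {side}")
    off = (side - crop_px) // 2
    return np.ascontiguousarray(patch[off:off + crop_px, off:off + crop_px])
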