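"""Nonparametric histogram skin color model and likelihood classifier.

Two 3D color histograms (one for skin, one for non-skin) are accumulated
in 24-bit RGB space with 32 bins per channel (32,768 bins each) and
normalised to discrete probability distributions.  A pixel x is labelled

    skin     if p(x | skin) > p(x | nonskin)
    nonskin  otherwise

i.e. class-conditional likelihoods are compared directly; class priors
are not used, and ties (including bins unseen in both classes) fall to
nonskin via the "otherwise" branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DataError

BINS_PER_CHANNEL = 32
_BIN_WIDTH = 256 // BINS_PER_CHANNEL  # 8

SKIN_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SkinHistogramModel:
    """Paired 32x32x32 probability histograms for skin and non-skin."""

    skin_hist: np.ndarray
    nonskin_hist: np.ndarray
    skin_count: int
    nonskin_count: int
    smoothing: float = 0.0

    def __post_init__(self):
        for attr in ("skin_hist", "nonskin_hist"):
            h = np.asarray(getattr(self, attr), dtype=float)
            if h.shape != (BINS_PER_CHANNEL,) * 3:
                raise DataError(f"{attr} must be 32x32x32, got {h.shape}")
            if h.min() < 0.0:
                raise DataError(f"{attr} has negative entries")
            if abs(h.sum() - 1.0) > 1e-9:
                raise DataError(f"{attr} must sum to 1 (got {h.sum()!r})")
            object.__setattr__(self, attr, h)

    def to_json(self) -> str:
        return json.dumps({
            "format_version": SKIN_MODEL_FORMAT_VERSION,
            "bins_per_channel": BINS_PER_CHANNEL,
            "skin_count": int(self.skin_count),
            "nonskin_count": int(self.nonskin_count),
            "smoothing": float(self.smoothing),
            "skin_hist": self.skin_hist.ravel().tolist(),
            "nonskin_hist": self.nonskin_hist.ravel().tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "SkinHistogramModel":
        d = json.loads(text)
        if d.get("bins_per_channel") != BINS_PER_CHANNEL:
            raise DataError("unsupported bin count in skin model file")
        shape = (BINS_PER_CHANNEL,) * 3
        return cls(
            skin_hist=np.asarray(d["skin_hist"], dtype=float).reshape(shape),
            nonskin_hist=np.asarray(d["nonskin_hist"], dtype=float).reshape(shape),
            skin_count=int(d["skin_count"]),
            nonskin_count=int(d["nonskin_count"]),
            smoothing=float(d.get("smoothing", 0.0)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "SkinHistogramModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def rgb_to_bin(rgb) -> tuple:
    """Map an 8-bit RGB triple to its (floor-division) histogram bin."""
    arr = np.asarray(rgb)
    if arr.shape != (3,):
        raise DataError("expected a single 8-bit RGB triple")
    if np.any(arr < 0) or np.any(arr > 255):
        raise DataError(f"channel values outside 0..255: {tuple(arr)}")
    return tuple(int(v) // _BIN_WIDTH for v in arr)


def _accumulate(pixels) -> tuple:
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
        raise DataError("training pixels must be a nonempty (n, 3) array")
    if np.any(arr < 0) or np.any(arr > 255):
        raise DataError("training pixel values outside 0..255")
    bins = arr.astype(np.int64) // _BIN_WIDTH
    hist = np.zeros((BINS_PER_CHANNEL,) * 3, dtype=float)
    np.add.at(hist, (bins[:, 0], bins[:, 1], bins[:, 2]), 1.0)
    return hist, arr.shape[0]


def train_skin_model(skin_pixels, nonskin_pixels,
                     smoothing: float = 0.0) -> SkinHistogramModel:
    """Accumulate per-bin counts for both classes and normalise.

    ``smoothing`` adds that constant to every bin before normalisation
    (0 by default: raw counts).
    """
    if smoothing < 0:
        raise DataError("smoothing must be nonnegative")
    skin_hist, n_skin = _accumulate(skin_pixels)
    nonskin_hist, n_nonskin = _accumulate(nonskin_pixels)
    skin_hist += smoothing
    nonskin_hist += smoothing
    return SkinHistogramModel(
        skin_hist=skin_hist / skin_hist.sum(),
        nonskin_hist=nonskin_hist / nonskin_hist.sum(),
        skin_count=n_skin,
        nonskin_count=n_nonskin,
        smoothing=smoothing,
    )


def classify_pixel(rgb, model: SkinHistogramModel) -> str:
    """Label one 8-bit RGB triple 'skin' or 'nonskin'."""
    b = rgb_to_bin(rgb)
    return "skin" if model.skin_hist[b] > model.nonskin_hist[b] else "nonskin"


def classify_image(image, model: SkinHistogramModel) -> np.ndarray:
    """Per-pixel skin mask for an image with channels in [0, 1].

    The image is quantised to 8 bits (round-half-away after scaling by
    255) before bin lookup; returns a boolean H x W raster.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        return np.zeros(img.shape[:2], dtype=bool)
    if img.ndim != 3 or img.shape[2] != 3:
        raise DataError(f"expected an H x W x 3 image, got shape {img.shape}")
    q = np.clip(np.rint(img * 255.0), 0, 255).astype(np.int64)
    bins = q // _BIN_WIDTH
    idx = (bins[..., 0], bins[..., 1], bins[..., 2])
    return model.skin_hist[idx] > model.nonskin_hist[idx]
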