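"""Per-region trimmed-mean CIELAB color features.

Each facial region is summarised by the quartile-trimmed mean of its
L*, a* and b* pixel values: the lowest floor(n/4) and highest
floor(n/4) values of each channel are discarded independently before
averaging, which suppresses localised outliers (rashes, dots, scars,
whiskers) while reflecting the overall color of the region.

The left and right cheek circles are pooled into single "upper_cheek"
and "lower_cheek" records (one pixel multiset per pair, not an average
of per-side means).  All regions except the lip are restricted to
pixels the skin classifier accepts; the lip bypasses the skin mask
because lip color is, by design, not skin-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .landmarks import ROIMaskSet

logger = logging.getLogger(__name__)

#: Output region names, in reporting order.
FEATURE_REGIONS = ("whole_face", "forehead", "upper_cheek", "lower_cheek",
                   "nose", "chin", "lip")

#: Regions whose pixel set is the union of two rasters.
_POOLED = {
    "upper_cheek": ("upper_cheek_right", "upper_cheek_left"),
    "lower_cheek": ("lower_cheek_right", "lower_cheek_left"),
}

#: Regions exempt from the skin-mask restriction.
_SKIN_EXEMPT = frozenset({"lip"})


@dataclass(frozen=True)
class ColorFeatureRecord:
    subject_id: str
    region: str
    L_star: float
    a_star: float
    b_star: float
    n_pixels: int


def trimmed_mean(values) -> float:
    """Mean after discarding the lowest and highest floor(n/4) values.

    For n < 4 nothing is discarded.  Deterministic for every n.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise DataError("trimmed_mean of an empty sample")
    k = arr.size // 4
    kept = np.sort(arr)[k:arr.size - k]
    return float(kept.mean())


def extract_region_colors(lab, masks: ROIMaskSet, skin_mask,
                          subject_id: str) -> list:
    """Trimmed-mean L*, a*, b* per region; empty regions are omitted.

    ``lab`` is the H x W x 3 CIELAB image; ``skin_mask`` a boolean H x W
    raster.  Each channel is trimmed on its own distribution.
    """
    lab = np.asarray(lab, dtype=float)
    skin_mask = np.asarray(skin_mask, dtype=bool)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise DataError(f"expected an H x W x 3 CIELAB image, got {lab.shape}")
    if lab.shape[:2] != (masks.height, masks.width):
        raise DataError("mask set dimensions do not match the image")
    if skin_mask.shape != lab.shape[:2]:
        raise DataError("skin mask dimensions do not match the image")

    records = []
    for region in FEATURE_REGIONS:
        if region in _POOLED:
            a, b = _POOLED[region]
            mask = masks.masks[a] | masks.masks[b]
        else:
            mask = masks.masks[region]
        if region not in _SKIN_EXEMPT:
            mask = mask & skin_mask
        n = int(mask.sum())
        if n == 0:
            logger.warning("region '%s' of subject '%s' has no surviving "
                           "pixels; record omitted", region, subject_id)
            continue
        px = lab[mask]
        records.append(ColorFeatureRecord(
            subject_id=subject_id,
            region=region,
            L_star=trimmed_mean(px[:, 0]),
            a_star=trimmed_mean(px[:, 1]),
            b_star=trimmed_mean(px[:, 2]),
            n_pixels=n,
        ))
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Stack feature records into the canonical long-format table."""
    return pd.DataFrame(
        [{"subject_id": r.subject_id, "region": r.region,
          "L_star": r.L_star, "a_star": r.a_star, "b_star": r.b_star,
          "n_pixels": r.n_pixels} for r in records],
        columns=["subject_id", "region", "L_star", "a_star", "b_star",
                 "n_pixels"],
    )
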