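"""File formats: images, landmark JSON, model JSON, CSV tables."""

from __future__ import annotations

import json

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .correction import TERM_ORDER, PolynomialCorrectionModel, TargetChart
from .errors import DataError
from .landmarks import LandmarkSet


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG as an H x W x 3 float array in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return np.clip(arr.astype(float), 0.0, 1.0)


def save_image(path, image) -> None:
    """Write a float [0, 1] image (or boolean mask) as 8-bit PNG/JPEG."""
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    else:
        arr = np.clip(np.rint(np.asarray(arr, float) * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def load_landmarks(path) -> LandmarkSet:
    """Read the landmark JSON interchange format.

    ``{"image": name, "width": W, "height": H,
       "points": {"1": [x, y], ..., "79": [x, y]}, "extrapolated": bool}``
    with 1-based keys.
    """
    with open(path) as fh:
        d = json.load(fh)
    pts_map = d.get("points")
    if not isinstance(pts_map, dict):
        raise DataError("landmark file lacks a 'points' mapping")
    try:
        pts = np.array([pts_map[str(i)] for i in range(1, 80)], dtype=float)
    except KeyError as exc:
        raise DataError(f"landmark file missing point {exc}") from exc
    return LandmarkSet(pts, image_width=int(d["width"]),
                       image_height=int(d["height"]),
                       extrapolated=bool(d.get("extrapolated", False)))


def save_landmarks(path, landmarks: LandmarkSet, image_name: str = "") -> None:
    d = {
        "image": image_name,
        "width": int(landmarks.image_width),
        "height": int(landmarks.image_height),
        "points": {str(i): [float(v) for v in landmarks.pt(i)]
                   for i in range(1, 80)},
        "extrapolated": bool(landmarks.extrapolated),
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


def load_correction_model(path) -> PolynomialCorrectionModel:
    with open(path) as fh:
        d = json.load(fh)
    if tuple(d.get("term_order", ())) != TERM_ORDER:
        raise DataError("correction model file has an unexpected term order")
    return PolynomialCorrectionModel(np.asarray(d["coefficients"], dtype=float))


def save_correction_model(path, model: PolynomialCorrectionModel) -> None:
    with open(path, "w") as fh:
        json.dump({"term_order": list(model.term_order),
                   "coefficients": model.coefficients.tolist()}, fh, indent=1)


def load_target_chart(path) -> TargetChart:
    """Read a target chart CSV (columns patch_index, R, G, B; 0-1 floats)."""
    df = pd.read_csv(path)
    needed = {"patch_index", "R", "G", "B"}
    if not needed.issubset(df.columns):
        raise DataError(f"target chart CSV needs columns {sorted(needed)}")
    df = df.sort_values("patch_index")
    if list(df["patch_index"]) != list(range(24)):
        raise DataError("target chart CSV must enumerate patch_index 0..23")
    return TargetChart(df[["R", "G", "B"]].to_numpy(dtype=float))


def save_target_chart(path, target: TargetChart) -> None:
    df = pd.DataFrame(target.colors, columns=["R", "G", "B"])
    df.insert(0, "patch_index", range(24))
    df.to_csv(path, index=False)


def load_labeled_pixels(path) -> tuple:
    """Read the labeled-pixel CSV (R, G, B, label in {skin, nonskin})."""
    df = pd.read_csv(path)
    needed = {"R", "G", "B", "label"}
    if not needed.issubset(df.columns):
        raise DataError(f"labeled-pixel CSV needs columns {sorted(needed)}")
    bad = set(df["label"]) - {"skin", "nonskin"}
    if bad:
        raise DataError(f"unknown labels in pixel CSV: {sorted(bad)}")
    skin = df.loc[df["label"] == "skin", ["R", "G", "B"]].to_numpy()
    nonskin = df.loc[df["label"] == "nonskin", ["R", "G", "B"]].to_numpy()
    return skin, nonskin
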