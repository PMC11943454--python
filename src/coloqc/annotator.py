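"""Annotation encodings: color-coded TIFF for review, grayscale PNG for training.

A label map assigns every pixel one RegionClass.  Two lossless encodings are
used: a 24-bit color TIFF for on-screen quality control (pure red mucosa,
pure green residues, pure blue artifacts, pure black lumen) and an 8-bit
grayscale PNG consumed by the training code (mucosa 64, residues 94,
artifacts 124, lumen 154, background/unclassified 0).  Both are exact
inverses through the label map; JPEG is never used because compression would
corrupt the pure marker colors.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .color_features import RegionClass

#: RGB marker colors of the review encoding.
COLOR_CODE: dict[RegionClass, tuple[int, int, int]] = {
    RegionClass.MUCOSA: (255, 0, 0),
    RegionClass.RESIDUE: (0, 255, 0),
    RegionClass.ARTIFACT: (0, 0, 255),
    RegionClass.LUMEN: (0, 0, 0),
}

#: Gray levels of the training encoding; 0 marks unannotated background.
GRAY_CODE: dict[RegionClass, int] = {
    RegionClass.MUCOSA: 64,
    RegionClass.RESIDUE: 94,
    RegionClass.ARTIFACT: 124,
    RegionClass.LUMEN: 154,
    RegionClass.UNCLASSIFIED: 0,
}

#: Marker used for unclassified pixels in the color encoding when no source
#: frame is supplied (mid-gray; distinct from all four pure marker colors).
UNCLASSIFIED_COLOR = (128, 128, 128)

_GRAY_TO_CLASS = {v: k for k, v in GRAY_CODE.items()}
_COLOR_TO_CLASS = {v: k for k, v in COLOR_CODE.items()}


def _check_labels(labels: np.ndarray) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.ndim != 2:
        raise ValueError("label map must be 2-D")
    if arr.max(initial=0) > int(RegionClass.UNCLASSIFIED):
        raise ValueError("label map holds values outside RegionClass")
    return arr.astype(np.uint8)


def write_color_annotation(
    labels: np.ndarray, path: str | Path, frame: np.ndarray | None = None
) -> None:
    """Write the review encoding as a lossless 24-bit TIFF.

    Unclassified pixels keep the original frame pixel when ``frame`` is
    given (mirroring the visual QA workflow), otherwise mid-gray.
    """
    arr = _check_labels(labels)
    if frame is None:
        out = np.empty(arr.shape + (3,), dtype=np.uint8)
        out[:] = UNCLASSIFIED_COLOR
    else:
        out = np.asarray(frame, dtype=np.uint8).copy()
        if out.shape[:2] != arr.shape:
            raise ValueError("frame and label map dimensions differ")
    for cls, rgb in COLOR_CODE.items():
        out[arr == int(cls)] = rgb
    tifffile.imwrite(Path(path), out)


def write_training_label(labels: np.ndarray, path: str | Path) -> None:
    """Write the training encoding as a single-channel 8-bit PNG."""
    arr = _check_labels(labels)
    lut = np.zeros(256, dtype=np.uint8)
    for cls, g in GRAY_CODE.items():
        lut[int(cls)] = g
    iio.imwrite(Path(path), lut[arr], extension=".png")


def decode_gray(img: np.ndarray) -> np.ndarray:
    """Decode a grayscale training label image to a RegionClass map."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError("training label must be single-channel")
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for g, cls in _GRAY_TO_CLASS.items():
        out[arr == g] = int(cls)
    if (out == 255).any():
        bad = int(arr[out == 255].flat[0])
        raise ValueError(f"unknown gray level {bad} in training label")
    return out


def decode_color(img: np.ndarray, strict: bool = False) -> np.ndarray:
    """Decode a color annotation image to a RegionClass map.

    Pixels matching none of the four pure marker colors decode to
    UNCLASSIFIED (they carry the original frame content or the mid-gray
    filler).  With ``strict`` any such pixel other than the mid-gray filler
    raises instead.
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("color annotation must be H x W x 3")
    out = np.full(arr.shape[:2], int(RegionClass.UNCLASSIFIED), dtype=np.uint8)
    matched = np.zeros(arr.shape[:2], dtype=bool)
    for rgb, cls in _COLOR_TO_CLASS.items():
        hit = np.all(arr == np.array(rgb, dtype=np.uint8), axis=-1)
        out[hit] = int(cls)
        matched |= hit
    if strict:
        filler = np.all(arr == np.array(UNCLASSIFIED_COLOR, dtype=np.uint8), axis=-1)
        stray = ~(matched | filler)
        if stray.any():
            bad = tuple(int(v) for v in arr[stray][0])
            raise ValueError(f"unknown annotation color {bad}")
    return out


def read_label(path: str | Path) -> np.ndarray:
    """Read either encoding back into a RegionClass label map."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 2:
        return decode_gray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        return decode_color(arr[..., :3])
    raise ValueError(f"unsupported label image shape {arr.shape}")
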