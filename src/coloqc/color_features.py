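"""Color-occupancy-cube pixel classification in coded CIELAB space.

A colonoscopy frame is characterised by four regions of interest: intestinal
mucosa (reds to browns), residues (yellows to browns), the dark lumen, and
bright/uninformative artifacts.  For each of the first three, a *color cube*
is accumulated from a library of small rectangular image patches: a logical
256x256x256 occupancy array over byte-coded CIELAB coordinates, counting how
often each color nuance occurs in the library.  Classification of a pixel then
proceeds rule-first:

1. coded L >= ``artifact_L_min`` (default 253)  -> ARTIFACT
2. coded L <  ``lumen_L_max``   (default 50)    -> LUMEN
3. otherwise the pixel is assigned to the cube with the largest occupancy
   count at its coordinate (ties broken by a fixed precedence), or left
   UNCLASSIFIED when no cube contains the nuance.

The byte coding of CIELAB (D65 illuminant, 2-degree observer) is

    L_coded = round(L* * 255 / 100),  a_coded = round(a* + 128),
    b_coded = round(b* + 128),

each clamped to [0, 255], so a triplet such as (118, 129, 143) addresses one
cell of the cube.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.color import rgb2lab


class RegionClass(IntEnum):
    """The four regions of interest plus the rule-classifier's reject label."""

    MUCOSA = 0
    RESIDUE = 1
    ARTIFACT = 2
    LUMEN = 3
    UNCLASSIFIED = 4


#: Region classes that a trained segmentation model may emit (never UNCLASSIFIED).
MODEL_CLASSES = (
    RegionClass.MUCOSA,
    RegionClass.RESIDUE,
    RegionClass.ARTIFACT,
    RegionClass.LUMEN,
)


def rgb_to_lab8(rgb: np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB values to byte-coded CIELAB triplets.

    Parameters
    ----------
    rgb
        Array of shape ``(..., 3)`` with integer values in [0, 255] (a single
        ``(3,)`` triplet is accepted).

    Returns
    -------
    ndarray of uint8, same shape, holding ``(L_coded, a_coded, b_coded)``.
    """
    arr = np.asarray(rgb)
    if arr.shape[-1] != 3:
        raise ValueError("expected an array with a trailing axis of 3 (RGB)")
    lab = rgb2lab(arr.astype(np.float64) / 255.0)
    coded = np.empty(lab.shape, dtype=np.float64)
    coded[..., 0] = lab[..., 0] * 255.0 / 100.0
    coded[..., 1] = lab[..., 1] + 128.0
    coded[..., 2] = lab[..., 2] + 128.0
    return np.clip(np.rint(coded), 0, 255).astype(np.uint8)


def _lab8_keys(lab8: np.ndarray) -> np.ndarray:
    """Flatten coded (L, a, b) triplets to scalar cube addresses."""
    a = np.asarray(lab8, dtype=np.uint32)
    return (a[..., 0] << 16) | (a[..., 1] << 8) | a[..., 2]


@dataclass
class ColorCube:
    """Sparse occupancy counts over the 256^3 coded-Lab cube for one region.

    ``keys`` is a sorted array of scalar addresses ``(L<<16)|(a<<8)|b`` and
    ``counts`` the matching occupancy counts; cells absent from ``keys`` hold
    zero.  ``sum(counts) == n_pixels`` always.
    """

    keys: np.ndarray
    counts: np.ndarray
    n_patches: int
    n_pixels: int
    class_name: str = ""

    def __post_init__(self) -> None:
        self.keys = np.asarray(self.keys, dtype=np.uint32)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.keys.shape != self.counts.shape:
            raise ValueError("keys and counts must have the same length")
        if self.counts.sum() != self.n_pixels:
            raise ValueError("sum of counts must equal n_pixels")

    @property
    def n_nuances(self) -> int:
        return int(self.keys.size)

    def lookup(self, lab8: np.ndarray) -> np.ndarray:
        """Occupancy count at each coded-Lab coordinate (0 where absent)."""
        q = _lab8_keys(lab8)
        pos = np.searchsorted(self.keys, q)
        pos = np.minimum(pos, max(self.keys.size - 1, 0))
        out = np.zeros(q.shape, dtype=np.int64)
        if self.keys.size:
            hit = self.keys[pos] == q
            out[hit] = self.counts[pos[hit]]
        return out

    def count_at(self, lab8: Sequence[int]) -> int:
        return int(self.lookup(np.asarray(lab8).reshape(1, 3))[0])

    def __add__(self, other: "ColorCube") -> "ColorCube":
        keys = np.concatenate([self.keys, other.keys])
        counts = np.concatenate([self.counts, other.counts])
        uk, inv = np.unique(keys, return_inverse=True)
        merged = np.zeros(uk.size, dtype=np.int64)
        np.add.at(merged, inv, counts)
        return ColorCube(
            uk,
            merged,
            self.n_patches + other.n_patches,
            self.n_pixels + other.n_pixels,
            self.class_name or other.class_name,
        )

    def save(self, path: str | Path) -> None:
        """Serialise as a compressed sparse triplet file with a JSON header."""
        header = json.dumps(
            {
                "class_name": self.class_name,
                "n_patches": self.n_patches,
                "n_pixels": self.n_pixels,
            }
        )
        np.savez_compressed(
            path,
            L=(self.keys >> 16).astype(np.uint8),
            a=((self.keys >> 8) & 0xFF).astype(np.uint8),
            b=(self.keys & 0xFF).astype(np.uint8),
            count=self.counts,
            header=np.array(header),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ColorCube":
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            keys = (
                (z["L"].astype(np.uint32) << 16)
                | (z["a"].astype(np.uint32) << 8)
                | z["b"].astype(np.uint32)
            )
            order = np.argsort(keys)
            return cls(
                keys[order],
                z["count"][order],
                header["n_patches"],
                header["n_pixels"],
                header["class_name"],
            )


def build_cube(patches: Iterable[np.ndarray], class_name: str = "") -> ColorCube:
    """Accumulate a color cube from a library of RGB patch images.

    Every pixel of every patch increments the cube cell at its coded-Lab
    coordinate by one, so nuances seen repeatedly acquire larger counts and
    are treated as more characteristic of the region.

    Raises
    ------
    ValueError
        If the collection is empty or a patch is not a non-empty RGB image.
    """
    all_keys = []
    n_patches = 0
    n_pixels = 0
    for patch in patches:
        arr = np.asarray(patch)
        if arr.ndim != 3 or arr.shape[-1] != 3 or arr.size == 0:
            raise ValueError("each patch must be a non-empty H x W x 3 RGB image")
        lab8 = rgb_to_lab8(arr)
        all_keys.append(_lab8_keys(lab8).ravel())
        n_patches += 1
        n_pixels += arr.shape[0] * arr.shape[1]
    if n_patches == 0:
        raise ValueError("no patches supplied: cannot build color features")
    keys, counts = np.unique(np.concatenate(all_keys), return_counts=True)
    return ColorCube(keys, counts.astype(np.int64), n_patches, n_pixels, class_name)


@dataclass
class ClassifierRules:
    """Luminance rules and tie-breaking for the rule-based classifier.

    ``artifact_L_min``: coded-L at or above which a pixel is an artifact
    (very bright nuances: reflections, overexposure, overlays).
    ``lumen_L_max``: coded-L strictly below which a pixel is lumen (the dark
    cavity ahead of the endoscope).  ``precedence`` orders the cube classes
    for ties in occupancy count; residues come first because they are rarer
    and clinically critical.
    """

    artifact_L_min: int = 253
    lumen_L_max: int = 50
    precedence: tuple[RegionClass, ...] = (
        RegionClass.RESIDUE,
        RegionClass.MUCOSA,
        RegionClass.LUMEN,
    )

    def __post_init__(self) -> None:
        if not 0 <= self.lumen_L_max < self.artifact_L_min <= 255:
            raise ValueError("require 0 <= lumen_L_max < artifact_L_min <= 255")


REQUIRED_CUBES = (RegionClass.MUCOSA, RegionClass.RESIDUE, RegionClass.LUMEN)


def classify_lab8(
    lab8: np.ndarray,
    cubes: Mapping[RegionClass, ColorCube],
    rules: ClassifierRules | None = None,
) -> np.ndarray:
    """Classify an array of coded-Lab triplets; returns RegionClass values."""
    rules = rules or ClassifierRules()
    for cls in REQUIRED_CUBES:
        if cls not in cubes:
            raise KeyError(f"missing required color cube for {cls.name}")
    lab8 = np.asarray(lab8)
    L = lab8[..., 0].astype(np.int64)
    out = np.full(L.shape, int(RegionClass.UNCLASSIFIED), dtype=np.uint8)

    # occupancy votes, stacked in precedence order so argmax resolves ties
    stacked = np.stack([cubes[c].lookup(lab8) for c in rules.precedence], axis=0)
    best = np.argmax(stacked, axis=0)
    any_hit = stacked.max(axis=0) > 0
    prec = np.array([int(c) for c in rules.precedence], dtype=np.uint8)
    out[any_hit] = prec[best[any_hit]]

    out[L < rules.lumen_L_max] = int(RegionClass.LUMEN)
    out[L >= rules.artifact_L_min] = int(RegionClass.ARTIFACT)
    return out


def classify_pixel(
    lab8: Sequence[int],
    cubes: Mapping[RegionClass, ColorCube],
    rules: ClassifierRules | None = None,
) -> RegionClass:
    """Classify a single coded-Lab triplet."""
    res = classify_lab8(np.asarray(lab8, dtype=np.uint8).reshape(1, 3), cubes, rules)
    return RegionClass(int(res[0]))


def classify_frame(
    frame: np.ndarray,
    cubes: Mapping[RegionClass, ColorCube],
    rules: ClassifierRules | None = None,
) -> np.ndarray:
    """Classify every pixel of a 24-bit RGB frame.

    Returns a label map (H x W uint8 of RegionClass values) with the same
    spatial dimensions as the input.
    """
    arr = np.asarray(frame)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("frame must be an H x W x 3 RGB image")
    return classify_lab8(rgb_to_lab8(arr), cubes, rules)
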