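"""Synthetic colonoscopy-like frames with exact ground-truth masks.

Real colonoscopy video cannot be redistributed, so every stage of the
pipeline is exercised on generated data: organic blob-shaped regions of
mucosa-like (red-brown), residue-like (yellow-brown), dark-lumen and
bright-artifact colors, with the generating mask kept as ground truth.

Region colors are drawn from per-class RGB samplers whose supports are
chosen so the luminance rules hold by construction: lumen samples always
code to L < 50, bright-artifact samples always to L >= 253 (all channels in
[253, 255]).  Mucosa and residue occupy red-brown and yellow-brown boxes
whose green-channel ranges are disjoint by default; a ``hue_overlap``
parameter in [0, 1] slides the two boxes together so tests can probe the
cube tie-break and the segmentation model's advantage over the rule-based
classifier on ambiguous nuances.

Region geometry: a Gaussian-smoothed white-noise field is partitioned at
the quantiles of the requested area fractions, producing seeded, connected,
organically shaped regions whose areas match the request to the pixel.
There is no attempt at photorealism (no specular geometry, motion blur or
text overlays beyond the flat bright-artifact regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from . import video_stats
from .color_features import RegionClass, rgb_to_lab8
from .framedb import DEFAULT_FPS
from .video_stats import FrameStats, SegmentBoundaries, VideoReport, aggregate

#: Mask assignment order along the smoothed field's quantiles (dark lumen in
#: the field minima, bright artifacts at the maxima; fixed but arbitrary).
_FIELD_ORDER = (
    RegionClass.LUMEN,
    RegionClass.MUCOSA,
    RegionClass.RESIDUE,
    RegionClass.ARTIFACT,
)


@dataclass
class RegionPalette:
    """Per-class RGB samplers with a mucosa/residue overlap dial.

    ``hue_overlap`` = 0 keeps the mucosa and residue color boxes disjoint in
    the green channel (gap 90..100 at 0); 1 slides them ~40 gray levels into
    each other.  ``dispersion`` scales nothing by itself; the boxes are the
    dispersion.  Lumen and bright-artifact samples are rejection-validated
    against the coded-luminance rules, so rule-based classification of those
    pixels recovers ground truth with probability 1.
    """

    hue_overlap: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hue_overlap <= 1.0:
            raise ValueError("hue_overlap must lie in [0, 1]")

    def sample(self, cls: RegionClass, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` RGB colors of class ``cls`` as an (n, 3) uint8 array."""
        ov = self.hue_overlap
        if cls == RegionClass.MUCOSA:
            # reds to browns; overlap raises green toward residue territory
            r = rng.integers(120, 201, n)
            g = rng.integers(30, int(91 + 40 * ov), n)
            b = rng.integers(25, 71, n)
            rgb = np.stack([r, g, np.minimum(b, g)], axis=1)
            return self._validated(rgb, self._mid_L, cls, rng)
        if cls == RegionClass.RESIDUE:
            # yellows to browns; overlap lowers green toward mucosa territory
            r = rng.integers(150, 221, n)
            g = rng.integers(int(100 - 40 * ov), 171, n)
            b = rng.integers(20, 71, n)
            return self._validated(np.stack([r, g, b], axis=1), self._mid_L, cls, rng)
        if cls == RegionClass.LUMEN:
            r = rng.integers(10, 61, n)
            g = rng.integers(5, 41, n)
            b = rng.integers(5, 41, n)
            return self._validated(
                np.stack([r, g, b], axis=1), lambda L: L < 50, cls, rng
            )
        if cls == RegionClass.ARTIFACT:
            # very bright: every channel in [253, 255] codes to L >= 253
            return rng.integers(253, 256, (n, 3)).astype(np.uint8)
        raise ValueError("cannot sample colors for UNCLASSIFIED")

    @staticmethod
    def _mid_L(L: np.ndarray) -> np.ndarray:
        return (L >= 50) & (L < 253)

    def _validated(self, rgb, predicate, cls, rng, max_rounds: int = 20) -> np.ndarray:
        rgb = rgb.astype(np.uint8)
        for _ in range(max_rounds):
            L = rgb_to_lab8(rgb)[:, 0].astype(np.int64)
            bad = ~predicate(L)
            if not bad.any():
                return rgb
            rgb[bad] = self.sample(cls, int(bad.sum()), rng)
        raise RuntimeError(f"palette for {cls.name} cannot satisfy its rule")


@dataclass
class SceneSpec:
    """One generated frame: size, per-class area fractions, blob geometry."""

    height: int = 64
    width: int = 64
    fractions: dict = field(
        default_factory=lambda: {
            RegionClass.MUCOSA: 0.60,
            RegionClass.RESIDUE: 0.15,
            RegionClass.ARTIFACT: 0.10,
            RegionClass.LUMEN: 0.15,
        }
    )
    smoothness: float = 8.0  # sigma of the blob field, in pixels
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("area fractions must sum to 1")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("area fractions must be nonnegative")


def generate_mask(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Blob mask realising the requested area fractions to the pixel."""
    fld = gaussian_filter(
        rng.standard_normal((spec.height, spec.width)), spec.smoothness
    )
    order = np.argsort(fld.ravel(), kind="stable")
    n = order.size
    mask = np.empty(n, dtype=np.uint8)
    start = 0
    budgets = [int(round(spec.fractions.get(c, 0.0) * n)) for c in _FIELD_ORDER]
    budgets[-1] = n - sum(budgets[:-1])  # largest-remainder fixup
    for cls, budget in zip(_FIELD_ORDER, budgets):
        mask[order[start : start + budget]] = int(cls)
        start += budget
    return mask.reshape(spec.height, spec.width)


def generate_frame(
    spec: SceneSpec, palette: RegionPalette | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one RGB frame and its ground-truth label map."""
    palette = palette or RegionPalette()
    rng = np.random.default_rng(spec.seed)
    mask = generate_mask(spec, rng)
    frame = np.zeros(mask.shape + (3,), dtype=np.uint8)
    for cls in _FIELD_ORDER:
        sel = mask == int(cls)
        cnt = int(sel.sum())
        if cnt:
            frame[sel] = palette.sample(cls, cnt, rng)
    return frame, mask


def generate_patch_library(
    cls: RegionClass,
    n: int,
    palette: RegionPalette | None = None,
    seed: int = 0,
    size_range: tuple[int, int] = (30, 80),
) -> list[np.ndarray]:
    """``n`` small rectangular single-class patches (library thumbnails)."""
    if n < 1:
        raise ValueError("need at least one patch")
    if cls == RegionClass.UNCLASSIFIED:
        raise ValueError("no patch library for UNCLASSIFIED")
    palette = palette or RegionPalette()
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    patches = []
    for _ in range(n):
        h = int(rng.integers(lo, hi + 1))
        w = int(rng.integers(lo, hi + 1))
        patches.append(palette.sample(cls, h * w, rng).reshape(h, w, 3))
    return patches


#: Library sizes mirroring the real patch collections (mucosa/residue/lumen).
DEFAULT_LIBRARY_SIZES = {
    RegionClass.MUCOSA: 209,
    RegionClass.RESIDUE: 84,
    RegionClass.LUMEN: 154,
}


def generate_patch_libraries(
    palette: RegionPalette | None = None,
    seed: int = 0,
    sizes: dict | None = None,
) -> dict[RegionClass, list[np.ndarray]]:
    sizes = sizes or DEFAULT_LIBRARY_SIZES
    return {
        cls: generate_patch_library(cls, cnt, palette, seed=seed + int(cls))
        for cls, cnt in sizes.items()
    }


@dataclass
class SegmentProfile:
    """Per-segment generative condition: mean fractions plus per-frame noise.

    ``fraction_jitter`` is the s.d. of truncated-normal per-frame wobble on
    each fraction (renormalised); ``artifact_spike_prob`` is the chance a
    frame is artifact-dominated (fraction ``artifact_spike_level``),
    emulating reflections/overexposure bursts that the validity filter must
    reject.
    """

    fractions: dict
    fraction_jitter: float = 0.06
    artifact_spike_prob: float = 0.0
    artifact_spike_level: float = 0.5


def good_prep_profile() -> SegmentProfile:
    """Well-prepared segment: dominant mucosa, sparse residue/artifacts."""
    return SegmentProfile(
        fractions={
            RegionClass.MUCOSA: 0.72,
            RegionClass.RESIDUE: 0.06,
            RegionClass.ARTIFACT: 0.08,
            RegionClass.LUMEN: 0.14,
        },
        artifact_spike_prob=0.05,
    )


def poor_prep_profile() -> SegmentProfile:
    """Poorly prepared segment: heavy residue, frequent artifact bursts."""
    return SegmentProfile(
        fractions={
            RegionClass.MUCOSA: 0.40,
            RegionClass.RESIDUE: 0.22,
            RegionClass.ARTIFACT: 0.23,
            RegionClass.LUMEN: 0.15,
        },
        artifact_spike_prob=0.30,
    )


def _frame_fractions(profile: SegmentProfile, rng: np.random.Generator) -> dict:
    if rng.random() < profile.artifact_spike_prob:
        spike = profile.artifact_spike_level
        rest = 1.0 - spike
        base = {c: f for c, f in profile.fractions.items() if c != RegionClass.ARTIFACT}
        tot = sum(base.values())
        out = {c: rest * f / tot for c, f in base.items()}
        out[RegionClass.ARTIFACT] = spike
        return out
    vals = {}
    for c, f in profile.fractions.items():
        vals[c] = max(f + profile.fraction_jitter * rng.standard_normal(), 0.005)
    tot = sum(vals.values())
    return {c: v / tot for c, v in vals.items()}


def generate_video(
    n_frames: int,
    profiles: Sequence[SegmentProfile],
    seed: int = 0,
    height: int = 64,
    width: int = 64,
    palette: RegionPalette | None = None,
    validity_threshold: float = video_stats.DEFAULT_VALIDITY_THRESHOLD,
    fps: float = DEFAULT_FPS,
):
    """Generate a pseudo-video with planted segment boundaries.

    Returns ``(frames, masks, boundaries, truth_report)`` where the report
    is computed by direct counting on the ground-truth masks.  The three
    segments split ``n_frames`` near-equally at cuts ``n//3 + 1`` and
    ``2*(n//3) + 1``; when ``n//3`` is a multiple of ``fps`` the planted
    boundaries fall on whole seconds and round-trip through mm:ss
    timestamps.
    """
    if n_frames < 3:
        raise ValueError("need at least three frames for three segments")
    if len(profiles) != 3:
        raise ValueError("exactly three segment profiles required")
    rng = np.random.default_rng(seed)

    third = n_frames // 3
    cut_1_2 = max(2, third + 1)
    cut_2_3 = max(cut_1_2 + 1, 2 * third + 1)
    bounds = SegmentBoundaries(cut_1_2=cut_1_2, cut_2_3=cut_2_3)

    frames, masks, stats = [], [], []
    for i in range(1, n_frames + 1):
        profile = profiles[bounds.segment_of(i) - 1]
        spec = SceneSpec(
            height=height,
            width=width,
            fractions=_frame_fractions(profile, rng),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        frame, mask = generate_frame(spec, palette)
        frames.append(frame)
        masks.append(mask)
        stats.append(video_stats.frame_stats(mask, validity_threshold))
    truth = aggregate(stats, bounds, validity_threshold)
    return frames, masks, bounds, truth
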