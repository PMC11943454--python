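"""Frame database: extraction, naming, candidate sampling, timestamps.

Colonoscopy videos (25 frames/s, 720x576 RGB) are decomposed into lossless
TIFF frames named ``VV_FFFFF.tiff`` where ``VV`` is the zero-padded video id
and ``FFFFF`` the 1-based frame index — ``04_07563.tiff`` is the 7563rd frame
of video #4.  An ordered directory of images is accepted wherever a video
file is, so the pipeline runs without codec dependencies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import tifffile

DEFAULT_FPS = 25.0

_NAME_RE = re.compile(r"^(\d{2,})_(\d{5,})\.tiff?$", re.IGNORECASE)

_IMAGE_EXTS = {".tif", ".tiff", ".png", ".bmp", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class FrameRef:
    """Reference to one extracted frame on disk."""

    video_id: int
    frame_index: int  # 1-based
    path: Path


def format_frame_name(video_id: int, frame_index: int) -> str:
    """Canonical file name, e.g. ``format_frame_name(4, 7563) == '04_07563.tiff'``."""
    if video_id < 0 or frame_index < 1:
        raise ValueError("video_id must be >= 0 and frame_index >= 1")
    return f"{video_id:02d}_{frame_index:05d}.tiff"


def parse_frame_name(name: str) -> tuple[int, int]:
    """Inverse of :func:`format_frame_name`; raises ValueError on foreign names."""
    m = _NAME_RE.match(Path(name).name)
    if not m:
        raise ValueError(f"not a frame database file name: {name!r}")
    return int(m.group(1)), int(m.group(2))


def _iter_source_frames(source) -> Iterator[np.ndarray]:
    """Yield RGB frames from a video file, a directory of images, or arrays."""
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.is_dir():
            files = sorted(
                f for f in p.iterdir() if f.suffix.lower() in _IMAGE_EXTS
            )
            if not files:
                raise IOError(f"no image files found in {p}")
            import imageio.v3 as iio

            for f in files:
                yield np.asarray(iio.imread(f))
        else:
            import imageio.v3 as iio

            for frame in iio.imiter(p):
                yield np.asarray(frame)
    else:
        for frame in source:
            yield np.asarray(frame)


def extract_frames(source, out_dir: str | Path, video_id: int) -> list[FrameRef]:
    """Decompose a video (or ordered frame sequence) into named TIFF frames.

    One 24-bit RGB TIFF per frame is written to ``out_dir`` following the
    naming convention; indices start at 1 and are dense.  On a read failure
    the error reports how many frames were extracted before it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    refs: list[FrameRef] = []
    it = _iter_source_frames(source)
    while True:
        try:
            frame = next(it)
        except StopIteration:
            break
        except Exception as exc:  # unreadable container mid-stream
            raise IOError(
                f"failed reading source after {len(refs)} frames: {exc}"
            ) from exc
        arr = np.asarray(frame)
        if arr.ndim == 3 and arr.shape[-1] == 4:
            arr = arr[..., :3]
        if arr.ndim != 3 or arr.shape[-1] != 3:
            raise IOError(
                f"frame {len(refs) + 1} is not RGB (shape {arr.shape}); "
                f"{len(refs)} frames extracted so far"
            )
        idx = len(refs) + 1
        path = out / format_frame_name(video_id, idx)
        tifffile.imwrite(path, arr.astype(np.uint8))
        refs.append(FrameRef(video_id, idx, path))
    return refs


def load_frame(ref: FrameRef | str | Path) -> np.ndarray:
    path = ref.path if isinstance(ref, FrameRef) else Path(ref)
    return np.asarray(tifffile.imread(path))


def list_frames(frame_dir: str | Path) -> list[FrameRef]:
    """Enumerate database frames in a directory, ordered by frame index."""
    refs = []
    for f in Path(frame_dir).iterdir():
        try:
            vid, idx = parse_frame_name(f.name)
        except ValueError:
            continue
        refs.append(FrameRef(vid, idx, f))
    return sorted(refs, key=lambda r: (r.video_id, r.frame_index))


def sample_candidates(frames: Sequence, step: int = 10) -> list:
    """Every ``step``-th frame (the first, then 1+step, ...), order preserved.

    Browsing one frame in ten at 25 fps inspects the sequence every 0.4 s,
    which is dense enough for candidate selection.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    return list(frames[::step])


def timestamp_to_frame(minute: int, second: int, fps: float = DEFAULT_FPS) -> int:
    """Map a (minute, second) timestamp to a 1-based frame index.

    ``(0, 0)`` maps to frame 1; ``(0, 1)`` to frame 26 at 25 fps (25 frames
    elapse during the first second).
    """
    if minute < 0 or not 0 <= second < 60:
        raise ValueError("require minute >= 0 and 0 <= second < 60")
    if fps <= 0:
        raise ValueError("fps must be positive")
    return int(np.floor((60 * minute + second) * fps)) + 1
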