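"""Depth-frame sequence I/O and multiview synchronization.

Frames are 8-bit single-channel depth images (0 = near, 255 = far).
Sequences live on disk as ``<view>/<frame %06d>.pgm`` (binary P5) or
8-bit grayscale PNG, paired with a YAML manifest that records the
views, the number of leading background-only frames, and a labels CSV
(``frame_index,label``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

FRAME_EXTENSIONS = (".pgm", ".png")


class DepthFormatError(ValueError):
    """Raised for inputs that are not 8-bit single-channel depth images."""


@dataclass(frozen=True)
class DepthFrame:
    """One 8-bit depth image from one view at one time index."""

    pixels: np.ndarray  # uint8, shape (height, width); 0 = near, 255 = far
    frame_index: int
    view_id: str = "view0"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise DepthFormatError(
                f"depth frame must be a non-empty 2-D grid, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            raise DepthFormatError(
                f"depth frames are 8-bit (0-255); got dtype {px.dtype}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ViewStream:
    """Ordered frame sequence from one camera view."""

    frames: list[DepthFrame]
    view_id: str
    view_angle_deg: Optional[float] = None
    background_count: int = 0

    def __post_init__(self) -> None:
        if self.background_count < 0:
            raise ValueError("background_count must be >= 0")
        shapes = {f.pixels.shape for f in self.frames}
        if len(shapes) > 1:
            raise DepthFormatError(f"mixed frame dimensions in stream: {shapes}")
        indices = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def background_frames(self) -> list[DepthFrame]:
        return self.frames[: self.background_count]

    @property
    def action_frames(self) -> list[DepthFrame]:
        return self.frames[self.background_count:]


@dataclass
class MultiViewSample:
    """Synchronized frames, one per view, at a single time step."""

    frames: list[DepthFrame]
    time_index: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a sample needs at least one view")


def _load_frame_file(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        # grayscale PNGs sometimes decode with a redundant channel axis
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise DepthFormatError(f"{path.name}: multi-channel image, expected grayscale")
    if arr.dtype != np.uint8:
        raise DepthFormatError(
            f"{path.name}: dtype {arr.dtype} refused; depth dialect is fixed to 8-bit"
        )
    return arr


def read_sequence(
    source: Path | str | Sequence[Path | str],
    view_id: str = "view0",
    background_count: int = 0,
    view_angle_deg: Optional[float] = None,
) -> ViewStream:
    """Read a depth-frame sequence from a directory or explicit file list.

    Files are taken in lexicographic order; pixel values are passed
    through untouched. Non-8-bit or multi-channel inputs raise
    :class:`DepthFormatError` rather than being rescaled.
    """
    if isinstance(source, (str, Path)):
        root = Path(source)
        if not root.is_dir():
            raise FileNotFoundError(f"{root} is not a directory")
        files = sorted(
            p for p in root.iterdir() if p.suffix.lower() in FRAME_EXTENSIONS
        )
    else:
        files = [Path(p) for p in source]
    if not files:
        raise DepthFormatError(f"no frames found in {source!r}")
    frames = [
        DepthFrame(pixels=_load_frame_file(p), frame_index=i, view_id=view_id)
        for i, p in enumerate(files)
    ]
    return ViewStream(
        frames=frames,
        view_id=view_id,
        view_angle_deg=view_angle_deg,
        background_count=background_count,
    )


def write_sequence(stream: ViewStream, directory: Path | str, fmt: str = "pgm") -> list[Path]:
    """Write a stream as numbered frame files; inverse of :func:`read_sequence`."""
    if fmt not in ("pgm", "png"):
        raise ValueError(f"unsupported format {fmt!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(stream.frames):
        path = directory / f"{i:06d}.{fmt}"
        iio.imwrite(path, frame.pixels)
        paths.append(path)
    return paths


def synchronize(streams: Sequence[ViewStream]) -> list[MultiViewSample]:
    """Pair frames across views by ordinal index.

    Streams are assumed pre-synchronized at capture time, so sample *t*
    simply holds frame *t* of every stream. Output length is the minimum
    stream length; trailing extras are dropped with a warning.
    """
    if not streams:
        raise ValueError("synchronize needs at least one stream")
    n = min(len(s) for s in streams)
    for s in streams:
        if len(s) > n:
            log.warning(
                "view %s: dropping %d trailing frame(s) past the shortest stream",
                s.view_id, len(s) - n,
            )
    return [
        MultiViewSample(frames=[s.frames[t] for s in streams], time_index=t)
        for t in range(n)
    ]


# ---------------------------------------------------------------------------
# dataset manifest


@dataclass
class SequenceEntry:
    """One recorded sequence of a dataset: per-view directories plus labels."""

    sequence_id: str
    view_dirs: dict[str, str]  # view_id -> relative directory
    background_count: int
    labels_file: Optional[str] = None
    label: Optional[str] = None


@dataclass
class DatasetManifest:
    views: list[str]
    view_angles_deg: dict[str, float]
    background_count: int
    sequences: list[SequenceEntry]
    parameters: dict = field(default_factory=dict)

    def to_yaml(self, path: Path | str) -> None:
        doc = {
            "views": self.views,
            "view_angles_deg": self.view_angles_deg,
            "background_count": self.background_count,
            "parameters": self.parameters,
            "sequences": [
                {
                    "sequence_id": s.sequence_id,
                    "view_dirs": s.view_dirs,
                    "background_count": s.background_count,
                    "labels_file": s.labels_file,
                    "label": s.label,
                }
                for s in self.sequences
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "DatasetManifest":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            views=doc["views"],
            view_angles_deg=doc.get("view_angles_deg", {}),
            background_count=doc["background_count"],
            parameters=doc.get("parameters", {}),
            sequences=[SequenceEntry(**s) for s in doc["sequences"]],
        )


def read_labels(path: Path | str) -> dict[int, str]:
    """Read a ``frame_index,label`` CSV into a mapping."""
    df = pd.read_csv(path)
    return dict(zip(df["frame_index"].astype(int), df["label"].astype(str)))


def load_sequence_views(
    manifest: DatasetManifest, entry: SequenceEntry, root: Path | str
) -> list[ViewStream]:
    """Load all view streams of one manifest sequence."""
    root = Path(root)
    streams = []
    for view_id in manifest.views:
        streams.append(
            read_sequence(
                root / entry.view_dirs[view_id],
                view_id=view_id,
                background_count=entry.background_count,
                view_angle_deg=manifest.view_angles_deg.get(view_id),
            )
        )
    return streams
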