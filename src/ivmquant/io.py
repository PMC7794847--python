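"""Reading and writing imaging sessions.

A *session* is one animal imaged over ~80 minutes after probe injection:
a time-lapse frame stack (multi-page TIFF, or a directory of single-page
TIFFs in lexical order) plus a human-editable YAML sidecar carrying the
acquisition timestamps, exposure, probe name, group label and the paths of
the per-session calibration frames (dark, pre-injection background, uniform
phantom, fluorescence standard).

All pixel data is promoted to float64 on read regardless of the on-disk
integer type: the calibration chain subtracts and divides, which produces
negative and fractional values. ``write_map`` always emits 32-bit float
single-page TIFF and round-trips bit-exactly for float32 data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

from .errors import MetadataError, StructuralError, ValidationError

__all__ = [
    "FrameStack",
    "SessionMeta",
    "read_stack",
    "write_stack",
    "read_map",
    "write_map",
    "read_sidecar",
    "write_sidecar",
]


@dataclasses.dataclass
class FrameStack:
    """Ordered 2D fluorescence frames with timestamps in minutes post-injection.

    Negative timestamps denote pre-injection (baseline/background) frames.

    Parameters
    ----------
    frames
        ``(n, h, w)`` float array, one page per time point.
    times_min
        Strictly increasing acquisition times, minutes post-injection.
    probe
        Probe label, e.g. ``"BodipyFLc16"`` or ``"TMRE"``.
    exposure_s
        Camera exposure per frame in seconds (positive when given).
    pixel_size_um
        Physical pixel pitch in micrometres, optional.
    """

    frames: np.ndarray
    times_min: np.ndarray
    probe: str = "BodipyFLc16"
    exposure_s: float | None = None
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise StructuralError(
                f"frames must be a (n, h, w) array, got ndim={self.frames.ndim}"
            )
        if self.times_min.ndim != 1 or len(self.times_min) != len(self.frames):
            raise MetadataError(
                f"{len(self.times_min)} timestamps for {len(self.frames)} frames"
            )
        if len(self.times_min) > 1 and not np.all(np.diff(self.times_min) > 0):
            raise MetadataError("times_min must be strictly increasing")
        if self.exposure_s is not None and not self.exposure_s > 0:
            raise ValidationError(f"exposure_s must be > 0, got {self.exposure_s}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of one frame."""
        return self.frames.shape[1:]

    def frame_at(self, t_min: float) -> np.ndarray:
        """Frame whose timestamp is nearest ``t_min`` (ties -> earlier frame)."""
        i = nearest_time_index(self.times_min, t_min)
        return self.frames[i]


def nearest_time_index(times_min: np.ndarray, t: float) -> int:
    """Index of the timestamp nearest ``t``; exact ties go to the earlier frame."""
    d = np.abs(np.asarray(times_min, dtype=float) - t)
    return int(np.argmin(d))  # argmin returns the first (earlier) minimum


@dataclasses.dataclass
class SessionMeta:
    """Identity and design metadata for one imaging session."""

    animal_id: str
    group: str = ""
    session_day: int = 0
    paired_with: str | None = None
    extra: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.animal_id:
            raise MetadataError("animal_id must be non-empty")


def _load_pages(path: Path) -> np.ndarray:
    """Read a multi-page TIFF or a directory of single-page TIFFs as (n, h, w)."""
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise StructuralError(f"no TIFF files in directory {path}")
        pages = [np.asarray(tifffile.imread(f)) for f in files]
    else:
        try:
            arr = np.asarray(tifffile.imread(path))
        except (ValueError, tifffile.TiffFileError):
            arr = None
        if arr is not None and arr.ndim in (2, 3):
            if arr.ndim == 2:
                arr = arr[None]
            return arr.astype(float)
        # irregular file (e.g. pages of differing sizes): inspect page by page
        with tifffile.TiffFile(path) as tf:
            pages = [p.asarray() for p in tf.pages]
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise StructuralError(f"pages of differing sizes in {path}: {sorted(shapes)}")
    if pages[0].ndim != 2:
        raise StructuralError(f"expected 2D pages in {path}, got shape {pages[0].shape}")
    return np.stack([p.astype(float) for p in pages])


def read_sidecar(meta_path: str | Path) -> dict:
    """Load the YAML session sidecar as a plain dict."""
    with open(meta_path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise MetadataError(f"sidecar {meta_path} is not a key/value document")
    return doc


def write_sidecar(doc: dict, meta_path: str | Path) -> None:
    with open(meta_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_stack(
    path: str | Path, meta_path: str | Path
) -> tuple[FrameStack, SessionMeta]:
    """Read a frame stack and its sidecar.

    ``path`` may be a multi-page TIFF or a directory of single-page TIFFs in
    lexical time order. The sidecar's ``times_min`` list is authoritative and
    must match the page count.
    """
    path = Path(path)
    frames = _load_pages(path)
    doc = read_sidecar(meta_path)
    times = doc.get("times_min")
    if times is None or len(times) != len(frames):
        n = 0 if times is None else len(times)
        raise MetadataError(
            f"sidecar lists {n} timestamps but stack has {len(frames)} frames"
        )
    stack = FrameStack(
        frames=frames,
        times_min=np.asarray(times, dtype=float),
        probe=doc.get("probe", "BodipyFLc16"),
        exposure_s=doc.get("exposure_s"),
        pixel_size_um=doc.get("pixel_size_um"),
    )
    meta = SessionMeta(
        animal_id=str(doc.get("animal_id", "")),
        group=str(doc.get("group", "")),
        session_day=int(doc.get("session_day", 0)),
        paired_with=doc.get("paired_with"),
        extra={
            k: v
            for k, v in doc.items()
            if k
            not in {
                "animal_id",
                "group",
                "session_day",
                "paired_with",
                "times_min",
                "probe",
                "exposure_s",
                "pixel_size_um",
            }
        },
    )
    return stack, meta


def write_stack(
    stack: FrameStack,
    meta: SessionMeta,
    path: str | Path,
    meta_path: str | Path,
    extra_sidecar: dict | None = None,
) -> None:
    """Write a multi-page float32 TIFF plus its YAML sidecar."""
    if not np.all(np.isfinite(stack.frames)):
        raise ValidationError("stack contains non-finite pixels")
    # explicit photometric: a (3, h, w) stack must not be guessed as RGB
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    doc = {
        "animal_id": meta.animal_id,
        "group": meta.group,
        "session_day": meta.session_day,
        "paired_with": meta.paired_with,
        "probe": stack.probe,
        "exposure_s": stack.exposure_s,
        "pixel_size_um": stack.pixel_size_um,
        "times_min": [float(t) for t in stack.times_min],
    }
    if extra_sidecar:
        doc.update(extra_sidecar)
    write_sidecar(doc, meta_path)


def read_map(path: str | Path) -> np.ndarray:
    """Read a single 2D image as float64."""
    arr = np.asarray(tifffile.imread(path)).astype(float)
    if arr.ndim != 2:
        raise StructuralError(f"{path} is not a single 2D image (shape {arr.shape})")
    return arr


def write_map(image: np.ndarray | Sequence, path: str | Path) -> None:
    """Write a 2D image as a 32-bit float single-page TIFF.

    Raises :class:`ValidationError` on non-finite pixels; float32 data
    round-trips bit-exactly through ``read_map``.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise StructuralError(f"write_map expects a 2D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValidationError("image contains non-finite pixels")
    tifffile.imwrite(path, image)
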