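"""Uptake kinetics: per-animal curves, plateau check, and the 60-minute summary.

After calibration, the mean intensity over the field of view (or a supplied
ROI) at each time point forms the kinetic uptake curve. Probe uptake
saturates: fluorescence rises for roughly 30 minutes and then stays stable
through 80 minutes. The calibrated fluorescence at 60 minutes — the
mid-point of that plateau — is the per-animal summary parameter (Bodipy_60
for the fatty-acid probe, TMRE_60 for the mitochondrial-potential probe).

Summary-frame selection is nearest-timestamp, never interpolation: the
summary image is an acquired frame, not a manufactured one.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .calibration import CalibratedStack
from .errors import ValidationError
from .io import nearest_time_index

__all__ = [
    "KineticCurve",
    "SummaryImage",
    "PlateauReport",
    "kinetic_curve",
    "normalize_curve",
    "plateau_check",
    "summary_value",
    "summary_image",
    "tumor_volume",
]


@dataclasses.dataclass
class KineticCurve:
    """Mean calibrated intensity over an ROI at each post-injection time point."""

    times_min: np.ndarray
    mean_intensity: np.ndarray
    normalized: np.ndarray | None = None
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if self.times_min.shape != self.mean_intensity.shape:
            raise ValidationError("times and values length mismatch")

    def __len__(self) -> int:
        return len(self.times_min)


@dataclasses.dataclass
class SummaryImage:
    """The calibrated frame nearest the summary time (default 60 min)."""

    image: np.ndarray
    summary_time_min: float
    actual_time_min: float
    probe: str = "BodipyFLc16"


@dataclasses.dataclass
class PlateauReport:
    """Coefficient of variation of the curve within the plateau window."""

    cv: float
    stable: bool
    window_min: tuple[float, float]
    n_points: int
    cv_threshold: float


def kinetic_curve(
    stack: CalibratedStack,
    roi: np.ndarray | None = None,
    animal_id: str = "",
    group: str = "",
) -> KineticCurve:
    """Mean intensity per frame over ``roi`` (default: whole field of view)."""
    if len(stack) == 0:
        raise ValidationError("empty stack")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != stack.shape:
            raise ValidationError(
                f"roi shape {roi.shape} does not match frames {stack.shape}"
            )
        if not roi.any():
            raise ValidationError("roi is empty")
        values = stack.frames[:, roi].mean(axis=1)
    else:
        values = stack.frames.mean(axis=(1, 2))
    return KineticCurve(
        times_min=stack.times_min.copy(),
        mean_intensity=values,
        animal_id=animal_id,
        group=group,
    )


def normalize_curve(curve: KineticCurve) -> KineticCurve:
    """Divide by the curve maximum so the peak is exactly 1 (scale-invariant)."""
    peak = float(curve.mean_intensity.max())
    if peak <= 0:
        raise ValidationError(f"curve maximum must be > 0, got {peak}")
    return dataclasses.replace(
        curve, normalized=curve.mean_intensity / peak
    )


def plateau_check(
    curve: KineticCurve,
    window_min: tuple[float, float] = (30.0, 80.0),
    cv_threshold: float = 0.10,
) -> PlateauReport:
    """Check that the curve is stable (low CV) inside the plateau window.

    CV is the sample standard deviation over the mean of the points with
    ``window_min[0] <= t <= window_min[1]``; ``stable`` means
    ``cv <= cv_threshold``.
    """
    lo, hi = window_min
    sel = (curve.times_min >= lo) & (curve.times_min <= hi)
    n = int(sel.sum())
    if n < 2:
        raise ValidationError(
            f"plateau window [{lo}, {hi}] min contains {n} time points; need >= 2"
        )
    vals = curve.mean_intensity[sel]
    mean = float(vals.mean())
    if mean == 0:
        raise ValidationError("plateau window mean is zero; cv undefined")
    cv = float(vals.std(ddof=1) / abs(mean))
    return PlateauReport(
        cv=cv, stable=cv <= cv_threshold, window_min=(lo, hi),
        n_points=n, cv_threshold=cv_threshold,
    )


def _nearest_frame_index(times_min: np.ndarray, t: float) -> int:
    i = nearest_time_index(times_min, t)
    if len(times_min) > 1:
        half_interval = float(np.median(np.diff(times_min))) / 2.0
        if abs(times_min[i] - t) > half_interval:
            raise ValidationError(
                f"no frame within {half_interval:g} min of t={t:g} "
                f"(nearest at {times_min[i]:g} min)"
            )
    return i


def summary_value(curve: KineticCurve, t: float = 60.0) -> float:
    """Curve value at the frame nearest ``t`` minutes (ties -> earlier frame)."""
    i = _nearest_frame_index(curve.times_min, t)
    return float(curve.mean_intensity[i])


def summary_image(stack: CalibratedStack, t: float = 60.0) -> SummaryImage:
    """The calibrated frame nearest ``t`` minutes, as a SummaryImage."""
    if len(stack) == 0:
        raise ValidationError("empty stack")
    i = _nearest_frame_index(stack.times_min, t)
    return SummaryImage(
        image=stack.frames[i],
        summary_time_min=float(t),
        actual_time_min=float(stack.times_min[i]),
        probe=stack.probe,
    )


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume, Volume = Length x Width^2 / 2 (mm^3).

    Width is the smallest axis; if the arguments arrive swapped they are
    exchanged with a warning.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValidationError("length and width must be positive")
    if width_mm > length_mm:
        warnings.warn(
            "width > length; swapping so width is the smallest axis",
            stacklevel=2,
        )
        length_mm, width_mm = width_mm, length_mm
    return float(length_mm * width_mm**2 / 2.0)
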