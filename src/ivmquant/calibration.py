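"""Per-session image calibration.

Raw intravital frames carry four instrument signatures that must be removed
before sessions or animals can be compared:

1. **dark offset** — camera signal with the laser off;
2. **autofluorescence background** — tissue signal imaged before probe
   injection (itself dark-subtracted);
3. **beam shape** — the Gaussian illumination profile (vignetting), removed
   by dividing by a unit-mean image of a uniform fluorescent phantom;
4. **day-to-day system gain** — removed by scaling to a stable fluorescence
   standard (Rhodamine B solution) imaged in every session.

``calibrate_session`` applies the four steps in exactly that order and
records them in the output's provenance. Dark is a scalar (the mean of the
laser-off image) by default; background is pixelwise (the per-pixel mean of
the pre-injection frames) by default — both are configurable. Negative
pixels produced by the subtractions are retained so that means stay
unbiased; clip only for display.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .errors import CalibrationError, ConfigurationError, StructuralError
from .io import FrameStack

__all__ = [
    "CalibrationSet",
    "CalibratedStack",
    "subtract_dark",
    "subtract_background",
    "flatfield_correct",
    "calibration_factor",
    "calibrate_session",
]

CHAIN_STEPS = ("dark", "background", "flatfield", "standard")


@dataclasses.dataclass
class CalibrationSet:
    """Everything needed to convert one session's raw frames to calibrated units.

    Parameters
    ----------
    dark
        Laser-off frame (2D) or scalar dark level, raw units.
    phantom
        Raw frame of a uniform fluorescent phantom (not yet dark-subtracted).
    standard_frame
        Raw frame of the fluorescence standard (not yet dark-subtracted).
    background
        Pre-injection frame(s) (2D, or (n, h, w) to be averaged) or scalar,
        raw units *including* dark. Optional: if None, pre-injection frames
        in the data stack (times < 0) are used instead.
    standard_reference
        Assigned value of the standard in calibrated units. Default 1.0, i.e.
        outputs are in "standard-equivalent" units.
    """

    dark: np.ndarray | float
    phantom: np.ndarray | None = None
    standard_frame: np.ndarray | None = None
    background: np.ndarray | float | None = None
    standard_reference: float = 1.0

    def __post_init__(self) -> None:
        if self.standard_reference <= 0:
            raise CalibrationError(
                f"standard_reference must be > 0, got {self.standard_reference}"
            )


def _as_subtrahend(value: np.ndarray | float, shape: tuple[int, int], what: str):
    """Validate a frame-or-scalar correction term against a frame shape."""
    if np.isscalar(value) or np.ndim(value) == 0:
        return float(value)
    arr = np.asarray(value, dtype=float)
    if arr.shape != shape:
        raise StructuralError(
            f"{what} shape {arr.shape} does not match frame shape {shape}"
        )
    return arr


def subtract_dark(frame: np.ndarray, dark: np.ndarray | float) -> np.ndarray:
    """Subtract the laser-off (dark) signal; negatives are preserved."""
    frame = np.asarray(frame, dtype=float)
    return frame - _as_subtrahend(dark, frame.shape, "dark")


def subtract_background(
    frame: np.ndarray, background: np.ndarray | float
) -> np.ndarray:
    """Subtract the pre-injection autofluorescence (already dark-subtracted)."""
    frame = np.asarray(frame, dtype=float)
    return frame - _as_subtrahend(background, frame.shape, "background")


def _unit_mean_phantom(
    phantom: np.ndarray, smooth_sigma: float = 2.0
) -> np.ndarray:
    """Smooth and normalize a dark-subtracted phantom frame to unit mean."""
    phantom = np.asarray(phantom, dtype=float)
    if smooth_sigma > 0:
        phantom = ndimage.gaussian_filter(phantom, sigma=smooth_sigma, mode="nearest")
    if np.any(phantom <= 0):
        raise CalibrationError("phantom has nonpositive pixels after smoothing")
    return phantom / phantom.mean()


def flatfield_correct(
    frame: np.ndarray, phantom: np.ndarray, smooth_sigma: float = 2.0
) -> np.ndarray:
    """Divide out the illumination profile measured on a uniform phantom.

    The (dark-subtracted) phantom is Gaussian-smoothed (``smooth_sigma`` in
    pixels; 0 disables smoothing) and normalized to unit mean before
    division, so a constant phantom is a no-op and the overall intensity
    scale of ``frame`` is preserved.
    """
    frame = np.asarray(frame, dtype=float)
    phantom = np.asarray(phantom, dtype=float)
    if phantom.shape != frame.shape:
        raise StructuralError(
            f"phantom shape {phantom.shape} does not match frame shape {frame.shape}"
        )
    return frame / _unit_mean_phantom(phantom, smooth_sigma)


def calibration_factor(
    standard_frame: np.ndarray,
    standard_reference: float,
    roi: np.ndarray | None = None,
) -> float:
    """Session gain factor from the fluorescence standard.

    Returns ``standard_reference / mean(standard_frame over roi)``; the
    standard frame must already be dark-subtracted. Multiplying any frame by
    the factor expresses it in standard-equivalent units.
    """
    standard_frame = np.asarray(standard_frame, dtype=float)
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != standard_frame.shape:
            raise StructuralError("roi shape does not match standard frame")
        values = standard_frame[roi]
        if values.size == 0:
            raise CalibrationError("empty ROI on standard frame")
    else:
        values = standard_frame
    m = float(values.mean())
    if m <= 0:
        raise CalibrationError(f"standard frame mean must be > 0, got {m}")
    return float(standard_reference) / m


@dataclasses.dataclass
class CalibratedStack:
    """A frame stack after the full correction chain, in calibrated units."""

    frames: np.ndarray
    times_min: np.ndarray
    calibration_factor: float
    provenance: tuple[str, ...]
    probe: str = "BodipyFLc16"
    exposure_s: float | None = None
    pixel_size_um: float | None = None

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def _dark_scalar_or_frame(cal: CalibrationSet, mode: str):
    if np.isscalar(cal.dark) or np.ndim(cal.dark) == 0:
        return float(cal.dark)
    dark = np.asarray(cal.dark, dtype=float)
    if mode == "scalar":
        return float(dark.mean())
    return dark


def _resolve_background(
    cal: CalibrationSet,
    stack: FrameStack,
    dark,
    mode: str,
) -> np.ndarray | float:
    """Dark-subtracted background from the calibration set or pre-injection frames."""
    if cal.background is not None:
        bg = cal.background
        if np.isscalar(bg) or np.ndim(bg) == 0:
            return float(bg)
        bg = np.asarray(bg, dtype=float)
        if bg.ndim == 3:
            bg = bg.mean(axis=0)
    else:
        pre = stack.frames[stack.times_min < 0]
        if len(pre) == 0:
            raise ConfigurationError(
                "background: no background frames in CalibrationSet and no "
                "pre-injection (time < 0) frames in the stack"
            )
        bg = subtract_dark(pre.mean(axis=0), dark)
    if mode == "scalar":
        return float(np.mean(bg))
    return np.asarray(bg, dtype=float)


def calibrate_session(
    stack: FrameStack,
    cal: CalibrationSet,
    *,
    dark_mode: str = "scalar",
    background_mode: str = "pixel",
    background_after_flatfield: bool = False,
    phantom_smooth_sigma: float = 2.0,
    standard_roi: np.ndarray | None = None,
) -> CalibratedStack:
    """Apply the full correction chain to a session.

    Order: dark subtraction -> background subtraction -> flat-field division
    -> multiplication by the standard calibration factor. Pre-injection
    frames (``times_min < 0``) are consumed to build the background (when
    ``cal.background`` is None) and are not emitted.

    ``background_after_flatfield=True`` moves the background subtraction
    after the flat-field step (the background is then flat-fielded too);
    off by default to match the stated chain order.
    """
    if cal.phantom is None:
        raise ConfigurationError("calibration set is missing component: phantom")
    if cal.standard_frame is None:
        raise ConfigurationError("calibration set is missing component: standard")
    if cal.dark is None:
        raise ConfigurationError("calibration set is missing component: dark")
    if dark_mode not in ("scalar", "pixel"):
        raise ConfigurationError(f"dark_mode must be 'scalar' or 'pixel', got {dark_mode!r}")
    if background_mode not in ("scalar", "pixel"):
        raise ConfigurationError(
            f"background_mode must be 'scalar' or 'pixel', got {background_mode!r}"
        )

    dark = _dark_scalar_or_frame(cal, dark_mode)
    background = _resolve_background(cal, stack, dark, background_mode)

    phantom_ds = subtract_dark(np.asarray(cal.phantom, dtype=float), dark)
    unit_phantom = _unit_mean_phantom(phantom_ds, phantom_smooth_sigma)
    standard_ds = subtract_dark(np.asarray(cal.standard_frame, dtype=float), dark)
    factor = calibration_factor(standard_ds, cal.standard_reference, roi=standard_roi)

    post = stack.times_min >= 0
    frames = stack.frames[post]
    times = stack.times_min[post]

    out = np.empty_like(frames, dtype=float)
    for i, frame in enumerate(frames):
        f = subtract_dark(frame, dark)
        if background_after_flatfield:
            f = f / unit_phantom
            f = subtract_background(f, np.asarray(background) / unit_phantom
                                    if np.ndim(background) == 2 else background)
        else:
            f = subtract_background(f, background)
            f = f / unit_phantom
        out[i] = f * factor

    return CalibratedStack(
        frames=out,
        times_min=times,
        calibration_factor=factor,
        provenance=CHAIN_STEPS,
        probe=stack.probe,
        exposure_s=stack.exposure_s,
        pixel_size_um=stack.pixel_size_um,
    )
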