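"""Synthetic imaging-session simulator.

Generates complete sessions — raw time-lapse frames plus the matching
calibration frames and the noise-free ground truth — with the statistical
structure the calibration chain assumes, so every pipeline stage is
testable without animal data.

Forward model (pixelwise, per frame at time t):

    raw(t) = dark_offset
             + gain * V * (autofluorescence + U * (1 - exp(-t / tau)))
             + shot noise

where ``V`` is a Gaussian-beam vignette, ``U`` is the per-pixel plateau
uptake field (a smoothed Gaussian random field, clipped at 0, so its
spatial sd and correlation length are the two texture knobs), ``tau`` is
the uptake time constant and shot noise is Gaussian with variance
proportional to the expected signal above dark (Poisson available by
flag). Calibration frames are drawn from the same model: a laser-off dark
frame (offset + read noise), two or more pre-injection background frames,
a uniform phantom (gain * V * level + dark) and a fluorescence-standard
frame (gain * V * level + dark).

Defaults emulate the study conditions: frames every 5 min from 0 to 80
min, tau = 10 min (so uptake is ~95% saturated by 30 min and stable
through 80), a 2.1 x 1.6 mm field of view, 5 s exposure, and 4 animals
per group.

Seeding: a master seed spawns per-animal substreams via
``np.random.SeedSequence(seed, spawn_key=(animal_index,))``, so adding an
animal never perturbs existing ones and identical (config, seed) pairs
give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import CalibrationSet
from .errors import ConfigurationError, ValidationError
from .io import FrameStack, SessionMeta, write_map, write_stack

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_session",
    "simulate_experiment",
]

DEFAULT_TIMES_MIN = tuple(float(t) for t in range(0, 85, 5))


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic forward model (all intensities in raw camera units).

    ``image_shape`` defaults to 160 x 210 px: the 2.1 x 1.6 mm window field
    of view at a 10 um pixel pitch (a desk-scale raster; the physical FOV is
    what matters to the pipeline, not the pixel count).
    """

    image_shape: tuple[int, int] = (160, 210)
    times_min: tuple[float, ...] = DEFAULT_TIMES_MIN
    amplitude_mean: float = 100.0      # plateau uptake level A
    amplitude_cv: float = 0.15         # between-animal variability of A
    tau_min: float = 10.0              # uptake time constant
    texture_sd: float = 20.0           # spatial sd of the uptake field
    texture_corr_len_px: float = 5.0   # GRF correlation length
    autofluorescence_level: float = 20.0
    dark_offset: float = 100.0
    read_noise_sd: float = 1.0
    vignette_sigma_frac: float = 0.6   # beam sigma / frame diagonal
    gain: float = 1.0
    shot_noise: bool = True
    shot_noise_scale: float = 1.0      # variance per unit expected signal
    poisson: bool = False              # exact Poisson instead of Gaussian
    phantom_level: float = 200.0
    standard_level: float = 150.0
    standard_reference: float = 1.0
    n_preinjection_frames: int = 2
    pixel_size_um: float = 10.0
    exposure_s: float = 5.0
    probe: str = "BodipyFLc16"
    n_animals: int = 4

    def __post_init__(self) -> None:
        if self.tau_min <= 0:
            raise ValidationError("tau_min must be > 0")
        if min(self.image_shape) < 1:
            raise ValidationError("image_shape must be positive")
        for name in (
            "amplitude_mean", "amplitude_cv", "texture_sd", "autofluorescence_level",
            "dark_offset", "read_noise_sd", "gain", "phantom_level",
            "standard_level", "standard_reference", "shot_noise_scale",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_preinjection_frames < 1:
            raise ValidationError("need at least one pre-injection frame")


@dataclasses.dataclass
class GroundTruth:
    """Noise-free quantities behind one simulated session."""

    uptake_field: np.ndarray          # per-pixel plateau amplitude U
    amplitude: float                  # animal's mean plateau amplitude A
    vignette: np.ndarray              # beam profile V (unit peak)
    times_min: np.ndarray
    curve_true: np.ndarray            # mean(U) * (1 - exp(-t/tau))
    temporal_fraction: np.ndarray     # 1 - exp(-t/tau)
    calibrated_scale: float           # standard_reference / standard_level

    def calibrated_frame(self, i: int) -> np.ndarray:
        """Expected calibrated frame i: scale * U * (1 - exp(-t_i/tau))."""
        return self.calibrated_scale * self.uptake_field * self.temporal_fraction[i]


def _vignette(shape: tuple[int, int], sigma_frac: float) -> np.ndarray:
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    sigma = sigma_frac * np.hypot(h, w)
    return np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2.0 * sigma**2))


def _uptake_field(cfg: SimulationConfig, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smoothed Gaussian random field, mean = amplitude, sd = texture_sd, clipped at 0."""
    if cfg.texture_sd == 0:
        return np.full(cfg.image_shape, amplitude)
    white = rng.standard_normal(cfg.image_shape)
    smooth = ndimage.gaussian_filter(white, sigma=cfg.texture_corr_len_px, mode="wrap")
    sd = smooth.std()
    if sd > 0:
        smooth = (smooth - smooth.mean()) / sd
    return np.clip(amplitude + cfg.texture_sd * smooth, 0.0, None)


def _add_shot_noise(expected: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Noise on the expected signal above dark; Gaussian var ~ signal by default."""
    if not cfg.shot_noise:
        return expected
    if cfg.poisson:
        scaled = np.clip(expected, 0.0, None) / cfg.shot_noise_scale
        return rng.poisson(scaled) * cfg.shot_noise_scale
    sd = np.sqrt(cfg.shot_noise_scale * np.clip(expected, 0.0, None))
    return expected + rng.normal(0.0, 1.0, expected.shape) * sd


def simulate_session(
    config: SimulationConfig,
    animal_index: int = 0,
    seed: int = 0,
    amplitude: float | None = None,
) -> tuple[FrameStack, CalibrationSet, GroundTruth]:
    """One animal's raw stack, calibration frames, and ground truth.

    The raw stack includes ``n_preinjection_frames`` baseline frames at
    negative timestamps (consumed by ``calibrate_session`` to build the
    background) followed by the post-injection time course. ``amplitude``
    overrides the per-animal draw (used by paired designs).
    """
    ss = np.random.SeedSequence(seed, spawn_key=(animal_index,))
    rng_field, rng_noise, rng_amp = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    if amplitude is None:
        jitter = 1.0 + config.amplitude_cv * rng_amp.standard_normal()
        amplitude = float(config.amplitude_mean * max(0.0, jitter))
    V = _vignette(config.image_shape, config.vignette_sigma_frac)
    U = _uptake_field(config, amplitude, rng_field)
    times = np.asarray(config.times_min, dtype=float)
    frac = 1.0 - np.exp(-times / config.tau_min)

    def expected_signal(signal: np.ndarray) -> np.ndarray:
        return config.gain * V * signal

    def raw_frame(signal: np.ndarray) -> np.ndarray:
        exp_sig = expected_signal(signal)
        return config.dark_offset + _add_shot_noise(exp_sig, config, rng_noise)

    pre_dt = np.arange(config.n_preinjection_frames, 0, -1, dtype=float)
    pre_times = -pre_dt  # ... -2, -1 min
    pre_frames = [
        raw_frame(np.full(config.image_shape, config.autofluorescence_level))
        for _ in pre_times
    ]
    post_frames = [
        raw_frame(config.autofluorescence_level + U * f) for f in frac
    ]

    stack = FrameStack(
        frames=np.stack(pre_frames + post_frames),
        times_min=np.concatenate([pre_times, times]),
        probe=config.probe,
        exposure_s=config.exposure_s,
        pixel_size_um=config.pixel_size_um,
    )

    dark_frame = config.dark_offset + (
        rng_noise.normal(0.0, config.read_noise_sd, config.image_shape)
        if config.shot_noise
        else np.zeros(config.image_shape)
    )
    phantom = raw_frame(np.full(config.image_shape, config.phantom_level))
    standard = raw_frame(np.full(config.image_shape, config.standard_level))

    cal = CalibrationSet(
        dark=dark_frame,
        phantom=phantom,
        standard_frame=standard,
        standard_reference=config.standard_reference,
    )
    truth = GroundTruth(
        uptake_field=U,
        amplitude=amplitude,
        vignette=V,
        times_min=times,
        curve_true=float(U.mean()) * frac,
        temporal_fraction=frac,
        calibrated_scale=config.standard_reference / config.standard_level,
    )
    return stack, cal, truth


def simulate_experiment(
    config_by_group: Mapping[str, SimulationConfig],
    seed: int,
    out_dir: str | Path | None = None,
    paired_amplitude_factor: float | None = None,
    matched_amplitudes: bool = False,
) -> tuple[list[dict], pd.DataFrame]:
    """Simulate a multi-group experiment; optionally write it to disk.

    Each group gets ``config.n_animals`` sessions with per-animal seeds
    derived deterministically from the master seed. With
    ``paired_amplitude_factor`` set, every animal is simulated twice
    (session_day 0 and 4) sharing its uptake-field geometry, with the
    day-4 plateau amplitude rescaled by the factor — the longitudinal
    paired design.

    ``matched_amplitudes=True`` gives the k-th animal of every group the
    same random substream, so per-animal amplitude jitter and field
    geometry are shared across groups and the ground-truth group amplitude
    ratios equal the ratios of the configs' ``amplitude_mean`` exactly —
    use this to test fold-change recovery without between-animal sampling
    noise in the design itself.

    Returns (sessions, manifest): sessions is a list of dicts with keys
    ``stack``, ``cal``, ``truth``, ``meta``; the manifest table records
    animal, group, day, ground-truth amplitude and (when written) paths.
    """
    if len(config_by_group) == 0:
        raise ConfigurationError("need at least one group")
    if len(set(config_by_group)) != len(config_by_group):
        raise ConfigurationError("duplicate group labels")
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    sessions: list[dict] = []
    rows: list[dict] = []
    for g_idx, (group, cfg) in enumerate(config_by_group.items()):
        for a in range(cfg.n_animals):
            # group index folded into the animal index keeps streams disjoint
            # (unless amplitudes are matched across groups by design)
            idx = a if matched_amplitudes else g_idx * 10_000 + a
            animal_id = f"{group}_{a:02d}"
            base = simulate_session(cfg, animal_index=idx, seed=seed)
            days = [(0, base)]
            if paired_amplitude_factor is not None:
                day4 = simulate_session(
                    cfg,
                    animal_index=idx,
                    seed=seed,
                    amplitude=base[2].amplitude * paired_amplitude_factor,
                )
                days.append((4, day4))
            for day, (stack, cal, truth) in days:
                meta = SessionMeta(
                    animal_id=animal_id,
                    group=group,
                    session_day=day,
                    paired_with=f"{animal_id}/day0" if day else None,
                )
                session = {"stack": stack, "cal": cal, "truth": truth, "meta": meta}
                sessions.append(session)
                row = {
                    "animal_id": animal_id,
                    "group": group,
                    "session_day": day,
                    "amplitude_true": truth.amplitude,
                }
                if out_dir is not None:
                    # manifest paths are relative to out_dir so trees are portable
                    row["path"] = str(_write_session(out_dir, session).relative_to(out_dir))
                rows.append(row)

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return sessions, manifest


def _write_session(out_dir: Path, session: dict) -> Path:
    """Write one session in the standard on-disk layout; returns its directory."""
    meta: SessionMeta = session["meta"]
    cal: CalibrationSet = session["cal"]
    truth: GroundTruth = session["truth"]
    d = out_dir / f"{meta.animal_id}_day{meta.session_day}"
    (d / "calibration").mkdir(parents=True, exist_ok=True)
    (d / "ground_truth").mkdir(exist_ok=True)
    write_stack(
        session["stack"], meta, d / "stack.tif", d / "session.yaml",
        extra_sidecar={
            "calibration": {
                "dark": "calibration/dark.tif",
                "phantom": "calibration/phantom.tif",
                "standard": "calibration/standard.tif",
                "standard_reference": float(cal.standard_reference),
            }
        },
    )
    write_map(np.asarray(cal.dark, dtype=float), d / "calibration" / "dark.tif")
    write_map(cal.phantom, d / "calibration" / "phantom.tif")
    write_map(cal.standard_frame, d / "calibration" / "standard.tif")
    write_map(truth.uptake_field, d / "ground_truth" / "uptake_field.tif")
    return d
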