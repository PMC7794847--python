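"""End-to-end orchestration: simulate/load -> calibrate -> kinetics ->
heterogeneity -> compare.

``run_pipeline`` drives the whole chain from a single :class:`RunConfig`
and writes, per session: the calibrated stack, the kinetic-curve table, the
summary image and local-range map; and per run: a summary-value table, the
group test results and a JSON report. Every artifact gets a provenance
sidecar (inputs, parameters, package version, seed) so reruns are
auditable; with a fixed seed the outputs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibratedStack, CalibrationSet, calibrate_session
from .errors import ConfigurationError, IVMQuantError
from .heterogeneity import intensity_vs_range, local_range_map
from .io import FrameStack, SessionMeta, read_map, read_stack, write_map
from .kinetics import (
    kinetic_curve,
    normalize_curve,
    plateau_check,
    summary_image,
    summary_value,
)
from .simulator import SimulationConfig, simulate_experiment
from .stats import curve_anova, ks_compare, paired_group_test, pixel_pdf, unpaired_group_tests

__all__ = ["RunConfig", "run_pipeline", "load_session", "PRESETS", "preset_configs"]

log = logging.getLogger("ivmquant")


@dataclasses.dataclass
class RunConfig:
    """Single source of truth for one pipeline run.

    Exactly one of ``input_dir`` (a directory of session subdirectories,
    each with ``stack.tif`` + ``session.yaml``) or ``preset`` (a named
    simulated design) must be set.
    """

    out_dir: str | Path
    input_dir: str | Path | None = None
    preset: str | None = None
    seed: int = 0
    summary_time_min: float = 60.0
    plateau_window_min: tuple[float, float] = (30.0, 80.0)
    heterogeneity_fraction: float = 0.01
    paired: bool = False
    dark_mode: str = "scalar"
    background_mode: str = "pixel"
    phantom_smooth_sigma: float = 2.0
    bins: int = 100

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.preset is None):
            raise ConfigurationError(
                "exactly one of input_dir or preset must be set"
            )


PRESETS = ("two-group", "paired", "three-group")


def preset_configs(preset: str) -> tuple[dict[str, SimulationConfig], float | None]:
    """Simulation configs (and paired factor) for the named design.

    * ``two-group`` — high/low uptake groups, 3-fold amplitude ratio
      (the MYC-on vs MYC-off style unpaired comparison);
    * ``paired`` — one group imaged on day 0 and day 4 with the day-4
      amplitude scaled by 1/3 (the longitudinal regression design);
    * ``three-group`` — equal-vs-graded amplitudes with increasing texture
      (the metastatic-potential panel: intensity and heterogeneity rise
      together).
    """
    small = {"image_shape": (80, 105)}
    if preset == "two-group":
        return (
            {
                "high": SimulationConfig(amplitude_mean=100.0, **small),
                "low": SimulationConfig(amplitude_mean=100.0 / 3.0, **small),
            },
            None,
        )
    if preset == "paired":
        return ({"tumor": SimulationConfig(amplitude_mean=100.0, **small)}, 1.0 / 3.0)
    if preset == "three-group":
        return (
            {
                "low": SimulationConfig(amplitude_mean=50.0, texture_sd=10.0, **small),
                "mid": SimulationConfig(amplitude_mean=100.0, texture_sd=20.0, **small),
                "high": SimulationConfig(amplitude_mean=100.0, texture_sd=30.0, **small),
            },
            None,
        )
    raise ConfigurationError(f"unknown preset {preset!r}; choose from {PRESETS}")


def load_session(session_dir: str | Path) -> tuple[FrameStack, CalibrationSet, SessionMeta]:
    """Load one on-disk session (stack.tif + session.yaml + calibration/)."""
    d = Path(session_dir)
    stack, meta = read_stack(d / "stack.tif", d / "session.yaml")
    calmeta = meta.extra.get("calibration")
    if not isinstance(calmeta, dict):
        raise ConfigurationError(f"{d}/session.yaml has no 'calibration' section")
    missing = [k for k in ("dark", "phantom", "standard") if k not in calmeta]
    if missing:
        raise ConfigurationError(
            f"calibration section missing component(s): {', '.join(missing)}"
        )
    cal = CalibrationSet(
        dark=read_map(d / calmeta["dark"]),
        phantom=read_map(d / calmeta["phantom"]),
        standard_frame=read_map(d / calmeta["standard"]),
        background=(
            read_map(d / calmeta["background"]) if "background" in calmeta else None
        ),
        standard_reference=float(calmeta.get("standard_reference", 1.0)),
    )
    return stack, cal, meta


def _provenance(path: Path, stage: str, params: dict, inputs: list[str], seed: int) -> None:
    doc = {
        "artifact": path.name,
        "stage": stage,
        "inputs": inputs,
        "parameters": params,
        "package": "ivmquant",
        "version": __version__,
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(doc, indent=2, sort_keys=True)
    )


def _json_safe(obj):
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return _json_safe(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and write the report bundle; returns the report dict.

    Stage failures abort with the failing stage named; partial outputs are
    moved under ``<out_dir>/quarantine``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        t0 = time.time()
        stage = "input"
        if config.preset is not None:
            log.info("simulating preset %r (seed=%d)", config.preset, config.seed)
            group_cfgs, paired_factor = preset_configs(config.preset)
            if config.preset == "paired":
                config.paired = True
            sessions, manifest = simulate_experiment(
                group_cfgs, seed=config.seed, out_dir=out / "sessions",
                paired_amplitude_factor=paired_factor,
            )
            loaded = [(s["stack"], s["cal"], s["meta"]) for s in sessions]
        else:
            root = Path(config.input_dir)
            dirs = sorted(p for p in root.iterdir() if (p / "session.yaml").exists())
            if not dirs:
                raise ConfigurationError(f"no sessions found under {root}")
            loaded = [load_session(d) for d in dirs]
            manifest = None

        stage = "calibrate"
        calibrated: list[tuple[CalibratedStack, SessionMeta]] = []
        for stack, cal, meta in loaded:
            cstack = calibrate_session(
                stack, cal,
                dark_mode=config.dark_mode,
                background_mode=config.background_mode,
                phantom_smooth_sigma=config.phantom_smooth_sigma,
            )
            calibrated.append((cstack, meta))
        log.info("calibrated %d sessions", len(calibrated))

        stage = "kinetics"
        curve_rows, value_rows = [], []
        curves_by_group: dict[str, list] = {}
        summaries: list[tuple[SessionMeta, np.ndarray]] = []
        for cstack, meta in calibrated:
            curve = normalize_curve(
                kinetic_curve(cstack, animal_id=meta.animal_id, group=meta.group)
            )
            plateau = plateau_check(curve, window_min=config.plateau_window_min)
            simg = summary_image(cstack, t=config.summary_time_min)
            sval = summary_value(curve, t=config.summary_time_min)
            key = f"{meta.animal_id}_day{meta.session_day}"
            for t, v, nv in zip(curve.times_min, curve.mean_intensity, curve.normalized):
                curve_rows.append(
                    {"animal_id": meta.animal_id, "group": meta.group,
                     "session_day": meta.session_day, "time_min": t,
                     "mean_intensity": v, "normalized": nv}
                )
            value_rows.append(
                {"animal_id": meta.animal_id, "group": meta.group,
                 "session_day": meta.session_day, "summary_value": sval,
                 "plateau_cv": plateau.cv, "plateau_stable": plateau.stable,
                 "summary_time_actual_min": simg.actual_time_min}
            )
            curves_by_group.setdefault(meta.group, []).append(curve)
            summaries.append((meta, simg.image))
            spath = out / f"summary_{key}.tif"
            write_map(simg.image, spath)
            _provenance(spath, "kinetics",
                        {"summary_time_min": config.summary_time_min}, [key], config.seed)
        curves_df = pd.DataFrame(curve_rows)
        values_df = pd.DataFrame(value_rows)
        curves_df.to_csv(out / "curves.csv", index=False)
        values_df.to_csv(out / "summary_values.csv", index=False)

        stage = "heterogeneity"
        het_rows = []
        for meta, img in summaries:
            lrm = local_range_map(img, fraction=config.heterogeneity_fraction)
            key = f"{meta.animal_id}_day{meta.session_day}"
            lpath = out / f"local_range_{key}.tif"
            write_map(lrm.image, lpath)
            _provenance(
                lpath, "heterogeneity",
                {"fraction": lrm.fraction, "window_side_px": lrm.window_side_px,
                 "window_shape": lrm.shape}, [key], config.seed,
            )
            table = intensity_vs_range(img, lrm)
            het_rows.append(
                {"animal_id": meta.animal_id, "group": meta.group,
                 "session_day": meta.session_day,
                 "mean_local_range": float(table["local_range"].mean())}
            )
        het_df = pd.DataFrame(het_rows)
        het_df.to_csv(out / "local_range_means.csv", index=False)

        stage = "compare"
        report: dict = {
            "config": _json_safe(dataclasses.asdict(config)),
            "n_sessions": len(calibrated),
            "groups": {},
            "tests": {},
        }
        day0 = values_df[values_df.session_day == 0]
        for g, sub in day0.groupby("group"):
            report["groups"][g] = {
                "n": int(len(sub)),
                "summary_mean": float(sub.summary_value.mean()),
                "summary_sd": float(sub.summary_value.std(ddof=1)) if len(sub) > 1 else 0.0,
                "mean_local_range": float(
                    het_df[(het_df.group == g) & (het_df.session_day == 0)]
                    .mean_local_range.mean()
                ),
            }

        if config.paired:
            piv = values_df.pivot_table(
                index="animal_id", columns="session_day", values="summary_value"
            )
            days = sorted(piv.columns)
            if len(days) == 2:
                res = paired_group_test(piv[days[0]].values, piv[days[1]].values)
                report["tests"]["signed_rank"] = _json_safe(res)
                table = piv.rename(columns={d: f"day{int(d)}" for d in days})
                report["paired_table"] = _json_safe(table.reset_index().to_dict("records"))
                pools = {
                    d: np.concatenate(
                        [img.ravel() for (m, img) in summaries
                         if m.session_day == d]
                    )
                    for d in days
                }
                report["tests"]["ks_day0_vs_day4"] = _json_safe(
                    ks_compare(pools[days[0]], pools[days[1]])
                )
        else:
            groups_vals = {
                g: sub.summary_value.tolist() for g, sub in day0.groupby("group")
            }
            if len(groups_vals) >= 2 and all(len(v) >= 2 for v in groups_vals.values()):
                report["tests"]["rank_sum"] = [
                    _json_safe(r) for r in unpaired_group_tests(groups_vals)
                ]
                anova = curve_anova(
                    {g: cs for g, cs in curves_by_group.items()}
                )
                report["tests"]["curve_anova"] = _json_safe(
                    anova.reset_index().rename(columns={"index": "term"})
                    .to_dict("records")
                )
                pools = {
                    g: np.concatenate(
                        [img.ravel() for (m, img) in summaries if m.group == g]
                    )
                    for g in groups_vals
                }
                labels = sorted(pools)
                edges = np.linspace(
                    min(p.min() for p in pools.values()),
                    max(p.max() for p in pools.values()),
                    config.bins + 1,
                )
                pdf_rows = []
                for g in labels:
                    pdf = pixel_pdf([pools[g]], bins=edges, group=g)
                    centers = 0.5 * (pdf.bin_edges[:-1] + pdf.bin_edges[1:])
                    pdf_rows += [
                        {"group": g, "intensity": c, "density": d}
                        for c, d in zip(centers, pdf.density)
                    ]
                pd.DataFrame(pdf_rows).to_csv(out / "pixel_pdfs.csv", index=False)
                report["tests"]["ks_pixels"] = [
                    _json_safe(
                        dict(_json_safe(ks_compare(pools[a], pools[b])),
                             labels=[a, b])
                    )
                    for i, a in enumerate(labels)
                    for b in labels[i + 1:]
                ]

        report["runtime_s"] = round(time.time() - t0, 3)
        (out / "report.json").write_text(json.dumps(_json_safe(report), indent=2, sort_keys=True))
        _provenance(out / "report.json", "compare",
                    {"paired": config.paired, "bins": config.bins}, [], config.seed)
        log.info("pipeline complete in %.1fs -> %s", report["runtime_s"], out)
        return report
    except IVMQuantError:
        _quarantine(out)
        raise
    except Exception as exc:  # annotate which stage failed
        _quarantine(out)
        raise IVMQuantError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _quarantine(out: Path) -> None:
    q = out / "quarantine"
    q.mkdir(exist_ok=True)
    for p in out.iterdir():
        if p == q or p.is_dir():
            continue
        p.rename(q / p.name)
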