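"""File formats, configuration, and the end-to-end pipeline driver.

Image stacks are plain multi-page TIFF (8/16-bit grayscale); tables are CSV
with units in the column names (``x_um``, ``t_s``); configuration is a YAML
document with one block per pipeline stage.  Every output file embeds the
config hash, the RNG seed, and the package version in a comment header so a
run can be traced back to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .acoustics import AcousticParams, BubbleGeom, PulseTrain
from .imagequant import nuclear_mask, quantify_marker, records_to_frame, \
    to_8bit, yap_positive_fraction
from .pulse_metrics import metrics_for_trajectory, summarize
from .synthetic import KVParams, NucleiSceneSpec, SceneSpec, \
    default_calibration, render_frames, render_nuclei_image, simulate_scene
from .tracking import detect_stack, link, to_physical
from .viscoelastic import fit_kv

__all__ = ["FrameStack", "read_stack", "write_stack", "load_config",
           "config_hash", "run_pipeline"]


@dataclass
class FrameStack:
    """An image stack with its physical calibration."""

    data: np.ndarray        # (frames, rows, cols)
    pixel_size: float       # µm / px
    frame_rate: float       # Hz


def read_stack(path: str | Path) -> FrameStack:
    """Read a multi-page grayscale TIFF stack (8- or 16-bit).

    Calibration (pixel size, frame rate) is taken from a sidecar YAML file
    ``<stem>.yaml`` next to the stack when present, else defaults to
    0.33 µm/px and 1000 fps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        if "S" in series.axes:      # per-pixel samples => RGB(A)
            raise ValueError(
                f"{path}: RGB/multi-sample TIFF; expected a grayscale stack")
        data = series.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale stack, got shape {data.shape}")
    if data.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"{path}: unsupported bit depth {data.dtype}; "
                         "expected 8- or 16-bit grayscale")
    pixel_size, frame_rate = 0.33, 1000.0
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        pixel_size = float(meta.get("pixel_size_um", pixel_size))
        frame_rate = float(meta.get("frame_rate_hz", frame_rate))
    return FrameStack(data=data, pixel_size=pixel_size, frame_rate=frame_rate)


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF plus a calibration sidecar YAML."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    path.with_suffix(".yaml").write_text(yaml.safe_dump({
        "pixel_size_um": stack.pixel_size,
        "frame_rate_hz": stack.frame_rate,
    }))


_REQUIRED_BLOCKS = ("acoustics", "scene")


def load_config(path: str | Path) -> dict:
    """Load and validate a pipeline YAML config.

    Required blocks: ``acoustics`` (prf_hz, duty, n_pulses, pressure_mpa)
    and ``scene`` (bubbles, kv); optional: ``tracking``, ``metrics``,
    ``nuclei``, ``rng_seed``, ``out_dir``.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    missing = [b for b in _REQUIRED_BLOCKS if b not in cfg]
    if missing:
        raise ValueError(f"config missing required block(s): {missing}")
    ac = cfg["acoustics"]
    for key in ("prf_hz", "duty", "n_pulses"):
        if key not in ac:
            raise ValueError(f"acoustics block missing key {key!r}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _meta_header(cfg: dict, seed: int) -> str:
    return (f"# atckit v{__version__} | config_hash={config_hash(cfg)} "
            f"| seed={seed}\n")


def write_csv(df: pd.DataFrame, path: Path, cfg: dict, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header(cfg, seed))
        df.to_csv(fh, index=False)


def train_from_config(ac: dict) -> PulseTrain:
    p = ac.get("pressure_mpa", 0.035)
    if isinstance(p, (int, float)):
        segments = ((float("inf"), float(p) * 1e6),)
    else:
        segments = tuple((float(d), float(pa) * 1e6) for d, pa in p)
    return PulseTrain(prf=float(ac["prf_hz"]), duty=float(ac["duty"]),
                      n_pulses=int(ac["n_pulses"]),
                      pressure_segments=segments)


def scene_from_config(cfg: dict, seed: int) -> SceneSpec:
    sc = cfg["scene"]
    bubbles = [BubbleGeom(id=str(b["id"]),
                          position=(float(b["x_um"]), float(b["y_um"])),
                          radius=float(b.get("radius_um", 2.0)))
               for b in sc["bubbles"]]
    kv_cfg = sc.get("kv", {})
    if "duty_calibration" in kv_cfg:
        kv = default_calibration(float(kv_cfg["duty_calibration"]))
    else:
        kv = KVParams(tau=float(kv_cfg.get("tau_s", 1.0)),
                      x_inf=float(kv_cfg.get("x_inf_um", 5.0)),
                      beta=float(kv_cfg.get("beta_um_s", 0.0)),
                      plastic_fraction=float(kv_cfg.get("plastic_fraction", 0.0)))
    ac = cfg["acoustics"]
    acoustic = AcousticParams(
        pressure_amplitude=float(ac.get("p_a_mpa", 0.035)) * 1e6
        if "p_a_mpa" in ac else train_from_config(ac).pressure_segments[0][1],
        center_frequency=float(ac.get("f0_mhz", 1.25)) * 1e6,
        damping_constant=float(ac.get("delta_tot", 0.16)),
        medium_density=float(ac.get("rho0", 1000.0)),
        sound_speed=float(ac.get("c", 1500.0)))
    return SceneSpec(
        bubbles=bubbles, kv_params=kv,
        primary_direction=tuple(sc.get("primary_direction", (1.0, 0.0))),
        bjerknes_coupling=float(sc.get("bjerknes_coupling", 0.0)),
        radius_decay_rate=float(sc.get("radius_decay_rate", 0.002)),
        noise_sd=float(sc.get("noise_sd_um", 0.1)),
        pixel_size=float(sc.get("pixel_size_um", 0.33)),
        frame_rate=float(sc.get("frame_rate_hz", 1000.0)),
        rng_seed=seed, acoustic=acoustic,
        fov_px=tuple(sc.get("fov_px", (96, 96))),
        background_level=float(sc.get("background_level", 100.0)),
        spot_peak=float(sc.get("spot_peak", 1000.0)),
        image_noise_sd=float(sc.get("image_noise_sd", 0.0)))


def run_pipeline(cfg: dict, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Run simulate → render → track → metrics → fit (→ quantify → stats).

    Each stage writes its artifact under ``out_dir``; deterministic stages
    are bit-identical across reruns with the same config and seed.  A stage
    failure aborts with the stage name while earlier outputs are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("rng_seed", 0)) if seed is None else int(seed)
    stage = "setup"
    try:
        stage = "simulate"
        train = train_from_config(cfg["acoustics"])
        spec = scene_from_config(cfg, seed)
        duration = float(cfg.get("duration_s", train.total_duration))
        trajectories, truth = simulate_scene(spec, train, duration)
        write_csv(truth, out / "ground_truth.csv", cfg, seed)

        stage = "render"
        stack = FrameStack(render_frames(trajectories, spec),
                           spec.pixel_size, spec.frame_rate)
        write_stack(stack, out / "stack.tif")

        stage = "track"
        tr_cfg = cfg.get("tracking", {})
        diameter = int(tr_cfg.get("diameter_px", 13))
        dets = detect_stack(stack.data, diameter,
                            float(tr_cfg.get("min_mass", 0.0)))
        tracks = link(dets, float(tr_cfg.get("max_disp_px", 5.0)),
                      int(tr_cfg.get("memory", 3)))
        physical = [to_physical(tk, stack.pixel_size, stack.frame_rate)
                    for tk in tracks if len(tk) >= 2]
        write_csv(pd.concat([t.to_frame() for t in physical],
                            ignore_index=True),
                  out / "trajectories.csv", cfg, seed)

        stage = "metrics"
        origin = int(cfg.get("metrics", {}).get("origin_frames", 1))
        sets = [metrics_for_trajectory(t, train, origin_window=origin)
                for t in physical]
        write_csv(pd.concat([m.to_frame() for m in sets], ignore_index=True),
                  out / "pulse_metrics.csv", cfg, seed)
        write_csv(summarize(sets, n=min(5, train.n_pulses)),
                  out / "metrics_summary.csv", cfg, seed)

        stage = "fit"
        fits = {}
        for t in physical:
            from .pulse_metrics import displacement_magnitude
            series = displacement_magnitude(t, origin)
            fr = fit_kv(series, t.t, train)
            fits[t.bubble_id] = {
                "tau_s": fr.params.tau, "x_inf_um": fr.params.x_inf,
                "rms_um": fr.residual_norm, "converged": fr.converged}
        (out / "kv_fits.json").write_text(json.dumps({
            "meta": {"version": __version__, "config_hash": config_hash(cfg),
                     "seed": seed},
            "fits": fits}, indent=2))

        if "nuclei" in cfg:
            stage = "quantify"
            nspec = NucleiSceneSpec(rng_seed=seed,
                                    **cfg["nuclei"].get("spec", {}))
            scene = render_nuclei_image(nspec)
            labels = nuclear_mask(to_8bit(scene.dapi))
            records = quantify_marker(scene.marker, labels, scene.dapi)
            write_csv(records_to_frame(records), out / "nuclei_records.csv",
                      cfg, seed)
            frac, n_pos = yap_positive_fraction(records)
            (out / "nuclei_summary.json").write_text(json.dumps({
                "meta": {"version": __version__,
                         "config_hash": config_hash(cfg), "seed": seed},
                "n_nuclei": len(records), "n_yap_positive": n_pos,
                "yap_positive_fraction": frac}, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
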