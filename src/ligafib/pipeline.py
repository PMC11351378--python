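"""Pipeline orchestration: phantom -> segment -> distributions -> forward -> fit.

A single YAML-style configuration (nested dict) drives the five stages;
every stochastic stage derives its random state from the top-level seed, so
identical configurations produce byte-identical CSV outputs.  Each run
writes a JSON manifest recording inputs, outputs, seeds, package versions
and wall-clock time per stage.
"""

from __future__ import annotations

import copy
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .distributions import (
    build_angular_distribution,
    build_volume_fraction,
    angular_density_family,
    count_stats,
    default_theta_edges,
    volume_fraction_family,
)
from .fitting import FitConfig, fit
from .model import DEFAULT_LAMBDA_GRID, LoadCurve, ModelParams, sigma_curve
from .segmentation import (
    compute_metrics,
    filter_artifacts,
    niblack_threshold,
    read_volume,
    remove_speckle,
    separate_objects,
    write_labels,
    write_volume,
)
from .synthetic import (
    BundleGeometry,
    PhantomConfig,
    generate_phantom,
    orientation_sampler,
    reorient_affine,
)

__all__ = ["PipelineError", "default_config", "run_pipeline"]

STAGES = ("phantom", "segment", "distributions", "forward", "fit")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def default_config() -> dict:
    """Demo configuration: a small phantom pushed through all five stages."""
    return {
        "seed": 0,
        "output_dir": "ligafib_run",
        "stages": list(STAGES),
        "phantom": {
            "shape": [64, 64, 64],
            "voxel_size_mm": 0.009,
            "n_fibers": 6,
            "radius_range_mm": [0.03, 0.045],
            "length_range_mm": [0.35, 0.5],
            "orientation": {"name": "truncated_normal", "mean_deg": 15.0, "sd_deg": 8.0},
            "intensity_background": 5.0,
            "intensity_matrix": 150.0,
            "intensity_fiber": 200.0,
            "noise_sd": 5.0,
            "matrix_radius_fraction": 0.8,
            "avoid_overlap": True,
            "min_separation_mm": 0.02,
        },
        "segment": {
            "window_radius": 7,
            "k": 1.5,
            "min_speckle_voxels": 30,
            "h": 2.0,
            "smooth_sigma": 1.0,
            "angle_tol": 1.0,
        },
        "distributions": {
            "n_bins": 9,
            "lam_grid": list(DEFAULT_LAMBDA_GRID),
        },
        "forward": {
            "params": {"E_f_MPa": 100.0, "beta": 2.0, "delta": 0.245, "gamma": 1.0, "N0": 1.0},
        },
        "fit": {
            "n_starts": 4,
        },
    }


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def _phantom_config(section: dict, seed: int) -> PhantomConfig:
    section = copy.deepcopy(section)
    orient = section.pop("orientation", None)
    kwargs = {}
    for key in (
        "voxel_size_mm", "n_fibers", "intensity_background", "intensity_matrix",
        "intensity_fiber", "noise_sd", "matrix_radius_fraction", "avoid_overlap",
        "min_separation_mm",
    ):
        if key in section:
            kwargs[key] = section[key]
    for key in ("shape", "radius_range_mm", "length_range_mm"):
        if key in section:
            kwargs[key] = tuple(section[key])
    if orient is not None:
        kwargs["orientation"] = orientation_sampler(**orient)
    return PhantomConfig(seed=seed, **kwargs)


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest."""
    cfg = copy.deepcopy(config)
    seed = int(cfg.get("seed", 0))
    out = Path(output_dir or cfg.get("output_dir", "ligafib_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in cfg.get("stages", STAGES)]
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "stages": {},
    }
    state: dict = {}

    for stage in stages:
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_RUNNERS[stage](cfg.get(stage, {}) or {}, seed, out, state)
        except PipelineError:
            raise
        except Exception as exc:  # tag the failing stage
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = {
            "outputs": outputs,
            "wall_clock_s": round(time.perf_counter() - t0, 3),
        }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# stage runners (each returns the list of output paths)
# ---------------------------------------------------------------------------

def _run_phantom(section: dict, seed: int, out: Path, state: dict) -> list[str]:
    pc = _phantom_config(section, seed)
    volume, truth = generate_phantom(pc)
    vol_path = out / "phantom.tif"
    truth_path = out / "phantom_truth.csv"
    write_volume(vol_path, volume, seed=seed, overlap_fraction=truth.attrs["overlap_fraction"])
    truth.to_csv(truth_path, index=False)
    state["volume"] = volume
    state["phantom_config"] = pc
    return [str(vol_path), str(truth_path)]


def _run_segment(section: dict, seed: int, out: Path, state: dict) -> list[str]:
    if "volume" not in state:
        inp = section.get("input")
        if inp is None:
            raise PipelineError(
                "segment", "no phantom stage output and no 'input' volume configured"
            )
        state["volume"] = read_volume(inp, section.get("voxel_size_mm"))
    volume = state["volume"]
    binary = niblack_threshold(
        volume,
        window_radius=int(section.get("window_radius", 15)),
        k=float(section.get("k", 0.2)),
    )
    min_speckle = int(section.get("min_speckle_voxels", 0))
    if min_speckle:
        binary = remove_speckle(binary, min_speckle)
    labeled = separate_objects(
        binary,
        h=float(section.get("h", 2.0)),
        smooth_sigma=float(section.get("smooth_sigma", 1.0)),
    )
    records = compute_metrics(labeled)
    fibers, artifacts = filter_artifacts(
        records, angle_tol=float(section.get("angle_tol", 1.0))
    )
    lab_path = out / "labels.tif"
    obj_path = out / "objects.csv"
    fib_path = out / "fibers.csv"
    write_labels(lab_path, labeled)
    records.to_csv(obj_path, index=False)
    fibers.to_csv(fib_path, index=False)
    state["fibers"] = fibers
    state["artifacts"] = artifacts
    return [str(lab_path), str(obj_path), str(fib_path)]


def _run_distributions(section: dict, seed: int, out: Path, state: dict) -> list[str]:
    if "fibers" not in state:
        inp = section.get("tables")
        if inp is None:
            raise PipelineError(
                "distributions", "no segment stage output and no 'tables' configured"
            )
        state["fibers"] = pd.read_csv(inp)
    fibers = state["fibers"]
    if len(fibers) == 0:
        raise PipelineError("distributions", "no fibers survived artifact filtering")
    edges = default_theta_edges(int(section.get("n_bins", 9)))
    lam_grid = [float(x) for x in section.get("lam_grid", DEFAULT_LAMBDA_GRID)]

    if "v_tot_mm3" in section:
        geometry = None
        v_tot0 = float(section["v_tot_mm3"])
    else:
        pc = state.get("phantom_config")
        if pc is None:
            raise PipelineError(
                "distributions", "need 'v_tot_mm3' when no phantom stage ran"
            )
        extent = np.asarray(pc.shape) * pc.voxel_size_mm
        if pc.matrix_radius_fraction is not None:
            r = pc.matrix_radius_fraction * min(pc.shape[1], pc.shape[2]) * pc.voxel_size_mm
            a_tot = np.pi * r**2
        else:
            a_tot = extent[1] * extent[2]
        geometry = BundleGeometry(L0_mm=float(extent[0]), A_tot_mm2=float(a_tot))
        v_tot0 = geometry.v_tot(1.0)

    dists, vmaps, tables = [], [], {}
    paths = []
    for lam in lam_grid:
        table = reorient_affine(fibers, lam)
        tables[lam] = table
        v_tot = v_tot0 * lam
        dist = build_angular_distribution(table, edges, lam)
        vmap = build_volume_fraction(table, v_tot, edges, lam)
        dists.append(dist)
        vmaps.append(vmap)
        tag = f"{lam:.2f}".replace(".", "p")
        p_path = out / f"P_lam{tag}.csv"
        n_path = out / f"nu_lam{tag}.csv"
        dist.to_frame().to_csv(p_path, index=False)
        vmap.to_frame().to_csv(n_path, index=False)
        paths += [str(p_path), str(n_path)]
    n_art = len(state.get("artifacts", []))
    stats = count_stats(tables, {lam: n_art for lam in lam_grid})
    summary_path = out / "distribution_summary.json"
    summary_path.write_text(json.dumps(stats.to_dict(), indent=2) + "\n")
    paths.append(str(summary_path))
    state["P"] = angular_density_family(dists)
    state["nu"] = volume_fraction_family(vmaps)
    state["lam_grid"] = lam_grid
    return paths


def _run_forward(section: dict, seed: int, out: Path, state: dict) -> list[str]:
    if "P" not in state or "nu" not in state:
        raise PipelineError("forward", "distributions stage must run before forward")
    params = ModelParams.from_dict(
        section.get("params", default_config()["forward"]["params"])
    )
    lam_grid = [float(x) for x in section.get("lam_grid", state["lam_grid"])]
    curve = sigma_curve(lam_grid, params, state["P"], state["nu"])
    curve_path = out / "curve.csv"
    curve.to_csv(curve_path)
    params_path = out / "forward_params.json"
    params.to_json(params_path)
    state["curve"] = curve
    return [str(curve_path), str(params_path)]


def _run_fit(section: dict, seed: int, out: Path, state: dict) -> list[str]:
    if "curve" not in state:
        inp = section.get("curve")
        if inp is None:
            raise PipelineError("fit", "no forward stage output and no 'curve' configured")
        state["curve"] = LoadCurve.from_csv(inp)
    if "P" not in state or "nu" not in state:
        raise PipelineError("fit", "distributions stage must run before fit")
    kwargs = {
        k: section[k]
        for k in ("n_starts", "init_spread", "nm_maxiter", "gamma", "N0")
        if k in section
    }
    config = FitConfig(seed=seed, **kwargs)
    result = fit(state["curve"], state["P"], state["nu"], config=config)
    fit_path = out / "fit.json"
    result.to_json(fit_path)
    return [str(fit_path)]


_STAGE_RUNNERS = {
    "phantom": _run_phantom,
    "segment": _run_segment,
    "distributions": _run_distributions,
    "forward": _run_forward,
    "fit": _run_fit,
}
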