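"""End-to-end pipeline: simulate (optional) -> track -> fit -> energy.

A single flat YAML/JSON config drives the whole chain.  Every run writes a
manifest (parameters, seed, input digests, stage list, package version,
timestamps) so that deterministic stages can be reproduced bit-identically
from the manifest alone.  Numeric output columns carry units in their
headers; times are seconds, forces pN, energies kcal/mol.

Config schema (sections optional unless noted)::

    seed: 1
    physics:            # spin & acquisition parameters
      rpm: 1221         # or force_pN: 15.0 (converted via force_to_rpm)
      rotor_radius_m: 0.133
      bead_mass_eff_kg: 6.9e-15
      temperature_K: 294.15
      frame_interval_s: 5.0
    simulate:           # either this section or `events`
      dG_kcal_mol: -1.5
      control_off_rate_s: 0.05
      n_tethers: 200
      n_replicates: 3
      duration_s: 7200.0
      stuck_fraction: 0.02
      slow_fraction: 0.01
      render_movies: false
      movie: {frame_shape: [512, 512], n_frames: 240, ...}
    events:             # pre-extracted dissociation-time CSVs per arm
      stack: [a1.csv, a2.csv]
      control: [c1.csv, c2.csv]
    track: {sensitivity: 0.5, drop_fraction: 0.5, persistence: 3,
            baseline_frames: 5, roi_scale: 1.5, min_separation_px: 10,
            t0_frame: 0, radius_range: [4, 10]}
    fit: {target_bins: 20}
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import DissociationDataset
from .energetics import delta_g_stack
from .kinetics import aggregate_replicates, build_survival_curve, fit_single_exponential
from .physics import AcquisitionConfig, force_to_rpm, rpm_to_force
from .synthetic import (
    MovieSpec,
    TetherPopulationModel,
    paired_experiment,
    simulate_movie,
    stack_off_rate,
    write_movie,
)
from .tracking import track_experiment

__all__ = ["load_config", "run_pipeline", "demo_config", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    """Read a YAML (or JSON — YAML is a superset) config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _acquisition(cfg: dict) -> AcquisitionConfig:
    phys = dict(cfg.get("physics", {}))
    kwargs = {
        "rotor_radius": phys.get("rotor_radius_m", 0.133),
        "bead_mass_eff": phys.get("bead_mass_eff_kg", 6.9e-15),
        "temperature": phys.get("temperature_K", 294.15),
        "frame_interval": phys.get("frame_interval_s", 5.0),
    }
    if "rpm" in phys:
        rpm = float(phys["rpm"])
    elif "force_pN" in phys:
        rpm = force_to_rpm(float(phys["force_pN"]), AcquisitionConfig(rpm=0.0, **kwargs))
    else:
        raise PipelineError("config", "physics section needs 'rpm' or 'force_pN'")
    return AcquisitionConfig(rpm=rpm, **kwargs)


def _validate(cfg: dict) -> None:
    if ("simulate" in cfg) == ("events" in cfg):
        raise PipelineError("config", "exactly one of 'simulate' or 'events' required")
    if "events" in cfg:
        ev = cfg["events"]
        if not isinstance(ev, dict) or set(ev) != {"stack", "control"}:
            raise PipelineError("config", "'events' needs 'stack' and 'control' lists")


def _simulate_stage(
    cfg: dict, acq: AcquisitionConfig, out: Path, manifest: dict
) -> tuple[list[DissociationDataset], list[DissociationDataset]]:
    sim = dict(cfg["simulate"])
    seed = int(cfg.get("seed", 0))
    model = TetherPopulationModel(
        n_tethers=int(sim.get("n_tethers", 200)),
        off_rate=float(sim.get("control_off_rate_s", 0.05)),
        stuck_fraction=float(sim.get("stuck_fraction", 0.02)),
        slow_fraction=float(sim.get("slow_fraction", 0.01)),
        slow_rate=float(sim.get("control_off_rate_s", 0.05)) / 10.0,
        duration=float(sim.get("duration_s", 7200.0)),
        seed=seed,
    )
    dg = float(sim.get("dG_kcal_mol", -1.5))
    n_rep = int(sim.get("n_replicates", 3))
    force = rpm_to_force(acq.rpm, acq)
    manifest["simulate"] = {
        "dG_true_kcal_mol": dg,
        "control_off_rate_s": model.off_rate,
        "stack_off_rate_s": stack_off_rate(dg, model.off_rate, acq.temperature),
        "model": dataclasses.asdict(model),
        "n_replicates": n_rep,
    }

    if not sim.get("render_movies", False):
        stack_ds, ctrl_ds = paired_experiment(
            dg, model.off_rate, acq.temperature, model, n_rep, force_pN=force
        )
        for arm, dss in (("stack", stack_ds), ("control", ctrl_ds)):
            for ds in dss:
                ds.to_csv(out / f"events_{arm}_rep{ds.data['replicate'].iloc[0]}.csv")
        return stack_ds, ctrl_ds

    movie_kwargs = dict(sim.get("movie", {}))
    if "frame_shape" in movie_kwargs:
        movie_kwargs["frame_shape"] = tuple(movie_kwargs["frame_shape"])
    movie_kwargs.setdefault("frame_interval", acq.frame_interval)
    spec = MovieSpec(**movie_kwargs)
    track_cfg = dict(cfg.get("track", {}))
    arms: list[list[DissociationDataset]] = []
    from .synthetic import _replicate_seed  # fixed master->replicate seed rule

    k_stack = stack_off_rate(dg, model.off_rate, acq.temperature)
    for arm_index, (label, rate) in enumerate([("stack", k_stack), ("control", model.off_rate)]):
        datasets = []
        for rep in range(n_rep):
            m = dataclasses.replace(
                model,
                off_rate=rate,
                slow_rate=min(model.slow_rate, rate / 2.0),
                seed=_replicate_seed(seed, arm_index, rep),
            )
            movie, truth, _ = simulate_movie(
                m, spec, construct=label, replicate=rep, force_pN=force
            )
            write_movie(out / f"movie_{label}_rep{rep}.tif", movie)
            truth.to_csv(out / f"truth_{label}_rep{rep}.csv")
            ds, log = track_experiment(
                movie,
                acq,
                construct=label,
                replicate=rep,
                **track_cfg,
            )
            ds.to_csv(out / f"events_{label}_rep{rep}.csv")
            (out / f"tracklog_{label}_rep{rep}.json").write_text(json.dumps(log, indent=2))
            datasets.append(ds)
        arms.append(datasets)
    return arms[0], arms[1]


def _events_stage(
    cfg: dict, acq: AcquisitionConfig, manifest: dict
) -> tuple[list[DissociationDataset], list[DissociationDataset]]:
    ev = cfg["events"]
    digests = {}
    arms = []
    for arm in ("stack", "control"):
        datasets = []
        for p in ev[arm]:
            path = Path(p)
            if not path.exists():
                raise PipelineError("events", f"missing events file {path}")
            digests[str(path)] = _sha256(path)
            datasets.append(
                DissociationDataset.from_csv(path, frame_interval=acq.frame_interval)
            )
        arms.append(datasets)
    manifest["input_digests"] = digests
    return arms[0], arms[1]


def run_pipeline(cfg: dict, output_dir: str | Path) -> dict:
    """Execute the configured pipeline and write all outputs to ``output_dir``.

    Returns a dict with the summary table, per-arm off-rate estimates,
    per-replicate fits and the manifest.  On stage failure a
    ``failure_marker.json`` naming the stage is left next to any partial
    outputs and the error re-raised.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "cfmkinetics",
        "version": __version__,
        "stages": [],
        "seed": int(cfg.get("seed", 0)),
        "config": cfg,
        "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    try:
        _validate(cfg)
        acq = _acquisition(cfg)
        manifest["acquisition"] = dataclasses.asdict(acq)
        if "simulate" in cfg:
            manifest["stages"].append("simulate")
            if cfg["simulate"].get("render_movies", False):
                manifest["stages"].append("track")
            stack_ds, ctrl_ds = _simulate_stage(cfg, acq, out, manifest)
        else:
            manifest["stages"].append("load_events")
            stack_ds, ctrl_ds = _events_stage(cfg, acq, manifest)

        manifest["stages"] += ["fit", "aggregate", "energy"]
        fits = {}
        fit_rows = []
        estimates = {}
        for label, dss in (("stack", stack_ds), ("control", ctrl_ds)):
            arm_fits = []
            for ds in dss:
                curve = build_survival_curve(ds)
                fit = fit_single_exponential(curve)
                arm_fits.append(fit)
                fit_rows.append(
                    {
                        "construct": label,
                        "force_pN": float(ds.data["force_pN"].iloc[0]),
                        "replicate": int(ds.data["replicate"].iloc[0]),
                        "k_per_s": fit.k,
                        "A": fit.A,
                        "y0": fit.y0,
                        "r_squared": fit.r_squared,
                        "n_tethers": fit.n,
                        "converged": fit.converged,
                    }
                )
            fits[label] = arm_fits
            estimates[label] = aggregate_replicates(
                arm_fits, construct=label, force=float(dss[0].data["force_pN"].iloc[0])
            )
        (out / "fits.json").write_text(json.dumps(fit_rows, indent=2))

        agg = pd.DataFrame(
            [
                {
                    "construct": e.construct,
                    "force_pN": e.force,
                    "k_mean_per_s": e.k_mean,
                    "k_sd_per_s": e.k_sd,
                    "n_replicates": e.n_replicates,
                    "n_tethers_total": e.n_tethers_total,
                }
                for e in estimates.values()
            ]
        )
        agg.to_csv(out / "off_rates.csv", index=False)

        energy = delta_g_stack(estimates["stack"], estimates["control"], acq.temperature)
        summary = pd.DataFrame(
            [
                {
                    "construct_pair": "|".join(energy.construct_pair),
                    "force_pN": energy.force,
                    "k_stack_per_s": estimates["stack"].k_mean,
                    "k_stack_sd_per_s": estimates["stack"].k_sd,
                    "k_control_per_s": estimates["control"].k_mean,
                    "k_control_sd_per_s": estimates["control"].k_sd,
                    "dG_kcal_mol": energy.dG,
                    "dG_err_kcal_mol": energy.dG_err,
                    "T_K": energy.temperature,
                }
            ]
        )
        summary.to_csv(out / "summary.csv", index=False)
        manifest["finished_utc"] = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return {
            "summary": summary,
            "energy": energy,
            "estimates": estimates,
            "fits": fits,
            "manifest": manifest,
        }
    except Exception as err:
        (out / "failure_marker.json").write_text(
            json.dumps({"error": str(err), "stages_completed": manifest["stages"]})
        )
        raise


def demo_config(seed: int = 1) -> dict:
    """Bundled small demonstration: 16-bead rendered movies, 3 replicates.

    A clean-condition showcase (no stuck or slow beads) mirroring a single
    sub-frame's worth of tethers per movie, at 15 pN with a known
    ground-truth stacking energy of -1.5 kcal/mol.
    """
    return {
        "seed": seed,
        "physics": {"force_pN": 15.0, "frame_interval_s": 5.0},
        "simulate": {
            "dG_kcal_mol": -1.5,
            "control_off_rate_s": 0.05,
            "n_tethers": 16,
            "n_replicates": 3,
            "duration_s": 7200.0,
            "stuck_fraction": 0.0,
            "slow_fraction": 0.0,
            "render_movies": True,
            "movie": {
                "frame_shape": [256, 256],
                "bead_radius_px": 6,
                "bead_contrast": 50.0,
                "background_level": 100.0,
                "noise_sd": 8.0,
                "n_frames": 240,
                "min_separation_px": 24.0,
            },
        },
        "track": {},
        "fit": {"target_bins": 20},
    }
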