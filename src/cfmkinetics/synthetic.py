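"""Synthetic force-clamp experiments with known ground truth.

Real CFM movies are terabyte-scale and not deposited, so every stage of the
pipeline is validated against this generator instead.  It emulates the
statistical structure the analysis assumes:

* first-order (exponential) dissociation at a construct- and
  force-dependent off-rate;
* a small fraction of *stuck* beads that never dissociate (anomalous
  tethers, absorbed by the fit's y-offset);
* a rare *slow* second phase from multiple tethers, drawn at a reduced
  off-rate;
* right-censoring at the experiment end — times past the recording are kept
  as censored observations, never discarded;
* paired stack/control experiments whose off-rate ratio encodes a known
  stacking free energy, dG = RT * ln(k_stack / k_control);
* rendered bead movies in which each bead is a bright-centred disc with a
  dark annulus (high local intensity variance) that vanishes between two
  consecutive saved frames at its dissociation time.

Reproducibility: all draws flow from ``numpy.random.default_rng(seed)``.
Replicate seeds in :func:`paired_experiment` are derived from the master
seed with ``np.random.SeedSequence(master, spawn_key=(arm_index, replicate))``
— a fixed mixing rule, so a multi-replicate study is reproducible from the
single master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import disk

from .dataset import DissociationDataset, GroundTruth
from .physics import CONSTANTS

__all__ = [
    "TetherPopulationModel",
    "MovieSpec",
    "sample_dissociation_times",
    "paired_experiment",
    "stack_off_rate",
    "place_beads",
    "render_movie",
    "simulate_movie",
    "write_movie",
]


@dataclass(frozen=True)
class TetherPopulationModel:
    """Population of single-molecule tethers in one constant-force run.

    Defaults encode a typical 15 pN run: off-rate 0.05 1/s (control-like,
    minutes-scale decay), 2% stuck beads, 1% slow multi-tether phase at a
    tenth of the off-rate, 2 h recording.
    """

    n_tethers: int = 200
    off_rate: float = 0.05
    stuck_fraction: float = 0.02
    slow_fraction: float = 0.01
    slow_rate: float = 0.005
    duration: float = 7200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tethers < 1:
            raise ValueError("n_tethers must be >= 1")
        if not (self.off_rate > 0 and math.isfinite(self.off_rate)):
            raise ValueError("off_rate must be finite and > 0")
        if not (self.slow_rate > 0 and math.isfinite(self.slow_rate)):
            raise ValueError("slow_rate must be finite and > 0")
        if not (self.duration > 0 and math.isfinite(self.duration)):
            raise ValueError("duration must be finite and > 0")
        for name in ("stuck_fraction", "slow_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.stuck_fraction + self.slow_fraction > 1.0:
            raise ValueError("stuck_fraction + slow_fraction must be <= 1")


@dataclass(frozen=True)
class MovieSpec:
    """Rendering geometry and noise for a synthetic bead movie."""

    frame_shape: tuple[int, int] = (512, 512)
    bead_radius_px: int = 6
    bead_contrast: float = 50.0
    background_level: float = 100.0
    noise_sd: float = 10.0
    frame_interval: float = 5.0
    n_frames: int = 100
    min_separation_px: float = 24.0

    def __post_init__(self) -> None:
        if self.bead_radius_px < 2:
            raise ValueError("bead_radius_px must be >= 2")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0 or self.noise_sd < 0:
            raise ValueError("frame_interval must be > 0 and noise_sd >= 0")


def sample_dissociation_times(
    model: TetherPopulationModel,
    *,
    construct: str = "construct",
    replicate: int = 0,
    force_pN: float = float("nan"),
) -> tuple[DissociationDataset, GroundTruth]:
    """Draw one experiment's dissociation times from the population model.

    Normal beads draw Exponential(off_rate) lifetimes, slow beads
    Exponential(slow_rate); stuck beads never dissociate.  Any lifetime
    exceeding ``model.duration`` is recorded censored at the duration.
    """
    rng = np.random.default_rng(model.seed)
    n = model.n_tethers
    p = [
        1.0 - model.stuck_fraction - model.slow_fraction,
        model.stuck_fraction,
        model.slow_fraction,
    ]
    classes = rng.choice(np.array(["normal", "stuck", "slow"]), size=n, p=p)
    true_t = np.full(n, np.inf)
    for cls, rate in (("normal", model.off_rate), ("slow", model.slow_rate)):
        mask = classes == cls
        true_t[mask] = rng.exponential(1.0 / rate, mask.sum())

    censored = (true_t > model.duration) | ~np.isfinite(true_t)
    obs_t = np.where(censored, model.duration, true_t)

    data = pd.DataFrame(
        {
            "bead_id": np.arange(n),
            "time_s": obs_t,
            "censored": censored.astype(int),
            "construct": construct,
            "replicate": replicate,
            "force_pN": force_pN,
        }
    )
    truth = pd.DataFrame(
        {
            "bead_id": np.arange(n),
            "x_px": np.nan,
            "y_px": np.nan,
            "class": classes,
            "true_time_s": np.where(np.isfinite(true_t), true_t, model.duration),
            "censored": censored.astype(int),
        }
    )
    return (
        DissociationDataset(data, duration=model.duration),
        GroundTruth(truth),
    )


def stack_off_rate(dG_stack: float, control_rate: float, temperature: float) -> float:
    """Off-rate of the stacked construct implied by dG = RT ln(k_stack/k_ctrl)."""
    if temperature <= 0 or not math.isfinite(temperature):
        raise ValueError("temperature must be finite and > 0")
    rt = CONSTANTS.gas_constant * temperature
    return control_rate * math.exp(dG_stack / rt)


def _replicate_seed(master_seed: int, arm_index: int, rep: int) -> int:
    """Fixed master-seed -> replicate-seed mixing rule (documented contract)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(arm_index, rep))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def paired_experiment(
    dG_stack: float,
    control_rate: float,
    temperature: float,
    model_base: TetherPopulationModel,
    n_replicates: int = 3,
    *,
    force_pN: float = float("nan"),
) -> tuple[list[DissociationDataset], list[DissociationDataset]]:
    """Simulate a stack/control construct pair with known stacking energy.

    The stacked arm's off-rate is ``control_rate * exp(dG_stack / RT)`` —
    exact by construction, so the generated pair carries a known ground-truth
    dG.  Each replicate of each arm gets an independent seed derived from
    ``model_base.seed``.  Returns ``(stack_datasets, control_datasets)``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    k_stack = stack_off_rate(dG_stack, control_rate, temperature)
    arms = []
    for arm_index, (label, rate) in enumerate(
        [("stack", k_stack), ("control", control_rate)]
    ):
        datasets = []
        for rep in range(n_replicates):
            model = replace(
                model_base,
                off_rate=rate,
                slow_rate=min(model_base.slow_rate, rate / 2.0),
                seed=_replicate_seed(model_base.seed, arm_index, rep),
            )
            ds, _ = sample_dissociation_times(
                model, construct=label, replicate=rep, force_pN=force_pN
            )
            datasets.append(ds)
        arms.append(datasets)
    return arms[0], arms[1]


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------


def place_beads(
    spec: MovieSpec, n: int, rng: np.random.Generator, max_tries: int = 200_000
) -> np.ndarray:
    """Random bead centres (y, x) at least ``min_separation_px`` apart.

    Centres keep a margin of bead_radius + 4 px from the frame edge so the
    full disc (and the tracker's ROI) fits inside.  Raises if the packing
    cannot be achieved within the retry budget.
    """
    h, w = spec.frame_shape
    margin = spec.bead_radius_px + 4
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError("frame too small for bead radius")
    pos: list[tuple[float, float]] = []
    tries = 0
    while len(pos) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} beads with min separation "
                f"{spec.min_separation_px} px in {max_tries} tries"
            )
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if all(
            (y - py) ** 2 + (x - px) ** 2 >= spec.min_separation_px**2
            for py, px in pos
        ):
            pos.append((y, x))
    return np.asarray(pos, dtype=float).reshape(n, 2)


def _paint_bead(frame: np.ndarray, y: float, x: float, spec: MovieSpec) -> None:
    # dark annulus first, bright core on top: high ROI variance either way
    rr, cc = disk((y, x), spec.bead_radius_px + 2, shape=frame.shape)
    frame[rr, cc] = spec.background_level - 0.6 * spec.bead_contrast
    rr, cc = disk((y, x), spec.bead_radius_px, shape=frame.shape)
    frame[rr, cc] = spec.background_level + spec.bead_contrast


def render_movie(
    spec: MovieSpec, truth: GroundTruth, seed: int = 0
) -> np.ndarray:
    """Render an image stack (n_frames, H, W) uint16 from a ground truth table.

    Each bead is drawn in every frame acquired strictly before its true
    dissociation time and absent afterwards (disappearance is instantaneous
    between consecutive saved frames).  Censored beads persist to the end.
    Per-frame i.i.d. Gaussian pixel noise with sd ``noise_sd`` is added.
    Deterministic for a given (spec, truth, seed).
    """
    tdf = truth.data
    if tdf[["x_px", "y_px"]].isna().any().any() and len(tdf) > 0:
        raise ValueError("ground truth has no rendered positions")
    rng = np.random.default_rng(seed)
    h, w = spec.frame_shape
    margin = spec.bead_radius_px
    if len(tdf) and (
        (tdf["x_px"] < margin).any()
        or (tdf["y_px"] < margin).any()
        or (tdf["x_px"] > w - margin).any()
        or (tdf["y_px"] > h - margin).any()
    ):
        raise ValueError("bead positions must fit inside the frame with margin")

    true_t = tdf["true_time_s"].to_numpy(float)
    cens = tdf["censored"].to_numpy(int) == 1
    ys = tdf["y_px"].to_numpy(float)
    xs = tdf["x_px"].to_numpy(float)

    stack = np.empty((spec.n_frames, h, w), dtype=np.uint16)
    for f in range(spec.n_frames):
        t_f = f * spec.frame_interval
        frame = np.full((h, w), spec.background_level, dtype=float)
        present = cens | (t_f < true_t)
        for i in np.flatnonzero(present):
            _paint_bead(frame, ys[i], xs[i], spec)
        frame += rng.normal(0.0, spec.noise_sd, size=frame.shape)
        stack[f] = np.clip(np.rint(frame), 0, 65535).astype(np.uint16)
    return stack


def simulate_movie(
    model: TetherPopulationModel,
    spec: MovieSpec,
    *,
    construct: str = "construct",
    replicate: int = 0,
    force_pN: float = float("nan"),
) -> tuple[np.ndarray, GroundTruth, DissociationDataset]:
    """Sample a tether population and render it as a movie.

    The movie's censoring horizon is the recording length
    ``(n_frames - 1) * frame_interval`` (the acquisition time of the last
    frame), applied on top of the model's own duration.  Returns
    ``(stack, truth, dataset)`` where the dataset holds the continuous-time
    draws re-censored at the movie horizon.
    """
    horizon = (spec.n_frames - 1) * spec.frame_interval
    movie_model = replace(model, duration=min(model.duration, horizon))
    ds, truth = sample_dissociation_times(
        movie_model, construct=construct, replicate=replicate, force_pN=force_pN
    )
    rng = np.random.default_rng(np.random.SeedSequence(model.seed, spawn_key=(97,)))
    pos = place_beads(spec, model.n_tethers, rng)
    tdf = truth.data.copy()
    tdf["y_px"] = pos[:, 0]
    tdf["x_px"] = pos[:, 1]
    truth = GroundTruth(tdf, frame_interval=spec.frame_interval)
    stack = render_movie(spec, truth, seed=int(model.seed) % 2**31)
    ds.frame_interval = spec.frame_interval
    return stack, truth, ds


def write_movie(path, stack: np.ndarray) -> None:
    """Write a stack as a multi-page grayscale TIFF."""
    tifffile.imwrite(path, stack, photometric="minisblack")
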