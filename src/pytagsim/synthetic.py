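"""Synthetic single-cell intensity tables with model-derived dynamics.

The generator emulates the statistical structure of the live-cell imaging
tables the quantification stage consumes, with full ground truth recorded
alongside so every quantifier output can be scored:

* per-cell receptor and reporter expression drawn log-normally
  (independent, geometric SD 1.8 by default — wide enough to span the
  receptor:reporter ratio range over which biosensor amplitude varies);
* cytosolic reporter intensity proportional to the free-reporter fraction
  of that cell's own simulated trajectory, with a flat pre-stimulus
  baseline segment;
* multiplicative log-normal measurement noise per frame (fluorescence-like;
  no photobleaching by default, an optional linear bleach slope is
  available for robustness studies);
* occasional frame-wide intensity artifacts (whole-frame fold changes, the
  "abnormally dark or bright image" failure mode of the microscope).

All randomness flows from the seed in :class:`PopulationSpec`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .parameters import LigandSpec, ModelParameters
from .quantify import CellTrace
from .simulate import simulate_timecourse

__all__ = ["PopulationSpec", "GroundTruth", "generate_population",
           "generate_ktr_traces", "generate_line_profile"]


@dataclass(frozen=True)
class PopulationSpec:
    """Statistical description of a synthetic imaging experiment."""

    n_cells: int = 50
    receptor_gsd: float = 1.8          # geometric SD of expression multiplier
    reporter_gsd: float = 1.8
    noise_cv: float = 0.05             # per-frame multiplicative CV
    aberrant_frame_rate: float = 0.0   # per-frame probability (frames >= 1)
    aberrant_fold: float = 3.0         # fold change of an artifact frame
    frame_interval_s: float = 30.0
    duration_s: float = 1800.0
    pre_stimulus_frames: int = 5
    reporter_intensity_scale: float = 1000.0
    bleach_slope_per_s: float = 0.0    # optional linear bleaching
    experiment_id: str = "exp0"
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.aberrant_frame_rate <= 1:
            raise ValueError("aberrant_frame_rate must be in [0, 1]")
        if self.receptor_gsd < 1 or self.reporter_gsd < 1:
            raise ValueError("geometric SDs must be >= 1")
        if self.pre_stimulus_frames < 1:
            raise ValueError("need at least one pre-stimulus frame")


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score quantifier output against the generator."""

    times: np.ndarray                  # full frame grid, s (stimulus at 0)
    stimulation_frame: int
    true_clearance: dict[str, np.ndarray]   # per cell, % on the frame grid
    artifact_frames: tuple[int, ...]
    artifact_folds: dict[int, float]
    receptor_multiplier: dict[str, float]
    reporter_multiplier: dict[str, float]
    beta: float
    gamma: float
    dose_ng_ml: float

    def write(self, path: str | Path) -> None:
        data = {
            "times": self.times.tolist(),
            "stimulation_frame": self.stimulation_frame,
            "true_clearance": {k: v.tolist()
                               for k, v in self.true_clearance.items()},
            "artifact_frames": list(self.artifact_frames),
            "artifact_folds": {str(k): v
                               for k, v in self.artifact_folds.items()},
            "receptor_multiplier": self.receptor_multiplier,
            "reporter_multiplier": self.reporter_multiplier,
            "beta": self.beta, "gamma": self.gamma,
            "dose_ng_ml": self.dose_ng_ml,
        }
        Path(path).write_text(json.dumps(data, indent=2))


def generate_population(spec: PopulationSpec, params: ModelParameters,
                        ligand: LigandSpec
                        ) -> tuple[list[CellTrace], GroundTruth]:
    """Simulate a population and emit measured-style intensity traces.

    Each cell's trajectory is solved at that cell's own receptor and
    reporter totals; the cytosolic intensity is the free-reporter fraction
    scaled by the cell's reporter expression, with noise and frame-wide
    artifacts applied on top.  Frame 0 is never an artifact (it could not
    be repaired by the previous-frame placeholder rule).
    """
    rng = np.random.default_rng(spec.seed)
    n_pre = spec.pre_stimulus_frames
    n_post = int(round(spec.duration_s / spec.frame_interval_s)) + 1
    post_times = np.arange(n_post) * spec.frame_interval_s
    times = np.concatenate([
        -spec.frame_interval_s * np.arange(n_pre, 0, -1), post_times])
    n_frames = n_pre + n_post

    log_r = np.log(spec.receptor_gsd)
    log_z = np.log(spec.reporter_gsd)
    rec_mult = np.exp(rng.normal(0.0, log_r, spec.n_cells)) if log_r > 0 \
        else np.ones(spec.n_cells)
    rep_mult = np.exp(rng.normal(0.0, log_z, spec.n_cells)) if log_z > 0 \
        else np.ones(spec.n_cells)

    # frame-wide artifacts shared by all cells of the experiment
    artifact_mask = rng.random(n_frames) < spec.aberrant_frame_rate
    artifact_mask[0] = False
    art_frames = tuple(int(i) for i in np.nonzero(artifact_mask)[0])
    art_folds = {}
    frame_factor = np.ones(n_frames)
    for f in art_frames:
        fold = spec.aberrant_fold if rng.random() < 0.5 \
            else 1.0 / spec.aberrant_fold
        art_folds[f] = float(fold)
        frame_factor[f] = fold

    traces: list[CellTrace] = []
    true_clear: dict[str, np.ndarray] = {}
    for i in range(spec.n_cells):
        cid = f"{spec.experiment_id}_c{i:03d}"
        p = params.replace(receptor_total=params.receptor_total * rec_mult[i],
                           reporter_total=params.reporter_total * rep_mult[i])
        traj = simulate_timecourse(p, ligand, duration=spec.duration_s,
                                   output_step=spec.frame_interval_s)
        clearance = np.concatenate([np.zeros(n_pre), traj.clearance])
        true_clear[cid] = clearance
        free_frac = 1.0 - clearance / 100.0
        signal = spec.reporter_intensity_scale * rep_mult[i] * free_frac
        if spec.bleach_slope_per_s:
            signal = signal * np.clip(
                1.0 - spec.bleach_slope_per_s * (times - times[0]), 0.0, None)
        if spec.noise_cv > 0:
            sigma = np.sqrt(np.log1p(spec.noise_cv ** 2))
            noise = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, n_frames))
        else:
            noise = np.ones(n_frames)
        intensity = signal * noise * frame_factor
        traces.append(CellTrace(
            cell_id=cid, times=times, cytosolic=intensity,
            receptor_expression=float(rec_mult[i]),
            reporter_expression=float(rep_mult[i]),
            pre_stimulus_frames=n_pre,
            experiment_id=spec.experiment_id))
    truth = GroundTruth(times=times, stimulation_frame=n_pre,
                        true_clearance=true_clear,
                        artifact_frames=art_frames, artifact_folds=art_folds,
                        receptor_multiplier={t.cell_id: float(m) for t, m in
                                             zip(traces, rec_mult)},
                        reporter_multiplier={t.cell_id: float(m) for t, m in
                                             zip(traces, rep_mult)},
                        beta=ligand.beta, gamma=ligand.gamma,
                        dose_ng_ml=ligand.dose_ng_ml)
    return traces, truth


def generate_ktr_traces(clearance_traces: list[tuple[np.ndarray, np.ndarray]],
                        lag_s: float = 240.0, ratio_baseline: float = 1.0,
                        ratio_gain: float = 0.01,
                        nuclear_intensity: float = 500.0,
                        smoothing_tau_s: float = 0.0,
                        experiment_id: str = "exp0") -> list[CellTrace]:
    """Kinase-translocation-reporter tables driven by clearance signals.

    Each input is ``(times, clearance_pct)``.  The cytosolic:nuclear KTR
    ratio follows the clearance signal through a transport delay of
    ``lag_s`` seconds (downstream kinase activity trails receptor activity),
    mapped affinely: ``ratio = ratio_baseline + ratio_gain * delayed``.
    ``smoothing_tau_s`` optionally applies first-order smoothing on top of
    the delay.  The delay is the recorded ground truth and is exactly
    recoverable from the time-to-half-max difference of the two readouts.
    """
    if lag_s < 0:
        raise ValueError("lag must be >= 0")
    out = []
    for i, (times, clearance) in enumerate(clearance_traces):
        delayed = np.interp(times - lag_s, times, clearance,
                            left=clearance[0])
        if smoothing_tau_s > 0:
            sm = np.empty_like(delayed)
            sm[0] = delayed[0]
            for j in range(1, len(delayed)):
                dt = times[j] - times[j - 1]
                a = dt / (smoothing_tau_s + dt)
                sm[j] = sm[j - 1] + a * (delayed[j] - sm[j - 1])
            delayed = sm
        ratio = ratio_baseline + ratio_gain * delayed
        nuclear = np.full_like(ratio, nuclear_intensity)
        out.append(CellTrace(
            cell_id=f"{experiment_id}_ktr{i:03d}", times=np.asarray(times),
            cytosolic=ratio * nuclear, nuclear=nuclear,
            pre_stimulus_frames=1, experiment_id=experiment_id))
    return out


def generate_line_profile(membrane_position: float, amplitude: float,
                          width: float, baseline: float,
                          noise_sd: float = 0.0, n_points: int = 101,
                          extent: float = 10.0, seed: int = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian membrane bump on a flat baseline, with optional noise.

    Returns ``(positions, intensities)``; the ground-truth peak location is
    ``membrane_position`` and the noiseless peak value ``baseline +
    amplitude``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, extent, n_points)
    y = baseline + amplitude * np.exp(-0.5 * ((x - membrane_position) / width) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n_points)
    return x, y
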