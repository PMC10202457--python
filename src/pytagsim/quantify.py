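"""Quantification of biosensor and KTR trajectories from intensity tables.

Inputs are per-cell cytosolic (and optionally nuclear) fluorescence
timeseries, as produced by segmenting cells in timelapse images and
measuring mean intensities — or by the synthetic generator in
:mod:`pytagsim.synthetic`.  The central readout is

    activity_RTK(t) = -100 * (I_cyt(t) / I_cyt,o - 1)

the percentage of reporter cleared from the cytosol relative to the mean
pre-stimulus cytosolic intensity ``I_cyt,o``.  Replicate aggregation is
hierarchical: population-averaged means are formed per experiment first and
the reported mean +/- SD is taken across experiment means, never across
pooled cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CellTrace", "ActivityTrace", "ReplicateSummary", "RepairSettings",
    "clearance_activity", "repair_aberrant_frames", "minmax_normalize",
    "time_to_half_max", "ktr_activity", "membrane_enrichment",
    "aggregate_replicates", "sort_by_expression_ratio",
    "traces_to_frame", "frame_to_traces",
]


@dataclass(frozen=True)
class CellTrace:
    """One cell's intensity timeseries.

    ``pre_stimulus_frames`` counts the frames recorded before ligand
    addition; their mean cytosolic intensity is the normalization baseline.
    ``receptor_expression`` / ``reporter_expression`` are pre-stimulus
    expression proxies (e.g. initial membrane receptor and cytosolic
    reporter fluorescence).
    """

    cell_id: str
    times: np.ndarray                  # s, shared grid within an experiment
    cytosolic: np.ndarray              # fluorescence, > 0
    nuclear: np.ndarray | None = None
    receptor_expression: float | None = None
    reporter_expression: float | None = None
    pre_stimulus_frames: int = 1
    experiment_id: str = "exp0"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.cytosolic, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cytosolic", c)
        if self.nuclear is not None:
            object.__setattr__(self, "nuclear",
                               np.asarray(self.nuclear, dtype=float))
        if t.shape != c.shape:
            raise ValueError("times and cytosolic must have the same length")
        if not np.all(np.isfinite(c)):
            raise ValueError("intensities must be finite")
        if not 1 <= self.pre_stimulus_frames < len(t):
            raise ValueError("pre_stimulus_frames must be in [1, n_frames)")


@dataclass(frozen=True)
class ActivityTrace:
    """Clearance activity (%) of one cell, with its baseline."""

    cell_id: str
    times: np.ndarray
    activity: np.ndarray               # %, Eq-4 convention
    baseline: float                    # I_cyt,o
    replaced_frames: tuple[int, ...] = ()
    experiment_id: str = "exp0"


def clearance_activity(trace: CellTrace) -> ActivityTrace:
    """Percent reporter cleared from the cytosol vs pre-stimulus baseline."""
    baseline = float(np.mean(trace.cytosolic[: trace.pre_stimulus_frames]))
    if baseline <= 0:
        raise ValueError("pre-stimulus baseline must be positive")
    activity = -100.0 * (trace.cytosolic / baseline - 1.0)
    return ActivityTrace(cell_id=trace.cell_id, times=trace.times,
                         activity=activity, baseline=baseline,
                         experiment_id=trace.experiment_id)


@dataclass(frozen=True)
class RepairSettings:
    """Detection rule for microscope frames that are aberrantly dark/bright.

    A frame is flagged when the *median across cells* of the signed relative
    intensity change from the previous (already repaired) frame exceeds
    ``median_change`` in magnitude and at least ``direction_frac`` of cells
    move in the same direction — i.e. a coordinated, frame-wide jump, not a
    single-cell event.
    """

    median_change: float = 0.30
    direction_frac: float = 0.80


def repair_aberrant_frames(traces: list[CellTrace],
                           settings: RepairSettings | None = None
                           ) -> tuple[list[CellTrace], list[int]]:
    """Replace frame-wide aberrant intensities with the previous frame.

    All cells of the experiment share the frame grid; flagged frames have
    every cell's cytosolic intensity replaced by that cell's value at the
    previous time point (the placeholder rule).  Returns the repaired
    traces and the sorted list of flagged frame indices.
    """
    st = settings or RepairSettings()
    if not traces:
        raise ValueError("no traces given")
    n_frames = len(traces[0].times)
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    for tr in traces:
        if len(tr.times) != n_frames:
            raise ValueError("all cells must share the frame grid")
    mat = np.stack([tr.cytosolic for tr in traces])  # cells x frames
    repaired = mat.copy()
    flagged: list[int] = []
    for f in range(1, n_frames):
        prev = repaired[:, f - 1]
        rel = (mat[:, f] - prev) / prev
        med = np.median(rel)
        same_dir = np.mean(np.sign(rel) == np.sign(med)) if med != 0 else 0.0
        if abs(med) > st.median_change and same_dir >= st.direction_frac:
            flagged.append(f)
            repaired[:, f] = prev
    if len(flagged) > 0.5 * (n_frames - 1):
        # every frame jumping away from frame 0 means frame 0 itself is the
        # aberrant one, and it has no predecessor to serve as placeholder
        raise ValueError("first frame appears aberrant and cannot be "
                         "repaired by the previous-frame placeholder rule")
    out = [replace(tr, cytosolic=repaired[i]) for i, tr in enumerate(traces)]
    return out, flagged


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Scale a trace to [0, 1] by its own minimum and maximum."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise ValueError("cannot min-max normalize a constant trace")
    return (v - lo) / (hi - lo)


def time_to_half_max(values: np.ndarray, times: np.ndarray
                     ) -> tuple[float, bool]:
    """First time the trace crosses half of its maximum, interpolated.

    Returns ``(t_half, ok)``; ``ok`` is False for the degenerate case where
    the trace already starts at or above half its maximum (then the first
    frame time is returned).
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("trace must reach a positive maximum")
    half = 0.5 * vmax
    if v[0] >= half:
        return float(t[0]), False
    idx = np.nonzero(v >= half)[0]
    i = int(idx[0])
    frac = (half - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1])), True


def ktr_activity(trace: CellTrace) -> np.ndarray:
    """Cytosolic / nuclear intensity ratio (kinase-translocation readout)."""
    if trace.nuclear is None:
        raise ValueError("trace has no nuclear channel")
    if np.any(trace.nuclear <= 0):
        raise ValueError("nuclear intensities must be positive")
    return trace.cytosolic / trace.nuclear


def membrane_enrichment(profile: np.ndarray,
                        positions: np.ndarray | None = None
                        ) -> tuple[float, float]:
    """Peak of a line-scan intensity profile drawn across the membrane.

    Returns ``(peak_intensity, peak_position)``; the maximum of the profile
    defines the receptor intensity at the membrane.
    """
    v = np.asarray(profile, dtype=float)
    if v.size == 0:
        raise ValueError("empty profile")
    if positions is None:
        positions = np.arange(v.size, dtype=float)
    i = int(np.argmax(v))
    return float(v[i]), float(np.asarray(positions, dtype=float)[i])


@dataclass(frozen=True)
class ReplicateSummary:
    """Hierarchical replicate aggregate: mean/SD across experiment means."""

    times: np.ndarray
    experiment_means: dict[str, np.ndarray]
    grand_mean: np.ndarray
    sd: np.ndarray                     # sample SD across experiment means
    n_experiments: int


def aggregate_replicates(traces: list[ActivityTrace]) -> ReplicateSummary:
    """Mean +/- SD of population-averaged means from each experiment."""
    if not traces:
        raise ValueError("no traces given")
    times = traces[0].times
    groups: dict[str, list[np.ndarray]] = {}
    for tr in traces:
        if len(tr.times) != len(times):
            raise ValueError("all traces must share the frame grid")
        groups.setdefault(tr.experiment_id, []).append(tr.activity)
    exp_means = {k: np.mean(np.stack(v), axis=0)
                 for k, v in sorted(groups.items())}
    stacked = np.stack(list(exp_means.values()))
    grand = stacked.mean(axis=0)
    sd = (stacked.std(axis=0, ddof=1) if len(exp_means) > 1
          else np.zeros_like(grand))
    return ReplicateSummary(times=times, experiment_means=exp_means,
                            grand_mean=grand, sd=sd,
                            n_experiments=len(exp_means))


def sort_by_expression_ratio(traces: list[CellTrace]) -> pd.DataFrame:
    """Heatmap table of cells ordered by receptor:reporter expression ratio.

    Rows are cells in ascending ratio order; columns are frames.  The ratio
    column is attached for downstream correlation analyses.
    """
    rows = []
    for tr in traces:
        if tr.receptor_expression is None or tr.reporter_expression is None:
            raise ValueError(f"cell {tr.cell_id} lacks expression proxies")
        if tr.reporter_expression <= 0:
            raise ValueError(f"cell {tr.cell_id} has nonpositive reporter "
                             "expression")
        rows.append((tr.receptor_expression / tr.reporter_expression, tr))
    rows.sort(key=lambda x: x[0])
    data = {f"t{j}": [tr.cytosolic[j] for _, tr in rows]
            for j in range(len(rows[0][1].times))}
    df = pd.DataFrame({"cell_id": [tr.cell_id for _, tr in rows],
                       "expression_ratio": [r for r, _ in rows], **data})
    return df


# ---------------------------------------------------------------------------
# tidy-table interchange (one row per experiment, cell, frame)


def traces_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for j, t in enumerate(tr.times):
            row = {"experiment_id": tr.experiment_id, "cell_id": tr.cell_id,
                   "frame": j, "time_s": float(t),
                   "cytosolic": float(tr.cytosolic[j])}
            if tr.nuclear is not None:
                row["nuclear"] = float(tr.nuclear[j])
            if tr.receptor_expression is not None:
                row["receptor_expr"] = tr.receptor_expression
            if tr.reporter_expression is not None:
                row["reporter_expr"] = tr.reporter_expression
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_traces(df: pd.DataFrame, pre_stimulus_frames: int = 1
                    ) -> list[CellTrace]:
    traces = []
    for (exp, cell), grp in df.groupby(["experiment_id", "cell_id"],
                                       sort=False):
        grp = grp.sort_values("frame")
        traces.append(CellTrace(
            cell_id=str(cell),
            times=grp["time_s"].to_numpy(),
            cytosolic=grp["cytosolic"].to_numpy(),
            nuclear=grp["nuclear"].to_numpy() if "nuclear" in grp else None,
            receptor_expression=(float(grp["receptor_expr"].iloc[0])
                                 if "receptor_expr" in grp else None),
            reporter_expression=(float(grp["reporter_expr"].iloc[0])
                                 if "reporter_expr" in grp else None),
            pre_stimulus_frames=pre_stimulus_frames,
            experiment_id=str(exp)))
    return traces
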