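"""Trace-table IO, steady-state window selection, AP-region classification.

Trace tables are delimited text (comma or tab, autodetected) with one row per
nucleus and time point: embryo_id, cycle, nucleus_id, time_s, intensity and
optional ap_position (fraction of egg length, anterior = 0) and mother_id
(the nucleus id of the mother in the previous cell cycle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import OPTIONAL_COLUMNS, REQUIRED_COLUMNS, TraceSet

__all__ = [
    "SteadyStateWindow",
    "SchemaError",
    "load_traces",
    "save_traces",
    "select_steady_state",
    "classify_region",
]

#: AP-region definitions as fractions of egg length (inclusive bounds)
ANTERIOR_REGION = (0.0, 0.35)
BOUNDARY_REGION = (0.45, 0.55)


class SchemaError(ValueError):
    """Trace table does not match the expected schema."""


@dataclass(frozen=True)
class SteadyStateWindow:
    """Plateau window of the ensemble-mean intensity within one cell cycle."""

    start_s: float
    end_s: float
    plateau_fraction: float
    smooth_samples: int

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("window start must precede end")


def save_traces(traces: TraceSet | list[TraceSet], path: str | Path, sep: str = ",") -> None:
    """Write one or several TraceSets as a single long-format table."""
    sets = [traces] if isinstance(traces, TraceSet) else list(traces)
    frame = pd.concat([ts.to_frame() for ts in sets], ignore_index=True)
    frame.to_csv(path, sep=sep, index=False)


def _detect_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def load_traces(path: str | Path, grid_rtol: float = 1e-3) -> list[TraceSet]:
    """Load a trace table, returning one TraceSet per (embryo, cycle) group.

    Rows may arrive in any order; each group is validated to sit on a
    uniform time grid (within ``grid_rtol`` of the group's median interval).
    Nuclei with missing samples on the grid are flagged with a warning and
    their missing entries dropped from the set.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_detect_sep(path))
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trace table {path} lacks required columns {missing}")
    sets: list[TraceSet] = []
    for (embryo, cycle), grp in frame.groupby(["embryo_id", "cycle"], sort=True):
        times = np.sort(grp["time_s"].unique())
        if times.size >= 2:
            dts = np.diff(times)
            dt = np.median(dts)
            if np.any(np.abs(dts - dt) > grid_rtol * dt):
                raise SchemaError(
                    f"embryo {embryo!r} cycle {cycle}: non-uniform time grid "
                    f"(intervals range {dts.min():.4g}..{dts.max():.4g} s)"
                )
        pivot = grp.pivot_table(index="nucleus_id", columns="time_s", values="intensity")
        pivot = pivot.reindex(columns=times)
        incomplete = pivot.isna().any(axis=1)
        if incomplete.any():
            warnings.warn(
                f"embryo {embryo!r} cycle {cycle}: dropping "
                f"{int(incomplete.sum())} trace(s) with missing samples"
            )
            pivot = pivot.loc[~incomplete]
        nuclei = pivot.index.to_numpy()
        per_nuc = grp.drop_duplicates("nucleus_id").set_index("nucleus_id")
        meta = pd.DataFrame(
            {"embryo_id": embryo, "cycle": cycle, "nucleus_id": nuclei}
        )
        for col in OPTIONAL_COLUMNS:
            if col in per_nuc.columns:
                meta[col] = per_nuc.loc[nuclei, col].to_numpy()
        sets.append(
            TraceSet(times_s=times, values=pivot.to_numpy(float), meta=meta)
        )
    return sets


def select_steady_state(
    traces: TraceSet,
    plateau_fraction: float = 0.8,
    smooth_samples: int = 3,
) -> SteadyStateWindow:
    """Find the expression plateau of the ensemble-mean intensity.

    The mean intensity over all traces is smoothed with a short moving
    average; the window is the contiguous stretch where it stays above
    ``plateau_fraction`` of its maximum.  The window must not touch the
    first or last sample (the gene has to visibly activate and deactivate
    within the trace), otherwise no plateau is declared and manual bounds
    are suggested.  The criterion is scale invariant.
    """
    if traces.n_times < 5:
        raise ValueError("need at least 5 time points for plateau detection")
    mean = traces.values.mean(axis=0)
    w = max(1, int(smooth_samples))
    kernel = np.ones(w) / w
    smooth = np.convolve(mean, kernel, mode="same")
    # moving average with 'same' underweights the edges; renormalize
    norm = np.convolve(np.ones_like(mean), kernel, mode="same")
    smooth = smooth / norm
    above = smooth >= plateau_fraction * smooth.max()
    idx = np.flatnonzero(above)
    first, last = int(idx[0]), int(idx[-1])
    if first == 0 or last == traces.n_times - 1:
        raise ValueError(
            "no interior expression plateau found (mean intensity does not "
            "both reach and leave the plateau); pass explicit bounds via "
            "TraceSet.with_window(start, end)"
        )
    if not above[first : last + 1].all():
        # use the longest contiguous run above threshold
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        best = max(runs, key=len)
        first, last = int(best[0]), int(best[-1])
    return SteadyStateWindow(
        start_s=float(traces.times_s[first]),
        end_s=float(traces.times_s[last]),
        plateau_fraction=plateau_fraction,
        smooth_samples=w,
    )


def classify_region(ap_position: float) -> str:
    """Label an AP position: 'anterior' [0, 0.35], 'boundary' [0.45, 0.55].

    Positions in the gap or posterior of the boundary are 'unclassified'.
    """
    if not 0.0 <= ap_position <= 1.0:
        raise ValueError("AP position must be a fraction of egg length in [0, 1]")
    if ANTERIOR_REGION[0] <= ap_position <= ANTERIOR_REGION[1]:
        return "anterior"
    if BOUNDARY_REGION[0] <= ap_position <= BOUNDARY_REGION[1]:
        return "boundary"
    return "unclassified"
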