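"""The TraceSet container: fluorescence traces on one uniform time grid.

A TraceSet bundles the intensity matrix (traces x time points) with per-trace
metadata (nucleus id, anterior-posterior position as a fraction of egg
length, cell cycle, embryo id, optional mother nucleus for lineage tracking)
and an optional steady-state window.  Datasets with several sampling
intervals (different embryos) are lists of TraceSets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["TraceSet", "REQUIRED_COLUMNS", "OPTIONAL_COLUMNS"]

REQUIRED_COLUMNS = ("embryo_id", "cycle", "nucleus_id", "time_s", "intensity")
OPTIONAL_COLUMNS = ("ap_position", "mother_id")


@dataclass(frozen=True)
class TraceSet:
    """Intensity traces sharing one uniform sampling grid.

    ``values[m, k]`` is the intensity of trace ``m`` at ``times_s[k]``.
    Intensities are background-subtracted and may therefore contain small
    negative values; these are kept and flagged via ``has_negative``.
    """

    times_s: np.ndarray
    values: np.ndarray
    meta: pd.DataFrame
    steady_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or t.ndim != 1 or v.shape[1] != t.size:
            raise ValueError("values must be (n_traces, n_times) matching times_s")
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times_s must form a uniform grid")
        if not np.isfinite(v).all():
            raise ValueError("intensities must be finite")
        if len(self.meta) != v.shape[0]:
            raise ValueError("meta must have one row per trace")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", v)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_matrix(
        cls,
        times_s: np.ndarray,
        values: np.ndarray,
        meta: pd.DataFrame | None = None,
        steady_window: tuple[float, float] | None = None,
        embryo_id: str = "sim",
        cycle: int = 13,
    ) -> "TraceSet":
        values = np.asarray(values, dtype=float)
        if meta is None:
            meta = pd.DataFrame(
                {
                    "embryo_id": embryo_id,
                    "cycle": cycle,
                    "nucleus_id": np.arange(values.shape[0]),
                    "ap_position": np.nan,
                    "mother_id": pd.array([pd.NA] * values.shape[0]),
                }
            )
        return cls(
            times_s=np.asarray(times_s, float),
            values=values,
            meta=meta.reset_index(drop=True),
            steady_window=steady_window,
        )

    # -- basic properties --------------------------------------------------
    @property
    def n_traces(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def dt_s(self) -> float:
        if self.times_s.size < 2:
            raise ValueError("need at least two time points for a sampling interval")
        return float(self.times_s[1] - self.times_s[0])

    @property
    def has_negative(self) -> bool:
        """True when background subtraction left small negative intensities."""
        return bool((self.values < 0).any())

    # -- transforms --------------------------------------------------------
    def with_window(self, start_s: float, end_s: float) -> "TraceSet":
        if not start_s < end_s:
            raise ValueError("window start must precede end")
        return replace(self, steady_window=(float(start_s), float(end_s)))

    def scaled(self, factor: float) -> "TraceSet":
        return replace(self, values=self.values * factor)

    def subset(self, indices: np.ndarray) -> "TraceSet":
        indices = np.asarray(indices)
        return replace(
            self,
            values=self.values[indices],
            meta=self.meta.iloc[indices].reset_index(drop=True),
        )

    def steady_state(self) -> "TraceSet":
        """Restrict to the marked steady-state window (error if unmarked)."""
        if self.steady_window is None:
            raise ValueError(
                "no steady-state window marked; run select_steady_state or "
                "set one explicitly with with_window(start, end)"
            )
        lo, hi = self.steady_window
        keep = (self.times_s >= lo - 1e-9) & (self.times_s <= hi + 1e-9)
        return replace(
            self,
            times_s=self.times_s[keep],
            values=self.values[:, keep],
            steady_window=self.steady_window,
        )

    # -- long-format conversion -------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per (trace, time point)."""
        M, K = self.values.shape
        meta = self.meta
        frame = pd.DataFrame(
            {
                "embryo_id": np.repeat(meta["embryo_id"].to_numpy(), K),
                "cycle": np.repeat(meta["cycle"].to_numpy(), K),
                "nucleus_id": np.repeat(meta["nucleus_id"].to_numpy(), K),
                "time_s": np.tile(self.times_s, M),
                "intensity": self.values.ravel(),
            }
        )
        for col in OPTIONAL_COLUMNS:
            if col in meta.columns:
                frame[col] = np.repeat(meta[col].to_numpy(), K)
        return frame
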