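"""Probe geometry: gene construct, loop function and the deterministic signal model.

The MS2-MCP reporter makes nascent transcription visible: as a polymerase
elongates through the MS2 cassette it produces stem-loops that bind
fluorescent MCP, so the fluorescence contributed by a single polymerase
depends only on how far along the gene it has travelled.  Discretizing the
gene into sites of one polymerase footprint (150 bp, traversed in
``step_time_s`` seconds), the cumulative number of loops made by a polymerase
at site ``i`` is the *loop function* ``L_i``.  With promoter occupancy
``X(t)`` (1 when a polymerase sits at the initiation site) the total signal is

    F(t) = sum_{i=1..r} L_i * X(t - i),

time counted in polymerase steps: the polymerase at site ``i`` started
``i`` steps ago, so it reports the promoter state at ``t - i``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "GeneConstruct",
    "LoopFunction",
    "PromoterStateTrace",
    "build_loop_function",
    "buffering_time",
    "fluorescence_from_states",
    "mean_fluorescence",
    "construct_from_config",
]

#: polymerase footprint in base pairs (one elongation step)
DEFAULT_STEP_BP = 150
#: seconds per polymerase step (the promoter blocking time tau_block)
DEFAULT_STEP_TIME_S = 6.0


class InvalidConstructError(ValueError):
    """Raised for geometrically impossible construct descriptions."""


@dataclass(frozen=True)
class GeneConstruct:
    """Geometry of the transcribed reporter in polymerase steps.

    Parameters
    ----------
    pre_cassette_steps
        150-bp polymerase steps transcribed before the first MS2 loop.
    cassette_steps
        Steps spanned by the MS2 cassette itself.
    post_cassette_steps
        Steps after the last loop (a 3' non-binding tail, as in a 5' design).
    loops_total
        Number of MS2 loops in the cassette (24 in the hunchback reporter).
    step_bp
        Base pairs per polymerase step.
    step_time_s
        Seconds per polymerase step.
    """

    pre_cassette_steps: int
    cassette_steps: int
    post_cassette_steps: int = 0
    loops_total: int = 24
    step_bp: int = DEFAULT_STEP_BP
    step_time_s: float = DEFAULT_STEP_TIME_S

    def __post_init__(self) -> None:
        for name in ("pre_cassette_steps", "cassette_steps", "post_cassette_steps"):
            if getattr(self, name) < 0:
                raise InvalidConstructError(f"{name} must be >= 0")
        if self.loops_total < 0:
            raise InvalidConstructError("loops_total must be >= 0")
        if self.loops_total >= 1 and self.cassette_steps < 1:
            raise InvalidConstructError(
                "a construct with MS2 loops needs cassette_steps >= 1"
            )
        if self.n_sites < 1:
            raise InvalidConstructError("construct must span at least one site")
        if self.step_time_s <= 0:
            raise InvalidConstructError("step_time_s must be > 0")

    @property
    def n_sites(self) -> int:
        """Total number of polymerase sites r on the transcribed sequence."""
        return self.pre_cassette_steps + self.cassette_steps + self.post_cassette_steps


@dataclass(frozen=True)
class LoopFunction:
    """Cumulative loop count L_i for a polymerase at site i = 1..r.

    Values are non-decreasing, start at >= 0 and end at ``loops_total``;
    they need not be integers because the 150-bp polymerase step and the
    loop spacing do not coincide.
    """

    values: np.ndarray
    step_time_s: float = DEFAULT_STEP_TIME_S

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("loop function must be a non-empty 1-D vector")
        if np.any(np.diff(v) < -1e-12) or v[0] < 0:
            raise ValueError("loop function must be non-negative and non-decreasing")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def total(self) -> float:
        """Saturation signal sum_i L_i (fluorescence of a fully loaded gene)."""
        return float(self.values.sum())


@dataclass(frozen=True)
class PromoterStateTrace:
    """Binary promoter occupancy X on the polymerase-step grid."""

    states: np.ndarray
    step_time_s: float = DEFAULT_STEP_TIME_S

    def __post_init__(self) -> None:
        s = np.asarray(self.states)
        if s.size < 1:
            raise ValueError("state trace must have length >= 1")
        if not np.isin(s, (0, 1)).all():
            raise ValueError("promoter states must be binary")
        object.__setattr__(self, "states", s.astype(np.int8))


def build_loop_function(construct: GeneConstruct) -> LoopFunction:
    """Loop function of a construct: zeros, a linear ramp, then saturation.

    L_i = 0 before the cassette, rises linearly at ``loops_total /
    cassette_steps`` loops per step across the cassette (about two loops per
    step for the 24x cassette) and stays at ``loops_total`` afterwards.
    """
    r = construct.n_sites
    values = np.zeros(r)
    if construct.loops_total >= 1:
        slope = construct.loops_total / construct.cassette_steps
        ramp = slope * np.arange(1, construct.cassette_steps + 1)
        lo = construct.pre_cassette_steps
        values[lo : lo + construct.cassette_steps] = ramp
        values[lo + construct.cassette_steps :] = construct.loops_total
    return LoopFunction(values=values, step_time_s=construct.step_time_s)


def buffering_time(construct: GeneConstruct) -> float:
    """Probe buffering time in seconds.

    The time a polymerase needs to traverse the loop-carrying part of the
    gene (cassette plus any downstream sequence): the intrinsic correlation
    time of the probe, 72 s for the 24-loop 3' construct at 6 s/step.
    """
    return (construct.cassette_steps + construct.post_cassette_steps) * construct.step_time_s


def fluorescence_from_states(
    states: PromoterStateTrace, loop_fn: LoopFunction
) -> np.ndarray:
    """Fluorescence (in loop units) from a promoter state history.

    Implements F(t) = sum_{i=1..r} L_i X(t - i) on the polymerase-step grid.
    Only steady-state samples are returned: the first r samples, for which
    the gene is not yet fully loaded (X(t-i) would need states before the
    start of the trace), are treated as warm-up and dropped.  The returned
    array has length ``len(states) - r`` and may be empty for short traces.
    """
    if states.step_time_s != loop_fn.step_time_s:
        raise ValueError(
            "state trace and loop function use different step times; "
            "convert to a common polymerase-step grid first"
        )
    x = states.states.astype(float)
    L = loop_fn.values
    r = L.size
    # F(t) = sum_i L_i x(t-i): correlation of x with reversed L
    full = np.convolve(x, L)  # full[t] = sum_j L_j x[t-j], j from 0
    # x index 0 is time step 1; F defined for t >= r+1 .. len(states): indices
    # where all r delayed states exist.
    n = x.size
    if n < r + 1:
        return np.empty(0)
    # full[k] = sum_j x[k-j] L[j]; with x[k] = X(k+1), L[j] = L_{j+1}:
    # F(t) = sum_i L_i X(t-i) = full[t-2] for t such that t-i >= 1 for all i
    return full[r - 1 : n - 1]


def mean_fluorescence(p_on: float, loop_fn: LoopFunction) -> float:
    """Steady-state mean signal  <F> = P_on * sum_i L_i."""
    if not 0.0 <= p_on <= 1.0:
        raise ValueError("P_on must lie in [0, 1]")
    return p_on * loop_fn.total


def construct_from_config(path: str | Path) -> GeneConstruct:
    """Read a construct description from a YAML/JSON key-value file.

    Expected keys: ``pre_cassette_bp``, ``cassette_bp``, ``post_cassette_bp``,
    ``loops_total`` and optional ``step_bp`` (150), ``step_time_s`` (6).
    Base-pair lengths are converted to polymerase steps by rounding to the
    nearest integer step.
    """
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise InvalidConstructError(f"construct config {path} is not a mapping")
    step_bp = int(cfg.get("step_bp", DEFAULT_STEP_BP))

    def steps(key: str) -> int:
        return int(round(float(cfg.get(key, 0)) / step_bp))

    return GeneConstruct(
        pre_cassette_steps=steps("pre_cassette_bp"),
        cassette_steps=steps("cassette_bp"),
        post_cassette_steps=steps("post_cassette_bp"),
        loops_total=int(cfg.get("loops_total", 24)),
        step_bp=step_bp,
        step_time_s=float(cfg.get("step_time_s", DEFAULT_STEP_TIME_S)),
    )
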