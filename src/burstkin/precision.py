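"""Precision of the transcriptional readout: relative error of produced mRNA.

A nucleus reads its position through the fraction of time its promoter is ON
during a cell-cycle window of length T.  Because the total mRNA produced in
the window is proportional to P_on, the readout precision equals the
relative error of the time-averaged occupancy, delta mRNA / <mRNA> =
delta P_on / P_on.  For a two-state promoter the gene resets itself on the
correlation time tau_i = 1/(k_on_eff + k_off), so a window provides about
T / (2 tau_i) independent measurements of a binary variable:

    delta mRNA / <mRNA> = sqrt( 2 tau_i (1 - P_on) / (T P_on) ),

valid for T >> tau_i.  The memoryless (poisson-like) promoter is limited
only by the firing-time statistics, sqrt( tau_block (1 - P_on) / T ).  The
cycle promoter has no printed closed form here; its finite-T error (and
everyone else's, away from the large-T limit) comes from a Monte-Carlo
estimator of the time-averaged ON indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import CycleParams, PoissonLikeParams, PromoterModel
from .simulate import occupancy_time_average
from .traces import TraceSet

__all__ = [
    "PrecisionEstimate",
    "relative_error_two_state",
    "relative_error_poisson",
    "relative_error_monte_carlo",
    "empirical_relative_error",
    "lineage_integrated_error",
    "integration_time_factor",
]


@dataclass(frozen=True)
class PrecisionEstimate:
    """Relative readout error with provenance.

    ``value`` is dimensionless (0.5 means 50% relative error); ``kind`` one
    of theory-two-state, theory-poisson, theory-cycle-MC, monte-carlo,
    empirical, empirical-binary; ``label`` an optional region/bin tag.
    """

    value: float
    kind: str
    window_s: float
    label: str | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window duration must be > 0")
        if self.value < 0:
            raise ValueError("relative error cannot be negative")


def relative_error_two_state(k_on: float, k_off: float, window_s: float) -> PrecisionEstimate:
    """Large-T relative error of a two-state readout.

    tau_i = 1/(k_on + k_off) is the promoter reset time; the factor 2 is the
    prefactor correction to the naive independent-measurement count (it is
    exactly the large-T variance of the time-averaged telegraph indicator,
    Var = 2 P(1-P) tau_i / T).
    """
    if window_s <= 0:
        raise ValueError("window duration must be > 0")
    tau_i = 1.0 / (k_on + k_off)
    p_on = k_on / (k_on + k_off)
    value = np.sqrt(2.0 * tau_i * (1.0 - p_on) / (window_s * p_on))
    return PrecisionEstimate(value=float(value), kind="theory-two-state", window_s=window_s)


def relative_error_poisson(
    tau_block: float,
    window_s: float,
    firing_rate: float | None = None,
    p_on: float | None = None,
) -> PrecisionEstimate:
    """Relative error of the poisson-like readout, sqrt(tau_block (1-P)/T).

    Provide either the bare firing rate (P_on = tau_block * r_eff follows)
    or the occupancy ``p_on`` directly.
    """
    if (firing_rate is None) == (p_on is None):
        raise ValueError("provide exactly one of firing_rate or p_on")
    if p_on is None:
        p_on = PoissonLikeParams(firing_rate=firing_rate, tau_block=tau_block).p_on
    if not 0.0 < p_on <= 1.0:
        raise ValueError("poisson-like P_on must lie in (0, 1]")
    value = np.sqrt(tau_block * (1.0 - p_on) / window_s)
    return PrecisionEstimate(value=float(value), kind="theory-poisson", window_s=window_s)


def relative_error_monte_carlo(
    model: PromoterModel,
    window_s: float,
    n_realizations: int = 2000,
    seed: int = 0,
) -> PrecisionEstimate:
    """SD/mean of the time-averaged ON indicator across realizations.

    The reference estimator for finite windows and for the cycle model
    (kind 'theory-cycle-MC'); for the poisson-like promoter the firing
    process (deterministic tau_block occupancy, exponential gaps) is
    simulated.
    """
    if n_realizations < 100:
        warnings.warn("fewer than 100 realizations; the error estimate is noisy")
    occ = occupancy_time_average(model, window_s, n_realizations, seed)
    mean = occ.mean()
    if mean == 0:
        raise ValueError("no realization ever switched ON; window too short")
    kind = "theory-cycle-MC" if isinstance(model, CycleParams) else "monte-carlo"
    return PrecisionEstimate(
        value=float(occ.std(ddof=1) / mean),
        kind=kind,
        window_s=window_s,
        n=n_realizations,
    )


def empirical_relative_error(
    traces: TraceSet,
    bin_edges: np.ndarray | None = None,
    binary: bool = False,
    min_nuclei: int = 3,
    active_threshold: float = 0.0,
) -> list[PrecisionEstimate]:
    """Per-spatial-bin SD/mean over nuclei of the time-averaged activity.

    ``traces`` should be calibrated (loop units); each nucleus contributes
    its time-averaged intensity over the steady-state window (or, with
    ``binary=True``, the 0/1 indicator of ever exceeding
    ``active_threshold``).  Default bins are 10%-egg-length strips; bins
    with fewer than ``min_nuclei`` nuclei are excluded with a warning.
    """
    ts = traces.steady_state() if traces.steady_window is not None else traces
    pos = ts.meta["ap_position"].to_numpy(dtype=float)
    if np.isnan(pos).all():
        raise ValueError("traces lack AP positions")
    window = ts.times_s[-1] - ts.times_s[0] if ts.n_times > 1 else 1.0
    if binary:
        signal = (ts.values.max(axis=1) > active_threshold).astype(float)
    else:
        signal = ts.values.mean(axis=1)
    if bin_edges is None:
        bin_edges = np.arange(0.0, 1.0001, 0.1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    out: list[PrecisionEstimate] = []
    kind = "empirical-binary" if binary else "empirical"
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        mask = (pos >= lo) & (pos < hi)
        n = int(mask.sum())
        if n == 0:
            continue
        if n < min_nuclei:
            warnings.warn(f"bin [{lo:.2f}, {hi:.2f}) has {n} < {min_nuclei} nuclei; skipped")
            continue
        vals = signal[mask]
        mean = vals.mean()
        value = 0.0 if mean == 0 else float(vals.std(ddof=1) / mean)
        out.append(
            PrecisionEstimate(
                value=value,
                kind=kind,
                window_s=float(window),
                label=f"{(lo + hi) / 2:.2f}",
                n=n,
            )
        )
    return out


def lineage_integrated_error(
    cycle_sets: dict[int, TraceSet],
    bin_edges: np.ndarray | None = None,
    min_nuclei: int = 3,
) -> list[PrecisionEstimate]:
    """Relative error of lineage-integrated mRNA production per spatial bin.

    For each nucleus of the last cell cycle, total production is its own
    integrated intensity plus one half of its mother's and one quarter of
    its grandmother's (mRNA assumed split equally at division).  Nuclei
    with unresolvable lineage links are skipped and counted.
    """
    cycles = sorted(cycle_sets)
    last = cycle_sets[cycles[-1]]

    def integral(ts: TraceSet) -> dict:
        tss = ts.steady_state() if ts.steady_window is not None else ts
        dt = tss.dt_s if tss.n_times > 1 else 1.0
        vals = tss.values.sum(axis=1) * dt
        return dict(zip(tss.meta["nucleus_id"], vals))

    def mothers(ts: TraceSet) -> dict:
        if "mother_id" not in ts.meta.columns:
            return {}
        return dict(zip(ts.meta["nucleus_id"], ts.meta["mother_id"]))

    integrals = {c: integral(cycle_sets[c]) for c in cycles}
    links = {c: mothers(cycle_sets[c]) for c in cycles}
    totals, positions = [], []
    skipped = 0
    pos = dict(zip(last.meta["nucleus_id"], last.meta["ap_position"].to_numpy(float)))
    for nuc in last.meta["nucleus_id"]:
        total = integrals[cycles[-1]][nuc]
        weight = 0.5
        current, ok = nuc, True
        for c_prev in reversed(cycles[:-1]):
            mother = links[cycles[cycles.index(c_prev) + 1]].get(current)
            if mother is None or (isinstance(mother, float) and np.isnan(mother)):
                ok = False
                break
            if mother not in integrals[c_prev]:
                ok = False
                break
            total += weight * integrals[c_prev][mother]
            weight *= 0.5
            current = mother
        if not ok and len(cycles) > 1:
            skipped += 1
            continue
        totals.append(total)
        positions.append(pos[nuc])
    if skipped:
        warnings.warn(f"{skipped} nucleus/nuclei skipped for broken lineage links")
    if bin_edges is None:
        bin_edges = np.arange(0.0, 1.0001, 0.1)
    totals = np.asarray(totals)
    positions = np.asarray(positions)
    window = float(last.times_s[-1] - last.times_s[0]) if last.n_times > 1 else 1.0
    out: list[PrecisionEstimate] = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        mask = (positions >= lo) & (positions < hi)
        n = int(mask.sum())
        if n < min_nuclei:
            continue
        vals = totals[mask]
        mean = vals.mean()
        value = 0.0 if mean == 0 else float(vals.std(ddof=1) / mean)
        out.append(
            PrecisionEstimate(
                value=value,
                kind="empirical-lineage",
                window_s=window,
                label=f"{(lo + hi) / 2:.2f}",
                n=n,
            )
        )
    return out


def integration_time_factor(current_error: float, target_error: float) -> float:
    """How much longer to integrate for a target precision.

    Errors fall as T^(-1/2), so the factor is (current/target)^2 — e.g. 25x
    to go from 50% to 10%.  Factors <= 1 mean the target is already met.
    """
    if current_error <= 0 or target_error <= 0:
        raise ValueError("errors must be > 0")
    return (current_error / target_error) ** 2
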