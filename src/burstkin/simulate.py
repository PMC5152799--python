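"""Stochastic simulation of promoter switching and fluorescent reporter traces.

The ON/OFF indicator of every promoter model is an alternating renewal
process: exponential ON dwells (rate ``k_off``) and model-specific OFF dwells
(exponential, hypoexponential for the cycle, or Gamma).  Paths are simulated
exactly in continuous time by drawing dwell sequences (the Gillespie scheme
specialized to a chain) and the fluorescence is evaluated directly at the
observation times through the delayed-readout formula

    F(t) = sum_{i=1..r} L_i X(t - i * step_time),

so sampled traces are exactly stationary and agree with the analytic
autocorrelation at every sampling interval, commensurate with the polymerase
step or not.  The poisson-like promoter follows the uncorrelated-step
convention: each polymerase blocking step is occupied independently with
probability P_on.

Every trace draws from an independent child of one master seed, so trace sets
are reproducible and individual traces can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .construct import GeneConstruct, LoopFunction, PromoterStateTrace, build_loop_function
from .models import (
    GammaParams,
    CycleParams,
    PoissonLikeParams,
    PromoterModel,
    TwoStateParams,
    mean_cycle_duration,
    stationary_on_probability,
)
from .traces import TraceSet

__all__ = [
    "SimulationSpec",
    "SwitchingPath",
    "simulate_promoter_trace",
    "simulate_switching_path",
    "simulate_trace_set",
    "simulate_two_color",
    "occupancy_time_average",
]


@dataclass(frozen=True)
class SimulationSpec:
    """One- or two-construct trace-set simulation settings.

    ``duration_s`` is the observed window T; ``dt_s`` the sampling interval
    (it need not equal the polymerase step time); ``noise_sd`` optional
    additive white observation noise (loop units, before the ``i0``
    intensity scale is applied).
    """

    model: PromoterModel
    construct: GeneConstruct
    n_traces: int
    duration_s: float
    dt_s: float
    seed: int
    i0: float = 1.0
    noise_sd: float = 0.0
    second_construct: GeneConstruct | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.dt_s <= 0 or self.n_traces < 1:
            raise ValueError("need duration_s > 0, dt_s > 0, n_traces >= 1")


@dataclass(frozen=True)
class SwitchingPath:
    """Piecewise-constant binary path: initial state and sorted jump times."""

    x0: int
    jump_times: np.ndarray
    t_end: float

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """X(t) for arbitrary (possibly unsorted) times within the path."""
        n_jumps = np.searchsorted(self.jump_times, np.asarray(t, float), side="right")
        return (self.x0 + n_jumps) % 2


def _draw_off_dwells(model: PromoterModel, rng: np.random.Generator, n: int) -> np.ndarray:
    if isinstance(model, TwoStateParams):
        return rng.exponential(1.0 / model.k_on, size=n)
    if isinstance(model, CycleParams):
        total = np.zeros(n)
        for k in model.off_rates:
            total += rng.exponential(1.0 / k, size=n)
        return total
    if isinstance(model, GammaParams):
        return rng.gamma(model.alpha, 1.0 / model.beta, size=n)
    raise TypeError(f"no OFF-dwell sampler for {type(model).__name__}")


def _draw_on_dwells(model: PromoterModel, rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.exponential(1.0 / model.k_off, size=n)


def simulate_switching_path(
    model: PromoterModel,
    duration_s: float,
    rng: np.random.Generator,
    equilibrate: bool = True,
) -> SwitchingPath:
    """Exact continuous-time path of the ON/OFF indicator on [0, duration_s].

    Poisson-like promoters return a path that is piecewise constant on the
    blocking-step grid with iid Bernoulli(P_on) occupancies.  For the other
    families the chain starts in a stationarily chosen state and, for the
    non-Markovian OFF dwells (cycle/gamma), a burn-in of several mean cycles
    is prepended so the observed window is stationary.
    """
    p_on = stationary_on_probability(model)
    if isinstance(model, PoissonLikeParams):
        tb = model.tau_block
        n_steps = int(np.ceil(duration_s / tb)) + 1
        occ = rng.random(n_steps) < p_on
        flips = np.flatnonzero(np.diff(occ.astype(np.int8)) != 0)
        return SwitchingPath(
            x0=int(occ[0]), jump_times=(flips + 1) * tb, t_end=duration_s
        )

    burn = 6.0 * mean_cycle_duration(model) if equilibrate else 0.0
    total = duration_s + burn
    x0 = int(rng.random() < p_on)
    mu = mean_cycle_duration(model)
    n_pairs = int(total / mu * 2 + 20)
    segments: list[np.ndarray] = []
    covered = 0.0
    state = x0
    while covered < total:
        on = _draw_on_dwells(model, rng, n_pairs)
        off = _draw_off_dwells(model, rng, n_pairs)
        dw = np.empty(2 * n_pairs)
        if state == 1:
            dw[0::2], dw[1::2] = on, off
        else:
            dw[0::2], dw[1::2] = off, on
        segments.append(dw)
        covered += dw.sum()
    dwells = np.concatenate(segments)
    jumps = np.cumsum(dwells)
    jumps = jumps[jumps < total] - burn
    # burn-in shift: state at time -burn was x0; parity of jumps before 0
    n_before = int(np.searchsorted(jumps, 0.0, side="right"))
    x_at_0 = (x0 + n_before) % 2
    return SwitchingPath(x0=int(x_at_0), jump_times=jumps[n_before:], t_end=duration_s)


def simulate_promoter_trace(
    model: PromoterModel, duration_steps: int, seed: int, step_time_s: float = 6.0
) -> PromoterStateTrace:
    """Binary promoter trace on the polymerase-step grid (state at step start)."""
    if duration_steps < 1:
        raise ValueError("duration must be at least one step")
    rng = np.random.default_rng(seed)
    path = simulate_switching_path(model, duration_steps * step_time_s, rng)
    t = np.arange(duration_steps) * step_time_s
    return PromoterStateTrace(states=path.state_at(t), step_time_s=step_time_s)


def _fluorescence_on_grid(
    path: SwitchingPath, loop_fn: LoopFunction, t_obs: np.ndarray, step_time_s: float
) -> np.ndarray:
    delays = np.arange(1, len(loop_fn) + 1) * step_time_s
    eval_t = t_obs[:, None] - delays[None, :]
    x = path.state_at(eval_t.ravel()).reshape(eval_t.shape)
    return x @ loop_fn.values


def simulate_trace_set(spec: SimulationSpec) -> TraceSet:
    """Simulate ``n_traces`` stationary fluorescence traces sampled at dt.

    The switching path is extended ``r`` polymerase steps before the first
    observation so the gene is fully loaded ("warm-up"): every returned
    sample is steady state, and the steady-state window spans the whole
    trace.  Intensities are ``i0 *`` loop units plus optional white noise.
    """
    loop_fn = build_loop_function(spec.construct)
    step = spec.construct.step_time_s
    lead = len(loop_fn) * step
    n_samples = int(np.floor(spec.duration_s / spec.dt_s)) + 1
    t_obs = np.arange(n_samples) * spec.dt_s
    rng = np.random.default_rng(spec.seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=spec.n_traces)
    values = np.empty((spec.n_traces, n_samples))
    for m, s in enumerate(child_seeds):
        r_m = np.random.default_rng(s)
        path = simulate_switching_path(model=spec.model, duration_s=spec.duration_s + lead, rng=r_m)
        values[m] = _fluorescence_on_grid(path, loop_fn, t_obs + lead, step)
        if spec.noise_sd > 0:
            values[m] += r_m.normal(0.0, spec.noise_sd, size=n_samples)
    values *= spec.i0
    return TraceSet.from_matrix(
        times_s=t_obs,
        values=values,
        steady_window=(0.0, float(t_obs[-1])),
    )


def simulate_two_color(spec: SimulationSpec) -> tuple[TraceSet, TraceSet]:
    """Two aligned trace sets driven by one promoter realization per nucleus.

    ``spec.second_construct`` describes the second color's cassette; both
    channels read the same switching path X(t), so their cross-correlation
    reflects the relative cassette positions (a 5' cassette's signal leads a
    3' cassette's).
    """
    if spec.second_construct is None:
        raise ValueError("two-color simulation needs spec.second_construct")
    if spec.second_construct.step_time_s != spec.construct.step_time_s:
        raise ValueError("both constructs must share the polymerase step time")
    loops = (build_loop_function(spec.construct), build_loop_function(spec.second_construct))
    step = spec.construct.step_time_s
    lead = max(len(lf) for lf in loops) * step
    n_samples = int(np.floor(spec.duration_s / spec.dt_s)) + 1
    t_obs = np.arange(n_samples) * spec.dt_s
    rng = np.random.default_rng(spec.seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=spec.n_traces)
    values = [np.empty((spec.n_traces, n_samples)) for _ in loops]
    for m, s in enumerate(child_seeds):
        r_m = np.random.default_rng(s)
        path = simulate_switching_path(spec.model, spec.duration_s + lead, r_m)
        for ch, lf in enumerate(loops):
            values[ch][m] = _fluorescence_on_grid(path, lf, t_obs + lead, step)
            if spec.noise_sd > 0:
                values[ch][m] += r_m.normal(0.0, spec.noise_sd, size=n_samples)
    window = (0.0, float(t_obs[-1]))
    return tuple(
        TraceSet.from_matrix(times_s=t_obs, values=spec.i0 * v, steady_window=window)
        for v in values
    )


def occupancy_time_average(
    model: PromoterModel,
    duration_s: float,
    n_realizations: int,
    seed: int | np.random.Generator,
    poisson_as_renewal: bool = True,
) -> np.ndarray:
    """Time-averaged ON occupancy over a window of length T, per realization.

    Vectorized over realizations; used by the precision estimators.  For the
    poisson-like promoter the default is the firing-process view
    (deterministic tau_block occupancy separated by Exp(firing_rate) gaps),
    whose integrated occupancy counts initiation events; with
    ``poisson_as_renewal=False`` the uncorrelated-step trace convention is
    used instead.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M = int(n_realizations)
    if isinstance(model, PoissonLikeParams) and not poisson_as_renewal:
        tb = model.tau_block
        n_steps = int(np.ceil(duration_s / tb))
        frac = duration_s / tb - (n_steps - 1)  # last, partial step weight
        occ = (rng.random((M, n_steps)) < model.p_on).astype(float)
        w = np.ones(n_steps)
        w[-1] = frac
        return (occ @ w) * tb / duration_s

    burn = 6.0 * mean_cycle_duration(model)
    total = burn + duration_s
    mu = mean_cycle_duration(model)
    n_pairs = int(total / mu * 3 + 30)
    p_on = stationary_on_probability(model)

    if isinstance(model, PoissonLikeParams):
        on = np.full((M, n_pairs), model.tau_block)
        off = rng.exponential(1.0 / model.firing_rate, size=(M, n_pairs))
        x0 = np.ones(M, dtype=int)
    else:
        on = rng.exponential(1.0 / model.k_off, size=(M, n_pairs))
        if isinstance(model, TwoStateParams):
            off = rng.exponential(1.0 / model.k_on, size=(M, n_pairs))
        elif isinstance(model, CycleParams):
            off = np.zeros((M, n_pairs))
            for k in model.off_rates:
                off += rng.exponential(1.0 / k, size=(M, n_pairs))
        elif isinstance(model, GammaParams):
            off = rng.gamma(model.alpha, 1.0 / model.beta, size=(M, n_pairs))
        else:
            raise TypeError(f"unknown promoter model {type(model).__name__}")
        x0 = (rng.random(M) < p_on).astype(int)

    dwells = np.empty((M, 2 * n_pairs))
    first_on = x0 == 1
    dwells[first_on, 0::2], dwells[first_on, 1::2] = on[first_on], off[first_on]
    dwells[~first_on, 0::2], dwells[~first_on, 1::2] = off[~first_on], on[~first_on]
    edges = np.cumsum(dwells, axis=1)
    if edges[:, -1].min() < total:  # pragma: no cover - margin is generous
        raise RuntimeError("dwell buffer too short; increase n_pairs margin")
    # clip every dwell interval to the observation window [burn, total]
    starts = np.concatenate([np.zeros((M, 1)), edges[:, :-1]], axis=1)
    lo = np.clip(starts, burn, total)
    hi = np.clip(edges, burn, total)
    seg = hi - lo
    on_mask = np.zeros_like(seg)
    on_mask[first_on, 0::2] = 1.0
    on_mask[~first_on, 1::2] = 1.0
    return (seg * on_mask).sum(axis=1) / duration_s
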