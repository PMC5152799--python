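"""Synthetic embryo-like datasets and Ornstein-Uhlenbeck validation traces.

``generate_embryo_dataset`` emulates the structure of live-imaging data from
early fly embryos: several embryos recorded at different sampling intervals,
cell cycles 11-13 of increasing duration, nuclei doubling between cycles
with lineage links, and an anterior-posterior activation profile in which
the ON-switching rate follows an exponentially decaying activator gradient
(length scale 100 um on a 500 um embryo), giving a ~5-fold drop in the mean
k_on between the anterior and boundary regions.  Traces ramp up after
mitosis, sit at steady state mid-interphase, and shut down before the next
division, so the steady-state window selection has something to find.

``generate_ou_traces`` produces short Ornstein-Uhlenbeck traces
(dx = -lambda x dt + gamma dW) whose exactly known exponential
autocorrelation validates the finite-trace correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .construct import GeneConstruct, build_loop_function
from .models import TwoStateParams
from .simulate import simulate_switching_path
from .traces import TraceSet

__all__ = ["EmbryoSpec", "generate_embryo_dataset", "generate_ou_traces"]

#: default interphase durations per cell cycle (s)
DEFAULT_CYCLE_DURATIONS = {11: 360.0, 12: 540.0, 13: 780.0}
#: default sampling intervals of the four recorded embryos (s)
DEFAULT_EMBRYO_DTS = (13.1, 10.2, 5.1, 4.3)


@dataclass(frozen=True)
class EmbryoSpec:
    """Parameters of the embryo-like dataset generator.

    ``anterior_k_on`` is the ON rate at the reference anterior position
    ``x_ref``; elsewhere k_on(x) = anterior_k_on * exp(-(x - x_ref) *
    embryo_length_um / gradient_length_um), mirroring an exponentially
    decaying activator gradient.  ``n_nuclei_final`` nuclei per region in
    the last cycle halve in each earlier cycle, with lineage links.
    """

    n_embryos: int = 4
    embryo_dts_s: tuple[float, ...] = DEFAULT_EMBRYO_DTS
    cycles: tuple[int, ...] = (11, 12, 13)
    cycle_durations_s: dict = field(default_factory=lambda: dict(DEFAULT_CYCLE_DURATIONS))
    n_nuclei_final: int = 48
    anterior_k_on: float = 0.015
    k_off: float = 0.015
    x_ref: float = 0.175
    gradient_length_um: float = 100.0
    embryo_length_um: float = 500.0
    construct: GeneConstruct = field(
        default_factory=lambda: GeneConstruct(
            pre_cassette_steps=12, cassette_steps=12, post_cassette_steps=0
        )
    )
    i0: float = 1.0
    noise_sd: float = 0.0
    shutdown_s: float = 60.0
    seed: int = 0

    def k_on_at(self, x: np.ndarray | float) -> np.ndarray:
        """Position-dependent ON rate from the activator gradient."""
        x = np.asarray(x, dtype=float)
        return self.anterior_k_on * np.exp(
            -(x - self.x_ref) * self.embryo_length_um / self.gradient_length_um
        )


def _positions(spec: EmbryoSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Half the nuclei in the anterior strip, half across the boundary."""
    ant = rng.uniform(0.05, 0.35, size=n - n // 2)
    bnd = rng.uniform(0.45, 0.55, size=n // 2)
    return np.concatenate([ant, bnd])


def generate_embryo_dataset(spec: EmbryoSpec) -> list[TraceSet]:
    """Simulate the full multi-embryo, multi-cycle dataset with lineage.

    Returns one TraceSet per (embryo, cycle).  Nucleus ids encode the
    lineage: nucleus ``i`` of cycle ``c`` is the mother of nuclei ``2i`` and
    ``2i + 1`` of cycle ``c + 1``; both daughters inherit a small jitter
    around the mother's AP position.  Each trace shows activation (the gene
    fills with polymerases), a steady-state plateau and a forced shutdown
    ``shutdown_s`` before mitosis; the plateau window is marked on the set.
    """
    rng = np.random.default_rng(spec.seed)
    loop_fn = build_loop_function(spec.construct)
    step = spec.construct.step_time_s
    lead = len(loop_fn) * step
    cycles = list(spec.cycles)
    sets: list[TraceSet] = []
    for e in range(spec.n_embryos):
        dt = spec.embryo_dts_s[e % len(spec.embryo_dts_s)]
        n_last = spec.n_nuclei_final
        # positions of the last cycle's nuclei; earlier cycles use mothers
        n_per_cycle = {c: max(2, n_last // 2 ** (len(cycles) - 1 - i)) for i, c in enumerate(cycles)}
        pos = {cycles[0]: _positions(spec, n_per_cycle[cycles[0]], rng)}
        for prev, cur in zip(cycles[:-1], cycles[1:]):
            mothers = np.repeat(np.arange(n_per_cycle[prev]), 2)[: n_per_cycle[cur]]
            jitter = rng.normal(0.0, 0.005, size=n_per_cycle[cur])
            pos[cur] = np.clip(pos[prev][mothers] + jitter, 0.0, 1.0)
        for ci, c in enumerate(cycles):
            duration = spec.cycle_durations_s[c]
            n = n_per_cycle[c]
            t_obs = np.arange(0.0, duration + 1e-9, dt)
            values = np.empty((n, t_obs.size))
            k_on = spec.k_on_at(pos[c])
            active = duration - spec.shutdown_s
            delays = np.arange(1, len(loop_fn) + 1) * step
            for m in range(n):
                model = TwoStateParams(k_on=float(k_on[m]), k_off=spec.k_off)
                sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
                path = simulate_switching_path(model, active, sub)
                # the promoter is silent outside the interphase: the gene is
                # empty at mitosis exit (signal ramps up over the buffering
                # time) and initiation stops shutdown_s before division
                # (signal decays as the last polymerases run off)
                eval_t = t_obs[:, None] - delays[None, :]
                x = path.state_at(np.clip(eval_t, 0.0, None).ravel()).reshape(eval_t.shape)
                x = np.where((eval_t < 0.0) | (eval_t > active), 0, x)
                f = x @ loop_fn.values
                if spec.noise_sd > 0:
                    f = f + sub.normal(0.0, spec.noise_sd, size=f.size)
                values[m] = f * spec.i0
            mothers = (
                pd.array([pd.NA] * n)
                if ci == 0
                else pd.array(np.repeat(np.arange(n_per_cycle[cycles[ci - 1]]), 2)[:n])
            )
            meta = pd.DataFrame(
                {
                    "embryo_id": f"embryo{e + 1}",
                    "cycle": c,
                    "nucleus_id": np.arange(n),
                    "ap_position": pos[c],
                    "mother_id": mothers,
                }
            )
            window = (lead * 1.2, active)
            sets.append(
                TraceSet(times_s=t_obs, values=values, meta=meta, steady_window=window)
            )
    return sets


def generate_ou_traces(
    lam: float,
    gamma: float,
    duration_s: float,
    n_traces: int,
    seed: int,
    dt_s: float = 0.05,
    substeps: int = 10,
) -> TraceSet:
    """Euler-Maruyama traces of dx = -lambda x dt + gamma dW.

    Sampled every ``dt_s`` with ``substeps`` integration steps per sample;
    started from the stationary distribution N(0, gamma^2 / (2 lambda)).
    A warning is raised if the integration step is too coarse
    (lambda * dt > 0.1) for the linear scheme to be faithful.
    """
    import warnings

    if lam <= 0 or gamma <= 0:
        raise ValueError("lambda and gamma must be > 0")
    h = dt_s / substeps
    if lam * h > 0.1:
        warnings.warn(
            f"integration step {h:.3g}s is coarse for lambda={lam} (lambda*h > 0.1); "
            "increase substeps"
        )
    rng = np.random.default_rng(seed)
    n_samples = int(np.floor(duration_s / dt_s)) + 1
    sigma_st = gamma / np.sqrt(2.0 * lam)
    x = rng.normal(0.0, sigma_st, size=n_traces)
    values = np.empty((n_traces, n_samples))
    values[:, 0] = x
    sq = gamma * np.sqrt(h)
    for k in range(1, n_samples):
        for _ in range(substeps):
            x = x - lam * x * h + sq * rng.standard_normal(n_traces)
        values[:, k] = x
    times = np.arange(n_samples) * dt_s
    return TraceSet.from_matrix(times_s=times, values=values, embryo_id="ou")
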