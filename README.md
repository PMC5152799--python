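# burstkin

Transcriptional bursting kinetics from short live-imaging time traces.

In early fly embryos, nascent transcription at a single locus can be watched
in every nucleus with the MS2-MCP system: stem-loops in the nascent RNA bind
a fluorescent coat protein, so the spot intensity tracks how many polymerases
are elongating through the reporter. Two things make these traces hard to
interpret. First, the probe itself *buffers* the signal: a polymerase stays
fluorescent for the time it needs to transcribe the loop-carrying sequence
(τ_buff = 72 s for a 24-loop 3' cassette at 6 s per 150-bp step), hiding fast
promoter switching. Second, interphases of cell cycles 11–13 last only
minutes, and the connected autocorrelation of such short traces is biased:
subtracting a trace's own empirical mean forces the curve's area to zero and
digs a spurious negative valley.

burstkin implements the full analysis that deals with both problems:

* a deterministic probe model — the loop function `L_i` and the signal
  `F(t) = Σ_i L_i X(t − i)` — for arbitrary cassette placements, including
  two-color cross-correlations;
* four promoter-switching models (memoryless "poisson-like", two-state
  telegraph, irreversible multi-OFF-state cycle, and Gamma-distributed OFF
  dwells) with stationary occupancies `P_on`, ON→ON propagators `A(t)` and
  signal autocovariances
  `C(τ) = Σ_{i,j} L_i L_j P_on (A(|τ + i − j|) − P_on)`;
* the exact finite-trace correction that maps an infinite-trace model curve
  to the expectation of the short-trace empirical estimator;
* a three-step inference (intensity calibration → `P_on` → rate-scale fit by
  pair-count-weighted least squares on the corrected curve) with
  subset-resampling error bars and two-vs-three-state discrimination;
* readout-precision estimators: `δmRNA/⟨mRNA⟩ = sqrt(2 τ_i (1 − P_on) /
  (T P_on))` for the telegraph (τ_i = 1/(k_on + k_off)),
  `sqrt(τ_block (1 − P_on)/T)` for the poisson-like promoter, Monte-Carlo for
  finite windows and promoter cycles, plus empirical per-AP-bin and
  lineage-integrated estimators;
* exact stochastic simulation of all of the above and a generator of
  embryo-like datasets (cycles 11–13, lineage, gradient-driven `k_on(x)`),
  so every stage is testable without microscope data.

## A worked example

```python
import burstkin as bk

construct = bk.GeneConstruct(pre_cassette_steps=12, cassette_steps=12,
                             post_cassette_steps=0)   # 24-loop 3' cassette
truth = bk.TwoStateParams(k_on=0.004, k_off=0.036)    # P_on = 0.1
spec = bk.SimulationSpec(model=truth, construct=construct, n_traces=200,
                         duration_s=600.0, dt_s=6.0, seed=7, i0=3.2)
traces = bk.simulate_trace_set(spec)
result = bk.run_inference(traces, "two_state", construct, seed=0)
print(result.i0, result.p_on, result.k_sum, result.rate_sd["k_sum"])
```

prints (run it: `python examples/04_infer_switching_rates.py`)

```
calibration I0:  1.952 intensity units per loop (truth 3.2)
estimated P_on:  0.162 (truth 0.100)
fitted k_sum:    0.0379 +/- 0.0031 /s (truth 0.0400)
```

The max-based calibration overestimates `P_on` at low occupancy (the gene
rarely saturates in a 600-s window), but the fitted switching timescale is
immune: the *shape* of the normalized two-state autocorrelation depends on
`k_on + k_off` alone, and it is recovered within one resampling SD.

Each script in `examples/` demonstrates one capability (probe geometry,
theory-vs-simulation agreement, the finite-trace valley, inference,
precision, embryo-scale datasets) and prints a few annotated numbers.

A thin CLI mirrors the library for shell workflows:

```
burstkin simulate-embryo --seed 4 --out runs/embryo
burstkin infer --traces runs/embryo/traces.csv --cycle 13 --region anterior \
    --model two_state --seed 1 --out runs/fit
```

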