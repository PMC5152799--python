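"""Three-step inference of bursting kinetics from raw intensity traces.

Simulated boundary-like data: P_on = 0.1, k_on + k_off = 0.04 /s, 200 nuclei
imaged for 600 s, with an unknown intensity scale of 3.2 camera units per
MS2 loop.  The pipeline (1) calibrates the intensity per loop from the mean
of per-trace maxima, (2) reads P_on off the calibrated mean, and (3) fits
the remaining rate scale to the finite-trace-corrected autocorrelation,
with subset-resampling error bars.
"""

import burstkin as bk

construct = bk.GeneConstruct(pre_cassette_steps=12, cassette_steps=12, post_cassette_steps=0)
truth = bk.TwoStateParams(k_on=0.004, k_off=0.036)

spec = bk.SimulationSpec(
    model=truth, construct=construct, n_traces=200, duration_s=600.0, dt_s=6.0,
    seed=7, i0=3.2,
)
traces = bk.simulate_trace_set(spec)

result = bk.run_inference(traces, "two_state", construct, seed=0)

print(f"calibration I0:  {result.i0:.3f} intensity units per loop (truth 3.2)")
print(f"estimated P_on:  {result.p_on:.3f} (truth 0.100)")
print(f"fitted k_sum:    {result.k_sum:.4f} +/- {result.rate_sd['k_sum']:.4f} /s (truth 0.0400)")
print(f"  k_on  = {result.rates['k_on']:.4f} /s  (truth 0.0040)")
print(f"  k_off = {result.rates['k_off']:.4f} /s  (truth 0.0360)")

# P_on fixes only the ratio k_on/k_off; the autocorrelation fit supplies the
# overall timescale.  Note that the max-based calibration overestimates
# P_on at low occupancy (the gene rarely saturates), but the fitted k_sum is
# immune: the normalized two-state curve shape depends on k_sum alone.
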