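"""Simulate bursty transcription and compare the empirical autocorrelation
with the finite-trace-corrected analytic curve.

A two-state (telegraph) promoter with k_on = 0.005 /s and k_off = 0.01 /s is
imaged for 360 s at 6-s sampling in 2000 nuclei.  Because each trace is only
~6 promoter correlation times long, the naive connected autocorrelation is
biased (its area is forced to zero); the corrected model curve accounts for
that exactly.
"""

import numpy as np

import burstkin as bk

construct = bk.GeneConstruct(pre_cassette_steps=12, cassette_steps=12, post_cassette_steps=0)
model = bk.TwoStateParams(k_on=0.005, k_off=0.01)

spec = bk.SimulationSpec(
    model=model, construct=construct, n_traces=2000, duration_s=360.0, dt_s=6.0, seed=1
)
traces = bk.simulate_trace_set(spec)

empirical = bk.empirical_connected_autocorrelation(traces)
K = traces.n_times
loops = bk.build_loop_function(construct)
corrected = bk.corrected_model_curve(model, loops, traces.dt_s, K)
infinite = bk.theoretical_autocorrelation(
    model, loops, np.arange(K) * traces.dt_s
).values

print(" lag(s)  empirical  corrected  infinite-trace")
for r in range(1, 16, 2):
    print(
        f"{empirical.lag_s[r]:7.0f}  {empirical.values[r]:9.3f}"
        f"  {corrected[r]:9.3f}  {infinite[r]:9.3f}"
    )
z = np.abs((empirical.values[1 : K // 2] - corrected[1 : K // 2]) / empirical.se[1 : K // 2])
print(f"\nmax |z| over lags <= K/2: {z.max():.2f} (corrected theory vs data, in SE units)")
print("note how the corrected curve dips negative while the infinite-trace one does not:")
print(f"  min corrected = {corrected.min():.3f}, min infinite = {infinite.min():.3f}")
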