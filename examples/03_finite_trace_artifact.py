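"""The finite-trace artifact: short observation windows dig a spurious
negative valley into the connected autocorrelation.

Same fast-switching promoter (k_on = k_off = 0.06 /s), sampled every 4 s,
observed either for 60 s or for 300 s.  Subtracting the empirical mean of a
short trace correlates the mean with every sample, so the curve must
integrate to zero — the shorter the window, the deeper the valley.  The
correction predicts both curves from the same infinite-trace theory.
"""

import numpy as np

import burstkin as bk

construct = bk.GeneConstruct(pre_cassette_steps=12, cassette_steps=12, post_cassette_steps=0)
loops = bk.build_loop_function(construct)
model = bk.TwoStateParams(k_on=0.06, k_off=0.06)

for T, M in [(60.0, 10000), (300.0, 2000)]:
    spec = bk.SimulationSpec(
        model=model, construct=construct, n_traces=M, duration_s=T, dt_s=4.0, seed=21
    )
    traces = bk.simulate_trace_set(spec)
    emp = bk.empirical_connected_autocorrelation(traces)
    theo = bk.corrected_model_curve(model, loops, 4.0, traces.n_times)
    print(
        f"T = {T:5.0f} s ({M} nuclei): empirical valley {emp.values[1:].min():6.3f}, "
        f"corrected-theory valley {theo.min():6.3f}"
    )

print("\nthe valley is an artifact of trace length, not of the kinetics:")
print("60-s windows produce a deep dip that 300-s windows nearly lack,")
print("and the corrected theory reproduces both from identical rate constants.")
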