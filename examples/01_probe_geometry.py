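"""Probe geometry: the loop function and buffering time of an MS2 construct.

The reporter used throughout these examples carries a 24-loop MS2 cassette
at the 3' end of the transcribed sequence.  The loop function L_i counts how
many fluorescent loops a polymerase at site i (one site = one 150-bp
polymerase footprint, traversed in 6 s) has produced.
"""

import burstkin as bk

construct = bk.GeneConstruct(pre_cassette_steps=12, cassette_steps=12, post_cassette_steps=0)
loops = bk.build_loop_function(construct)

print("sites (r):            ", len(loops))
print("loop function L_i:    ", loops.values)
print("saturation sum_i L_i: ", loops.total)
print("buffering time (s):   ", bk.buffering_time(construct))
print("mean signal at P_on=0.5:", bk.mean_fluorescence(0.5, loops))

# The buffering time (72 s here) is how long a single polymerase keeps the
# locus fluorescent after initiation: it sets the probe's intrinsic
# correlation time and hides promoter switching faster than itself.  The
# mean signal is simply P_on times the saturation level, which is how the
# occupancy is read off calibrated data.
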