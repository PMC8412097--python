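"""Compare cardiogenic-artifact removal methods on the same test signal.

Each method is scored by the residual QRS fraction: the RMS of what remains
of the artifact inside the QRS windows, relative to the artifact before
removal, averaged over beats (ground-truth EMG component from the
generator).  Smaller is better; 1.0 means nothing was removed.
"""

import respfatigue as rf
from respfatigue.pipeline import make_bench

bench = make_bench(seed=3, etas=(0.05,), duration=60.0)
ats = bench.ats[(60, 0.05)]
ann = bench.ann_true
emg = bench.emg_mod[(60, 0.05)]

print("method   residual QRS fraction")
for method in ("NONE", "HP15", "TS15", "TSW15", "TSWD15", "DSO"):
    clean, _ = rf.run_removal(ats, ann, method=method)
    # compare against the high-pass-filtered EMG component where the method
    # includes a post filter, so both signals saw the same linear stage
    ref = rf.highpass(emg, 15) if method.endswith("15") else emg
    frac = rf.residual_qrs_fraction(ats, clean, ann, emg_component=ref)
    print(f"{method:7s}  {frac:.3f}")
# Template subtraction removes most of the repetitive artifact; the damping
# step (TSWD) attacks what irregular beat shapes leave behind.
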