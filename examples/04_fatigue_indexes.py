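"""Compute the three fatigue indexes on a fatiguing (60 % MVC) record.

The surrogate sEMG compresses its spectrum over the minute (mean frequency
130 -> 85 Hz), emulating the spectral signature of muscle fatigue.  MNF
falls with fatigue, SMR5 rises steeply, and fApEn falls as the waveform
becomes more regular.
"""

import numpy as np

import respfatigue as rf
from respfatigue.fatigue import EpochSpec
from respfatigue.pipeline import make_bench

bench = make_bench(seed=4, etas=(0.05,), duration=60.0)
rsm = bench.rsm[60]  # uncontaminated, breathing-modulated reference signal

for fd, psd in (("MNF", "welch"), ("SMR5", "burg"), ("fApEn", None)):
    series = rf.compute_fatigue_series(
        rsm, None, fd=fd, spec=EpochSpec(ne=256), psd_method=psd or "burg", bl=35.0
    )
    m = np.isfinite(series.values)
    first = np.mean(series.values[m][:40])  # ~first 5 s of values
    last = np.mean(series.values[m][-40:])  # ~last 5 s
    print(f"{fd:6s} start {first:12.5g}   end {last:12.5g}   ratio {last / first:6.3f}")
# MNF and fApEn drop over the minute while SMR5 grows severalfold: all three
# indexes see the programmed fatigue, each on its own scale - which is why
# series are normalized against the reference trend before evaluation.
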