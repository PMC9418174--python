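"""Robust T2 from a multi-echo decay with a corrupted first echo + outlier.

The generator biases echo 1 by 15% (the artifact that motivates always
excluding it) and we corrupt one later echo 10x (a motion-corrupted frame).
The Huber-weighted fit shrugs both off; an ordinary least-squares fit of the
same data does not.
"""

import numpy as np

from mrimon.relaxometry import fit_t2_monoexp, stability_report
from mrimon.series import DECAY
from mrimon.synth import SignalGenConfig, generate_decay_series
from mrimon.synth.signals import DEFAULT_ECHO_SCHEDULE

config = SignalGenConfig(
    model_kind=DECAY,
    true_params={"m0": 1000.0, "t2": 16.0, "c": 30.0, "first_echo_factor": 0.85},
    schedule=DEFAULT_ECHO_SCHEDULE,     # 14 echoes, TE = 6 ... 84 ms
    noise_sigma=10.0,
    magnitude_mode=True,
    seed=7,
)
series = generate_decay_series(config)
series.signals[5] *= 10.0               # gross outlier at echo 6

robust = fit_t2_monoexp(series, robust=True)
ols = fit_t2_monoexp(series, robust=False)
print(f"true T2          : 16.0 ms")
print(f"robust fit T2    : {robust.t2:6.2f} ms  (M0 {robust.m0:7.1f}, c {robust.c:5.1f})")
print(f"unit-weight T2   : {ols.t2:6.2f} ms   <- dragged by the outlier")
print(f"echoes used      : {robust.n_points_used} of {series.times.size} (echo 1 always excluded)")

# Longitudinal stability of an internal reference tissue across 4 visits:
rep = stability_report({2.0: 15.8, 4.0: 16.3, 6.0: 16.0, 8.0: 15.9},
                       animal="m_con_01", tissue="paravertebral_muscle")
dev = ", ".join(f"{d:+.1f}%" for d in rep.percent_deviation)
print(f"muscle T2 drift  : {dev}  (CoV {rep.cov_percent:.2f}%)")
# Per-visit deviations around the animal mean within ~2% indicate the
# measurement, not the tissue, is stable across sessions.
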