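"""Fit Look-Locker inversion-recovery T1 from a noisy magnitude series.

Generates one vertebral-marrow-like recovery curve (true T1 = 700 ms, ideal
inversion b = 2a, SNR 50, Rician magnitude noise), restores polarity and
fits S(TI) = a − b·exp(−TI/T1*), then applies T1 = T1*·(b/a − 1).
"""

from mrimon.relaxometry import fit_t1_look_locker
from mrimon.series import IR
from mrimon.synth import SignalGenConfig, generate_ir_series
from mrimon.synth.signals import DEFAULT_IR_SCHEDULE

a = 1000.0
config = SignalGenConfig(
    model_kind=IR,
    true_params={"a": a, "b": 2 * a, "t1_star": 700.0},
    schedule=DEFAULT_IR_SCHEDULE,
    noise_sigma=a / 50.0,       # SNR 50
    magnitude_mode=True,
    seed=42,
)
series = generate_ir_series(config)
result = fit_t1_look_locker(series)

print(f"true T1        : 700.0 ms (b = 2a, so T1* = T1)")
print(f"fitted a, b    : {result.a:8.1f}, {result.b:8.1f}  (signal units)")
print(f"fitted T1*     : {result.t1_star:8.1f} ms  (apparent, Look-Locker)")
print(f"corrected T1   : {result.t1:8.1f} ms  = T1* x (b/a - 1)")
print(f"polarity flips : {result.polarity_flip_index} early samples restored to negative")
print(f"converged      : {result.converged}, residual rms {result.residual_rms:.1f}")
# The corrected T1 should sit within ~2% of 700 ms at this noise level; the
# flip count shows how many rectified pre-null samples the fitter un-rectified.
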