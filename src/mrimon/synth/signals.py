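"""Relaxation-signal generators under Gaussian or Rician (magnitude) noise.

Inversion-recovery series follow the Look-Locker readout model

    S(TI) = a − b · exp(−TI / T1*)

and echo decays follow the mono-exponential model with noise offset

    S(TE) = M0 · exp(−TE / T2) + c.

Magnitude-mode noise is Rician: the noiseless value is treated as the real
part of a complex signal, independent Gaussian components of standard
deviation ``noise_sigma`` are added to the real and imaginary parts, and the
magnitude is taken.  This is the standard noise model of magnitude-
reconstructed MR images and is why a magnitude series is never negative and
has a nonzero noise floor at long TE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mrimon.series import DECAY, IR, RelaxationSeries

#: Default inversion-time schedule: 50 samples, first TI 7 ms, uniform steps
#: spanning a long recovery window (step 140 ms -> last TI 6867 ms).
DEFAULT_IR_SCHEDULE = tuple(7.0 + 140.0 * k for k in range(50))

#: Default multi-echo schedule: 14 echoes at 6 ms spacing (TE = 6 ... 84 ms).
DEFAULT_ECHO_SCHEDULE = tuple(6.0 * (k + 1) for k in range(14))


def ir_signal(t: np.ndarray, a: float, b: float, t1_star: float) -> np.ndarray:
    """Noiseless Look-Locker inversion-recovery signal a − b·exp(−t/T1*)."""
    return a - b * np.exp(-np.asarray(t, float) / t1_star)


def decay_signal(t: np.ndarray, m0: float, t2: float, c: float) -> np.ndarray:
    """Noiseless mono-exponential echo decay M0·exp(−t/T2) + c."""
    return m0 * np.exp(-np.asarray(t, float) / t2) + c


def t1_from_look_locker(a: float, b: float, t1_star: float) -> float:
    """Look-Locker correction T1 = T1*·(b/a − 1)."""
    return t1_star * (b / a - 1.0)


@dataclass
class SignalGenConfig:
    """Ground truth and sampling scheme for one synthetic series.

    ``true_params`` keys: for inversion recovery ``a``, ``b`` and either
    ``t1_star`` or ``t1`` (ms; ``t1`` is converted through the Look-Locker
    correction); for echo decay ``m0``, ``t2`` (ms), ``c`` and optionally
    ``first_echo_factor`` — a multiplicative bias applied to the first echo
    only, emulating the stimulated-echo artifact that motivates first-echo
    exclusion.
    """

    model_kind: str
    true_params: dict
    schedule: tuple | list | np.ndarray = ()
    noise_sigma: float = 0.0
    magnitude_mode: bool = True
    seed: int = 0
    roi_label: str = ""
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.model_kind not in (IR, DECAY):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size == 0:
            raise ValueError("schedule must not be empty")
        if sched[0] <= 0 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing and positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        p = self.true_params
        if self.model_kind == IR:
            for key in ("a", "b"):
                if p.get(key, 0.0) <= 0:
                    raise ValueError(f"IR parameter {key!r} must be > 0")
            if "t1_star" not in p and "t1" not in p:
                raise ValueError("IR parameters need t1_star or t1")
            if p.get("t1_star", p.get("t1")) <= 0:
                raise ValueError("relaxation time must be > 0")
        else:
            if p.get("m0", 0.0) <= 0:
                raise ValueError("decay parameter 'm0' must be > 0")
            if p.get("t2", 0.0) <= 0:
                raise ValueError("decay parameter 't2' must be > 0")
            if p.get("c", 0.0) < 0:
                raise ValueError("decay parameter 'c' must be >= 0")

    def resolved_ir_params(self) -> tuple[float, float, float]:
        """Return (a, b, t1_star), deriving t1_star from t1 if needed."""
        a, b = self.true_params["a"], self.true_params["b"]
        if "t1_star" in self.true_params:
            t1_star = self.true_params["t1_star"]
        else:
            ratio = b / a - 1.0
            if ratio <= 0:
                raise ValueError("t1 parameterization requires b > a")
            t1_star = self.true_params["t1"] / ratio
        return float(a), float(b), float(t1_star)


def _apply_noise(
    clean: np.ndarray, sigma: float, magnitude: bool, rng: np.random.Generator
) -> np.ndarray:
    if sigma == 0:
        return np.abs(clean) if magnitude else clean.copy()
    if magnitude:
        real = clean + rng.normal(0.0, sigma, clean.shape)
        imag = rng.normal(0.0, sigma, clean.shape)
        return np.hypot(real, imag)
    return clean + rng.normal(0.0, sigma, clean.shape)


def generate_ir_series(config: SignalGenConfig) -> RelaxationSeries:
    """Generate one inversion-recovery series from ground-truth parameters.

    In magnitude mode the noiseless signal (which is negative at short TI)
    is rectified through the Rician magnitude operation, so the output is the
    kind of sign-less data a scanner reconstruction delivers; the fitter's
    polarity restoration undoes this.
    """
    if config.model_kind != IR:
        raise ValueError("config.model_kind must be 'inversion_recovery'")
    config.validate()
    a, b, t1_star = config.resolved_ir_params()
    times = np.asarray(config.schedule, dtype=float)
    clean = ir_signal(times, a, b, t1_star)
    rng = np.random.default_rng(config.seed)
    signals = _apply_noise(clean, config.noise_sigma, config.magnitude_mode, rng)
    return RelaxationSeries(
        kind=IR,
        times=times,
        signals=signals,
        roi_label=config.roi_label,
        meta={
            "true_params": {"a": a, "b": b, "t1_star": t1_star,
                            "t1": t1_from_look_locker(a, b, t1_star)},
            "noise_sigma": config.noise_sigma,
            "magnitude_mode": config.magnitude_mode,
            "seed": config.seed,
        },
    )


def generate_decay_series(config: SignalGenConfig) -> RelaxationSeries:
    """Generate one multi-echo decay series from ground-truth parameters."""
    if config.model_kind != DECAY:
        raise ValueError("config.model_kind must be 'echo_decay'")
    config.validate()
    p = config.true_params
    m0, t2, c = float(p["m0"]), float(p["t2"]), float(p.get("c", 0.0))
    times = np.asarray(config.schedule, dtype=float)
    clean = decay_signal(times, m0, t2, c)
    factor = float(p.get("first_echo_factor", 1.0))
    clean[0] *= factor
    rng = np.random.default_rng(config.seed)
    signals = _apply_noise(clean, config.noise_sigma, config.magnitude_mode, rng)
    return RelaxationSeries(
        kind=DECAY,
        times=times,
        signals=signals,
        roi_label=config.roi_label,
        meta={
            "true_params": {"m0": m0, "t2": t2, "c": c,
                            "first_echo_factor": factor},
            "noise_sigma": config.noise_sigma,
            "magnitude_mode": config.magnitude_mode,
            "seed": config.seed,
        },
    )
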