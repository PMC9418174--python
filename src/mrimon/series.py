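"""Relaxation signal series: sampled signal vs. inversion or echo time."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IR = "inversion_recovery"
DECAY = "echo_decay"

#: minimum usable (non-excluded) points per series kind
MIN_POINTS = {IR: 4, DECAY: 3}


@dataclass
class RelaxationSeries:
    """One ROI's sampled relaxation signal.

    Parameters
    ----------
    kind
        ``"inversion_recovery"`` (times are TI) or ``"echo_decay"`` (times
        are TE), both in milliseconds.
    times
        Sample times in ms, strictly increasing, all positive.
    signals
        Signal intensities in arbitrary units, same length as ``times``.
    excluded
        Per-point exclusion flags (motion-corrupted frames, first echo, ...).
        Excluded points are kept in the series but ignored by the fitters.
    roi_label
        Free-text ROI name (``"marrow_L3"``, ``"spleen"``, ...).
    background_sigma
        Noise level estimated from a background ROI, if available.
    """

    kind: str
    times: np.ndarray
    signals: np.ndarray
    excluded: np.ndarray | None = None
    roi_label: str = ""
    background_sigma: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in (IR, DECAY):
            raise ValueError(f"kind must be {IR!r} or {DECAY!r}, got {self.kind!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.signals.shape:
            raise ValueError("times and signals must be 1-D arrays of equal length")
        if self.times.size and self.times[0] <= 0:
            raise ValueError("sample times must be positive")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.excluded is None:
            self.excluded = np.zeros(self.times.size, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape != self.times.shape:
                raise ValueError("excluded flags must match times in length")

    @property
    def n_usable(self) -> int:
        return int((~self.excluded).sum())

    def usable(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, signals) restricted to non-excluded points."""
        keep = ~self.excluded
        return self.times[keep], self.signals[keep]

    def require_usable(self, n_min: int | None = None) -> None:
        n_min = MIN_POINTS[self.kind] if n_min is None else n_min
        if self.n_usable < n_min:
            raise ValueError(
                f"{self.kind} series needs >= {n_min} usable points, "
                f"has {self.n_usable}"
            )
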