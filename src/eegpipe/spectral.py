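"""Window-level spectral features: Burg autoregressive coefficients and band power.

The AR model treats each sample as a weighted sum of its P predecessors,
written here in the convention ``x(t) = -sum_i a_i x(t-i) + e(t)``; the Burg
estimator picks, stage by stage, the reflection coefficient that minimises
the summed forward and backward prediction error, with the full coefficient
vector updated through the Levinson-Durbin recursion.  This always yields a
stable model (all reflection coefficients inside the unit interval).

Band power is the mean squared amplitude of the window after zero-phase
Butterworth filtering to one of the four canonical EEG bands: delta 0-4 Hz
(realised as a low-pass, since 0 Hz cannot be a band-pass corner), theta
4-8 Hz, alpha 8-13 Hz and beta 13-30 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "ARModel",
    "burg_ar",
    "BandDefinition",
    "BandPowerVector",
    "EEG_BANDS",
    "band_power",
]


@dataclass(frozen=True)
class ARModel:
    """Burg-estimated AR model of one window.

    ``coefficients[i-1]`` is ``a_i`` in ``x(t) = -sum a_i x(t-i)``; an AR(1)
    process ``x(t) = 0.9 x(t-1) + e`` therefore fits with ``a_1 = -0.9``.
    """

    order: int
    coefficients: np.ndarray = field(repr=False)
    reflection_coefficients: np.ndarray = field(repr=False)
    noise_variance: float = 0.0


def burg_ar(samples, order: int = 10) -> ARModel:
    """Fit an AR(P) model to a window by Burg's method.

    Raises
    ------
    ValidationError
        ``order < 1`` or ``N <= 2 * order``.
    DegenerateInputError
        Constant input (prediction errors identically zero).
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size
    if order < 1:
        raise ValidationError(f"order must be >= 1, got {order}")
    if n <= 2 * order:
        raise ValidationError(f"need N > 2*order samples; got N={n}, order={order}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("samples must be finite")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("constant input admits no AR fit")

    # phi convention internally: x(t) = sum phi_i x(t-i) + e(t)
    f = x[1:].copy()   # forward prediction error
    b = x[:-1].copy()  # backward prediction error
    phi = np.zeros(0)
    reflections = np.empty(order)
    variance = float(x @ x) / n
    for p in range(order):
        denom = float(f @ f + b @ b)
        if denom == 0.0:
            raise DegenerateInputError(
                f"prediction error vanished at stage {p + 1}; "
                "signal is perfectly predictable at lower order"
            )
        k = 2.0 * float(f @ b) / denom
        reflections[p] = k
        phi = np.concatenate([phi - k * phi[::-1], [k]])
        variance *= 1.0 - k * k
        f, b = f[1:] - k * b[1:], b[:-1] - k * f[:-1]

    return ARModel(
        order=order,
        coefficients=-phi,
        reflection_coefficients=reflections,
        noise_variance=variance,
    )


@dataclass(frozen=True)
class BandDefinition:
    """One EEG frequency band with its Butterworth filter order."""

    name: str
    low_hz: float
    high_hz: float
    filter_order: int = 5

    def __post_init__(self):
        if not 0 <= self.low_hz < self.high_hz:
            raise ValidationError(
                f"band {self.name}: need 0 <= low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )


#: The four canonical bands, in reporting order.
EEG_BANDS = (
    BandDefinition("delta", 0.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)


@dataclass(frozen=True)
class BandPowerVector:
    """Mean squared amplitude per band, in amplitude-units squared."""

    powers: dict

    def as_array(self, order=None) -> np.ndarray:
        names = order if order is not None else list(self.powers)
        return np.array([self.powers[name] for name in names])


@lru_cache(maxsize=64)
def _design_filter(fs: float, low: float, high: float, order: int):
    """Second-order-sections Butterworth filter, cached per (fs, band).

    A band with a 0 Hz lower edge is designed as a low-pass at the upper
    edge.  Sections are verified stable (poles strictly inside unit circle).
    """
    nyq = fs / 2.0
    if high >= nyq:
        raise ValidationError(
            f"band edge {high} Hz must be below Nyquist {nyq} Hz"
        )
    if low == 0.0:
        sos = sps.butter(order, high, btype="lowpass", fs=fs, output="sos")
    else:
        sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    poles = np.concatenate([np.roots(sec[3:]) for sec in sos])
    if np.any(np.abs(poles) >= 1.0):
        raise ValidationError(
            f"designed filter for ({low}, {high}) Hz at fs={fs} is unstable"
        )
    return sos


def band_power(samples, fs: float, bands=EEG_BANDS) -> BandPowerVector:
    """Mean squared amplitude of the window in each requested band.

    Filtering is zero-phase (forward-backward), which doubles the effective
    roll-off of the order-5 design but leaves in-band components unshifted
    within the short analysis window.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if not fs > 0:
        raise ValidationError(f"sampling rate must be positive, got {fs}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("samples must be finite")
    max_order = max(b.filter_order for b in bands)
    if x.size < 3 * max_order:
        raise ValidationError(
            f"window of {x.size} samples too short for order-{max_order} filtering"
        )
    powers = {}
    for band in bands:
        sos = _design_filter(float(fs), band.low_hz, band.high_hz, band.filter_order)
        filtered = sps.sosfiltfilt(sos, x)
        powers[band.name] = float(np.mean(filtered**2))
    return BandPowerVector(powers=powers)
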