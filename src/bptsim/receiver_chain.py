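"""Nonlinear reception: intermodulation algebra, IP2 power law, flux product.

A memoryless second-order nonlinearity ``y = a1 x + a2 x^2`` in the receive
preamplifier mixes two transmitted tones at f1, f2 into intermodulation
products at ``m f2 + n f1``.  The second-order difference product f2 - f1
is the received beat signal; its power follows the classic slope-2 law
``P_IMD = P1_out + P2_out - IP2`` (output-referred intercept point, dBm
into 50 ohms).  The received beat envelope is the product of the two coil
fluxes, ``conj(Phi_1) * Phi_2``.

Convention note: IP2 here is *output-referred* — both the fundamental and
IMD sweep curves are taken at the device output, and the intercept is the
extrapolated output power where they cross.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .em_bore import FluxSeries

__all__ = [
    "TonePair",
    "PreampModel",
    "ImdSpec",
    "imd_frequency",
    "enumerate_imd_products",
    "imd2_power",
    "apply_polynomial_nonlinearity",
    "fit_intercept_point",
    "bpt_rx_product",
    "dbm_to_amplitude",
    "amplitude_to_dbm",
]

_R_OHMS = 50.0


def dbm_to_amplitude(p_dbm: float) -> float:
    """Peak amplitude (V) of a sinusoid with power ``p_dbm`` into 50 ohms."""
    p_watts = 10.0 ** ((p_dbm - 30.0) / 10.0)
    return math.sqrt(2.0 * _R_OHMS * p_watts)


def amplitude_to_dbm(amp: float) -> float:
    """Power (dBm into 50 ohms) of a sinusoid with peak amplitude ``amp``."""
    if amp <= 0:
        raise ValueError("amplitude must be positive")
    return 10.0 * math.log10(amp**2 / (2.0 * _R_OHMS)) + 30.0


@dataclass(frozen=True)
class TonePair:
    """Two transmit tones with f2 > f1 > 0 and their powers in dBm."""

    f1: float
    f2: float
    p1_dbm: float = 0.0
    p2_dbm: float = 0.0

    def __post_init__(self) -> None:
        if not (self.f2 > self.f1 > 0):
            raise ValueError(f"need f2 > f1 > 0, got f1={self.f1}, f2={self.f2}")

    @property
    def beat_frequency(self) -> float:
        return self.f2 - self.f1


@dataclass
class PreampModel:
    """Preamplifier as linear gain plus output-referred IP2.

    ``gain_db`` and ``ip2_dbm`` determine the memoryless polynomial
    coefficients (a1, a2) under the fixed 50-ohm convention:
    ``a1 = 10^(gain_db/20)`` and ``20 log10 a2 = 10 + 2 gain_db - IP2``.
    An optional a3 adds third-order behavior for waveform-level studies
    only; the power formulas here are second order.
    """

    gain_db: float = 0.0
    ip2_dbm: float = 50.0
    a3: float = 0.0

    @property
    def a1(self) -> float:
        return 10.0 ** (self.gain_db / 20.0)

    @property
    def a2(self) -> float:
        return 10.0 ** ((10.0 + 2.0 * self.gain_db - self.ip2_dbm) / 20.0)

    @property
    def poly_coeffs(self) -> tuple[float, float, float]:
        return (self.a1, self.a2, self.a3)

    @classmethod
    def from_poly(cls, a1: float, a2: float, a3: float = 0.0) -> "PreampModel":
        if a1 <= 0 or a2 <= 0:
            raise ValueError("a1 and a2 must be positive")
        gain_db = 20.0 * math.log10(a1)
        ip2 = 10.0 + 2.0 * gain_db - 20.0 * math.log10(a2)
        return cls(gain_db=gain_db, ip2_dbm=ip2, a3=a3)


@dataclass(frozen=True)
class ImdSpec:
    """Intermodulation product ``m f2 + n f1`` of a tone pair."""

    m: int
    n: int
    frequency: float        # |m f2 + n f1|, Hz
    conjugated: bool = False  # raw m f2 + n f1 was negative

    @property
    def order(self) -> int:
        return abs(self.m) + abs(self.n)


def imd_frequency(m: int, n: int, tones: TonePair) -> ImdSpec:
    """Frequency of the (m, n) intermodulation product of a tone pair.

    A negative raw value is reported as its magnitude with
    ``conjugated=True`` (the physical spectral line is at |f| with
    conjugate phase).  (1, -1) on a 2400/2527.8 MHz pair lands at
    127.8 MHz — inside a 3 T MRI receiver band.
    """
    if m == 0 and n == 0:
        raise ValueError("m and n must not both be zero")
    raw = m * tones.f2 + n * tones.f1
    return ImdSpec(m=m, n=n, frequency=abs(raw), conjugated=raw < 0)


def enumerate_imd_products(tones: TonePair, max_order: int = 3) -> list[ImdSpec]:
    """All distinct (m, n) products with 1 <= |m|+|n| <= max_order."""
    out = []
    for m in range(-max_order, max_order + 1):
        for n in range(-max_order, max_order + 1):
            if (m, n) == (0, 0) or abs(m) + abs(n) > max_order:
                continue
            out.append(imd_frequency(m, n, tones))
    return out


def imd2_power(p1_dbm: float, p2_dbm: float, preamp: PreampModel) -> float:
    """Output power (dBm) of the second-order f2 - f1 product.

    ``P_IMD = (p1 + gain) + (p2 + gain) - IP2``: raising both inputs by
    1 dB raises the product by 2 dB, and equal inputs at ``IP2 - gain``
    put the product exactly at IP2.
    """
    return (p1_dbm + preamp.gain_db) + (p2_dbm + preamp.gain_db) - preamp.ip2_dbm


def apply_polynomial_nonlinearity(waveform: np.ndarray,
                                  poly_coeffs: Sequence[float], *,
                                  sample_rate: float | None = None,
                                  max_product_hz: float | None = None) -> np.ndarray:
    """Pointwise ``a1 x + a2 x^2 (+ a3 x^3)`` on a real uniformly sampled waveform.

    If both ``sample_rate`` and ``max_product_hz`` are given, rejects the
    call when the requested product frequency exceeds Nyquist (the product
    would alias).
    """
    x = np.asarray(waveform, dtype=float)
    if sample_rate is not None and max_product_hz is not None:
        if max_product_hz > sample_rate / 2.0:
            raise ValueError(
                f"product frequency {max_product_hz:g} Hz exceeds Nyquist "
                f"{sample_rate / 2.0:g} Hz"
            )
    coeffs = list(poly_coeffs) + [0.0] * (3 - len(poly_coeffs))
    a1, a2, a3 = coeffs[:3]
    return a1 * x + a2 * x * x + a3 * x * x * x


def fit_intercept_point(input_powers_dbm: np.ndarray,
                        fundamental_powers_dbm: np.ndarray,
                        imd_powers_dbm: np.ndarray, *,
                        slope_tolerance: float = 0.3) -> tuple[float, float]:
    """Fit (gain_db, ip2_dbm) from a two-tone power sweep.

    Least-squares lines with slopes constrained to 1 (fundamental) and 2
    (IMD); the output-referred intercept is where the extrapolated lines
    cross: ``IP2 = 2 gain - b2`` with ``b2`` the IMD line intercept.  If
    the unconstrained slopes deviate from 1/2 by more than
    ``slope_tolerance`` a compression warning is emitted.
    """
    p_in = np.asarray(input_powers_dbm, dtype=float)
    p_f = np.asarray(fundamental_powers_dbm, dtype=float)
    p_i = np.asarray(imd_powers_dbm, dtype=float)
    if p_in.size < 2:
        raise ValueError("need at least 2 sweep points to fit an intercept")
    if not (p_in.shape == p_f.shape == p_i.shape):
        raise ValueError("sweep arrays must have equal length")
    slope_f = np.polyfit(p_in, p_f, 1)[0]
    slope_i = np.polyfit(p_in, p_i, 1)[0]
    if abs(slope_f - 1.0) > slope_tolerance or abs(slope_i - 2.0) > slope_tolerance:
        warnings.warn(
            f"sweep slopes ({slope_f:.2f}, {slope_i:.2f}) deviate from (1, 2); "
            "gain compression suspected", stacklevel=2)
    gain = float(np.mean(p_f - p_in))
    b2 = float(np.mean(p_i - 2.0 * p_in))
    ip2 = 2.0 * gain - b2
    return gain, ip2


def bpt_rx_product(flux_f1: FluxSeries, flux_f2: FluxSeries) -> FluxSeries:
    """Received beat signal as the conjugate flux product.

    Per sample ``conj(Phi_1) * Phi_2``, so the magnitude is
    ``|Phi_1| |Phi_2|`` and the phase is the difference-frequency phase
    ``arg Phi_2 - arg Phi_1``.
    """
    if flux_f1.axis.shape != flux_f2.axis.shape or not np.allclose(
            flux_f1.axis, flux_f2.axis):
        raise ValueError("flux series axes do not match")
    if flux_f1.coil_id != flux_f2.coil_id:
        raise ValueError("flux series belong to different coils")
    beat = flux_f2.frequency - flux_f1.frequency
    return FluxSeries(
        coil_id=flux_f1.coil_id,
        frequency=abs(beat),
        axis=flux_f1.axis.copy(),
        flux=np.conj(flux_f1.flux) * flux_f2.flux,
        axis_name=flux_f1.axis_name,
    )
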