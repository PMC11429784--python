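"""Low-level signal transforms for pilot-tone motion traces.

Percent modulation, zero-group-delay filtering, Savitzky-Golay smoothing,
relative-phase extraction between coils, accelerometer-to-displacement
double integration, repeat alignment, and per-coil linear artifact
correction.  All operations are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, signal

__all__ = [
    "MotionTrace",
    "percent_modulation",
    "modulation_range_ratio",
    "zero_phase_lowpass",
    "zero_phase_highpass",
    "savgol_smooth",
    "phase_extract",
    "accel_to_displacement",
    "align_and_average",
    "artifact_linear_correct",
]


@dataclass
class MotionTrace:
    """Named uniformly sampled time series (real or complex)."""

    name: str
    sample_rate: float
    values: np.ndarray
    units: str = "a.u."
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.values = np.asarray(self.values)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) / self.sample_rate

    def with_values(self, values: np.ndarray, *, name: str | None = None,
                    units: str | None = None, **meta) -> "MotionTrace":
        return MotionTrace(name or self.name, self.sample_rate, values,
                           units or self.units, {**self.meta, **meta})


def percent_modulation(x: np.ndarray, low_mean_threshold: float = 0.1
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Convert a signal to percent modulation about its mean.

    ``(x / mean(x) - 1) * 100`` per channel (columns of a 2-D input).
    Channels whose |mean| falls below ``low_mean_threshold`` times the
    median |mean| are flagged excluded (their percent modulation would be
    artificially large) and returned as NaN.  Returns (percent, included
    mask).  Scale-invariant: multiplying x by any k > 0 leaves the output
    unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    one_d = x.ndim == 1
    xm = x[:, None] if one_d else x
    means = xm.mean(axis=0)
    med = np.median(np.abs(means))
    included = np.abs(means) >= low_mean_threshold * med
    included &= means != 0.0
    out = np.full_like(xm, np.nan)
    out[:, included] = (xm[:, included] / means[included] - 1.0) * 100.0
    if one_d:
        return out[:, 0], included
    return out, included


def modulation_range_ratio(range_a: tuple[float, float],
                           range_b: tuple[float, float]) -> float:
    """Ratio of peak-to-peak percent-modulation ranges (sensitivity ratio).

    E.g. a -89..84 % range against a -21..25 % range is a 3.8x increase in
    motion sensitivity.
    """
    pp_a = max(range_a) - min(range_a)
    pp_b = max(range_b) - min(range_b)
    if pp_b == 0:
        raise ValueError("reference range has zero peak-to-peak span")
    return pp_a / pp_b


def _butter_sos(cutoff_hz: float, sample_rate: float, btype: str, order: int):
    if not 0 < cutoff_hz < sample_rate / 2.0:
        raise ValueError(
            f"cutoff {cutoff_hz:g} Hz must be in (0, Nyquist={sample_rate / 2:g}) Hz")
    return signal.butter(order, cutoff_hz, btype=btype, fs=sample_rate,
                         output="sos")


def zero_phase_lowpass(x: np.ndarray, cutoff_hz: float, sample_rate: float,
                       order: int = 5) -> np.ndarray:
    """Butterworth low-pass applied forward-backward (zero group delay).

    The effective magnitude response is the squared one-pass response;
    reflection padding bounds edge transients.
    """
    sos = _butter_sos(cutoff_hz, sample_rate, "lowpass", order)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def zero_phase_highpass(x: np.ndarray, cutoff_hz: float, sample_rate: float,
                        order: int = 5) -> np.ndarray:
    """Butterworth high-pass applied forward-backward (zero group delay)."""
    sos = _butter_sos(cutoff_hz, sample_rate, "highpass", order)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def savgol_smooth(x: np.ndarray, window: int = 11, order: int = 4) -> np.ndarray:
    """Savitzky-Golay local least-squares polynomial smoothing.

    Defaults (window 11, order 4) match frame-rate navigator denoising;
    ``window=1`` is the identity.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    if window == 1:
        return np.asarray(x, dtype=float).copy()
    if order >= window:
        raise ValueError("polynomial order must be less than the window")
    return signal.savgol_filter(np.asarray(x, dtype=float), window, order, axis=0)


def phase_extract(values: np.ndarray, reference_coil: int | None = 0, *,
                  window: int | None = None) -> np.ndarray:
    """Per-coil phase relative to a reference coil via complex least squares.

    For each coil i the complex scale ``c_i`` minimizing
    ``|values_i - c_i values_ref|^2`` over a sliding window is computed in
    closed form (``<ref, x_i> / <ref, ref>``); the returned phase trace is
    the unwrapped ``arg c_i``.  The reference coil yields identically zero,
    and a common phase added to every coil cancels.  ``window=None`` uses
    the full record (constant phase per coil); ``reference_coil=None``
    picks the highest-energy coil.
    """
    v = np.asarray(values, dtype=complex)
    if v.ndim != 2 or v.shape[1] < 2:
        raise ValueError("need a [samples, coils] array with >= 2 coils")
    n, n_coils = v.shape
    if reference_coil is None:
        reference_coil = int(np.argmax(np.sum(np.abs(v) ** 2, axis=0)))
    ref = v[:, reference_coil]
    if np.sum(np.abs(ref) ** 2) == 0:
        raise ValueError("reference coil has zero energy")
    if window is None or window >= n:
        num = np.conj(ref)[:, None] * v          # [n, coils]
        c = num.sum(axis=0) / np.sum(np.abs(ref) ** 2)
        phases = np.tile(np.angle(c)[None, :], (n, 1))
    else:
        if window < 1:
            raise ValueError("window must be >= 1")
        kernel = np.ones(window)
        num = np.conj(ref)[:, None] * v
        den = np.abs(ref) ** 2
        num_s = np.apply_along_axis(
            lambda col: np.convolve(col, kernel, mode="same"), 0, num.real
        ) + 1j * np.apply_along_axis(
            lambda col: np.convolve(col, kernel, mode="same"), 0, num.imag)
        den_s = np.convolve(den, kernel, mode="same")
        den_s = np.where(den_s == 0, np.finfo(float).tiny, den_s)
        phases = np.unwrap(np.angle(num_s / den_s[:, None]), axis=0)
    phases[:, reference_coil] = 0.0
    return phases


def accel_to_displacement(accel: np.ndarray, sample_rate: float,
                          highpass_cutoff: float = 2.5,
                          order: int = 5) -> np.ndarray:
    """Displacement from acceleration: high-pass, then integrate twice.

    Zero-phase Butterworth high-pass (default cutoff 2.5 Hz for coil
    vibration; 4 Hz is typical for displacement ballistocardiography),
    followed by two cumulative trapezoidal integrations.  Each integration
    pass is linearly detrended (removing the mean and any residual ramp the
    unknown integration constants introduce) to bound drift.
    """
    a = zero_phase_highpass(np.asarray(accel, dtype=float), highpass_cutoff,
                            sample_rate, order)
    v = integrate.cumulative_trapezoid(a, dx=1.0 / sample_rate, initial=0.0, axis=0)
    v = signal.detrend(v, axis=0, type="linear")
    d = integrate.cumulative_trapezoid(v, dx=1.0 / sample_rate, initial=0.0, axis=0)
    return signal.detrend(d, axis=0, type="linear")


def align_and_average(repeats: list[np.ndarray]
                      ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Align repeated motion periods by cross-correlation and average them.

    Each repeat is aligned to the first by the integer lag maximizing the
    cross-correlation, then all are cropped to the common support.  Returns
    (pointwise mean, pointwise SD, lags).
    """
    if len(repeats) < 2:
        raise ValueError("need at least 2 repeats")
    reps = [np.asarray(r, dtype=float) for r in repeats]
    ref = reps[0] - reps[0].mean()
    lags = [0]
    for r in reps[1:]:
        # lag such that r[i] ~ ref[i - lag] (r delayed by lag w.r.t. ref)
        xc = signal.correlate(r - r.mean(), ref, mode="full")
        lags.append(int(np.argmax(xc)) - (len(ref) - 1))
    # aligned_k[i] = r_k[i + lag_k]; crop to the common support
    lo = max(0, max(-lag for lag in lags))
    hi = min(len(r) - lag for r, lag in zip(reps, lags))
    if hi <= lo:
        raise ValueError("no overlap remains after alignment")
    aligned = np.stack([r[lo + lag:hi + lag] for r, lag in zip(reps, lags)])
    return aligned.mean(axis=0), aligned.std(axis=0, ddof=0), lags


def artifact_linear_correct(trace: np.ndarray, regressors: np.ndarray | None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Subtract a per-coil linear fit of artifact regressors from a trace.

    Ordinary least squares of each coil's trace onto the regressors plus an
    intercept; returns (residual, coefficients [n_reg+1, n_coils] with the
    intercept first).  With no regressors this de-means the input.  A
    rank-deficient design falls back to the pseudo-inverse with a warning.
    """
    y = np.asarray(trace, dtype=float)
    one_d = y.ndim == 1
    ym = y[:, None] if one_d else y
    n = ym.shape[0]
    if regressors is None or (hasattr(regressors, "size") and regressors.size == 0):
        X = np.ones((n, 1))
    else:
        R = np.asarray(regressors, dtype=float)
        if R.ndim == 1:
            R = R[:, None]
        if R.shape[0] != n:
            raise ValueError("regressors must match the trace length")
        X = np.column_stack([np.ones(n), R])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient regressors; using pseudo-inverse",
                      stacklevel=2)
    coef = np.linalg.pinv(X) @ ym
    resid = ym - X @ coef
    if one_d:
        return resid[:, 0], coef[:, 0]
    return resid, coef
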