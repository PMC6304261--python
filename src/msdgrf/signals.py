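"""Signal conditioning and measurement conventions for running trials.

Force-platform GRF is handled on its native 3,000 Hz grid (newtons), trunk
accelerometry on its native 100 Hz grid (units of g, i.e. proper
acceleration divided by 9.81 m s^-2).  All filtering is zero-lag
(forward-backward) Butterworth, the convention used for gait signals, with
the requested order split across the two passes so that the dual-pass
result has the stated order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _sig

VALID_UNITS = ("N", "N/kg", "g", "m/s^2")


class NoContactError(ValueError):
    """Raised when no supra-threshold foot contact exists in a GRF trace."""


@dataclass(frozen=True)
class TrialSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    rate : float
        Sample rate, Hz.
    values : numpy.ndarray
        Samples, 1-D and finite.
    unit : str
        One of ``"N"``, ``"N/kg"``, ``"g"``, ``"m/s^2"``.
    """

    t0: float
    rate: float
    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Time span from first to last sample, seconds."""
        return (self.n - 1) / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def crop(self, i0: int, i1: int) -> "TrialSeries":
        """Samples ``i0..i1`` inclusive, keeping the absolute time base."""
        if not (0 <= i0 <= i1 < self.n):
            raise IndexError(f"crop window ({i0}, {i1}) outside series of length {self.n}")
        return replace(self, t0=self.t0 + i0 / self.rate, values=self.values[i0 : i1 + 1])


@dataclass(frozen=True)
class StanceWindow:
    """Foot-contact interval as inclusive sample indices on a GRF grid."""

    i_touchdown: int
    i_takeoff: int
    rate: float

    def __post_init__(self) -> None:
        if self.i_touchdown > self.i_takeoff:
            raise ValueError("touchdown index must not exceed takeoff index")

    @property
    def duration(self) -> float:
        return (self.i_takeoff - self.i_touchdown) / self.rate


def lowpass(series: TrialSeries, cutoff: float, order: int = 4) -> TrialSeries:
    """Zero-lag Butterworth low-pass filter.

    The filter runs forward and backward (``filtfilt``) so the result has
    no phase lag; each pass uses ``order / 2`` so the dual-pass response is
    of the requested ``order``.  At the cut-off frequency the dual-pass
    attenuation is -6.02 dB.  Edges are handled by reflective padding of
    ``3 * order`` samples.
    """
    if order < 2 or order % 2 != 0:
        raise ValueError(f"order must be an even integer >= 2, got {order}")
    nyq = series.rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff}")
    if series.n < 3 * order:
        raise ValueError(
            f"series too short to filter: {series.n} samples < {3 * order}"
        )
    sos = _sig.butter(order // 2, cutoff / nyq, btype="low", output="sos")
    padlen = min(3 * order, series.n - 1)
    out = _sig.sosfiltfilt(sos, series.values, padtype="even", padlen=padlen)
    return replace(series, values=out)


def detect_stance(grf: TrialSeries, threshold: float = 20.0) -> StanceWindow:
    """Delimit the stance phase by a force threshold (default 20 N).

    Touchdown is the first sample exceeding the threshold.  Takeoff is the
    last sample of the contiguous supra-threshold run that contains the
    global force maximum, which makes the rule robust to isolated noise
    crossings before or after contact.
    """
    if grf.unit != "N":
        raise ValueError(f"stance detection requires newtons, got unit {grf.unit!r}")
    above = grf.values > threshold
    if not above.any():
        raise NoContactError(f"no sample exceeds the {threshold} N threshold")
    i_td = int(np.argmax(above))
    i_max = int(np.argmax(grf.values))
    # walk to the end of the supra-threshold run containing the maximum
    i_to = i_max
    while i_to + 1 < grf.n and above[i_to + 1]:
        i_to += 1
    return StanceWindow(i_touchdown=i_td, i_takeoff=i_to, rate=grf.rate)


def gravity_correct(acc: TrialSeries, mode: str = "proper") -> TrialSeries:
    """Express trunk accelerometry in the convention the model uses.

    ``mode="proper"`` (default): the accelerometer magnitude already is
    proper acceleration in g (a static stance reads 1 g, free fall reads
    0 g) which is exactly the quantity the model's upper-mass channel
    produces, so the series passes through unchanged.  ``mode="subtract"``
    removes the 1 g static offset instead, for pipelines that prefer
    zero-referenced dynamic acceleration on both sides.
    """
    if acc.unit != "g":
        raise ValueError(f"gravity correction expects g-units, got {acc.unit!r}")
    if mode == "proper":
        return acc
    if mode == "subtract":
        return replace(acc, values=acc.values - 1.0)
    raise ValueError(f"unknown mode {mode!r}")


def resample(series: TrialSeries, target_rate: float) -> TrialSeries:
    """Linear interpolation onto a uniform grid at ``target_rate``.

    The new grid starts at the same instant and spans the same window (its
    last point is the largest multiple of ``1/target_rate`` not exceeding
    the original span); the first sample is preserved exactly.
    """
    if target_rate <= 0:
        raise ValueError(f"target rate must be positive, got {target_rate}")
    if target_rate == series.rate:
        return series
    n_new = int(np.floor(series.duration * target_rate + 1e-9)) + 1
    t_new = np.arange(n_new) / target_rate
    t_old = np.arange(series.n) / series.rate
    out = np.interp(t_new, t_old, series.values)
    return replace(series, rate=target_rate, values=out)


def normalise_bw(grf: TrialSeries, mass: float) -> TrialSeries:
    """Normalise a GRF series to body weight-independent N/kg."""
    if grf.unit != "N":
        raise ValueError(f"body-mass normalisation expects newtons, got {grf.unit!r}")
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    return replace(grf, values=grf.values / mass, unit="N/kg")


def rmse(a: TrialSeries, b: TrialSeries) -> float:
    """Root-mean-square difference between two series on the same grid."""
    if a.n != b.n:
        raise ValueError(f"length mismatch: {a.n} vs {b.n}")
    if a.unit != b.unit:
        raise ValueError(f"unit mismatch: {a.unit!r} vs {b.unit!r}")
    if a.rate != b.rate:
        raise ValueError(f"rate mismatch: {a.rate} vs {b.rate}")
    d = a.values - b.values
    return float(np.sqrt(np.mean(d * d)))
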