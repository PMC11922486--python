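"""Waveform utilities: time series container, cardiac/respiratory band
separation, respiratory-variation statistics, and force/frame synchronization.

The physiological convention adopted throughout: variation with period
shorter than 1 s that tracks the right-atrial pressure morphology is cardiac;
variation with period longer than 1 s and a roughly sinusoidal shape is
respiratory.  The boundary is therefore a 1 Hz cutoff, realized as a
zero-phase low-pass so neither band is delayed relative to the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "TimeSeries",
    "BandSplit",
    "split_bands",
    "respiratory_sd",
    "detect_sync_offsets",
]

#: Butterworth order of the band-splitting low-pass.  Applied forward and
#: backward (zero phase), so the effective magnitude response is squared:
#: a 1.2 Hz cardiac tone is attenuated by ~95% while 0.25 Hz respiration
#: passes essentially unchanged.
FILTER_ORDER = 8

CUTOFF_HZ = 1.0


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled signal with an explicit time base and unit tag."""

    t0: float
    dt: float
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.values))

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return self.dt * len(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        return float(np.mean(self.values))

    def with_values(self, values: np.ndarray, units: str | None = None) -> "TimeSeries":
        return TimeSeries(self.t0, self.dt, values, self.units if units is None else units)

    def shifted(self, tau: float) -> "TimeSeries":
        """Same samples, time base shifted by ``tau`` seconds."""
        return TimeSeries(self.t0 + tau, self.dt, self.values, self.units)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.t, "value": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, units: str = "") -> "TimeSeries":
        df = pd.read_csv(path)
        t = df["t"].to_numpy()
        dt = float(np.median(np.diff(t)))
        return cls(float(t[0]), dt, df["value"].to_numpy(), units)


@dataclass(frozen=True)
class BandSplit:
    """Cardiac (>1 Hz) and respiratory (<1 Hz, mean retained) components."""

    cardiac: TimeSeries
    respiratory: TimeSeries
    cutoff_hz: float = CUTOFF_HZ

    @property
    def reconstruction(self) -> np.ndarray:
        return self.cardiac.values + self.respiratory.values


def _lowpass_sos(cutoff_hz: float, sample_rate: float) -> np.ndarray:
    nyq = sample_rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz at or above Nyquist {nyq} Hz")
    return sps.butter(FILTER_ORDER, cutoff_hz / nyq, btype="low", output="sos")


def split_bands(x: TimeSeries, cutoff_hz: float = CUTOFF_HZ) -> BandSplit:
    """Separate a waveform into respiratory (low-pass, mean retained) and
    cardiac (residual) components with a zero-phase Butterworth filter.

    Edge effects are controlled by ``sosfiltfilt``'s odd reflection padding.
    Requires at least ``3 / cutoff_hz`` seconds of signal so the filter sees
    several periods at the band boundary.
    """
    if x.duration < 3.0 / cutoff_hz:
        raise ValueError(
            f"series too short for band split: {x.duration:.2f} s < {3.0 / cutoff_hz:.2f} s"
        )
    sos = _lowpass_sos(cutoff_hz, x.sample_rate)
    resp = sps.sosfiltfilt(sos, x.values)
    return BandSplit(
        cardiac=x.with_values(x.values - resp),
        respiratory=x.with_values(resp),
        cutoff_hz=cutoff_hz,
    )


def respiratory_sd(x: TimeSeries, cutoff_hz: float = CUTOFF_HZ) -> float:
    """Standard deviation about the mean attributable to respiration.

    For a pure respiratory sinusoid of amplitude A this is A/sqrt(2).
    """
    resp = split_bands(x, cutoff_hz).respiratory.values
    return float(np.std(resp))


def _transient_band(values: np.ndarray, sample_rate: float) -> np.ndarray:
    """High-pass above the band boundary to isolate quick-compression
    transients from slow physiological drift, then standardize."""
    sos = sps.butter(4, CUTOFF_HZ / (sample_rate / 2.0), btype="high", output="sos")
    y = sps.sosfiltfilt(sos, values)
    sd = np.std(y)
    return y / sd if sd > 0 else y


def detect_sync_offsets(
    force: TimeSeries,
    area: TimeSeries,
    max_lag_s: float = 2.0,
    neighborhood_s: float = 0.7,
) -> float:
    """Time offset (s) by which the area channel's events lag the force
    channel's quick-compression transients; ``area.shifted(-offset)``
    aligns the two channels.

    Both channels are high-passed above the cardiac/respiratory band to
    isolate the sync transients.  The force transients are localized first;
    cross-correlation is then evaluated only over those neighborhoods (so
    ongoing cardiac pulsation in the area channel cannot dominate) and over
    lags within ``max_lag_s``.  The match is polarity-robust: a compression
    spike appears as a dip in a vessel area but as a spike in a force-like
    reference, and either sign of the correlation peak is accepted.

    Raises ValueError("unsyncable capture ...") when either channel lacks
    two detectable transients.
    """
    if abs(force.dt - area.dt) > 1e-9:
        raise ValueError("force and area must share a sample rate")
    dt = force.dt
    f = _transient_band(force.values, force.sample_rate)
    a = _transient_band(area.values, area.sample_rate)

    min_dist = max(int(1.0 / dt), 1)
    # genuine transients must tower over the channel's robust noise floor;
    # pure sensor noise never clears this bar
    robust_sd = 1.4826 * np.median(np.abs(f - np.median(f))) + 1e-12
    height = max(0.5 * np.max(np.abs(f)), 6.0 * robust_sd)
    f_peaks, _ = sps.find_peaks(np.abs(f), height=height, distance=min_dist)
    if len(f_peaks) < 2:
        raise ValueError("unsyncable capture: fewer than two transients in force channel")

    w = int(neighborhood_s / dt)
    pad = int(max_lag_s / dt)
    f_mask = np.zeros(len(f))
    a_mask = np.zeros(len(a))
    for p in f_peaks:
        f_mask[max(p - w, 0): p + w] = 1.0
        a_mask[max(p - w - pad, 0): p + w + pad] = 1.0
    a_masked = a * a_mask[: len(a)]
    a_peaks, _ = sps.find_peaks(
        np.abs(a_masked), height=0.55 * np.max(np.abs(a_masked)), distance=min_dist
    )
    if len(a_peaks) < 2:
        raise ValueError("unsyncable capture: fewer than two transients in area channel")

    xc = sps.correlate(f * f_mask, a_masked, mode="full")
    lags = sps.correlation_lags(len(f), len(a), mode="full")
    # offset = (area event time) - (force event time); sample part is -lag
    tau = -lags * dt + (area.t0 - force.t0)
    score = np.where(np.abs(tau) <= max_lag_s, np.abs(xc), -np.inf)
    return float(tau[int(np.argmax(score))])
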