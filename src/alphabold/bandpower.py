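"""Alpha band-power time courses from the pooled occipital EEG.

Complex demodulation shifts the band of interest to baseband with a complex
exponential at the band center and low-passes the product at half the
bandwidth; the squared magnitude (scaled by 2 so a unit-amplitude in-band
sinusoid yields power 1/2) is the instantaneous band power. Power is then
averaged into non-overlapping one-second segments aligned with the fMRI
regressor grid, and an FFT-based relative-power summary supports the group
description.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .eeg import ArtifactMask


@dataclass(frozen=True)
class Band:
    """Frequency band with inclusive edges in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError("f_lo must be below f_hi")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    @property
    def half_width(self) -> float:
        return 0.5 * (self.f_hi - self.f_lo)


TOTAL_ALPHA = Band("total_alpha", 8.0, 12.0)
LOWER_ALPHA = Band("lower_alpha", 8.0, 10.0)
UPPER_ALPHA = Band("upper_alpha", 10.0, 12.0)
ALPHA_BANDS = (TOTAL_ALPHA, LOWER_ALPHA, UPPER_ALPHA)


@dataclass
class PowerSeries:
    """Band power per one-second segment (µV²) with validity flags."""

    values: np.ndarray
    band: Band
    rate: float = 1.0
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.values), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.valid) != len(self.values):
            raise ValueError("valid flags must align with values")
        if np.any(self.values < -1e-12):
            raise ValueError("power values must be non-negative")

    @property
    def times(self) -> np.ndarray:
        """Segment start times in seconds."""
        return np.arange(len(self.values)) / self.rate


EDGE_INVALID_S = 2.0  # demodulation filter transient margin


def complex_demodulate(
    series: np.ndarray, fs: float, band: Band, lp_order: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous band power at the input rate.

    Returns ``(power, valid)`` where ``power[t] = 2 |LP(x(t) e^{-i 2π f_c t})|²``
    (so a pure in-band sinusoid of amplitude A gives mean power A²/2) and
    ``valid`` is False inside the 2 s edge margins affected by filter
    transients.
    """
    series = np.asarray(series, dtype=float)
    if band.f_hi >= fs / 2:
        raise ValueError(f"band {band.name} above Nyquist for fs={fs}")
    t = np.arange(len(series)) / fs
    demod = series * np.exp(-2j * np.pi * band.center * t)
    sos = signal.butter(lp_order, band.half_width, btype="lowpass", fs=fs,
                        output="sos")
    filt = signal.sosfiltfilt(sos, demod.real) + 1j * signal.sosfiltfilt(
        sos, demod.imag
    )
    power = 2.0 * np.abs(filt) ** 2
    valid = np.ones(len(series), dtype=bool)
    edge = int(round(EDGE_INVALID_S * fs))
    if edge > 0:
        valid[:edge] = False
        valid[-edge:] = False
    return power, valid


def segment_power(
    power: np.ndarray,
    fs: float,
    band: Band,
    mask: ArtifactMask | None = None,
    edge_valid: np.ndarray | None = None,
    seg: float = 1.0,
) -> PowerSeries:
    """Average instantaneous power into non-overlapping ``seg``-second bins.

    A segment is invalid when it intersects any artifact interval of ``mask``
    or contains edge-invalid samples.
    """
    power = np.asarray(power, dtype=float)
    n_seg = int(np.floor(len(power) / fs / seg))
    if n_seg < 1:
        raise ValueError("duration must be at least one segment")
    spseg = int(round(fs * seg))
    values = power[: n_seg * spseg].reshape(n_seg, spseg).mean(axis=1)
    valid = np.ones(n_seg, dtype=bool)
    if edge_valid is not None:
        ev = np.asarray(edge_valid, dtype=bool)[: n_seg * spseg]
        valid &= ev.reshape(n_seg, spseg).all(axis=1)
    if mask is not None:
        for i in range(n_seg):
            if mask.intersects(i * seg, (i + 1) * seg):
                valid[i] = False
    return PowerSeries(values=values, band=band, rate=1.0 / seg, valid=valid)


def fft_relative_power(
    series: np.ndarray,
    fs: float,
    band: Band,
    total_band: tuple[float, float] = (1.0, 40.0),
    seg: float = 1.0,
) -> float:
    """Relative band power from per-segment periodograms.

    Each non-overlapping ``seg``-second segment contributes the ratio of
    band power to total-band power from its rectangular-window periodogram;
    the segment ratios are averaged. Result lies in [0, 1].
    """
    series = np.asarray(series, dtype=float)
    lo, hi = total_band
    if not (lo <= band.f_lo and band.f_hi <= hi):
        raise ValueError("band must lie inside total_band")
    spseg = int(round(fs * seg))
    n_seg = len(series) // spseg
    if n_seg < 2:
        raise ValueError("at least 2 s of data required")
    segs = series[: n_seg * spseg].reshape(n_seg, spseg)
    freqs = np.fft.rfftfreq(spseg, d=1.0 / fs)
    p = np.abs(np.fft.rfft(segs, axis=1)) ** 2
    in_band = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    in_total = (freqs >= lo) & (freqs <= hi)
    num = p[:, in_band].sum(axis=1)
    den = p[:, in_total].sum(axis=1)
    ok = den > 0
    if not np.any(ok):
        return 0.0
    return float(np.mean(num[ok] / den[ok]))


def plot_power(ps: PowerSeries, path: str) -> None:
    """QC plot of a band-power series to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(ps.times, ps.values, lw=0.8)
    bad = ~ps.valid
    if np.any(bad):
        ax.plot(ps.times[bad], ps.values[bad], "r.", ms=3, label="invalid")
        ax.legend()
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"{ps.band.name} power (µV²)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
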