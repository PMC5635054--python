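"""EEG cleaning for simultaneous EEG-fMRI recordings.

Implements the classic average-artifact-subtraction (AAS) chain used to
recover scalp EEG acquired inside the MR scanner: decimation, subtraction of
the TR-locked gradient artifact, subtraction of the R-peak-locked
ballistocardiogram (BCG) artifact, band filtering, an automated ICA-based
cleanup, residual-artifact interval marking, common-average re-referencing
and occipital channel pooling.

All operations are pure functions ``EEGRecording -> EEGRecording`` (or a
derived series); each appends a provenance entry to ``history``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

OCCIPITAL_CHANNELS = ("O1", "O2", "Oz")
ECG_LABEL = "ECG"


@dataclass
class EEGRecording:
    """Multichannel EEG time series in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Channel time courses in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per row of ``data`` (10-20 names plus ``"ECG"``).
    markers : list of (time_s, type, label)
        Event markers; scanner volume triggers carry type ``"Scanner"``.
    history : list of dict
        Append-only provenance of applied operations.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    markers: list[tuple[float, str, str]] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel row required")
        tol = 0.5 / self.fs
        dur = self.duration
        for t, _, _ in self.markers:
            if not (-tol <= t <= dur + tol):
                raise ValueError(f"marker at {t} s outside recording [0, {dur}]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label} not found") from None

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def eeg_channel_indices(self) -> list[int]:
        """Indices of scalp channels (everything except ECG)."""
        return [i for i, c in enumerate(self.channel_labels) if c != ECG_LABEL]

    def marker_times(self, marker_type: str) -> np.ndarray:
        return np.array([t for t, typ, _ in self.markers if typ == marker_type])

    def _evolve(self, data: np.ndarray, op: str, **params) -> "EEGRecording":
        rec = dataclasses.replace(
            self,
            data=data,
            markers=list(self.markers),
            history=self.history + [{"op": op, **params}],
        )
        return rec


@dataclass
class ArtifactMask:
    """Half-open artifact intervals ``[start, end)`` in seconds.

    ``flags[i]`` is True for intervals at least ``min_dur`` long; only those
    feed the fMRI nuisance regressor, but every interval invalidates the
    overlapping power segments.
    """

    intervals: list[tuple[float, float]]
    duration: float
    flags: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.flags:
            self.flags = [True] * len(self.intervals)
        prev_end = 0.0
        for (s, e), _ in zip(self.intervals, self.flags):
            if not (0 <= s < e <= self.duration + 1e-9):
                raise ValueError(f"interval [{s}, {e}) outside [0, {self.duration})")
            if s < prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = e

    def flagged_intervals(self) -> list[tuple[float, float]]:
        return [iv for iv, f in zip(self.intervals, self.flags) if f]

    def intersects(self, start: float, end: float, flagged_only: bool = False) -> bool:
        ivs = self.flagged_intervals() if flagged_only else self.intervals
        return any(s < end and start < e for s, e in ivs)


# ---------------------------------------------------------------------------
# decimation


def _decimation_stages(factor: int) -> list[int]:
    """Split a decimation factor into stages of at most 13 (filter stability)."""
    stages = []
    f = factor
    for p in (13, 11, 10, 8, 7, 6, 5, 4, 3, 2):
        while f % p == 0 and f > 13:
            stages.append(p)
            f //= p
    stages.append(f)
    return [s for s in sorted(stages, reverse=True) if s > 1]


def decimate(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Anti-alias filter and downsample to ``target_fs``.

    The ratio ``fs / target_fs`` must be an integer. Marker times are in
    seconds and therefore unchanged.
    """
    if target_fs >= rec.fs:
        raise ValueError("target_fs must be below current sampling rate")
    ratio = rec.fs / target_fs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9:
        raise ValueError(f"non-integer decimation factor {ratio}")
    data = rec.data
    for q in _decimation_stages(factor):
        data = signal.decimate(data, q, ftype="fir", axis=-1, zero_phase=True)
    return dataclasses.replace(
        rec,
        data=data,
        fs=float(target_fs),
        markers=list(rec.markers),
        history=rec.history + [{"op": "decimate", "target_fs": target_fs,
                                "factor": factor}],
    )


# ---------------------------------------------------------------------------
# epoch onsets / AAS


def epoch_onsets_from_markers(rec: EEGRecording, marker_type: str = "Scanner") -> np.ndarray:
    """Strictly increasing artifact-epoch onset times from event markers."""
    times = rec.marker_times(marker_type)
    if times.size == 0:
        raise ValueError(f"no markers of type {marker_type!r} found")
    if times.size < 2:
        raise ValueError("at least two markers required to define epochs")
    times = np.sort(times)
    spacing = np.diff(times)
    if np.ptp(spacing) > 1.0 / rec.fs:
        warnings.warn(
            "inter-marker spacing varies by more than one sample; "
            "epochs may be misaligned",
            RuntimeWarning,
        )
    return times


def _sliding_template_subtract(
    data: np.ndarray, starts: np.ndarray, length: int, n_avg: int
) -> np.ndarray:
    """Subtract, at each epoch, the mean of the ``n_avg`` nearest epochs.

    The window is centered on the epoch and truncated at the ends of the
    epoch sequence. Samples outside epochs are untouched.
    """
    n_ep = len(starts)
    # (n_ep, n_channels, length) view by fancy indexing
    idx = starts[:, None] + np.arange(length)[None, :]
    epochs = data[:, idx].transpose(1, 0, 2)  # (n_ep, n_ch, L)
    csum = np.concatenate(
        [np.zeros((1,) + epochs.shape[1:]), np.cumsum(epochs, axis=0)], axis=0
    )
    half = (n_avg - 1) // 2
    out = data.copy()
    for i in range(n_ep):
        lo = max(0, i - half)
        hi = min(n_ep, i + (n_avg - half))
        template = (csum[hi] - csum[lo]) / (hi - lo)
        out[:, starts[i] : starts[i] + length] -= template
    return out


def aas_subtract(
    rec: EEGRecording, onsets: np.ndarray, epoch_len: float, n_avg: int = 21
) -> EEGRecording:
    """Average-artifact subtraction of a trigger-locked periodic artifact.

    For each epoch ``[onset, onset + epoch_len)`` the mean over the ``n_avg``
    nearest epochs (centered sliding window, truncated at the edges) is
    subtracted channel-wise.
    """
    if n_avg < 1:
        raise ValueError("n_avg must be >= 1")
    onsets = np.asarray(onsets, dtype=float)
    starts = np.round(onsets * rec.fs).astype(int)
    length = int(round(epoch_len * rec.fs))
    if np.any(np.diff(starts) < length):
        raise ValueError("epochs overlap")
    if starts[-1] + length > rec.n_samples:
        raise ValueError("last epoch extends past end of data")
    if starts[0] < 0:
        raise ValueError("epoch starts before data")
    data = _sliding_template_subtract(rec.data, starts, length, n_avg)
    return rec._evolve(data, "aas_subtract", n_epochs=len(starts), n_avg=n_avg,
                       epoch_len=epoch_len)


# ---------------------------------------------------------------------------
# ECG / BCG


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Detect R-peak times (s) in an ECG trace.

    Energy-based detector: band-pass 5-20 Hz, square, smooth over 80 ms,
    adaptive threshold, 0.3 s refractory period. A flat trace yields an
    empty result with a warning rather than an exception.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < 10 * fs:
        raise ValueError("at least 10 s of ECG required")
    if np.ptp(ecg) < 1e-12 or not np.all(np.isfinite(ecg)):
        warnings.warn("flat or non-finite ECG; no R-peaks detected", RuntimeWarning)
        return np.array([])
    sos = signal.butter(2, [5.0, min(20.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, ecg)
    energy = signal.convolve(filt**2, np.ones(max(1, int(0.08 * fs))) / max(1, int(0.08 * fs)),
                             mode="same")
    thresh = 0.3 * np.percentile(energy, 99)
    if thresh <= 0:
        warnings.warn("no ECG energy above threshold", RuntimeWarning)
        return np.array([])
    peaks, _ = signal.find_peaks(energy, height=thresh, distance=int(0.3 * fs))
    # refine each peak to the local extremum of the band-passed trace
    refined = []
    w = int(0.05 * fs)
    for p in peaks:
        lo, hi = max(0, p - w), min(len(filt), p + w + 1)
        refined.append(lo + int(np.argmax(np.abs(filt[lo:hi]))))
    times = np.unique(np.asarray(refined)) / fs
    # enforce refractory period after refinement
    keep = [0]
    for i in range(1, len(times)):
        if times[i] - times[keep[-1]] >= 0.3:
            keep.append(i)
    return times[keep] if len(times) else times


def bcg_subtract(
    rec: EEGRecording,
    r_peaks: np.ndarray,
    delay: float = 0.21,
    template_len: float = 0.7,
    n_avg: int = 21,
) -> EEGRecording:
    """Subtract the ballistocardiogram artifact with heartbeat-locked AAS.

    Each artifact epoch is ``[peak + delay, peak + delay + template_len)``;
    the subtracted template is the sliding average over ``n_avg`` neighboring
    heartbeats.
    """
    r_peaks = np.asarray(r_peaks, dtype=float)
    if r_peaks.size == 0:
        raise ValueError("r_peaks must be non-empty")
    if delay < 0:
        raise ValueError("delay must be >= 0")
    if r_peaks.size > 1:
        rr = float(np.median(np.diff(np.sort(r_peaks))))
        if template_len > rr:
            raise ValueError(
                f"template_len {template_len} s exceeds median RR interval "
                f"{rr:.3f} s; choose a shorter template"
            )
    starts = np.round((np.sort(r_peaks) + delay) * rec.fs).astype(int)
    length = int(round(template_len * rec.fs))
    keep = (starts >= 0) & (starts + length <= rec.n_samples)
    starts = starts[keep]
    if starts.size == 0:
        raise ValueError("no complete BCG epoch fits inside the recording")
    data = _sliding_template_subtract(rec.data, starts, length, n_avg)
    return rec._evolve(data, "bcg_subtract", n_beats=len(starts), n_avg=n_avg,
                       delay=delay, template_len=template_len)


# ---------------------------------------------------------------------------
# filtering


def filter_eeg(
    rec: EEGRecording, hp: float = 0.5, lp: float = 70.0, notch: float = 50.0
) -> EEGRecording:
    """Zero-phase band filtering: high-pass, low-pass and a 2 Hz-wide notch.

    Fourth-order Butterworth edges applied forward-backward; the notch is a
    second-order band-stop (fourth effective order after filtfilt).
    """
    nyq = rec.fs / 2
    if not (0 < hp < lp < nyq):
        raise ValueError(f"invalid band edges hp={hp}, lp={lp} for fs={rec.fs}")
    data = rec.data
    sos_hp = signal.butter(4, hp, btype="highpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos_hp, data, axis=-1)
    sos_lp = signal.butter(4, lp, btype="lowpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos_lp, data, axis=-1)
    if notch is not None:
        if not (0 < notch < nyq):
            raise ValueError(f"notch frequency {notch} outside (0, {nyq})")
        sos_n = signal.butter(2, [notch - 1.0, notch + 1.0], btype="bandstop",
                              fs=rec.fs, output="sos")
        data = signal.sosfiltfilt(sos_n, data, axis=-1)
    return rec._evolve(data, "filter_eeg", hp=hp, lp=lp, notch=notch)


# ---------------------------------------------------------------------------
# ICA proxy


def _lowfreq_fraction(x: np.ndarray, fs: float, f_edge: float = 2.0) -> float:
    f, p = signal.welch(x, fs=fs, nperseg=min(len(x), int(8 * fs)))
    tot = float(np.sum(p))
    return float(np.sum(p[f < f_edge]) / tot) if tot > 0 else 0.0


def ica_autoclean(
    rec: EEGRecording,
    ecg: np.ndarray | None = None,
    corr_thresh: float = 0.3,
    lowfreq_frac_thresh: float = 0.6,
    seed: int = 0,
    fit_stride: int = 2,
) -> EEGRecording:
    """Automated ICA cleanup: remove ECG-correlated and drift components.

    A full-rank FastICA decomposition of the scalp channels is fit on a
    temporally strided subsample (the square mixing matrix makes the
    reconstruction exact regardless); components whose absolute correlation
    with the ECG exceeds ``corr_thresh`` or whose spectral power fraction
    below 2 Hz exceeds ``lowfreq_frac_thresh`` are zeroed. Decomposition
    failure skips the stage with a warning.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    eeg_idx = rec.eeg_channel_indices()
    if len(eeg_idx) < 2:
        raise ValueError("ICA requires at least 2 scalp channels")
    if ecg is None and ECG_LABEL in rec.channel_labels:
        ecg = rec.get_channel(ECG_LABEL)
    X = rec.data[eeg_idx].T  # (n_samples, n_ch)
    try:
        ica = FastICA(n_components=len(eeg_idx), random_state=seed,
                      max_iter=500, tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            ica.fit(X[::fit_stride])
            S = ica.transform(X)
        if not np.all(np.isfinite(S)):
            raise np.linalg.LinAlgError("non-finite sources")
    except Exception as exc:  # decomposition failure -> skip stage
        warnings.warn(f"ICA decomposition failed ({exc}); stage skipped",
                      RuntimeWarning)
        return rec._evolve(rec.data.copy(), "ica_autoclean", removed=[],
                           skipped=True)
    removed = []
    for k in range(S.shape[1]):
        comp = S[:, k]
        if ecg is not None and np.std(comp) > 0 and np.std(ecg) > 0:
            r = float(np.corrcoef(comp, ecg)[0, 1])
            if abs(r) > corr_thresh:
                removed.append(k)
                continue
        if _lowfreq_fraction(comp, rec.fs) > lowfreq_frac_thresh:
            removed.append(k)
    S_clean = S.copy()
    S_clean[:, removed] = 0.0
    X_clean = ica.inverse_transform(S_clean)
    data = rec.data.copy()
    data[eeg_idx] = X_clean.T
    return rec._evolve(data, "ica_autoclean", removed=removed, skipped=False)


# ---------------------------------------------------------------------------
# artifact marking


def mark_artifacts(
    series: np.ndarray,
    fs: float,
    z_thresh: float = 4.0,
    min_dur: float = 1.0,
    rms_window: float = 0.2,
    merge_gap: float = 0.5,
) -> ArtifactMask:
    """Mark high-amplitude intervals from a robust z-score of a moving RMS.

    The moving-RMS series is standardized with median/MAD (so a large burst
    does not inflate its own detection threshold); a sample is suprathreshold
    when its robust z exceeds ``z_thresh`` and its RMS also exceeds 1.5x the
    median RMS (guards against false alarms on homogeneous signals).
    Intervals closer than ``merge_gap`` seconds are merged; intervals of at
    least ``min_dur`` seconds are flagged for the fMRI nuisance regressor.
    """
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        raise ValueError("series must be finite")
    duration = len(series) / fs
    w = max(1, int(round(rms_window * fs)))
    from scipy.ndimage import uniform_filter1d

    rms = np.sqrt(uniform_filter1d(series**2, size=w, mode="nearest"))
    med = np.median(rms)
    scale = 1.4826 * np.median(np.abs(rms - med))
    if scale == 0:
        return ArtifactMask([], duration, [])
    z = (rms - med) / scale
    above = (z > z_thresh) & (rms > 1.5 * med)
    if not np.any(above):
        return ArtifactMask([], duration, [])
    padded = np.concatenate([[0], above.astype(int), [0]])
    d = np.diff(padded)
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)
    intervals = [(s / fs, e / fs) for s, e in zip(run_starts, run_ends)]
    merged: list[list[float]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    ivs = [(s, min(e, duration)) for s, e in merged]
    flags = [(e - s) >= min_dur for s, e in ivs]
    return ArtifactMask(ivs, duration, flags)


# ---------------------------------------------------------------------------
# re-reference / pooling


def rereference_common_average(rec: EEGRecording) -> EEGRecording:
    """Re-reference scalp channels to their instantaneous common average.

    The ECG channel is excluded from the average and left untouched. After
    the operation the scalp channels sum to zero at every sample.
    """
    eeg_idx = rec.eeg_channel_indices()
    if len(eeg_idx) < 2:
        raise ValueError("common-average reference requires >= 2 scalp channels")
    data = rec.data.copy()
    avg = data[eeg_idx].mean(axis=0)
    data[eeg_idx] -= avg
    return rec._evolve(data, "rereference_common_average")


def pool_occipital(
    rec: EEGRecording, channels: tuple[str, ...] = OCCIPITAL_CHANNELS
) -> np.ndarray:
    """Sample-wise arithmetic mean of the occipital channels of interest."""
    rows = []
    for ch in channels:
        if ch not in rec.channel_labels:
            raise KeyError(f"channel {ch} not found")
        rows.append(rec.get_channel(ch))
    return np.mean(rows, axis=0)
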