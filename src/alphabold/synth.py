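"""Synthetic simultaneous EEG-fMRI cohorts with known alpha/BOLD coupling.

Every downstream stage of the pipeline is validated against data from this
generator, which emulates a 32-channel 5 kHz EEG recorded inside the scanner
during ~7.5 min of eyes-closed rest together with the concurrently acquired
BOLD series (TR 2.6 s, small common-space voxel grid):

* a stochastically fluctuating occipital alpha source: a rectified AR(1)
  amplitude envelope modulating a sinusoidal carrier, projected to the scalp
  through a fixed occipital-dominant topography;
* white plus pink background noise per channel;
* a TR-periodic gradient artifact with per-volume scanner markers;
* an R-peak-locked ballistocardiogram artifact plus an ECG channel, with
  configurable heart-rate variability;
* a BOLD series in which designated voxels carry the HRF-convolved,
  standardized envelope with group-dependent signed coupling, over a
  baseline with slow drift and Gaussian noise.

The exported ground truth (envelope, coupling maps, artifact templates,
R-peak and volume times) suffices to compute every recovery metric without
re-simulation. The whole cohort is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .eeg import ECG_LABEL, EEGRecording
from .fmri import BOLDSeries
from .regressors import canonical_hrf

# 32-channel 10-20 montage (the scalp layout of a standard MR-compatible cap)
MONTAGE_32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)

# fixed occipital-dominant projection of the alpha source
ALPHA_TOPOGRAPHY = {
    "O1": 1.0, "O2": 1.0, "Oz": 1.0,
    "PO9": 0.7, "PO10": 0.7,
    "P7": 0.4, "P3": 0.4, "Pz": 0.4, "P4": 0.4, "P8": 0.4,
    "TP9": 0.2, "CP5": 0.2, "CP1": 0.2, "CP2": 0.2, "CP6": 0.2, "TP10": 0.2,
}
_DEFAULT_ALPHA_WEIGHT = 0.05

SCANNER_MARKER = "Scanner"

# Table-1-style covariate generating distributions (mean, sd) per group
DEFAULT_COVARIATE_PARAMS = {
    "AD": {"age": (75.3, 5.7), "education": (14.4, 2.7),
           "hippo_norm": (0.0042, 0.0008), "p_male": 10 / 14},
    "HC": {"age": (73.4, 3.1), "education": (13.6, 2.8),
           "hippo_norm": (0.0048, 0.0008), "p_male": 10 / 14},
}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_channels: int = 32
    fs_eeg: float = 5000.0
    duration: float = 468.0  # s (7.5 min + ramp to an integer volume count)
    tr: float = 2.6
    n_volumes: int = 180
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size: float = 3.5  # mm
    alpha_center: float = 10.0  # Hz
    alpha_phase_diffusion: float = 2.0  # rad/sqrt(s); spectral linewidth of the source
    envelope_fs: float = 20.0
    envelope_ar_coeff: float = 0.98
    envelope_mean: float = 20.0  # µV
    envelope_sd: float = 10.0  # µV
    gradient_amplitude: float = 1000.0  # µV
    gradient_jitter: float = 0.0  # fractional per-epoch amplitude jitter
    bcg_amplitude: float = 50.0  # µV
    bcg_delay: float = 0.21  # s after the R-peak
    heart_rate: float = 60.0  # bpm
    rr_jitter: float = 0.03  # fractional RR-interval variability
    noise_sd_eeg: float = 5.0  # µV, each of the white and pink components
    baseline_bold: float = 1000.0
    noise_sd_bold: float = 0.01  # fraction of baseline
    drift_amplitude: float = 0.01  # fraction of baseline
    drift_period: float = 300.0  # s
    coupling_maps: dict = field(default_factory=dict)  # group -> ndarray
    group_sizes: dict = field(default_factory=lambda: {"AD": 14, "HC": 14})
    covariate_params: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in
                                 DEFAULT_COVARIATE_PARAMS.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gradient_amplitude", "bcg_amplitude", "noise_sd_eeg",
                     "noise_sd_bold", "drift_amplitude", "envelope_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if not (0 <= self.envelope_ar_coeff < 1):
            raise ValueError("envelope_ar_coeff must be in [0, 1)")
        for g, m in self.coupling_maps.items():
            if np.asarray(m).shape != tuple(self.grid_shape):
                raise ValueError(f"coupling map for {g!r} does not match grid_shape")

    @property
    def n_markers(self) -> int:
        """Volumes acquired within the EEG recording window."""
        return min(self.n_volumes, int(np.floor(self.duration / self.tr + 1e-9)))

    def volume_onsets(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr


@dataclass
class GroundTruth:
    envelope: np.ndarray  # amplitude at envelope_fs, µV
    envelope_fs: float
    coupling_map: np.ndarray | None
    gradient_template: np.ndarray | None = None
    bcg_template: np.ndarray | None = None
    r_peak_times: np.ndarray | None = None
    volume_onsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.envelope < 0):
            raise ValueError("envelope must be non-negative")
        if self.r_peak_times is not None and len(self.r_peak_times) > 1:
            if not np.all(np.diff(self.r_peak_times) > 0):
                raise ValueError("r_peak_times must be strictly increasing")


@dataclass
class Subject:
    subject_id: str
    group: str
    eeg: EEGRecording | None
    bold: BOLDSeries | None
    truth: GroundTruth


@dataclass
class CohortDataset:
    subjects: list[Subject]
    covariates: "object"  # pandas DataFrame, one row per subject

    def by_group(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]


# ---------------------------------------------------------------------------
# envelope


def generate_envelope(
    duration: float,
    fs_env: float,
    ar_coeff: float,
    mean: float,
    sd: float,
    seed: int,
) -> np.ndarray:
    """Rectified AR(1) amplitude envelope.

    A stationary AR(1) Gaussian process with lag-1 autocorrelation
    ``ar_coeff`` and marginal standard deviation ``sd`` is added to ``mean``
    and rectified at zero. Identical seeds give bitwise-identical output.
    """
    for name, v in (("duration", duration), ("ar_coeff", ar_coeff),
                    ("mean", mean), ("sd", sd)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if fs_env <= 0:
        raise ValueError("fs_env must be positive")
    if not (0 <= ar_coeff < 1):
        raise ValueError("ar_coeff must be in [0, 1)")
    if mean <= 0:
        raise ValueError("mean must be positive")
    n = int(round(duration * fs_env))
    if sd == 0:
        return np.full(n, float(mean))
    rng = np.random.default_rng(seed)
    innov = rng.standard_normal(n) * sd * np.sqrt(1.0 - ar_coeff**2)
    x0 = rng.standard_normal() * sd  # stationary start
    x = signal.lfilter([1.0], [1.0, -ar_coeff], innov, zi=[ar_coeff * x0])[0]
    return np.maximum(mean + x, 0.0)


def _pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise with marginal standard deviation ``sd``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n)
    s = pink.std()
    return pink * (sd / s) if s > 0 else pink


def gradient_template(config: SimConfig) -> np.ndarray:
    """Deterministic TR-periodic gradient-artifact waveform (one epoch).

    A fast sawtooth (sub-TR period) plus a higher harmonic, so the raw
    spectrum carries energy at many multiples of 1/TR including the EEG
    bands of interest.
    """
    n = int(round(config.tr * config.fs_eeg))
    t = np.arange(n) / config.fs_eeg
    saw = signal.sawtooth(2 * np.pi * (10.0 / config.tr) * t)
    harm = 0.4 * np.sin(2 * np.pi * (17.0 / config.tr) * t)
    return config.gradient_amplitude * (saw + harm)


def bcg_template(config: SimConfig) -> np.ndarray:
    """Damped-oscillation pulse-artifact waveform (0.5 s, starts at the
    configured delay after each R-peak)."""
    n = int(round(0.5 * config.fs_eeg))
    t = np.arange(n) / config.fs_eeg
    return config.bcg_amplitude * np.exp(-t / 0.15) * np.sin(2 * np.pi * 7.0 * t)


def _ecg_waveform(fs: float) -> np.ndarray:
    """Stylized PQRST complex (0.4 s) peaking at its R wave (index 0.1 s)."""
    t = np.arange(int(0.4 * fs)) / fs
    r = 800.0 * np.exp(-((t - 0.1) / 0.012) ** 2)
    q = -150.0 * np.exp(-((t - 0.08) / 0.01) ** 2)
    s = -200.0 * np.exp(-((t - 0.12) / 0.01) ** 2)
    tw = 150.0 * np.exp(-((t - 0.3) / 0.05) ** 2)
    return r + q + s + tw


def _r_peak_times(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    rr_mean = 60.0 / config.heart_rate
    times = []
    t = 0.5 + rng.uniform(0, rr_mean / 4)
    while t < config.duration - 0.6:
        times.append(t)
        t += rr_mean * max(0.2, 1.0 + config.rr_jitter * rng.standard_normal())
    return np.asarray(times)


def simulate_eeg(
    envelope: np.ndarray,
    config: SimConfig,
    seed: int,
) -> tuple[EEGRecording, GroundTruth]:
    """Synthesize the in-scanner EEG recording for one subject.

    The occipital channels carry the envelope-modulated alpha oscillation
    through the fixed topography; every channel receives white and pink
    noise, the TR-locked gradient artifact (with per-volume markers) and the
    R-peak-locked pulse artifact; an ECG channel is appended.
    """
    labels = list(MONTAGE_32[: config.n_channels])
    missing = [c for c in ("O1", "O2", "Oz") if c not in labels]
    if missing:
        raise ValueError(f"montage lacks occipital channels: {missing}")
    n = int(round(config.duration * config.fs_eeg))
    env_t = np.arange(len(envelope)) / config.envelope_fs
    if env_t[-1] < config.duration - 1.0 / config.envelope_fs - 1e-9:
        raise ValueError("envelope shorter than requested duration")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / config.fs_eeg
    env_up = np.interp(t, env_t, envelope)
    # finite-linewidth oscillation: spontaneous alpha is not phase-coherent
    # over minutes (and must not be phase-locked to the TR grid)
    phase = 2 * np.pi * config.alpha_center * t + rng.uniform(0, 2 * np.pi)
    if config.alpha_phase_diffusion > 0:
        dphi = (config.alpha_phase_diffusion / np.sqrt(config.fs_eeg)
                * rng.standard_normal(n))
        phase = phase + np.cumsum(dphi)
    alpha_sig = env_up * np.sin(phase)
    del env_up, phase

    grad = gradient_template(config)
    bcg = bcg_template(config)
    r_times = _r_peak_times(config, rng)
    n_markers = config.n_markers
    marker_samples = (np.arange(n_markers) * config.tr * config.fs_eeg).round().astype(int)

    data = np.empty((config.n_channels + 1, n))
    bcg_starts = np.round((r_times + config.bcg_delay) * config.fs_eeg).astype(int)
    bcg_starts = bcg_starts[bcg_starts + len(bcg) <= n]
    # per-channel BCG weights: smooth deterministic front-to-back gradient
    bcg_w = np.linspace(0.4, 1.0, config.n_channels)
    for i, ch in enumerate(labels):
        w = ALPHA_TOPOGRAPHY.get(ch, _DEFAULT_ALPHA_WEIGHT)
        row = w * alpha_sig
        if config.noise_sd_eeg > 0:
            row = row + rng.standard_normal(n) * config.noise_sd_eeg
            row += _pink_noise(n, config.noise_sd_eeg, rng)
        if config.gradient_amplitude > 0:
            for k, s in enumerate(marker_samples):
                amp = 1.0
                if config.gradient_jitter > 0:
                    amp += config.gradient_jitter * rng.standard_normal()
                e = min(n, s + len(grad))
                row[s:e] += amp * grad[: e - s]
        if config.bcg_amplitude > 0:
            for s in bcg_starts:
                row[s : s + len(bcg)] += bcg_w[i] * bcg
        data[i] = row
    # ECG channel
    ecg = np.zeros(n)
    wave = _ecg_waveform(config.fs_eeg)
    r_idx = np.round(r_times * config.fs_eeg).astype(int)
    for ridx in r_idx:
        s = ridx - int(0.1 * config.fs_eeg)
        e = min(n, s + len(wave))
        if s >= 0:
            ecg[s:e] += wave[: e - s]
    ecg += rng.standard_normal(n) * 10.0
    data[-1] = ecg
    labels.append(ECG_LABEL)

    markers = [(k * config.tr, SCANNER_MARKER, f"V{k + 1}")
               for k in range(n_markers)]
    rec = EEGRecording(data=data, fs=config.fs_eeg, channel_labels=labels,
                       markers=markers)
    truth = GroundTruth(envelope=np.asarray(envelope, dtype=float),
                        envelope_fs=config.envelope_fs,
                        coupling_map=None,
                        gradient_template=grad, bcg_template=bcg,
                        r_peak_times=r_times,
                        volume_onsets=config.volume_onsets()[:n_markers])
    return rec, truth


# ---------------------------------------------------------------------------
# BOLD


def envelope_bold_predictor(envelope: np.ndarray, config: SimConfig) -> np.ndarray:
    """Standardized HRF-convolved envelope sampled at the volume onsets.

    The envelope is averaged into one-second bins, convolved with the
    canonical HRF at 1 Hz, linearly interpolated at each volume onset and
    z-scored. This is the true coupling time course carried by coupled
    voxels.
    """
    fs = config.envelope_fs
    n_sec = int(np.floor(len(envelope) / fs))
    per_sec = np.asarray(envelope[: int(n_sec * fs)], dtype=float).reshape(
        n_sec, int(fs)).mean(axis=1)
    kernel = canonical_hrf(dt=1.0).samples
    conv = np.convolve(per_sec, kernel)[:n_sec]
    onsets = config.volume_onsets()
    pred = np.interp(onsets, np.arange(n_sec, dtype=float), conv)
    sd = pred.std()
    return (pred - pred.mean()) / sd if sd > 0 else pred - pred.mean()


def simulate_bold(
    envelope: np.ndarray,
    coupling_map: np.ndarray,
    config: SimConfig,
    seed: int,
) -> BOLDSeries:
    """BOLD series with voxel-wise signed coupling to the alpha envelope.

    ``voxel(t) = baseline * (1 + coupling * z(t)) + drift + noise`` where
    ``z`` is the standardized HRF-convolved envelope at the volume onsets;
    negative coupling values yield anti-correlated voxels.
    """
    coupling = np.asarray(coupling_map, dtype=float)
    if coupling.shape != tuple(config.grid_shape):
        raise ValueError("coupling_map does not match grid_shape")
    if not np.all(np.isfinite(coupling)):
        raise ValueError("coupling_map must be finite")
    if config.n_volumes <= 6:
        raise ValueError("n_volumes must exceed the dropped saturation volumes")
    rng = np.random.default_rng(seed)
    z = envelope_bold_predictor(envelope, config)
    onsets = config.volume_onsets()
    base = config.baseline_bold
    nx, ny, nz = config.grid_shape
    nt = config.n_volumes
    data = base * (1.0 + coupling[..., None] * z[None, None, None, :])
    if config.drift_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=config.grid_shape)
        drift = config.drift_amplitude * base * np.cos(
            2 * np.pi * onsets[None, None, None, :] / config.drift_period
            + phases[..., None]
        )
        data = data + drift
    if config.noise_sd_bold > 0:
        data = data + rng.standard_normal((nx, ny, nz, nt)) * (
            config.noise_sd_bold * base)
    affine = np.diag([config.voxel_size] * 3 + [1.0])
    return BOLDSeries(data=data, voxel_size=config.voxel_size, tr=config.tr,
                      volume_onsets=onsets, affine=affine)


# ---------------------------------------------------------------------------
# cohort


def _subject_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _draw_covariates(config: SimConfig, seed: int):
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for group, size in config.group_sizes.items():
        params = config.covariate_params[group]
        for i in range(size):
            rows.append(dict(
                subject_id=f"{group}{i + 1:02d}",
                group=group,
                age=float(rng.normal(*params["age"])),
                gender=int(rng.random() < params["p_male"]),
                education=float(rng.normal(*params["education"])),
                hippo_norm=float(abs(rng.normal(*params["hippo_norm"]))),
            ))
    return pd.DataFrame(rows)


def simulate_subject(
    config: SimConfig,
    group: str,
    subject_id: str,
    seed: int,
    include_eeg: bool = True,
) -> Subject:
    """One subject's recording pair plus ground truth, from a single seed."""
    ss = np.random.SeedSequence(seed)
    s_env, s_eeg, s_bold = [int(s.generate_state(1)[0] % (2**31))
                            for s in ss.spawn(3)]
    envelope = generate_envelope(config.duration, config.envelope_fs,
                                 config.envelope_ar_coeff, config.envelope_mean,
                                 config.envelope_sd, s_env)
    coupling = config.coupling_maps.get(group)
    if coupling is None:
        coupling = np.zeros(config.grid_shape)
    bold = simulate_bold(envelope, coupling, config, s_bold)
    if include_eeg:
        eeg, truth = simulate_eeg(envelope, config, s_eeg)
        truth.coupling_map = np.asarray(coupling, dtype=float)
    else:
        eeg = None
        truth = GroundTruth(envelope=envelope, envelope_fs=config.envelope_fs,
                            coupling_map=np.asarray(coupling, dtype=float),
                            volume_onsets=config.volume_onsets())
    return Subject(subject_id=subject_id, group=group, eeg=eeg, bold=bold,
                   truth=truth)


def cohort_plan(config: SimConfig, seed: int) -> list[tuple[str, str, int]]:
    """Deterministic (subject_id, group, subject_seed) schedule for a cohort.

    Lets callers materialize subjects one at a time (the full-rate EEG of a
    whole cohort would not fit in memory at once).
    """
    for g, size in config.group_sizes.items():
        if size < 2:
            raise ValueError(f"group {g!r} must have at least 2 subjects")
    ids = [(f"{g}{i + 1:02d}", g)
           for g in config.group_sizes for i in range(config.group_sizes[g])]
    seeds = _subject_seeds(seed, len(ids) + 1)
    return [(sid, g, s) for (sid, g), s in zip(ids, seeds[1:])]


def cohort_covariates(config: SimConfig, seed: int):
    """Covariate table for the cohort defined by (config, seed)."""
    cov_seed = _subject_seeds(seed, 1)[0]
    return _draw_covariates(config, cov_seed)


def simulate_cohort(
    config: SimConfig, seed: int, include_eeg: bool = True
) -> CohortDataset:
    """Materialize the full cohort (use :func:`cohort_plan` + per-subject
    simulation for cohorts too large to hold in memory)."""
    plan = cohort_plan(config, seed)
    covariates = cohort_covariates(config, seed)
    subjects = [simulate_subject(config, g, sid, s, include_eeg=include_eeg)
                for sid, g, s in plan]
    return CohortDataset(subjects=subjects, covariates=covariates)


# ---------------------------------------------------------------------------
# demonstration study


def demo_regions(grid_shape=(20, 20, 20)) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth coupling regions of the bundled demonstration cohort:
    region A (positive coupling in controls) and region B (negative)."""
    a = np.zeros(grid_shape, dtype=bool)
    b = np.zeros(grid_shape, dtype=bool)
    a[4:9, 4:9, 4:9] = True
    b[12:17, 12:17, 12:17] = True
    return a, b


def demo_config(
    n_per_group: int = 8,
    coupling_strength: float = 0.02,
    **overrides,
) -> SimConfig:
    """Demonstration study: controls carry positive coupling in region A and
    negative coupling in region B; the patient group carries none."""
    grid = overrides.pop("grid_shape", (20, 20, 20))
    region_a, region_b = demo_regions(grid)
    hc_map = np.zeros(grid)
    hc_map[region_a] = coupling_strength
    hc_map[region_b] = -coupling_strength
    ad_map = np.zeros(grid)
    return SimConfig(
        grid_shape=grid,
        coupling_maps={"HC": hc_map, "AD": ad_map},
        group_sizes={"AD": n_per_group, "HC": n_per_group},
        **overrides,
    )
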