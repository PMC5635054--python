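"""Volume-grid predictors for the voxel-wise GLM.

The alpha-power regressor is the one-second band-power series, cleaned of
invalid segments by linear interpolation, mean-centered, convolved with the
canonical double-gamma hemodynamic response function, and sampled at the
retained volume onsets. The artifact nuisance regressor is the per-volume
overlap fraction with flagged (>= 1 s) artifact intervals and is not
convolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .bandpower import PowerSeries
from .eeg import ArtifactMask


@dataclass
class HRFKernel:
    """Canonical HRF sampled at resolution ``dt``: difference of two gamma
    densities (peak shape a1=6, undershoot shape a2=16, unit scales,
    undershoot ratio 1/6), normalized to unit peak, 32 s support."""

    samples: np.ndarray
    dt: float
    params: dict = field(default_factory=dict)

    def at_rate(self, rate: float) -> np.ndarray:
        """Kernel resampled (linear interpolation) onto a ``1/rate`` s grid."""
        t_src = np.arange(len(self.samples)) * self.dt
        t_new = np.arange(0.0, t_src[-1] + 1e-9, 1.0 / rate)
        return np.interp(t_new, t_src, self.samples)


@dataclass
class Regressor:
    """Predictor values on the retained volume grid."""

    values: np.ndarray
    label: str
    volume_onsets: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.volume_onsets = np.asarray(self.volume_onsets, dtype=float)
        if len(self.values) != len(self.volume_onsets):
            raise ValueError("one value per retained volume required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("regressor values must be finite")


def canonical_hrf(
    dt: float = 0.1,
    a1: float = 6.0,
    a2: float = 16.0,
    b1: float = 1.0,
    b2: float = 1.0,
    c: float = 1.0 / 6.0,
    length: float = 32.0,
) -> HRFKernel:
    """Canonical double-gamma HRF, peak-normalized to 1.

    ``h(t) = Gamma(a1, b1).pdf(t) - c * Gamma(a2, b2).pdf(t)``; with the
    defaults the response peaks near 5 s and undershoots near 15 s.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if min(a1, a2, b1, b2) <= 0:
        raise ValueError("gamma shape/scale parameters must be positive")
    t = np.arange(0.0, length + dt / 2, dt)
    h = stats.gamma.pdf(t, a1, scale=b1) - c * stats.gamma.pdf(t, a2, scale=b2)
    peak = np.max(h)
    if peak <= 0:
        raise ValueError("degenerate HRF: no positive lobe")
    h = h / peak
    return HRFKernel(samples=h, dt=dt,
                     params=dict(a1=a1, a2=a2, b1=b1, b2=b2, c=c, length=length))


def _interpolate_invalid(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    if not np.any(valid):
        raise ValueError("all power segments are invalid")
    if np.all(valid):
        return values.copy()
    idx = np.arange(len(values))
    return np.interp(idx, idx[valid], values[valid])


def build_alpha_regressor(
    ps: PowerSeries,
    hrf: HRFKernel,
    volume_onsets: np.ndarray,
    drop_k: int = 6,
    center: bool = True,
) -> Regressor:
    """HRF-convolved alpha-power regressor sampled at retained volume onsets.

    Invalid one-second segments are linearly interpolated from their nearest
    valid neighbors, the series is mean-centered, convolved with the HRF on
    the power-series grid, and evaluated at each retained volume onset by
    linear interpolation. The first ``drop_k`` volumes are excluded to match
    the dropped saturation volumes.
    """
    volume_onsets = np.asarray(volume_onsets, dtype=float)
    retained = volume_onsets[drop_k:]
    times = ps.times
    if retained.size and (retained[0] < times[0] - 1e-9 or retained[-1] > times[-1] + 1e-9):
        raise ValueError("volume onset outside power series span")
    v = _interpolate_invalid(ps.values, ps.valid)
    if center:
        v = v - v.mean()
    kernel = hrf.at_rate(ps.rate)
    conv = np.convolve(v, kernel)[: len(v)]
    reg = np.interp(retained, times, conv)
    return Regressor(values=reg, label=f"alpha_{ps.band.name}",
                     volume_onsets=retained)


def build_artifact_regressor(
    mask: ArtifactMask,
    volume_onsets: np.ndarray,
    tr: float,
    drop_k: int = 6,
) -> Regressor:
    """Unconvolved nuisance regressor: per-volume fraction of the acquisition
    window ``[onset, onset + tr)`` overlapped by flagged artifact intervals."""
    volume_onsets = np.asarray(volume_onsets, dtype=float)
    retained = volume_onsets[drop_k:]
    values = np.zeros(len(retained))
    for i, onset in enumerate(retained):
        lo, hi = onset, onset + tr
        overlap = 0.0
        for s, e in mask.flagged_intervals():
            overlap += max(0.0, min(e, hi) - max(s, lo))
        values[i] = overlap / tr
    return Regressor(values=values, label="artifact", volume_onsets=retained)
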