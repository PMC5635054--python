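"""Minimal volume-domain BOLD preprocessing on a common voxel grid.

Initial saturation volumes are dropped, each volume is smoothed with a 3D
Gaussian kernel specified by its FWHM in millimeters, and slow drifts are
removed by projecting each voxel time course onto the complement of a
discrete-cosine basis spanning periods of at least the cutoff (128 s by
default) — the idempotent high-pass used throughout fMRI analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BOLDSeries:
    """4D BOLD image: spatial grid × time.

    ``volume_onsets`` are absolute acquisition times (s) so regressors built
    on the EEG clock stay aligned after volume dropping.
    """

    data: np.ndarray  # (x, y, z, t)
    voxel_size: float  # mm, isotropic
    tr: float
    volume_onsets: np.ndarray
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("at least two volumes required")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.volume_onsets = np.asarray(self.volume_onsets, dtype=float)
        if len(self.volume_onsets) != self.data.shape[3]:
            raise ValueError("one onset per volume required")
        steps = np.diff(self.volume_onsets)
        if steps.size and not np.allclose(steps, self.tr, atol=1e-6):
            raise ValueError("volume onsets must be arithmetic with step tr")
        if self.affine is None:
            self.affine = np.diag([self.voxel_size] * 3 + [1.0])

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def drop_initial_volumes(bold: BOLDSeries, k: int = 6) -> BOLDSeries:
    """Remove the first ``k`` volumes (scanner saturation)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= bold.n_volumes:
        raise ValueError(f"cannot drop {k} of {bold.n_volumes} volumes")
    return replace(bold, data=bold.data[..., k:],
                   volume_onsets=bold.volume_onsets[k:])


def gaussian_smooth(bold: BOLDSeries, fwhm_mm: float = 8.0) -> BOLDSeries:
    """Per-volume 3D Gaussian smoothing with the given FWHM in mm.

    Boundary handling is nearest-edge replication, so spatially uniform
    volumes are unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return replace(bold, data=bold.data.copy(),
                       volume_onsets=bold.volume_onsets.copy())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / bold.voxel_size
    data = ndimage.gaussian_filter(bold.data, sigma=(sigma_vox,) * 3 + (0,),
                                   mode="nearest")
    return replace(bold, data=data, volume_onsets=bold.volume_onsets.copy())


def dct_highpass_basis(n: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Orthonormal drift basis over ``n`` samples spaced ``tr`` apart.

    Constant, linear ramp (so a pure linear drift is removed exactly, which
    truncated cosines alone only approximate) and the DCT-II components with
    period >= ``cutoff_s``.
    """
    k_max = int(np.floor(2.0 * n * tr / cutoff_s))
    t = np.arange(n)
    cols = [np.ones(n), t - t.mean()]
    for k in range(1, k_max + 1):
        cols.append(np.cos(np.pi * k * (t + 0.5) / n))
    q, _ = np.linalg.qr(np.column_stack(cols))
    return q


def highpass_time(x, tr: float, cutoff_s: float = 128.0):
    """Remove drift components with period >= ``cutoff_s`` (and the mean).

    Accepts a :class:`BOLDSeries` (filtered along time) or any array whose
    last axis is time. Implemented as an exact projection, hence idempotent.
    """
    if isinstance(x, BOLDSeries):
        filt = highpass_time(x.data, x.tr, cutoff_s)
        return replace(x, data=filt, volume_onsets=x.volume_onsets.copy())
    arr = np.asarray(x, dtype=float)
    n = arr.shape[-1]
    if n < 3:
        raise ValueError("series must have at least 3 samples")
    if cutoff_s <= 2 * tr:
        raise ValueError("cutoff period must exceed 2 * tr")
    basis = dct_highpass_basis(n, tr, cutoff_s)
    flat = arr.reshape(-1, n)
    coeffs = flat @ basis  # orthonormal basis: projection by inner product
    return (flat - coeffs @ basis.T).reshape(arr.shape)
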