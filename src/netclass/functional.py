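"""Raw functional metrics and ROI-to-ROI functional connectivity.

Implements the voxel-level resting-state measures — band-pass filtering,
low-frequency amplitude (ALFF) and its fractional version (fALFF), global
and local correlation maps (GCOR/LCOR) — and the Fisher-z ROI-to-ROI
connectivity matrix.  Filtering is done with an FFT mask (out-of-band
Fourier coefficients zeroed), which makes the attenuation exactly testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BandSpec",
    "TimeSeriesGrid",
    "bandpass_filter",
    "amplitude_metrics",
    "correlation_metrics",
    "roi_connectivity",
]

DEFAULT_BAND = (0.001, 0.09)
#: Pearson r is clipped at 1 - ATANH_EPS before the Fisher transform so that
#: degenerate (perfectly correlated) synthetic inputs stay finite.
ATANH_EPS = 1e-12


@dataclass(frozen=True)
class BandSpec:
    """Frequency band in Hz; must satisfy 0 <= low < high <= Nyquist."""

    low_hz: float = DEFAULT_BAND[0]
    high_hz: float = DEFAULT_BAND[1]

    def validate(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError(f"band: need 0 <= low < high, got ({self.low_hz}, {self.high_hz})")
        if self.high_hz > nyquist + 1e-12:
            raise ValueError(
                f"band: high edge {self.high_hz} Hz exceeds Nyquist {nyquist} Hz for TR {tr_seconds}s"
            )


@dataclass
class TimeSeriesGrid:
    """Voxel time series on a 3D grid: ``data`` is time x n_voxels in C order
    of ``grid_dims``; ``voxel_size_mm`` gives the physical spacing."""

    data: np.ndarray
    grid_dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("TimeSeriesGrid: data must be time x voxels with >= 2 timepoints")
        if self.data.shape[1] != int(np.prod(self.grid_dims)):
            raise ValueError("TimeSeriesGrid: data columns must match prod(grid_dims)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("TimeSeriesGrid: data must be finite")

    def coordinates_mm(self) -> np.ndarray:
        """(n_voxels, 3) physical coordinates of voxel centers."""
        grids = np.meshgrid(*[np.arange(d) for d in self.grid_dims], indexing="ij")
        coords = np.stack([g.ravel() for g in grids], axis=1).astype(float)
        return coords * np.asarray(self.voxel_size_mm)


def bandpass_filter(
    ts: np.ndarray, band: BandSpec | tuple[float, float], tr_seconds: float
) -> np.ndarray:
    """Band-pass a time x (anything) array by zeroing out-of-band rFFT bins.

    Frequencies f with ``low <= f <= high`` are kept untouched; all others
    (including DC when ``low > 0``) are removed exactly.
    """
    if not isinstance(band, BandSpec):
        band = BandSpec(*band)
    band.validate(tr_seconds)
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    keep = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    spec = np.fft.rfft(ts, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=0)


def amplitude_metrics(
    ts: np.ndarray, band: BandSpec | tuple[float, float], tr_seconds: float
) -> tuple[np.ndarray, np.ndarray]:
    """ALFF and fALFF of one or more voxel time series.

    ALFF is the root-mean-square of the band-passed series; fALFF is the
    ratio of that RMS to the RMS of the unfiltered series (0 where the
    unfiltered RMS is 0).  Input may be 1D (one voxel) or time x voxels.
    """
    ts = np.asarray(ts, dtype=float)
    squeeze = ts.ndim == 1
    if squeeze:
        ts = ts[:, None]
    if ts.shape[0] < 2:
        raise ValueError("amplitude_metrics: need >= 2 timepoints")
    filtered = bandpass_filter(ts, band, tr_seconds)
    rms = lambda x: np.sqrt(np.mean(x**2, axis=0))
    alff = rms(filtered)
    total = rms(ts)
    falff = np.divide(alff, total, out=np.zeros_like(alff), where=total > 0)
    if squeeze:
        return float(alff[0]), float(falff[0])
    return alff, falff


def _correlation_matrix(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlations between columns; zero-variance columns yield 0."""
    centered = data - data.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    degenerate = norms == 0
    safe = np.where(degenerate, 1.0, norms)
    unit = centered / safe
    corr = unit.T @ unit
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr, degenerate


def correlation_metrics(
    grid: TimeSeriesGrid, kernel_mm: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Global (GCOR) and local (LCOR) correlation maps.

    GCOR(v) is the mean Pearson correlation of voxel v with every other
    voxel; LCOR(v) averages over voxels within a Euclidean ball of radius
    ``kernel_mm / 2`` (the kernel size is read as a diameter), excluding v.
    Voxels with an empty neighborhood get LCOR 0 with a warning.
    """
    if kernel_mm <= 0:
        raise ValueError("kernel_mm must be positive")
    n_vox = grid.data.shape[1]
    if n_vox < 2:
        raise ValueError("correlation_metrics: need >= 2 voxels")
    corr, degenerate = _correlation_matrix(grid.data)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance voxels; their correlations set to 0"
        )
    gcor = (corr.sum(axis=1) - np.where(degenerate, 0.0, 1.0)) / (n_vox - 1)

    coords = grid.coordinates_mm()
    radius = kernel_mm / 2.0
    lcor = np.zeros(n_vox)
    empty = 0
    # Neighborhoods share a fixed offset stencil; accumulate by shifted slices.
    dims = grid.grid_dims
    vs = np.asarray(grid.voxel_size_mm)
    max_off = np.minimum(np.floor(radius / vs).astype(int), np.asarray(dims) - 1)
    sums = np.zeros(n_vox)
    counts = np.zeros(n_vox)
    flat = np.arange(n_vox).reshape(dims)

    def shifted(offsets, sign):
        slices = []
        for d, dim in zip(offsets, dims):
            d = sign * d
            slices.append(slice(max(0, -d), dim - max(0, d)))
        return flat[tuple(slices)].ravel()

    for dx in range(-max_off[0], max_off[0] + 1):
        for dy in range(-max_off[1], max_off[1] + 1):
            for dz in range(-max_off[2], max_off[2] + 1):
                if dx == dy == dz == 0:
                    continue
                if (dx * vs[0]) ** 2 + (dy * vs[1]) ** 2 + (dz * vs[2]) ** 2 > radius**2:
                    continue
                src = shifted((dx, dy, dz), +1)
                dst = shifted((dx, dy, dz), -1)
                sums[src] += corr[src, dst]
                counts[src] += 1
    have = counts > 0
    lcor[have] = sums[have] / counts[have]
    empty = int((~have).sum())
    if empty:
        warnings.warn(f"{empty} voxels have no neighbors within {kernel_mm} mm; LCOR set to 0")
    return gcor, lcor


def roi_connectivity(roi_ts: np.ndarray) -> np.ndarray:
    """Fisher-z ROI-to-ROI connectivity matrix from a time x n_roi series.

    Pearson r is clipped to (-1 + eps, 1 - eps) before atanh; the diagonal is
    set to 0; zero-variance ROIs get zero rows/columns with a warning.
    """
    roi_ts = np.asarray(roi_ts, dtype=float)
    if roi_ts.ndim != 2 or roi_ts.shape[1] < 2:
        raise ValueError("roi_connectivity: need a time x n_roi array with n_roi >= 2")
    if roi_ts.shape[0] < 3:
        raise ValueError("roi_connectivity: need >= 3 timepoints")
    corr, degenerate = _correlation_matrix(roi_ts)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance ROIs; their connectivity set to 0"
        )
    z = np.arctanh(np.clip(corr, -1 + ATANH_EPS, 1 - ATANH_EPS))
    z[degenerate, :] = 0.0
    z[:, degenerate] = 0.0
    np.fill_diagonal(z, 0.0)
    return z
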