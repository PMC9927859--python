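"""Per-voxel preprocessing reimplemented from first principles.

Covers the steps of the analysis that act on already-registered data:
linear detrending, temporal high-pass filtering (discrete-cosine drift
projection), Gaussian spatial smoothing, and nuisance regression of the
stimulus silence structure convolved with a canonical double-gamma
hemodynamic response function (HRF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal, stats

from .dataio import DataError, StimulusStructure, TimeSeriesImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF parameters (seconds).

    Defaults are the community-standard values: response peaking near 5-6 s
    with a late undershoot one sixth the peak amplitude.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 1.0 / 6.0
    kernel_length_s: float = 32.0

    def __post_init__(self) -> None:
        vals = (self.peak_delay_s, self.undershoot_delay_s, self.peak_dispersion_s,
                self.undershoot_dispersion_s, self.peak_undershoot_ratio,
                self.kernel_length_s)
        if any(v <= 0 for v in vals):
            raise DataError(f"HRF parameters must be positive: {self}")


def canonical_hrf(tr_s: float, params: HRFParams = HRFParams()) -> np.ndarray:
    """Sample the double-gamma HRF at tr_s resolution, peak-normalized to 1.

    Each gamma is parameterized so its mean delay and dispersion match the
    requested values (shape = delay/dispersion, scale = dispersion).
    """
    if tr_s <= 0:
        raise DataError("tr_s must be positive")
    t = np.arange(0.0, params.kernel_length_s, tr_s)
    peak = stats.gamma.pdf(t, params.peak_delay_s / params.peak_dispersion_s,
                           scale=params.peak_dispersion_s)
    under = stats.gamma.pdf(t, params.undershoot_delay_s / params.undershoot_dispersion_s,
                            scale=params.undershoot_dispersion_s)
    kernel = peak - params.peak_undershoot_ratio * under
    m = kernel.max()
    if not np.isfinite(m) or m <= 0:
        raise DataError("degenerate HRF parameters: kernel has no positive peak")
    return kernel / m


def silence_regressor(stim: StimulusStructure, n_timepoints: int, tr_s: float,
                      hrf_kernel: np.ndarray) -> np.ndarray:
    """HRF-convolved silence indicator sampled at volume acquisition times.

    Volume k covers the half-open interval [k*tr, (k+1)*tr); any overlap
    with a silence interval marks the volume.  Convolution is full linear
    (causal) convolution truncated to n_timepoints.
    """
    if stim.duration_s < n_timepoints * tr_s - tr_s:
        raise DataError(
            f"stimulus duration {stim.duration_s}s too short for "
            f"{n_timepoints} volumes at tr={tr_s}s")
    if not stim.silences:
        logger.warning("stimulus has no silence intervals; regressor is all zero")
        return np.zeros(n_timepoints)
    starts = np.arange(n_timepoints) * tr_s
    ends = starts + tr_s
    indicator = np.zeros(n_timepoints)
    for s, e in stim.silences:
        indicator[(starts < e) & (ends > s)] = 1.0
    return np.convolve(indicator, hrf_kernel)[:n_timepoints]


@dataclass
class NuisanceDesign:
    """Time x k design matrix (intercept + nuisance regressors)."""

    regressors: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=np.float64)
        if self.regressors.ndim != 2:
            raise DataError("design must be 2D (time x regressors)")
        if self.regressors.shape[1] != len(self.labels):
            raise DataError("one label per design column required")

    @classmethod
    def from_silence(cls, reg: np.ndarray) -> "NuisanceDesign":
        T = len(reg)
        return cls(regressors=np.column_stack([np.ones(T), reg]),
                   labels=["intercept", "silence"])


def _check_rank(design: NuisanceDesign) -> None:
    X = design.regressors
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which columns become redundant, in order
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(design.labels[j])
        raise DataError(f"rank-deficient nuisance design; collinear columns: {bad}")


def regress_out(ts: TimeSeriesImage, design: NuisanceDesign) -> TimeSeriesImage:
    """OLS residuals of every voxel time course against the design."""
    T = ts.n_timepoints
    if design.regressors.shape[0] != T:
        raise DataError(
            f"design has {design.regressors.shape[0]} rows but series has T={T}")
    _check_rank(design)
    X = design.regressors
    flat = ts.data.reshape(-1, T).T            # T x n_voxels
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    out = resid.T.reshape(ts.data.shape)
    return replace(ts, data=out)


def linear_detrend(ts: TimeSeriesImage) -> TimeSeriesImage:
    """Remove the per-voxel best-fit line (mean and linear trend)."""
    out = signal.detrend(ts.data, axis=-1, type="linear")
    return replace(ts, data=out)


def dct_drift_basis(n_timepoints: int, tr_s: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine drift columns with frequency below cutoff (no intercept).

    Cosine k has frequency k / (2 * T * tr); all k >= 1 below the cutoff are
    returned.  May be empty when the run is too short to resolve any drift.
    """
    t = np.arange(n_timepoints)
    order = int(np.floor(2.0 * n_timepoints * tr_s * cutoff_hz))
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_timepoints)) for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n_timepoints, 0))


def highpass(ts: TimeSeriesImage, cutoff_hz: float, tr_s: float | None = None) -> TimeSeriesImage:
    """Temporal high-pass by projecting out a discrete-cosine drift basis.

    Deterministic, linear and exactly idempotent; removes the mean and all
    cosine drift components slower than cutoff_hz.
    """
    tr = ts.tr if tr_s is None else tr_s
    nyquist = 0.5 / tr
    if not 0 < cutoff_hz < nyquist:
        raise DataError(f"cutoff {cutoff_hz} Hz outside (0, Nyquist={nyquist:.4g}) Hz")
    T = ts.n_timepoints
    drift = dct_drift_basis(T, tr, cutoff_hz)
    X = np.column_stack([np.ones(T), drift])
    flat = ts.data.reshape(-1, T).T
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    return replace(ts, data=resid.T.reshape(ts.data.shape))


def spatial_smooth(ts: TimeSeriesImage, fwhm_mm: float,
                   voxel_size_mm: tuple[float, float, float] | None = None) -> TimeSeriesImage:
    """Per-volume 3D Gaussian smoothing with the given FWHM in millimetres."""
    if fwhm_mm < 0:
        raise DataError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return replace(ts, data=ts.data.copy())
    vox = ts.voxel_size_mm if voxel_size_mm is None else voxel_size_mm
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / v for v in vox] + [0.0]  # no temporal smoothing
    out = ndimage.gaussian_filter(ts.data, sigma=sigma_vox, mode="reflect")
    return replace(ts, data=out)
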