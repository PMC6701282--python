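"""Spectral core: amplitude spectra, band-ratio fALFF, global z-scoring.

fALFF (fractional amplitude of low-frequency fluctuations) is, per voxel,
the sum of spectral amplitude over a low-frequency band divided by the
sum over the whole positive-frequency spectrum.  Amplitude is the square
root of power, i.e. proportional to the FFT magnitude; the proportionality
constant cancels in the ratio.

Band conventions are half-open ``[lo, hi)``; the DC bin is excluded from
both numerator and denominator and the Nyquist bin is included in the
denominator.  Default bands:

* broadband: 0.01-0.08 Hz
* slow-5:    0.01-0.027 Hz
* slow-4:    0.027-0.07 Hz

With a half-open convention the 0.027 Hz boundary bin, if it falls exactly
on an FFT bin centre, belongs to slow-4 and is never double-counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, half-open ``[lo_hz, hi_hz)``."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.lo_hz < self.hi_hz:
            raise ValueError(f"band {self.name!r}: need 0 < lo < hi, got [{self.lo_hz}, {self.hi_hz})")

    def bin_mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.lo_hz) & (freqs < self.hi_hz)


BROADBAND = BandDefinition("broadband", 0.01, 0.08)
SLOW5 = BandDefinition("slow5", 0.01, 0.027)
SLOW4 = BandDefinition("slow4", 0.027, 0.07)
DEFAULT_BANDS = (BROADBAND, SLOW5, SLOW4)


@dataclass
class FalffMap:
    """Per-subject voxelwise fALFF for one band (raw, optionally z-scored)."""

    raw: np.ndarray
    band: BandDefinition
    mask: np.ndarray
    n_volumes: int
    tr_seconds: float
    zscored: np.ndarray | None = field(default=None)


def amplitude_spectrum(series: np.ndarray, tr_seconds: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of a (batch of) time series.

    The series is linearly detrended (least-squares line removed), Fourier
    transformed, and the magnitude taken per bin.  The DC bin is dropped.

    Parameters
    ----------
    series:
        Array whose last axis is time, length ``t >= 8``.
    tr_seconds:
        Sampling interval (the repetition time).

    Returns
    -------
    freqs, amplitudes:
        ``freqs[k] = (k+1) / (t * tr)`` for ``k = 0 .. floor(t/2) - 1``;
        amplitudes have the same leading shape as ``series``.
    """
    series = np.asarray(series, dtype=float)
    t = series.shape[-1]
    if t < 8:
        raise ValueError(f"need at least 8 time points, got {t}")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains NaN or Inf")
    detrended = signal.detrend(series, axis=-1, type="linear")
    spectrum = np.abs(np.fft.rfft(detrended, axis=-1))[..., 1:]
    freqs = np.fft.rfftfreq(t, d=tr_seconds)[1:]
    return freqs, spectrum


def band_bin_count(n_volumes: int, tr_seconds: float, band: BandDefinition) -> int:
    """Number of FFT bins inside ``band`` for a run of this length."""
    freqs = np.fft.rfftfreq(n_volumes, d=tr_seconds)[1:]
    return int(band.bin_mask(freqs).sum())


def falff(series: np.ndarray, tr_seconds: float, band: BandDefinition) -> float:
    """Band-ratio fALFF of a single time series.

    Returns the sum of amplitudes at bins with ``lo <= f < hi`` divided by
    the sum over all positive-frequency bins up to Nyquist; the result lies
    in [0, 1].  A constant series has an all-zero spectrum and returns 0.
    """
    freqs, amps = amplitude_spectrum(np.atleast_1d(series), tr_seconds)
    in_band = band.bin_mask(freqs)
    if not in_band.any():
        t = len(series)
        min_t = int(np.ceil(1.0 / (band.lo_hz * tr_seconds))) + 1
        raise ValueError(
            f"band {band.name!r} [{band.lo_hz}, {band.hi_hz}) Hz contains no FFT bins for "
            f"t={t}, TR={tr_seconds}s; need at least ~{min_t} volumes"
        )
    total = amps.sum()
    # numerically constant series: the detrended spectrum is rounding dust
    if total <= 1e-9 * (1.0 + np.abs(series).max()) * len(freqs):
        log.warning("constant series: fALFF undefined, returning 0")
        return 0.0
    return float(amps[..., in_band].sum() / total)


def falff_map(
    data: np.ndarray,
    mask: np.ndarray,
    tr_seconds: float,
    band: BandDefinition,
) -> FalffMap:
    """Voxelwise fALFF over a cleaned 4D run.

    ``data`` is (x, y, z, t); out-of-mask voxels are set to 0 in the
    output.  Constant in-mask voxels (zero spectrum) get fALFF 0.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    if data.shape[:3] != mask.shape:
        raise ValueError(f"data grid {data.shape[:3]} != mask grid {mask.shape}")
    voxels = data[mask]  # (V, t)
    freqs, amps = amplitude_spectrum(voxels, tr_seconds)
    in_band = band.bin_mask(freqs)
    if not in_band.any():
        raise ValueError(f"band {band.name!r} contains no FFT bins for this run length")
    total = amps.sum(axis=-1)
    numer = amps[:, in_band].sum(axis=-1)
    floor = 1e-9 * (1.0 + np.abs(voxels).max(axis=-1)) * len(freqs)
    valid = total > floor
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(valid, numer / np.where(valid, total, 1.0), 0.0)
    out = np.zeros(mask.shape, dtype=float)
    out[mask] = ratio
    return FalffMap(raw=out, band=band, mask=mask, n_volumes=data.shape[-1], tr_seconds=tr_seconds)


def zscore_map(fmap: FalffMap, mask: np.ndarray | None = None) -> FalffMap:
    """Globally z-score a fALFF map within the mask.

    Each in-mask voxel has the global (in-mask) mean subtracted and is
    divided by the global standard deviation; out-of-mask voxels stay 0.
    """
    mask = fmap.mask if mask is None else np.asarray(mask, dtype=bool)
    values = fmap.raw[mask]
    if values.size < 2:
        raise ValueError("need at least 2 in-mask voxels to z-score")
    mean = values.mean()
    sd = values.std(ddof=0)
    if sd == 0:
        raise ValueError("zero global standard deviation: cannot z-score a constant map")
    z = np.zeros_like(fmap.raw)
    z[mask] = (values - mean) / sd
    fmap.zscored = z
    return fmap
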