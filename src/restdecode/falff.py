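"""ALFF / fALFF spectral statistics.

ALFF is the summed amplitude (square root of power) of a series'
spectrum inside the low-frequency band, 0.01-0.08 Hz by default.
fALFF is that amplitude as a fraction of the amplitude over the whole
measurable range, DC excluded, up to and including the Nyquist
frequency 1/(2 TR) — for TR = 2 s, 0-0.25 Hz.  Because numerator and
denominator share a common scale, fALFF is dimensionless, lies in
[0, 1], and is invariant to rescaling of the input series.

Conventions (fixed so results are bit-stable):

* amplitudes are ``sqrt(2/N) * |rfft|`` at every bin — Parseval's sum
  then matches the time-domain sum of squares up to an O(1/N) boundary
  term from the DC and Nyquist bins;
* low band is half-open, ``low <= f < high``; the full band is
  ``0 < f <= nyquist`` (DC excluded: series are detrended, so the DC
  bin is numerically zero and excluding it makes the [0, 1] bound
  exact);
* band aggregation sums bin amplitudes (``aggregate="mean"`` gives the
  ratio-of-means alternative);
* no tapering before the FFT by default (``window="hann"`` opts in).

The all-zero series has no defined fALFF; it is reported as NaN
("missing"), never as 0/0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal
from sklearn.base import BaseEstimator, TransformerMixin

from .template import RoiTemplate


@dataclass(frozen=True)
class SpectralBands:
    """Low-frequency band and full-band edges for a given TR."""

    tr: float = 2.0
    low: tuple[float, float] = (0.01, 0.08)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        lo, hi = self.low
        if not (0 <= lo < hi <= self.nyquist):
            raise ValueError(
                f"low band {self.low} must sit inside (0, nyquist={self.nyquist}]"
            )

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)

    @property
    def full(self) -> tuple[float, float]:
        return (0.0, self.nyquist)


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares straight line (slope and mean).

    Idempotent; the output has zero mean and zero least-squares slope.
    Operates on the last axis for 2-D input.
    """
    x = np.asarray(series, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 time points to fit a line")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return scipy.signal.detrend(x, axis=-1, type="linear")


def amplitude_spectrum(series: np.ndarray, tr: float,
                       window: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum.

    Returns ``(frequencies, amplitudes)`` where bin k sits at
    ``k/(N*tr)`` Hz and the amplitude is ``sqrt(2/N) |rfft|`` (square
    root of power, uniformly scaled).  Works on the last axis for 2-D
    input (rows = series).
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    if n < 4:
        raise ValueError("need at least 4 time points")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if tr <= 0:
        raise ValueError("tr must be positive")
    if window == "hann":
        x = x * np.hanning(n)
    elif window is not None:
        raise ValueError("window must be None or 'hann'")
    freqs = np.fft.rfftfreq(n, d=tr)
    amps = np.sqrt(2.0 / n) * np.abs(np.fft.rfft(x, axis=-1))
    return freqs, amps


def band_masks(freqs: np.ndarray, bands: SpectralBands) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (low-band, full-band-minus-DC) over spectrum bins."""
    lo, hi = bands.low
    low = (freqs >= lo) & (freqs < hi)
    full = (freqs > 0) & (freqs <= bands.nyquist + 1e-12)
    return low, full


def compute_falff(series: np.ndarray, tr: float, bands: SpectralBands | None = None,
                  aggregate: str = "sum", window: str | None = None
                  ) -> tuple[float, float]:
    """ALFF and fALFF of one (already detrended) series.

    Returns ``(alff, falff)``.  ``alff`` is the low-band aggregated
    amplitude in signal units; ``falff`` the low/full ratio in [0, 1]
    (NaN for an identically-zero series).
    """
    if aggregate not in ("sum", "mean"):
        raise ValueError("aggregate must be 'sum' or 'mean'")
    freqs, amps = amplitude_spectrum(series, tr, window=window)
    if bands is None:
        bands = SpectralBands(tr=tr)
    low, full = band_masks(freqs, bands)
    agg = np.mean if aggregate == "mean" else np.sum
    alff = float(agg(amps[..., low], axis=-1))
    denom = float(agg(amps[..., full], axis=-1))
    if denom == 0.0:
        warnings.warn("series has no spectral power; fALFF undefined (NaN)")
        return alff, float("nan")
    return alff, alff / denom


def falff_matrix(data: np.ndarray, tr: float, bands: SpectralBands | None = None,
                 aggregate: str = "sum", window: str | None = None) -> np.ndarray:
    """Vectorized fALFF over the columns of a time x ROI matrix."""
    x = np.asarray(data, dtype=float).T  # (n_rois, n_t)
    freqs, amps = amplitude_spectrum(x, tr, window=window)
    if bands is None:
        bands = SpectralBands(tr=tr)
    low, full = band_masks(freqs, bands)
    agg = np.mean if aggregate == "mean" else np.sum
    num = agg(amps[:, low], axis=-1)
    den = agg(amps[:, full], axis=-1)
    out = np.full(x.shape[0], np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def normalize_global_mean(values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Divide by the mean over ``mask`` (all entries when mask is None).

    The returned array has mean exactly 1 over the mask.
    """
    v = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(v.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no entries")
    gm = v[mask].mean()
    if not np.isfinite(gm) or gm <= 0:
        raise ValueError(f"global mean must be positive and finite, got {gm}")
    return v / gm


def smooth_gaussian(volume: np.ndarray, fwhm_mm: float,
                    voxel_size_mm: float | tuple[float, float, float] = 3.0) -> np.ndarray:
    """Gaussian-smooth a 3-D map; sigma = fwhm / (2 sqrt(2 ln 2)) per axis."""
    vol = np.asarray(volume, dtype=float)
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return vol.copy()
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return scipy.ndimage.gaussian_filter(vol, sigma=tuple(sigma_mm / vs))


def roi_aggregate(map_or_matrix, template: RoiTemplate,
                  affine: np.ndarray | None = None) -> np.ndarray:
    """Per-ROI mean vector in template order.

    ROI-matrix mode (1-D vector or pandas Series aligned to the
    template) is a labelled pass-through.  Volumetric mode (3-D map +
    affine) averages within the template's spheres; an empty sphere is
    reported as NaN with a warning, never silently as zero.
    """
    if isinstance(map_or_matrix, pd.Series):
        missing = [n for n in template.roi_names if n not in map_or_matrix.index]
        if missing:
            raise ValueError(f"ROI values missing for {missing[:5]}...")
        return map_or_matrix.loc[template.roi_names].to_numpy(dtype=float)
    arr = np.asarray(map_or_matrix, dtype=float)
    if arr.ndim == 1:
        if len(arr) != len(template):
            raise ValueError(f"expected {len(template)} ROI values, got {len(arr)}")
        return arr.copy()
    if arr.ndim != 3:
        raise ValueError("expected a 1-D ROI vector or a 3-D volume")
    if affine is None:
        raise ValueError("volumetric aggregation needs the volume's affine")
    from .volume import sphere_masks

    masks = sphere_masks(template, arr.shape, affine)
    out = np.full(len(template), np.nan)
    for i, m in enumerate(masks):
        if not m.any():
            warnings.warn(f"ROI {template.roi_names[i]!r} covers no voxels; NaN")
            continue
        out[i] = arr[m].mean()
    return out


class FalffExtractor(BaseEstimator, TransformerMixin):
    """Transformer: stack of recordings -> normalized fALFF features.

    For each recording (time x ROI), trims the first ``n_discard``
    volumes, removes the linear trend per ROI, computes fALFF per ROI,
    and (optionally) divides by the recording's global mean fALFF.

    Parameters follow scikit-learn conventions; the transformer is
    stateless (``fit`` only validates).
    """

    def __init__(self, tr: float = 2.0, low_band: tuple[float, float] = (0.01, 0.08),
                 n_discard: int = 10, normalize: bool = True,
                 aggregate: str = "sum", window: str | None = None):
        self.tr = tr
        self.low_band = low_band
        self.n_discard = n_discard
        self.normalize = normalize
        self.aggregate = aggregate
        self.window = window

    def _bands(self) -> SpectralBands:
        return SpectralBands(tr=self.tr, low=tuple(self.low_band))

    def fit(self, X, y=None):
        self._bands()  # validates tr/band geometry
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        self.n_features_in_ = np.asarray(X[0]).shape[-1] if len(X) else 0
        return self

    def transform(self, X) -> np.ndarray:
        """``X``: iterable of time x ROI arrays (or a 3-D stack)."""
        bands = self._bands()
        rows = []
        for rec in X:
            data = np.asarray(rec, dtype=float)[self.n_discard:, :]
            detr = detrend_linear(data.T).T
            vals = falff_matrix(detr, self.tr, bands, self.aggregate, self.window)
            if self.normalize:
                vals = normalize_global_mean(vals)
            rows.append(vals)
        return np.asarray(rows)


def falff_feature_table(recordings, template: RoiTemplate,
                        extractor: FalffExtractor | None = None
                        ) -> dict[str, pd.DataFrame]:
    """Per-condition subjects x ROIs fALFF tables from a cohort.

    Returns ``{"EC": DataFrame, "EO": DataFrame}`` with subject ids as
    the index and template ROI names as columns.
    """
    if extractor is None:
        extractor = FalffExtractor(tr=recordings[0].tr)
    by_cond: dict[str, dict[str, np.ndarray]] = {"EC": {}, "EO": {}}
    data = [r.data for r in recordings]
    feats = extractor.fit(data).transform(data)
    for rec, row in zip(recordings, feats):
        if rec.subject_id in by_cond[rec.condition]:
            raise ValueError(f"duplicate recording for {rec.subject_id}/{rec.condition}")
        by_cond[rec.condition][rec.subject_id] = row
    out = {}
    for cond, d in by_cond.items():
        df = pd.DataFrame.from_dict(d, orient="index", columns=template.roi_names)
        df.index.name = "subject_id"
        out[cond] = df.sort_index()
    return out
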