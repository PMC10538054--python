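"""Profile-spectrum preprocessing: baseline, smoothing, calibration, peaks, QC.

The chain mirrors standard MALDI-TOF practice: SNIP baseline subtraction,
Savitzky-Golay smoothing, alignment on prominent peaks, total-ion-count
normalization, peak detection on the average spectrum, lock-mass
recalibration, and a replicate coefficient-of-variation gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "ProfileSpectrum",
    "Peak",
    "PeakList",
    "FeatureMatrix",
    "CalibrationConfig",
    "QcReport",
    "LockMassError",
    "snip_baseline",
    "subtract_baseline",
    "savgol_smooth",
    "lock_mass_recalibrate",
    "tic_normalize",
    "align_spectra",
    "mean_spectrum",
    "detect_peaks",
    "build_feature_matrix",
    "extract_feature_matrix",
    "replicate_cv",
]


@dataclass
class ProfileSpectrum:
    """A continuous (profile-mode) spectrum on a strictly increasing m/z axis."""

    mz: np.ndarray
    intensity: np.ndarray
    polarity: int = +1
    sample_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")

    def copy(self) -> "ProfileSpectrum":
        return ProfileSpectrum(
            self.mz.copy(), self.intensity.copy(), self.polarity,
            self.sample_id, self.replicate_id,
        )

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    snr: float


@dataclass
class PeakList:
    peaks: list[Peak]
    polarity: int = +1
    sample_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        if any(p.snr < 0 for p in self.peaks):
            raise ValueError("peak snr must be non-negative")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


@dataclass
class FeatureMatrix:
    """Samples x consensus-m/z intensity matrix with sample metadata.

    ``samples`` carries one row per spectrum with at least ``sample_id``;
    optional columns ``group`` and ``bio_sample`` drive the differential and
    QC stages (technical replicates share a ``bio_sample``).
    """

    feature_mz: np.ndarray
    values: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), self.feature_mz.size):
            raise ValueError("values must be samples x features")
        if np.any(self.values < 0):
            raise ValueError("feature intensities must be non-negative")
        if self.feature_mz.size > 1 and not np.all(np.diff(self.feature_mz) > 0):
            raise ValueError("feature m/z must be ascending")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=np.round(self.feature_mz, 4),
            index=self.samples["sample_id"],
        )
        return df


@dataclass(frozen=True)
class CalibrationConfig:
    """Lock-mass internal recalibration settings (one lock mass per polarity)."""

    lock_mz_positive: float = 760.5851  # PC(34:1) [M+H]+
    lock_mz_negative: float = 885.5499  # PI(38:4) [M-H]-
    window: float = 0.5  # Da search window around the lock m/z
    max_rel_error: float = 5e-4

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("search window must be positive")

    def lock_mz(self, polarity: int) -> float:
        return self.lock_mz_positive if polarity > 0 else self.lock_mz_negative


class LockMassError(RuntimeError):
    """No peak found near the configured lock mass."""


@dataclass
class QcReport:
    feature_mz: np.ndarray
    feature_cv: np.ndarray
    mean_cv: float
    passed: bool
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

def snip_baseline(
    spectrum: ProfileSpectrum | np.ndarray, iterations: int = 100, *, lls: bool = True
) -> np.ndarray:
    """SNIP baseline estimate by iterative symmetric clipping.

    Runs ``b_i(k) = min(v_i, (v_{i-k} + v_{i+k}) / 2)`` for ``k = 1..iterations``
    on the (optionally log-log-sqrt transformed) intensities and
    back-transforms.  The result never exceeds the input envelope, so the
    clipped residual is non-negative.
    """
    v = spectrum.intensity if isinstance(spectrum, ProfileSpectrum) else np.asarray(spectrum, float)
    n = v.size
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if iterations >= n:
        raise ValueError("iterations must be smaller than the spectrum length")
    if lls:
        w = np.log(np.log(np.sqrt(v + 1.0) + 1.0) + 1.0)
    else:
        w = v.astype(float).copy()
    for k in range(1, iterations + 1):
        mid = 0.5 * (w[: n - 2 * k] + w[2 * k:])
        w[k: n - k] = np.minimum(w[k: n - k], mid)
    if lls:
        b = (np.exp(np.exp(w) - 1.0) - 1.0) ** 2 - 1.0
    else:
        b = w
    return np.minimum(np.maximum(b, 0.0), v)


def subtract_baseline(spectrum: ProfileSpectrum, iterations: int = 100) -> ProfileSpectrum:
    baseline = snip_baseline(spectrum, iterations)
    out = spectrum.copy()
    out.intensity = np.clip(spectrum.intensity - baseline, 0.0, None)
    return out


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def savgol_smooth(
    spectrum: ProfileSpectrum, half_window: int = 10, poly_order: int = 3
) -> ProfileSpectrum:
    """Savitzky-Golay least-squares polynomial smoothing (length preserving)."""
    window = 2 * half_window + 1
    if poly_order >= window:
        raise ValueError("poly_order must be < 2*half_window + 1")
    out = spectrum.copy()
    smoothed = savgol_filter(spectrum.intensity, window, poly_order, mode="interp")
    out.intensity = np.clip(smoothed, 0.0, None)
    return out


# ---------------------------------------------------------------------------
# normalization and calibration
# ---------------------------------------------------------------------------

def tic_normalize(obj: ProfileSpectrum | PeakList):
    """Scale intensities so the total ion count equals 1; returns (obj, scale)."""
    if isinstance(obj, PeakList):
        total = float(sum(p.intensity for p in obj.peaks))
        if total <= 0:
            raise ValueError("cannot TIC-normalize an all-zero peak list")
        peaks = [Peak(p.mz, p.intensity / total, p.snr) for p in obj.peaks]
        return PeakList(peaks, obj.polarity, obj.sample_id, obj.replicate_id), total
    total = obj.tic
    if total <= 0:
        raise ValueError("cannot TIC-normalize an all-zero spectrum")
    out = obj.copy()
    out.intensity = obj.intensity / total
    return out, total


def lock_mass_recalibrate(
    peaklist: PeakList, cfg: CalibrationConfig = CalibrationConfig()
) -> tuple[PeakList, float]:
    """Multiplicative one-point recalibration on the polarity's lock mass.

    Finds the most intense peak within ``cfg.window`` of the lock m/z and
    rescales every m/z by lock/observed.  Returns the recalibrated list and
    the applied relative shift (factor - 1).
    """
    if not peaklist.peaks:
        raise LockMassError("empty peak list")
    lock = cfg.lock_mz(peaklist.polarity)
    near = [p for p in peaklist.peaks if abs(p.mz - lock) <= cfg.window]
    if not near:
        raise LockMassError(
            f"lock mass {lock} not found within +/-{cfg.window} Da"
        )
    observed = max(near, key=lambda p: p.intensity).mz
    factor = lock / observed
    peaks = [Peak(p.mz * factor, p.intensity, p.snr) for p in peaklist.peaks]
    out = PeakList(peaks, peaklist.polarity, peaklist.sample_id, peaklist.replicate_id)
    return out, factor - 1.0


def recalibrate_spectrum(
    spectrum: ProfileSpectrum, cfg: CalibrationConfig = CalibrationConfig()
) -> tuple[ProfileSpectrum, float]:
    """Lock-mass recalibration of a profile spectrum (multiplicative warp).

    The warped intensities are re-interpolated back onto the original axis so
    downstream averaging can assume a shared grid.
    """
    lock = cfg.lock_mz(spectrum.polarity)
    sel = np.abs(spectrum.mz - lock) <= cfg.window
    if not np.any(sel) or spectrum.intensity[sel].max() <= 0:
        raise LockMassError(f"lock mass {lock} not found within +/-{cfg.window} Da")
    idx = np.flatnonzero(sel)[np.argmax(spectrum.intensity[sel])]
    factor = lock / spectrum.mz[idx]
    out = spectrum.copy()
    out.intensity = np.interp(
        spectrum.mz, spectrum.mz * factor, spectrum.intensity, left=0.0, right=0.0
    )
    return out, factor - 1.0


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def mean_spectrum(spectra: Sequence[ProfileSpectrum]) -> ProfileSpectrum:
    """Total average spectrum of spectra sharing one m/z axis."""
    if not spectra:
        raise ValueError("no spectra")
    mz0 = spectra[0].mz
    for s in spectra[1:]:
        if s.mz.shape != mz0.shape or not np.allclose(s.mz, mz0):
            raise ValueError("spectra must share a common m/z axis")
    avg = np.mean([s.intensity for s in spectra], axis=0)
    return ProfileSpectrum(mz0.copy(), avg, spectra[0].polarity, sample_id="mean")


def _local_maxima(intensity: np.ndarray) -> np.ndarray:
    left = np.r_[-np.inf, intensity[:-1]]
    right = np.r_[intensity[1:], -np.inf]
    return np.flatnonzero((intensity > left) & (intensity >= right) & (intensity > 0))


def align_spectra(
    spectra: Sequence[ProfileSpectrum],
    n_anchor_peaks: int = 10,
    match_window: float = 0.3,
) -> list[ProfileSpectrum]:
    """Realign spectra on prominent peaks of the total average spectrum.

    The ``n_anchor_peaks`` most intense local maxima of the mean spectrum act
    as anchors; each spectrum's nearest local maximum within ``match_window``
    Da of an anchor defines a control point of a monotone piecewise-linear m/z
    warp (constant shift beyond the outermost anchors).  Spectra with fewer
    than two matched anchors are returned unchanged with a warning.
    """
    if len(spectra) < 2:
        raise ValueError("alignment needs at least two spectra")
    ref = mean_spectrum(spectra)
    maxima = _local_maxima(ref.intensity)
    if maxima.size == 0:
        return [s.copy() for s in spectra]
    order = np.argsort(ref.intensity[maxima])[::-1]
    anchors = np.sort(ref.mz[maxima[order[:n_anchor_peaks]]])

    out = []
    for s in spectra:
        smax = _local_maxima(s.intensity)
        src, dst = [], []
        for a in anchors:
            if smax.size == 0:
                continue
            j = smax[np.argmin(np.abs(s.mz[smax] - a))]
            if abs(s.mz[j] - a) <= match_window:
                src.append(s.mz[j])
                dst.append(a)
        # keep the match set monotone in both coordinates
        keep_src, keep_dst = [], []
        for x, y in zip(src, dst):
            if not keep_src or (x > keep_src[-1] and y > keep_dst[-1]):
                keep_src.append(x)
                keep_dst.append(y)
        if len(keep_src) < 2:
            warnings.warn(
                f"spectrum {s.sample_id!r}: <2 matched anchors, identity warp",
                stacklevel=2,
            )
            out.append(s.copy())
            continue
        src_a = np.array(keep_src)
        dst_a = np.array(keep_dst)
        shift = dst_a - src_a
        # piecewise-linear shift, constant extrapolation beyond the anchors
        warped_mz = s.mz + np.interp(s.mz, src_a, shift)
        aligned = s.copy()
        aligned.intensity = np.interp(s.mz, warped_mz, s.intensity, left=0.0, right=0.0)
        out.append(aligned)
    return out


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def _blockwise_mad_noise(intensity: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Local (median, scaled-MAD) estimated in non-overlapping blocks.

    Both are linearly interpolated between block centers; the MAD gets a
    small floor so flat stretches cannot produce infinite SNR.
    """
    n = intensity.size
    window = max(3, min(window, n))
    centers, meds, mads = [], [], []
    for start in np.arange(0, n, window):
        block = intensity[start: start + window]
        med = np.median(block)
        meds.append(med)
        mads.append(1.4826 * np.median(np.abs(block - med)))
        centers.append(start + 0.5 * min(window, n - start))
    grid = np.arange(n)
    median = np.interp(grid, centers, meds)
    noise = np.interp(grid, centers, mads)
    floor = max(float(np.median(mads)), np.finfo(float).tiny)
    return median, np.maximum(noise, 1e-3 * floor)


def detect_peaks(
    spectrum: ProfileSpectrum,
    snr_threshold: float = 3.0,
    noise_window: int = 200,
) -> PeakList:
    """Local maxima rising ``snr_threshold`` x local MAD noise above the local median."""
    idx = _local_maxima(spectrum.intensity)
    if idx.size == 0:
        return PeakList([], spectrum.polarity, spectrum.sample_id, spectrum.replicate_id)
    median, noise = _blockwise_mad_noise(spectrum.intensity, noise_window)
    snr = np.clip(spectrum.intensity[idx] - median[idx], 0.0, None) / noise[idx]
    keep = snr >= snr_threshold
    peaks = [
        Peak(float(spectrum.mz[i]), float(spectrum.intensity[i]), float(s))
        for i, s in zip(idx[keep], snr[keep])
    ]
    return PeakList(peaks, spectrum.polarity, spectrum.sample_id, spectrum.replicate_id)


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def build_feature_matrix(
    peaklists: Sequence[PeakList],
    match_tolerance: float = 5e-4,
    samples: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Greedy single-linkage binning of peaks into consensus features.

    Peaks from all lists are pooled and sorted; a new feature bin opens when
    the gap to the previous peak exceeds ``match_tolerance`` (relative).  The
    feature m/z is the intensity-weighted mean of its member peaks; a sample
    without a member peak gets 0; two member peaks of one sample are summed.
    """
    if not peaklists:
        raise ValueError("no peak lists")
    polarity = peaklists[0].polarity
    if any(pl.polarity != polarity for pl in peaklists):
        raise ValueError("peak lists mix polarities")

    entries = []  # (mz, intensity, sample index)
    for si, pl in enumerate(peaklists):
        for p in pl.peaks:
            entries.append((p.mz, p.intensity, si))
    if samples is None:
        samples = pd.DataFrame(
            {
                "sample_id": [pl.sample_id or f"s{i}" for i, pl in enumerate(peaklists)],
                "replicate_id": [pl.replicate_id for pl in peaklists],
            }
        )
    if not entries:
        return FeatureMatrix(np.empty(0), np.zeros((len(peaklists), 0)), samples)
    entries.sort()

    bins: list[list[tuple[float, float, int]]] = [[entries[0]]]
    for e in entries[1:]:
        prev_mz = bins[-1][-1][0]
        if e[0] - prev_mz <= match_tolerance * e[0]:
            bins[-1].append(e)
        else:
            bins.append([e])

    feature_mz = np.empty(len(bins))
    values = np.zeros((len(peaklists), len(bins)))
    for j, members in enumerate(bins):
        mzs = np.array([m[0] for m in members])
        ints = np.array([m[1] for m in members])
        weights = ints if ints.sum() > 0 else np.ones_like(ints)
        feature_mz[j] = np.average(mzs, weights=weights)
        for mz, inten, si in members:
            values[si, j] += inten
    order = np.argsort(feature_mz)
    return FeatureMatrix(feature_mz[order], values[:, order], samples.reset_index(drop=True))


def extract_feature_matrix(
    spectra: Sequence[ProfileSpectrum],
    consensus: PeakList,
    window_rel: float = 2.5e-4,
    samples: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Per-sample intensities at consensus peak positions (no re-detection).

    Consensus peaks normally come from :func:`detect_peaks` on the total
    average spectrum; each sample contributes the maximum intensity within
    ``window_rel`` (relative) of every consensus m/z, or 0 if the window is
    empty.  Unlike :func:`build_feature_matrix` this cannot drop a feature in
    a subset of samples, which keeps replicate CVs meaningful for weak peaks.
    """
    if not spectra:
        raise ValueError("no spectra")
    feature_mz = consensus.mz
    if samples is None:
        samples = pd.DataFrame(
            {"sample_id": [s.sample_id or f"s{i}" for i, s in enumerate(spectra)]}
        )
    values = np.zeros((len(spectra), feature_mz.size))
    for si, s in enumerate(spectra):
        lo = np.searchsorted(s.mz, feature_mz * (1 - window_rel), side="left")
        hi = np.searchsorted(s.mz, feature_mz * (1 + window_rel), side="right")
        for j, (a, b) in enumerate(zip(lo, hi)):
            if b > a:
                values[si, j] = s.intensity[a:b].max()
    return FeatureMatrix(feature_mz, values, samples.reset_index(drop=True))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def replicate_cv(fm: FeatureMatrix, max_mean_cv: float = 0.50) -> QcReport:
    """Per-feature CV (sd/mean) across technical replicates, averaged over samples.

    Requires a ``bio_sample`` column grouping technical replicates; every
    biological sample must have at least two replicates.  (sample, feature)
    cells whose replicate mean is zero are excluded from the average and
    counted in ``n_excluded``.
    """
    if "bio_sample" not in fm.samples.columns:
        raise ValueError("sample metadata lacks a 'bio_sample' replicate map")
    groups = fm.samples.groupby("bio_sample").indices
    if any(len(ix) < 2 for ix in groups.values()):
        raise ValueError("every biological sample needs >=2 technical replicates")

    n_features = fm.feature_mz.size
    cv_sum = np.zeros(n_features)
    cv_count = np.zeros(n_features)
    n_excluded = 0
    for ix in groups.values():
        block = fm.values[np.asarray(ix)]
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        ok = mean > 0
        n_excluded += int((~ok).sum())
        cv_sum[ok] += sd[ok] / mean[ok]
        cv_count[ok] += 1
    with np.errstate(invalid="ignore"):
        feature_cv = np.where(cv_count > 0, cv_sum / np.maximum(cv_count, 1), np.nan)
    valid = np.isfinite(feature_cv)
    mean_cv = float(feature_cv[valid].mean()) if valid.any() else float("nan")
    return QcReport(
        feature_mz=fm.feature_mz.copy(),
        feature_cv=feature_cv,
        mean_cv=mean_cv,
        passed=bool(mean_cv < max_mean_cv),
        n_excluded=n_excluded,
    )
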