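"""MALDI-TOF profile processing and peak-list production.

The pipeline mirrors standard fingerprinting practice: baseline
subtraction, Savitzky-Golay smoothing (window given in m/z, converted to
points from the local sampling density), peak picking with an S/N and a
relative-intensity threshold, and deisotoping of singly charged envelopes.

The baseline corrector is a percentile-based piecewise model: the m/z
range is split into ``precision`` segments, each contributing one anchor
at ``segment minimum + (offset/100) * (segment median - segment
minimum)``; anchors are linearly interpolated and subtracted.  This is an
approximation of the (undocumented) mMass baseline semantics -- the two
parameters play the same roles as its "precision" and "relative offset"
knobs, but no bit-for-bit agreement is implied.

Noise is estimated *before* smoothing, as the scaled median absolute
deviation of the high-frequency residual (raw minus smoothed) over a
sliding window; S/N of a picked peak is its smoothed apex height over the
local noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .chem import ISOTOPE_SPACING, _LAMBDA_PER_DA

__all__ = [
    "RawSpectrum",
    "Peak",
    "PeakList",
    "preprocess",
    "pick_peaks",
    "deisotope",
    "collagen_screen",
    "read_spectrum",
    "write_spectrum",
    "read_peaklist",
    "write_peaklist",
    "read_mzml",
]

#: shared bovid/mammal collagen markers used for the quality screen
COLLAGEN_SCREEN_MASSES = (1105, 1648, 2131, 2792)

_NOISE_WINDOW_POINTS = 501


@dataclass
class RawSpectrum:
    """An ordered (m/z, intensity) profile with acquisition metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    sn: float


@dataclass
class PeakList:
    peaks: list[Peak]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def mzs(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])


def _window_points(mz: np.ndarray, window_mz: float) -> int:
    spacing = float(np.median(np.diff(mz)))
    pts = max(int(round(window_mz / spacing)), 3)
    if pts % 2 == 0:
        pts += 1
    return pts


def _sliding(values: np.ndarray, stat, scale: float = 1.0) -> np.ndarray:
    """Coarse sliding-window statistic, linearly interpolated to full length."""
    n = len(values)
    half = _NOISE_WINDOW_POINTS // 2
    centers = np.arange(half, n, max(half, 1))
    if len(centers) == 0:
        centers = np.array([n // 2])
    stats = [stat(values[max(0, c - half) : min(n, c + half + 1)]) for c in centers]
    return np.interp(np.arange(n), centers, np.asarray(stats)) * scale


def _noise_profile(mz: np.ndarray, residual: np.ndarray) -> np.ndarray:
    """Sliding-window 1.4826*MAD of the high-frequency residual."""
    noise = _sliding(residual, lambda seg: np.median(np.abs(seg - np.median(seg))), 1.4826)
    return np.maximum(noise, 1e-12)


def _background_profile(intensity: np.ndarray) -> np.ndarray:
    """Sliding-window median of the processed trace: the local background
    left over after the (offset-bearing) baseline subtraction."""
    return _sliding(intensity, np.median)


def preprocess(
    raw: RawSpectrum,
    baseline_precision: int = 52,
    baseline_offset: float = 39.0,
    smooth_window_mz: float = 0.3,
    polyorder: int = 2,
) -> RawSpectrum:
    """Baseline-subtract and smooth a profile spectrum."""
    if len(raw) < 10:
        raise ValueError("spectrum too short to preprocess (need >= 10 samples)")
    if not 1 <= baseline_precision <= 500:
        raise ValueError("baseline_precision out of range [1, 500]")
    if not 0 <= baseline_offset <= 100:
        raise ValueError("baseline_offset out of range [0, 100]")
    span = raw.mz[-1] - raw.mz[0]
    if smooth_window_mz >= span:
        raise ValueError("smoothing window wider than the spectrum span")

    # piecewise baseline
    edges = np.linspace(0, len(raw), baseline_precision + 1, dtype=int)
    anchors_x, anchors_y = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < 1:
            continue
        seg = raw.intensity[a:b]
        lo = float(np.min(seg))
        med = float(np.median(seg))
        anchors_x.append(float(np.mean(raw.mz[a:b])))
        anchors_y.append(lo + (baseline_offset / 100.0) * (med - lo))
    baseline = np.interp(raw.mz, anchors_x, anchors_y)
    # keep the corrected trace signed: clipping noise at zero would bias
    # its maxima upward and inflate the false-peak rate downstream
    corrected = raw.intensity - baseline

    pts = _window_points(raw.mz, smooth_window_mz)
    pts = max(pts, polyorder + 1 + (polyorder % 2))
    if pts % 2 == 0:
        pts += 1
    smoothed = savgol_filter(corrected, pts, polyorder)
    noise = _noise_profile(raw.mz, corrected - smoothed)
    # clip only after smoothing: clipping the raw trace first would rectify
    # the noise and bias peak maxima upward
    smoothed = np.maximum(smoothed, 0.0)

    meta = dict(raw.metadata)
    meta["processing"] = {
        "baseline_precision": baseline_precision,
        "baseline_offset": baseline_offset,
        "smooth_window_mz": smooth_window_mz,
        "polyorder": polyorder,
    }
    meta["noise"] = noise
    return RawSpectrum(mz=raw.mz.copy(), intensity=smoothed, metadata=meta)


def pick_peaks(
    processed: RawSpectrum,
    sn_min: float = 3.0,
    rel_intensity_min: float = 0.01,
) -> PeakList:
    """Local maxima with S/N >= ``sn_min`` and intensity >= ``rel_intensity_min``
    of the base peak; apex m/z refined by parabolic interpolation."""
    if len(processed) == 0 or float(np.max(processed.intensity, initial=0.0)) <= 0:
        return PeakList([], provenance={"sn_min": sn_min, "rel_intensity_min": rel_intensity_min})
    noise = processed.metadata.get("noise")
    if noise is None:
        noise = _noise_profile(processed.mz, np.diff(processed.intensity, prepend=processed.intensity[0]))
    y = processed.intensity
    background = _background_profile(y)
    height_above = y - background
    base = float(np.max(height_above))
    if base <= 0:
        return PeakList([], provenance={"sn_min": sn_min, "rel_intensity_min": rel_intensity_min})
    idx, _ = find_peaks(y)
    peaks = []
    for i in idx:
        if height_above[i] < rel_intensity_min * base:
            continue
        sn = height_above[i] / noise[i]
        if sn < sn_min:
            continue
        mz = processed.mz[i]
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if denom < 0:
                delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
                step = 0.5 * (processed.mz[i + 1] - processed.mz[i - 1])
                mz = processed.mz[i] + np.clip(delta, -0.5, 0.5) * step
        peaks.append(Peak(mz=float(mz), intensity=float(y[i]), sn=float(sn)))
    return PeakList(peaks, provenance={"sn_min": sn_min, "rel_intensity_min": rel_intensity_min})


def deisotope(
    peaklist: PeakList,
    max_charge: int = 1,
    iso_mass_tol: float = 0.1,
    iso_int_tol: float = 0.5,
    iso_shift: float = 0.0,
) -> PeakList:
    """Collapse singly charged isotope envelopes to their monoisotopic peaks.

    Peaks spaced ``ISOTOPE_SPACING + iso_shift`` (within ``iso_mass_tol``)
    whose successive intensity ratios agree with the Poisson envelope model
    within ``iso_int_tol`` (relative) are treated as one envelope; only the
    first (monoisotopic) peak is retained.  Only charge 1 is supported.
    """
    if max_charge != 1:
        raise NotImplementedError("only singly charged envelopes are supported")
    peaks = peaklist.peaks
    keep = []
    claimed = [False] * len(peaks)
    for i, p in enumerate(peaks):
        if claimed[i]:
            continue
        keep.append(p)
        # walk the envelope chain starting at p
        prev = p
        j = i + 1
        expected = p.mz + ISOTOPE_SPACING + iso_shift
        lam = _LAMBDA_PER_DA * p.mz
        k = 1
        while j < len(peaks):
            q = peaks[j]
            if q.mz > expected + iso_mass_tol:
                break
            if not claimed[j] and abs(q.mz - expected) <= iso_mass_tol:
                model_ratio = lam / k
                obs_ratio = q.intensity / prev.intensity if prev.intensity > 0 else np.inf
                if abs(obs_ratio - model_ratio) <= iso_int_tol * max(model_ratio, 1.0):
                    claimed[j] = True
                    prev = q
                    expected = q.mz + ISOTOPE_SPACING + iso_shift
                    k += 1
                    j += 1
                    continue
            j += 1
    return PeakList(keep, provenance=dict(peaklist.provenance, deisotoped=True))


def nominal_match(mz: float, nominal: int, tolerance: float = 0.5) -> bool:
    """Match a peak against an integer nominal mass.

    Nominal masses are floors of the true [M+H]+, so a peak matches when it
    falls in ``[nominal - tolerance, nominal + 1 + tolerance)``.
    """
    return nominal - tolerance <= mz < nominal + 1 + tolerance


def collagen_screen(
    peaklist: PeakList,
    k_min: int = 2,
    masses: tuple[int, ...] = COLLAGEN_SCREEN_MASSES,
    tolerance: float = 0.5,
) -> bool:
    """Quality call: True (has collagen) iff >= ``k_min`` shared collagen
    markers are present."""
    found = 0
    for nominal in masses:
        if any(nominal_match(p.mz, nominal, tolerance) for p in peaklist):
            found += 1
    return found >= k_min


# ---------------------------------------------------------------------------
# I/O: two-column text spectra, TSV peak lists


def read_spectrum(path) -> RawSpectrum:
    mz, inten = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        mz.append(float(parts[0]))
        inten.append(float(parts[1]))
    return RawSpectrum(np.array(mz), np.array(inten), metadata={"source": str(path)})


def write_spectrum(spectrum: RawSpectrum, path) -> None:
    lines = [f"{m:.6f}\t{i:.6f}" for m, i in zip(spectrum.mz, spectrum.intensity)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_peaklist(path) -> PeakList:
    """Read a peak list from two- or three-column text (m/z, intensity[, S/N])."""
    peaks = []
    text = Path(path).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("mz\t"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        mz = float(parts[0])
        inten = float(parts[1]) if len(parts) > 1 else 1.0
        sn = float(parts[2]) if len(parts) > 2 else float("inf")
        peaks.append(Peak(mz=mz, intensity=inten, sn=sn))
    return PeakList(peaks, provenance={"source": str(path)})


def write_peaklist(peaklist: PeakList, path) -> None:
    lines = ["mz\tintensity\tsn"]
    for p in peaklist:
        lines.append(f"{p.mz:.4f}\t{p.intensity:.4f}\t{p.sn:.2f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mzml(path, index: int = 0) -> RawSpectrum:
    """Read one spectrum from an mzML file (delegated to pyteomics)."""
    from pyteomics import mzml as _mzml

    with _mzml.read(str(path)) as reader:
        for i, entry in enumerate(reader):
            if i == index:
                return RawSpectrum(
                    np.asarray(entry["m/z array"], dtype=float),
                    np.asarray(entry["intensity array"], dtype=float),
                    metadata={"source": str(path), "index": index},
                )
    raise IndexError(f"spectrum index {index} not present in {path}")
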