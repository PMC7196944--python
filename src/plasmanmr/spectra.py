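"""Spectrum container, text I/O, diffusion-edit subtraction and QC metrics.

A :class:`Spectrum` is a frequency-domain 1D trace: a strictly increasing
ppm axis, an intensity vector of the same length, and a metadata mapping
(sample id, group, batch, method tag, gradient fraction, spectrometer
frequency).  Files are plain two-column text (ppm, intensity) with an
optional JSON sidecar holding the metadata; descending axes are accepted
on read and normalized to ascending order.

The processing operations here implement the diffusion-editing workflow:
subtracting the high-gradient LED spectrum from its low-gradient
counterpart to isolate small molecules, then removing the residual broad
"underground" envelope with a 20 Hz filter, plus axis referencing to the
glucose doublet and the resolution / signal-to-noise metrics used to
compare acquisition methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "Spectrum",
    "read_spectrum",
    "write_spectrum",
    "subtract_diffusion_pair",
    "remove_underground",
    "estimate_noise",
    "signal_to_noise",
    "peak_width_half_height",
    "reference_axis",
]

DEFAULT_FREQ = 500.13  # MHz, assumed when metadata carries no frequency


@dataclass
class Spectrum:
    """One 1D NMR spectrum on an ascending ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D")
        if self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must have equal length")
        if self.ppm.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.ppm) > 0):
            raise ValueError("ppm axis must be strictly increasing")
        if not (np.all(np.isfinite(self.ppm)) and np.all(np.isfinite(self.intensity))):
            raise ValueError("spectrum contains non-finite values")

    @property
    def freq(self) -> float:
        """Spectrometer frequency in MHz (ppm -> Hz conversion factor)."""
        return float(self.meta.get("spectrometer_freq", DEFAULT_FREQ))

    @property
    def step(self) -> float:
        """Median axis step in ppm."""
        return float(np.median(np.diff(self.ppm)))

    def hz_per_point(self) -> float:
        return self.step * self.freq

    def slice_indices(self, low: float, high: float) -> np.ndarray:
        if low > high:
            low, high = high, low
        return np.nonzero((self.ppm >= low) & (self.ppm <= high))[0]

    def with_intensity(self, intensity: np.ndarray, **meta_updates) -> "Spectrum":
        md = dict(self.meta)
        md.update(meta_updates)
        return Spectrum(ppm=self.ppm.copy(), intensity=np.asarray(intensity, float), meta=md)


# ---------------------------------------------------------------------------
# I/O


def write_spectrum(spec: Spectrum, path: str | Path, sidecar: bool = True) -> Path:
    """Write a two-column (ppm, intensity) text file plus a JSON sidecar."""
    path = Path(path)
    data = np.column_stack([spec.ppm, spec.intensity])
    np.savetxt(path, data, fmt="%.17g", delimiter="\t")
    if sidecar:
        side = path.with_suffix(path.suffix + ".json")
        meta = {k: v for k, v in spec.meta.items()}
        side.write_text(json.dumps(meta, indent=1, default=str))
    return path


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column text spectrum; a descending axis is reversed.

    The sidecar ``<file>.json`` is loaded into ``meta`` when present.
    A reversed input is flagged with ``meta['axis_reversed'] = True``.
    """
    path = Path(path)
    data = np.loadtxt(path, ndmin=2)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly 2 numeric columns")
    ppm, intensity = data[:, 0], data[:, 1]
    meta: dict = {}
    side = path.with_suffix(path.suffix + ".json")
    if side.exists():
        meta = json.loads(side.read_text())
    reversed_axis = False
    d = np.diff(ppm)
    if np.all(d < 0):
        ppm, intensity = ppm[::-1].copy(), intensity[::-1].copy()
        reversed_axis = True
    elif not np.all(d > 0):
        raise ValueError(f"{path}: ppm axis is not strictly monotone")
    if reversed_axis:
        meta["axis_reversed"] = True
    return Spectrum(ppm=ppm, intensity=intensity, meta=meta)


# ---------------------------------------------------------------------------
# diffusion-edit subtraction and underground removal


def subtract_diffusion_pair(low: Spectrum, high: Spectrum) -> Spectrum:
    """Subtract the high-gradient LED spectrum from the low-gradient one.

    Small molecules diffuse fast and vanish at high gradient, so the
    difference retains their signals while the (slow-diffusing)
    macromolecule envelope cancels.
    """
    for s, role in ((low, "low"), (high, "high")):
        if s.meta.get("method") != "led":
            raise ValueError(f"{role} spectrum is not tagged method='led'")
    gl = low.meta.get("gradient_fraction")
    gh = high.meta.get("gradient_fraction")
    if gl is None or gh is None or not gl < gh:
        raise ValueError(
            f"gradient fractions must satisfy low < high (got {gl!r}, {gh!r})"
        )
    if low.ppm.shape != high.ppm.shape or not np.array_equal(low.ppm, high.ppm):
        raise ValueError("spectra must share an identical ppm axis")
    out = low.with_intensity(low.intensity - high.intensity,
                             method="led_diff", gradient_fraction=None)
    out.meta["gradient_pair"] = (gl, gh)
    return out


def _window_points(spec: Spectrum, width_hz: float) -> int:
    pts = int(round(width_hz / spec.hz_per_point()))
    return max(pts, 1)


def remove_underground(spec: Spectrum, filter_width_hz: float = 20.0) -> Spectrum:
    """Remove broad baseline ("underground") features wider than the filter.

    The baseline is estimated as a rolling median over a window of
    ``filter_width_hz`` and subtracted.  Features much broader than the
    window are tracked by the median and removed; peaks much narrower
    than the window occupy too few points to move the median and
    survive.  Unlike a rolling-minimum estimator, the median is unbiased
    on zero-mean noise, so noise-region integrals stay centered at zero.
    """
    if filter_width_hz <= 0:
        raise ValueError("filter_width_hz must be > 0")
    w = _window_points(spec, filter_width_hz)
    if w < 3:
        raise ValueError(
            f"filter width {filter_width_hz} Hz spans {w} points; need >= 3 "
            "(axis too coarse)"
        )
    baseline = median_filter(spec.intensity, size=w, mode="nearest")
    out = spec.with_intensity(spec.intensity - baseline)
    out.meta["underground_removed_hz"] = float(filter_width_hz)
    return out


# ---------------------------------------------------------------------------
# QC metrics


def estimate_noise(spec: Spectrum, region: tuple[float, float] | None = None) -> float:
    """Robust noise sd from a signal-free region (default: above 10 ppm).

    Uses 1.4826 x median absolute deviation, which tolerates the odd
    stray peak inside the noise window.
    """
    if region is None:
        region = (10.0, float(spec.ppm[-1]))
    lo, hi = min(region), max(region)
    idx = spec.slice_indices(lo, hi)
    if idx.size == 0:
        raise ValueError(f"noise region {region} does not overlap the axis")
    if idx.size < 50:
        raise ValueError(
            f"noise region {region} covers only {idx.size} points (need >= 50)"
        )
    x = spec.intensity[idx]
    mad = np.median(np.abs(x - np.median(x)))
    return float(1.4826 * mad)


def _local_max_index(spec: Spectrum, peak_ppm: float, window: float) -> int:
    idx = spec.slice_indices(peak_ppm - window, peak_ppm + window)
    if idx.size == 0:
        raise ValueError(f"no axis points within {window} ppm of {peak_ppm}")
    return int(idx[np.argmax(spec.intensity[idx])])


def signal_to_noise(
    spec: Spectrum,
    peak_ppm: float = 6.0,
    noise_region: tuple[float, float] = (8.50, 9.99),
    window: float = 0.05,
) -> float:
    """Peak height above local baseline divided by the noise sd.

    Defaults follow the acquisition-method comparison convention: the
    maleate singlet at 6 ppm against the 8.50-9.99 ppm noise window.
    Returns ``inf`` for a noise-free spectrum.
    """
    i = _local_max_index(spec, peak_ppm, window)
    idx = spec.slice_indices(peak_ppm - window, peak_ppm + window)
    local_base = float(np.min(spec.intensity[idx]))
    height = float(spec.intensity[i]) - local_base
    if height <= 0:
        raise ValueError(f"no peak found near {peak_ppm} ppm")
    noise = estimate_noise(spec, noise_region)
    if noise == 0.0:
        return float("inf")
    return height / noise


def peak_width_half_height(
    spec: Spectrum, peak_ppm: float, window: float = 0.05
) -> float:
    """Full width at half maximum of the peak near ``peak_ppm``, in Hz.

    Half-maximum crossings are linearly interpolated between bracketing
    grid points; the local minimum inside the search window serves as the
    baseline reference.
    """
    i = _local_max_index(spec, peak_ppm, window)
    idx = spec.slice_indices(peak_ppm - window, peak_ppm + window)
    base = float(np.min(spec.intensity[idx]))
    apex = float(spec.intensity[i])
    if apex - base <= 0:
        raise ValueError(f"no resolvable peak near {peak_ppm} ppm")
    half = base + 0.5 * (apex - base)
    y = spec.intensity
    x = spec.ppm

    j = i
    while j > 0 and y[j] > half:
        j -= 1
    if y[j] > half:
        raise ValueError("peak truncated at the lower axis boundary")
    left = x[j] + (x[j + 1] - x[j]) * (half - y[j]) / (y[j + 1] - y[j])

    k = i
    n = y.size
    while k < n - 1 and y[k] > half:
        k += 1
    if y[k] > half:
        raise ValueError("peak truncated at the upper axis boundary")
    right = x[k - 1] + (x[k] - x[k - 1]) * (half - y[k - 1]) / (y[k] - y[k - 1])

    return float((right - left) * spec.freq)


def reference_axis(
    spec: Spectrum,
    observed_peak_ppm: float,
    target_ppm: float = 5.22,
    window: float = 0.1,
    doublet: bool = True,
) -> Spectrum:
    """Rigidly shift the axis so the located reference peak sits at target.

    With ``doublet=True`` (the glucose-doublet convention) the reference
    point is the midpoint of the two tallest local maxima in the search
    window when a genuine second line is present (>=50% of the top line);
    otherwise the parabolic-interpolated apex of the single maximum.
    """
    idx = spec.slice_indices(observed_peak_ppm - window, observed_peak_ppm + window)
    if idx.size < 3:
        raise ValueError(
            f"reference peak not found within {window} ppm of {observed_peak_ppm}"
        )
    y = spec.intensity[idx]
    x = spec.ppm[idx]
    noise_floor = np.median(y)
    spread = y.max() - noise_floor
    if spread <= 0:
        raise ValueError("no peak found in the reference window")

    # local maxima inside the window
    interior = np.nonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]))[0] + 1
    if interior.size == 0:
        raise ValueError("no local maximum in the reference window")
    order = interior[np.argsort(y[interior])[::-1]]

    def refine(j: int) -> float:
        if 0 < j < y.size - 1:
            denom = y[j - 1] - 2 * y[j] + y[j + 1]
            if denom != 0:
                delta = 0.5 * (y[j - 1] - y[j + 1]) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
                return float(x[j] + delta * (x[min(j + 1, y.size - 1)] - x[j - 1]) / 2)
        return float(x[j])

    top = order[0]
    observed = refine(top)
    if doublet and order.size > 1:
        second = order[1]
        separated = abs(x[second] - x[top]) > 2 * spec.step
        if separated and y[second] - noise_floor >= 0.5 * (y[top] - noise_floor):
            observed = 0.5 * (refine(top) + refine(second))

    shift = target_ppm - observed
    out = Spectrum(ppm=spec.ppm + shift, intensity=spec.intensity.copy(),
                   meta=dict(spec.meta))
    out.meta["axis_shift_ppm"] = float(shift)
    return out
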