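"""Spectral reduction: equidistant bucketing and peak picking / grouping /
filling, with exclusion of uninformative ppm regions.

Two reduction modes convert a collection of spectra to a samples x
features table.  Bucketing splits the 0-10 ppm window into 0.02 ppm bins
whose values are plain sums of point intensities ("no scaling").  Peak
mode detects local maxima above a signal-to-noise threshold, groups
matching peaks across samples by single-linkage clustering on chemical
shift, and fills group gaps by direct integration, recording true
non-detects as missing so the downstream presence filter can act on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks, peak_widths

from .features import FeatureTable
from .spectra import Spectrum, estimate_noise

__all__ = [
    "DEFAULT_EXCLUSION_REGIONS",
    "Peak",
    "PeakGroup",
    "bucket",
    "bucket_table",
    "exclude_regions",
    "position_excluded",
    "pick_peaks",
    "group_peaks",
    "fill_peaks",
    "peak_table",
]

#: shipped exclusion list: macromolecule envelopes, water, glucose and
#: urea, 1-methylhistidine and acetate regions (closed ppm intervals)
DEFAULT_EXCLUSION_REGIONS: tuple[tuple[float, float], ...] = (
    (0.73, 0.90),
    (1.09, 1.30),
    (1.89, 1.92),
    (3.17, 3.27),
    (3.35, 3.54),
    (3.67, 3.92),
    (4.39, 5.17),
    (5.23, 5.37),
    (5.49, 5.98),
    (7.01, 7.08),
    (7.75, 7.85),
)


@dataclass
class Peak:
    position: float  # ppm, parabolic-refined
    height: float
    fwhm: float  # ppm
    area: float  # trapezoidal, intensity * ppm
    sample_id: str

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("peak height must be > 0")
        if self.fwhm <= 0:
            raise ValueError("peak fwhm must be > 0")


@dataclass
class PeakGroup:
    group_id: int
    members: dict[str, Peak]  # at most one peak per sample
    position: float  # consensus (median of member positions)
    width: float  # consensus width (median member fwhm)


# ---------------------------------------------------------------------------
# bucketing


def bucket(
    spec: Spectrum,
    width: float = 0.02,
    ppm_range: tuple[float, float] = (0.0, 10.0),
) -> pd.Series:
    """Sum point intensities into contiguous half-open [low, low+width) bins.

    Returns a Series indexed by bucket centers; no per-bucket scaling is
    applied.
    """
    lo, hi = ppm_range
    if width <= 0:
        raise ValueError("bucket width must be > 0")
    if width >= hi - lo:
        raise ValueError("bucket width must be smaller than the range span")
    n = int(round((hi - lo) / width))
    edges = lo + width * np.arange(n + 1)
    idx = np.floor((spec.ppm - lo) / width).astype(int)
    ok = (spec.ppm >= lo) & (spec.ppm < edges[-1])
    sums = np.zeros(n)
    np.add.at(sums, idx[ok], spec.intensity[ok])
    centers = edges[:-1] + width / 2.0
    return pd.Series(sums, index=centers, name=spec.meta.get("sample_id"))


def bucket_table(
    spectra: dict[str, Spectrum],
    width: float = 0.02,
    ppm_range: tuple[float, float] = (0.0, 10.0),
    groups: dict[str, str] | None = None,
    batches: dict[str, int] | None = None,
) -> FeatureTable:
    """Bucket every spectrum of a collection into one FeatureTable."""
    rows = {sid: bucket(s, width, ppm_range) for sid, s in spectra.items()}
    values = pd.DataFrame(rows).T
    values.index.name = "sample_id"
    positions = values.columns.to_numpy(dtype=float)
    g = b = None
    if groups is not None:
        g = pd.Series(groups, name="group")
    elif all("group" in s.meta for s in spectra.values()):
        g = pd.Series({sid: s.meta["group"] for sid, s in spectra.items()},
                      name="group")
    if batches is not None:
        b = pd.Series(batches, name="batch")
    elif all("batch" in s.meta for s in spectra.values()):
        b = pd.Series({sid: s.meta["batch"] for sid, s in spectra.items()},
                      name="batch")
    return FeatureTable(values=values, positions=positions, groups=g, batches=b)


# ---------------------------------------------------------------------------
# region exclusion


def position_excluded(position: float,
                      regions=DEFAULT_EXCLUSION_REGIONS) -> bool:
    """True iff the ppm position falls inside any closed interval."""
    for lo, hi in regions:
        if lo > hi:
            raise ValueError(f"inverted exclusion interval ({lo}, {hi})")
        if lo <= position <= hi:
            return True
    return False


def exclude_regions(table: FeatureTable,
                    regions=DEFAULT_EXCLUSION_REGIONS) -> FeatureTable:
    """Drop features whose center lies inside any exclusion interval."""
    keep = np.array([not position_excluded(p, regions) for p in table.positions])
    out = table.copy_with(table.values.loc[:, keep],
                          positions=table.positions[keep])
    out.history.append("exclude_regions")
    return out


# ---------------------------------------------------------------------------
# peak picking


def pick_peaks(
    spec: Spectrum,
    snr_min: float = 3.0,
    min_separation: float = 0.003,
    noise_sd: float | None = None,
    regions=None,
    min_fwhm_hz: float = 0.5,
    baseline_width_hz: float = 20.0,
) -> list[Peak]:
    """Detect local maxima whose height above the local baseline exceeds
    ``snr_min`` times the noise sd.

    The signal is first baseline-corrected with a rolling median over
    ``baseline_width_hz`` so that broad envelopes (residual macromolecule
    humps, underground remnants) do not contribute to peak heights —
    the implicit behavior of the wavelet detectors this local-maximum
    picker replaces.  Candidate maxima must clear ``snr_min * noise_sd``
    in both height and topographic prominence on the corrected signal.
    Positions are refined by 3-point parabolic interpolation, widths are
    taken at half prominence with linear interpolation, and areas by
    trapezoidal integration of the corrected signal over +-2 FWHM.
    ``regions`` optionally drops peaks whose centers fall in exclusion
    intervals before they enter grouping.  ``min_fwhm_hz`` plays the role
    of the minimum scale of a wavelet detector: single-gridpoint noise
    spikes are narrower than any genuine resonance line and are rejected
    by width.
    """
    if spec.ppm.size < 5:
        raise ValueError("spectrum too short for peak picking (need >= 5 points)")
    if noise_sd is None:
        noise_sd = estimate_noise(spec)
    ppm = spec.ppm
    w_base = int(round(baseline_width_hz / spec.hz_per_point()))
    if w_base >= 3:
        y = spec.intensity - median_filter(spec.intensity, size=w_base,
                                           mode="nearest")
    else:
        y = spec.intensity
    if noise_sd > 0:
        height = snr_min * noise_sd
    else:
        height = 1e3 * np.finfo(float).tiny
    distance = max(int(round(min_separation / spec.step)), 1)
    idx, props = find_peaks(y, height=height, prominence=height,
                            distance=distance)
    if idx.size == 0:
        return []
    widths_pts, _, _, _ = peak_widths(y, idx, rel_height=0.5,
                                      prominence_data=(props["prominences"],
                                                       props["left_bases"],
                                                       props["right_bases"]))
    sid = spec.meta.get("sample_id", "")
    peaks: list[Peak] = []
    for i, prom, w_pts in zip(idx, props["prominences"], widths_pts):
        # parabolic refinement of apex position and height
        pos, h = float(ppm[i]), float(y[i])
        if 0 < i < y.size - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if denom != 0:
                delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
                if abs(delta) <= 1.0:
                    pos = float(ppm[i] + delta * spec.step)
                    h = float(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta)
        w = float(w_pts) * spec.step
        if w <= 0 or w * spec.freq < min_fwhm_hz:
            continue
        if regions is not None and position_excluded(pos, regions):
            continue
        sl = spec.slice_indices(pos - 2 * w, pos + 2 * w)
        area = float(np.trapezoid(y[sl], ppm[sl]))
        if area <= 0:
            continue
        peaks.append(Peak(position=pos, height=h, fwhm=w,
                          area=area, sample_id=sid))
    return peaks


# ---------------------------------------------------------------------------
# peak grouping


def _single_linkage_clusters(positions: np.ndarray, tol: float) -> np.ndarray:
    """Single-linkage labels with the dendrogram cut at ``tol``.

    In one dimension single linkage reduces to splitting the sorted
    positions wherever the gap exceeds ``tol`` (O(n log n); identical to
    `scipy.cluster.hierarchy.linkage(method='single')` + `fcluster`).
    """
    if positions.size == 1:
        return np.zeros(1, dtype=int)
    order = np.argsort(positions)
    gaps = np.diff(positions[order]) > tol
    labels_sorted = np.concatenate([[0], np.cumsum(gaps)])
    labels = np.empty(positions.size, dtype=int)
    labels[order] = labels_sorted
    return labels


def group_peaks(peaks: list[Peak], tol: float = 0.0075) -> list[PeakGroup]:
    """Group peaks across samples by single-linkage clustering on position.

    Within a cluster each sample may contribute only one peak; extra
    peaks from the same sample are returned to the pool and re-grouped,
    so close-but-distinct signals are not silently merged away.
    """
    if tol <= 0:
        raise ValueError("grouping tolerance must be > 0")
    groups: list[PeakGroup] = []
    pool = list(peaks)
    gid = 0
    while pool:
        positions = np.array([p.position for p in pool])
        labels = _single_linkage_clusters(positions, tol)
        leftover: list[Peak] = []
        for lab in np.unique(labels):
            cluster = [p for p, l in zip(pool, labels) if l == lab]
            med = float(np.median([p.position for p in cluster]))
            members: dict[str, Peak] = {}
            for p in sorted(cluster, key=lambda p: abs(p.position - med)):
                if p.sample_id not in members:
                    members[p.sample_id] = p
                else:
                    leftover.append(p)
            groups.append(PeakGroup(
                group_id=gid,
                members=members,
                position=float(np.median([p.position for p in members.values()])),
                width=float(np.median([p.fwhm for p in members.values()])),
            ))
            gid += 1
        if len(leftover) == len(pool):  # no progress; stop
            break
        pool = leftover
    groups.sort(key=lambda g: g.position)
    for i, g in enumerate(groups):
        g.group_id = i
    return groups


# ---------------------------------------------------------------------------
# filling


def fill_peaks(
    groups: list[PeakGroup],
    spectra: dict[str, Spectrum],
    noise_sds: dict[str, float] | None = None,
    snr_min: float = 3.0,
    group_labels: dict[str, str] | None = None,
) -> FeatureTable:
    """Build the feature table: picked areas, filled integrals, non-detects.

    Where a sample has no picked member, the spectrum is integrated over
    the consensus position +- consensus width; integrals below
    ``snr_min * noise_sd * interval_width`` are recorded missing
    (non-detects) so the presence filter can drop unreliable features.
    """
    sample_ids = list(spectra)
    if noise_sds is None:
        noise_sds = {sid: estimate_noise(s) for sid, s in spectra.items()}
    cols = {}
    positions = []
    for g in groups:
        vals = {}
        for sid in sample_ids:
            if sid in g.members:
                vals[sid] = g.members[sid].area
            else:
                s = spectra[sid]
                lo, hi = g.position - g.width, g.position + g.width
                sl = s.slice_indices(lo, hi)
                if sl.size < 2:
                    vals[sid] = np.nan
                    continue
                integral = float(np.trapezoid(s.intensity[sl], s.ppm[sl]))
                threshold = snr_min * noise_sds[sid] * (hi - lo)
                vals[sid] = integral if integral >= threshold else np.nan
        cols[g.position] = vals
        positions.append(g.position)
    values = pd.DataFrame(cols, index=sample_ids)
    values.index.name = "sample_id"
    grp = None
    if group_labels is not None:
        grp = pd.Series(group_labels, name="group")
    elif all("group" in s.meta for s in spectra.values()):
        grp = pd.Series({sid: s.meta["group"] for sid, s in spectra.items()},
                        name="group")
    batches = None
    if all("batch" in s.meta for s in spectra.values()):
        batches = pd.Series({sid: s.meta["batch"] for sid, s in spectra.items()},
                            name="batch")
    return FeatureTable(values=values, positions=np.array(positions),
                        groups=grp, batches=batches)


def peak_table(
    spectra: dict[str, Spectrum],
    snr_min: float = 3.0,
    min_separation: float = 0.003,
    tol: float = 0.0075,
    regions=DEFAULT_EXCLUSION_REGIONS,
    min_fwhm_hz: float = 0.5,
) -> FeatureTable:
    """Full peak-mode reduction: pick, exclude, group and fill."""
    noise_sds = {sid: estimate_noise(s) for sid, s in spectra.items()}
    all_peaks: list[Peak] = []
    for sid, s in spectra.items():
        all_peaks.extend(pick_peaks(s, snr_min=snr_min,
                                    min_separation=min_separation,
                                    noise_sd=noise_sds[sid], regions=regions,
                                    min_fwhm_hz=min_fwhm_hz))
    groups = group_peaks(all_peaks, tol=tol)
    return fill_peaks(groups, spectra, noise_sds=noise_sds, snr_min=snr_min)
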