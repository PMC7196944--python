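"""Quantification-performance assessment.

Standard-addition linearity (ordinary least squares of the NMR-measured
concentration on the known added amount), detection limits derived from
the intercept standard error, recovery against a reference assay,
Bland-Altman method agreement, and QC repeatability (per-peak relative
standard deviation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LinearityReport",
    "fit_standard_addition",
    "lod",
    "loq",
    "recovery",
    "BlandAltman",
    "bland_altman",
    "repeatability_rsd",
    "QuantReport",
]


@dataclass
class LinearityReport:
    """OLS summary for one metabolite's standard-addition series."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r2_adj: float
    slope_p: float
    rse: float  # residual standard error
    prediction_error: float  # rse / mean measured concentration
    n: int


def fit_standard_addition(added, measured) -> LinearityReport:
    """Regress the NMR-measured concentration on the known added amount."""
    added = np.asarray(added, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if added.shape != measured.shape:
        raise ValueError("added and measured must have equal length")
    if np.unique(added).size < 3:
        raise ValueError("need at least 3 distinct added levels")
    if np.ptp(added) == 0:
        raise ValueError("added amounts are constant")
    model = sm.OLS(measured, sm.add_constant(added)).fit()
    intercept, slope = model.params
    se_intercept, se_slope = model.bse
    rse = float(np.sqrt(model.ssr / model.df_resid)) if model.df_resid > 0 else 0.0
    mean_measured = float(np.mean(measured))
    return LinearityReport(
        slope=float(slope),
        intercept=float(intercept),
        se_slope=float(se_slope),
        se_intercept=float(se_intercept),
        r2_adj=float(model.rsquared_adj),
        slope_p=float(model.pvalues[1]),
        rse=rse,
        prediction_error=rse / mean_measured if mean_measured != 0 else np.inf,
        n=int(len(added)),
    )


def lod(report: LinearityReport) -> float:
    """Limit of detection: 3.3 x SE(intercept) / slope."""
    if report.slope == 0:
        raise ValueError("slope is zero; LOD undefined")
    return 3.3 * report.se_intercept / report.slope


def loq(report: LinearityReport) -> float:
    """Limit of quantification: 3.3 x LOD."""
    return 3.3 * lod(report)


def recovery(measured_by_nmr, reference, mode: str = "ratio") -> dict:
    """Per-level recovery of the NMR method against the reference assay.

    ``measured_by_nmr`` and ``reference`` map level -> replicate value
    arrays.  ``mode='ratio'`` reports ``100 * mean_NMR / mean_reference``
    (the default); ``mode='difference'`` reports
    ``100 * (mean_NMR - mean_ref) / mean_ref``.  The RSD column is
    ``100 * sd / mean`` of the NMR replicates.
    """
    if mode not in ("ratio", "difference"):
        raise ValueError("mode must be 'ratio' or 'difference'")
    if set(measured_by_nmr) != set(reference):
        raise ValueError("levels of the two methods do not match")
    out = {}
    for level in measured_by_nmr:
        nmr = np.asarray(measured_by_nmr[level], dtype=float)
        ref = np.asarray(reference[level], dtype=float)
        if nmr.size < 2:
            raise ValueError(f"level {level!r}: need >= 2 replicates for RSD")
        mean_ref = float(ref.mean())
        if mean_ref == 0:
            raise ValueError(f"level {level!r}: zero reference mean")
        mean_nmr = float(nmr.mean())
        if mode == "ratio":
            rec = 100.0 * mean_nmr / mean_ref
        else:
            rec = 100.0 * (mean_nmr - mean_ref) / mean_ref
        rsd = 100.0 * float(nmr.std(ddof=1)) / mean_nmr if mean_nmr != 0 else np.inf
        out[level] = {"recovery_pct": rec, "rsd_pct": rsd}
    return out


@dataclass
class BlandAltman:
    """Agreement summary; differences are a - b (NMR minus reference),
    so a positive bias means the NMR method reads high."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    differences: np.ndarray


def bland_altman(method_a, method_b) -> BlandAltman:
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("method vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired measurements")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(a + b) / 2.0,
        differences=diff,
    )


def repeatability_rsd(qc_table, cutoff: float = 30.0) -> dict:
    """Per-peak RSD over replicate QC runs plus summary statistics.

    ``qc_table`` is runs x peaks (DataFrame or array).  Returns per-peak
    RSD (%), the median RSD, and the count/fraction of peaks with RSD
    below ``cutoff`` (%).
    """
    df = pd.DataFrame(qc_table)
    if df.shape[0] < 3:
        raise ValueError("need at least 3 QC runs")
    means = df.mean(axis=0)
    if (means == 0).any():
        bad = list(means.index[means == 0])
        raise ValueError(f"zero-mean peak(s): {bad}")
    rsd = 100.0 * df.std(axis=0, ddof=1) / means
    below = rsd < cutoff
    return {
        "per_peak_rsd": rsd,
        "median_rsd": float(rsd.median()),
        "n_peaks": int(rsd.size),
        "n_below_cutoff": int(below.sum()),
        "fraction_below_cutoff": float(below.mean()),
        "cutoff": float(cutoff),
    }


@dataclass
class QuantReport:
    """Aggregated quantification-validation results."""

    linearity: dict[str, LinearityReport] = field(default_factory=dict)
    lod: dict[str, float] = field(default_factory=dict)
    loq: dict[str, float] = field(default_factory=dict)
    recovery: dict[str, dict] = field(default_factory=dict)
    bland_altman: dict[str, BlandAltman] = field(default_factory=dict)
    repeatability: dict[str, dict] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, lin in self.linearity.items():
            rows.append({
                "metabolite": name,
                "slope": lin.slope,
                "intercept": lin.intercept,
                "r2_adj": lin.r2_adj,
                "slope_p": lin.slope_p,
                "rse": lin.rse,
                "prediction_error": lin.prediction_error,
                "lod_mM": self.lod.get(name),
                "loq_mM": self.loq.get(name),
            })
        return pd.DataFrame(rows).set_index("metabolite") if rows else pd.DataFrame()
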