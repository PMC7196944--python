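"""Feature-table conditioning: presence filter, reference scaling, PQN,
KNN imputation, and the generalized log transform.

The conditioning chain runs in a fixed order,

    presence_filter -> scale_to_reference -> pqn -> knn_impute -> glog,

mirroring the processing sequence used for untargeted plasma peak and
bucket tables; each :class:`FeatureTable` records the stages applied and
the module refuses to run a stage after a later one has already been
applied.  Each step is also available as a scikit-learn style
transformer operating on plain (samples x features) arrays with NaN as
the missing-value marker.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._base import BaseEstimator, TransformerMixin, check_is_fitted

__all__ = [
    "FeatureTable",
    "presence_filter",
    "scale_to_reference_feature",
    "pqn_normalize",
    "knn_impute",
    "glog_transform",
    "estimate_glog_lambda",
    "glog_table",
    "condition_table",
    "PresenceFilter",
    "ReferenceFeatureScaler",
    "PQNNormalizer",
    "FeatureKNNImputer",
    "GlogTransformer",
]

#: enforced stage order of the conditioning chain
STAGES = ("presence_filter", "scale_to_reference", "pqn", "knn_impute", "glog")


class PipelineOrderError(RuntimeError):
    """Raised when a conditioning stage is applied out of order."""


@dataclass
class FeatureTable:
    """Samples x features matrix with ppm positions and sample labels.

    ``values`` holds one row per sample; columns are features whose ppm
    centers live in ``positions`` (same order).  Missing values are NaN.
    """

    values: pd.DataFrame
    positions: np.ndarray
    groups: pd.Series | None = None
    batches: pd.Series | None = None
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.size != self.values.shape[1]:
            raise ValueError("positions length must match the feature count")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def copy_with(self, values: pd.DataFrame | np.ndarray,
                  positions: np.ndarray | None = None,
                  stage: str | None = None) -> "FeatureTable":
        if isinstance(values, np.ndarray):
            values = pd.DataFrame(values, index=self.values.index,
                                  columns=self.values.columns)
        pos = self.positions if positions is None else np.asarray(positions, float)
        hist = list(self.history) + ([stage] if stage else [])
        return FeatureTable(values=values, positions=pos, groups=self.groups,
                            batches=self.batches, history=hist)

    def feature_index_near(self, position: float, tol: float = 0.02) -> int:
        """Index of the feature whose center is nearest ``position``."""
        d = np.abs(self.positions - position)
        j = int(np.argmin(d))
        if d[j] > tol:
            raise KeyError(
                f"no feature within {tol} ppm of {position} "
                f"(nearest at {self.positions[j]:.4f})"
            )
        return j

    # -- persistence (delimited text; missing cells are empty) --------------

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.values.copy()
        df.columns = [f"{p:.6f}" for p in self.positions]
        if self.groups is not None:
            df.insert(0, "group", self.groups)
        if self.batches is not None:
            df.insert(1 if self.groups is not None else 0, "batch", self.batches)
        df.to_csv(path, index_label="sample_id")
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="sample_id")
        groups = batches = None
        if "group" in df.columns:
            groups = df.pop("group")
        if "batch" in df.columns:
            batches = df.pop("batch")
        positions = np.array([float(c) for c in df.columns])
        return cls(values=df, positions=positions, groups=groups, batches=batches)


def _check_order(table: FeatureTable, stage: str) -> None:
    rank = STAGES.index(stage)
    for done in table.history:
        if done in STAGES and STAGES.index(done) > rank:
            raise PipelineOrderError(
                f"cannot apply {stage!r} after {done!r}; the conditioning "
                f"chain order is {' -> '.join(STAGES)}"
            )


# ---------------------------------------------------------------------------
# presence filter


class PresenceFilter(BaseEstimator, TransformerMixin):
    """Drop features with too many non-detects in every group.

    A feature is kept iff its observed fraction is at least ``min_frac``
    within at least one group (``rule='any'``); ``rule='all'`` requires
    the threshold in every group.
    """

    def __init__(self, min_frac: float = 0.8, rule: str = "any"):
        self.min_frac = min_frac
        self.rule = rule

    def fit(self, X, y=None):
        if not 0.0 <= self.min_frac <= 1.0:
            raise ValueError("min_frac must lie in [0, 1]")
        if self.rule not in ("any", "all"):
            raise ValueError("rule must be 'any' or 'all'")
        X = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError("presence filtering needs group labels y")
        y = np.asarray(y)
        labels = np.unique(y)
        if len(labels) < 2 or any((y == g).sum() < 2 for g in labels):
            raise ValueError("need >=2 groups with >=2 samples each")
        fracs = np.vstack([
            np.mean(~np.isnan(X[y == g]), axis=0) for g in labels
        ])
        if self.rule == "any":
            self.support_ = (fracs >= self.min_frac).any(axis=0)
        else:
            self.support_ = (fracs >= self.min_frac).all(axis=0)
        self.group_fractions_ = pd.DataFrame(fracs, index=labels)
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X, dtype=float)[:, self.support_]


def presence_filter(table: FeatureTable, min_frac: float = 0.8,
                    rule: str = "any") -> FeatureTable:
    _check_order(table, "presence_filter")
    if table.groups is None:
        raise ValueError("table carries no group labels")
    f = PresenceFilter(min_frac=min_frac, rule=rule).fit(
        table.matrix(), table.groups.to_numpy()
    )
    keep = f.support_
    out = table.copy_with(table.values.loc[:, keep],
                          positions=table.positions[keep],
                          stage="presence_filter")
    return out


# ---------------------------------------------------------------------------
# internal-standard scaling


class ReferenceFeatureScaler(BaseEstimator, TransformerMixin):
    """Divide each sample by its value of one reference feature."""

    def __init__(self, ref_index: int = 0, drop_reference: bool = False):
        self.ref_index = ref_index
        self.drop_reference = drop_reference

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        ref = X[:, self.ref_index]
        bad = np.nonzero(~(ref > 0))[0]
        if bad.size:
            raise ValueError(
                f"reference feature missing or <= 0 in sample row(s) {bad.tolist()}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float)
        ref = X[:, self.ref_index]
        out = X / ref[:, None]
        if self.drop_reference:
            out = np.delete(out, self.ref_index, axis=1)
        return out


def scale_to_reference_feature(table: FeatureTable, ref_position: float = 6.0,
                               tol: float = 0.02) -> FeatureTable:
    """Scale every sample to its internal-standard (maleate) feature."""
    _check_order(table, "scale_to_reference")
    j = table.feature_index_near(ref_position, tol)
    ref = table.values.iloc[:, j]
    bad = ref.index[~(ref > 0) | ref.isna()]
    if len(bad):
        raise ValueError(
            f"reference feature at {table.positions[j]:.4f} ppm missing or <= 0 "
            f"in sample(s): {', '.join(map(str, bad))}"
        )
    scaler = ReferenceFeatureScaler(ref_index=j).fit(table.matrix())
    out = table.copy_with(scaler.transform(table.matrix()), stage="scale_to_reference")
    return out


# ---------------------------------------------------------------------------
# probabilistic quotient normalization


def _pqn_median_quotient_pass(X: np.ndarray, min_shared: int) -> np.ndarray:
    """One application of the PQN map: median spectrum, median quotients."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref = np.nanmedian(X, axis=0)
    usable = ~np.isnan(X) & ~np.isnan(ref) & (ref != 0)
    factors = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        m = usable[i]
        if m.sum() < min_shared:
            raise ValueError(
                f"sample row {i} shares only {int(m.sum())} observed "
                f"features with the reference (need >= {min_shared})"
            )
        factors[i] = np.median(X[i, m] / ref[m])
    return factors


def _pqn_factors(X: np.ndarray, min_shared: int = 3, max_iter: int = 500,
                 tol: float = 1e-12) -> np.ndarray:
    """Total per-sample PQN factors at the fixpoint of the quotient map.

    The median-quotient map is applied repeatedly (each pass recomputes
    the median reference spectrum from the current table) until every
    per-pass factor is 1 within ``tol``; the returned factors are the
    accumulated products.  At the fixpoint, re-running the normalization
    leaves the table unchanged (idempotence).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PQN needs at least 3 samples")
    total = np.ones(X.shape[0])
    current = X.copy()
    devs: list[float] = []
    for it in range(max_iter):
        f = _pqn_median_quotient_pass(current, min_shared)
        total *= f
        current = current / f[:, None]
        dev = float(np.max(np.abs(f - 1.0)))
        devs.append(dev)
        if dev < tol:
            return total
        # noise-dominated tables can settle into a small limit cycle
        # instead of a fixpoint; stop once progress stalls
        if it >= 50 and dev > 0.5 * devs[it - 25]:
            warnings.warn(
                f"PQN quotient map settled into a limit cycle (residual "
                f"factor deviation {dev:.2e}); returning the accumulated "
                "factors", RuntimeWarning)
            return total
    warnings.warn("PQN fixpoint iteration did not converge; factors are "
                  "the best available", RuntimeWarning)
    return total


class PQNNormalizer(BaseEstimator, TransformerMixin):
    """Probabilistic quotient normalization with missing-value support.

    The reference spectrum is the feature-wise median over samples
    (ignoring non-detects); each sample is divided by the median of its
    observed quotients against that reference.  The map is iterated to
    its fixpoint so the normalization is idempotent: factors recomputed
    on an already-normalized table are all 1.
    """

    def __init__(self, min_shared: int = 3, max_iter: int = 500,
                 tol: float = 1e-12):
        self.min_shared = min_shared
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 3:
            raise ValueError("PQN needs at least 3 samples")
        f = _pqn_factors(X, self.min_shared, self.max_iter, self.tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.reference_ = np.nanmedian(X / f[:, None], axis=0)
        return self

    def factors(self, X) -> np.ndarray:
        check_is_fitted(self, "reference_")
        return _pqn_factors(np.asarray(X, dtype=float), self.min_shared,
                            self.max_iter, self.tol)

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        f = self.factors(X)
        return X / f[:, None]


def pqn_normalize(table: FeatureTable) -> tuple[FeatureTable, pd.Series]:
    """PQN-normalize a table; returns the table and per-sample factors."""
    _check_order(table, "pqn")
    f = _pqn_factors(table.matrix())
    factors = pd.Series(f, index=table.values.index, name="pqn_factor")
    out = table.copy_with(table.matrix() / f[:, None], stage="pqn")
    return out, factors


# ---------------------------------------------------------------------------
# KNN imputation (neighbors are features)


class FeatureKNNImputer(BaseEstimator, TransformerMixin):
    """Impute non-detects from the k most similar *features*.

    Feature-feature distance is the root-mean-square difference over
    co-observed samples (so sparsity does not shrink distances); an
    imputed cell is the inverse-distance-weighted mean of the k nearest
    features' values in that sample.  Zero-distance neighbors share
    uniform weights.  When fewer than k neighbors are observed in the
    sample, the feature's own observed mean is used instead.
    """

    def __init__(self, k: int = 10):
        self.k = k

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        obs = ~np.isnan(X)
        if not obs.any(axis=0).all():
            raise ValueError("a feature is entirely missing")
        if not obs.any(axis=1).all():
            raise ValueError("a sample is entirely missing")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float).copy()
        obs = ~np.isnan(X)
        if obs.all():
            return X
        n, p = X.shape
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            feat_means = np.nanmean(X, axis=0)

        # pairwise RMS distance over co-observed samples; Xz is zero where
        # unobserved so the masked sums reduce to matrix products
        Xz = np.where(obs, X, 0.0)
        O = obs.astype(float)
        co = O.T @ O  # co-observed counts
        cross = Xz.T @ Xz
        ss = (Xz * Xz).T @ O
        d2 = ss + ss.T - 2.0 * cross
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.sqrt(np.maximum(d2, 0.0) / co)
        D[co == 0] = np.inf
        np.fill_diagonal(D, np.inf)

        for j in range(p):
            rows = np.nonzero(~obs[:, j])[0]
            if rows.size == 0:
                continue
            order = np.argsort(D[j])
            for i in rows:
                # neighbors must be observed in sample i and comparable to j
                cand = [l for l in order
                        if np.isfinite(D[j, l]) and obs[i, l]]
                if len(cand) < self.k:
                    X[i, j] = feat_means[j]
                    continue
                nn = np.array(cand[: self.k])
                d = D[j, nn]
                if np.any(d == 0):
                    zero = nn[d == 0]
                    X[i, j] = float(np.mean(X[i, zero]))
                else:
                    w = 1.0 / d
                    X[i, j] = float(np.sum(w * X[i, nn]) / np.sum(w))
        return X


def knn_impute(table: FeatureTable, k: int = 10) -> FeatureTable:
    _check_order(table, "knn_impute")
    imp = FeatureKNNImputer(k=k).fit(table.matrix())
    return table.copy_with(imp.transform(table.matrix()), stage="knn_impute")


# ---------------------------------------------------------------------------
# generalized log transform


def glog_transform(x, lambda_: float):
    """Generalized log ``g(x) = ln(x + sqrt(x**2 + lambda))``.

    With ``lambda = 0`` this is ``ln(2x)`` (x > 0 required); at ``x = 0``
    it equals ``ln(lambda)/2``.
    """
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    x = np.asarray(x, dtype=float)
    root = np.sqrt(x * x + lambda_)
    # for x < 0 the direct form x + root cancels catastrophically; the
    # algebraically equal lambda / (root - x) stays accurate
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = np.where(x >= 0, x + root, lambda_ / (root - x))
    if np.any(inner[~np.isnan(inner)] <= 0):
        raise ValueError("glog domain violation: x + sqrt(x^2 + lambda) <= 0")
    out = np.log(inner)
    return out if out.ndim else float(out)


def _heterogeneity(X: np.ndarray, lam: float) -> float:
    """Spread of per-feature replicate variances after glog (lower = flatter)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.log(X + np.sqrt(X * X + lam))
    if not np.all(np.isfinite(g)):
        return float("inf")  # lambda too small for the data's negatives
    v = np.var(g, axis=0, ddof=1)
    m = v.mean()
    if m <= 0:
        return 0.0
    return float(v.std(ddof=0) / m)


def estimate_glog_lambda(
    table_or_matrix, replicate_group: str | None = None,
    n_grid: int = 60, n_golden: int = 60,
) -> float:
    """Calibrate the glog lambda on a technical-replicate block.

    Minimizes the heterogeneity of per-feature variances of the
    transformed replicate values over ``lambda`` in
    ``[1e-12, 1e12] * median(value)**2`` — a coarse log-spaced grid
    followed by golden-section refinement on log lambda.
    """
    if isinstance(table_or_matrix, FeatureTable):
        table = table_or_matrix
        if replicate_group is None:
            raise ValueError("replicate_group is required with a FeatureTable")
        mask = (table.groups == replicate_group).to_numpy()
        X = table.matrix()[mask]
    else:
        X = np.asarray(table_or_matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 replicate samples to calibrate lambda")
    if np.isnan(X).any():
        raise ValueError("replicate block must be complete (impute first)")

    scale = float(np.median(np.abs(X[X != 0]))) if np.any(X != 0) else 1.0
    lo, hi = math.log(1e-12 * scale * scale), math.log(1e12 * scale * scale)

    if np.allclose(np.var(X, axis=0), 0.0):
        warnings.warn("replicate block has zero variance; returning the "
                      "lambda search lower bound", RuntimeWarning)
        return math.exp(lo)

    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([_heterogeneity(X, math.exp(u)) for u in grid])
    j = int(np.argmin(vals))
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, n_grid - 1)]

    # golden-section refinement on log-lambda
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _heterogeneity(X, math.exp(c))
    fd = _heterogeneity(X, math.exp(d))
    for _ in range(n_golden):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _heterogeneity(X, math.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _heterogeneity(X, math.exp(d))
    return math.exp(0.5 * (a + b))


class GlogTransformer(BaseEstimator, TransformerMixin):
    """Variance-stabilizing glog; lambda fixed or calibrated on replicates."""

    def __init__(self, lam: float | None = None):
        self.lam = lam

    def fit(self, X, y=None, replicate_mask=None):
        X = np.asarray(X, dtype=float)
        if self.lam is not None:
            self.lambda_ = float(self.lam)
        else:
            block = X if replicate_mask is None else X[np.asarray(replicate_mask)]
            self.lambda_ = estimate_glog_lambda(block)
        return self

    def transform(self, X):
        check_is_fitted(self, "lambda_")
        return glog_transform(X, self.lambda_)


def glog_table(table: FeatureTable, replicate_group: str,
               lam: float | None = None) -> tuple[FeatureTable, float]:
    _check_order(table, "glog")
    if "knn_impute" not in table.history and np.isnan(table.matrix()).any():
        raise ValueError("glog requires a complete table; run knn_impute first")
    mask = None
    if lam is None:
        if table.groups is None:
            raise ValueError("lambda calibration needs group labels")
        mask = (table.groups == replicate_group).to_numpy()
        if mask.sum() < 3:
            raise ValueError(
                f"replicate group {replicate_group!r} has fewer than 3 samples"
            )
    t = GlogTransformer(lam=lam).fit(table.matrix(), replicate_mask=mask)
    out = table.copy_with(t.transform(table.matrix()), stage="glog")
    return out, t.lambda_


# ---------------------------------------------------------------------------
# the full chain


def condition_table(
    table: FeatureTable,
    min_frac: float = 0.8,
    presence_rule: str = "any",
    ref_position: float = 6.0,
    ref_tol: float = 0.02,
    k: int = 10,
    replicate_group: str = "PA",
    lam: float | None = None,
) -> tuple[FeatureTable, dict]:
    """Run the full conditioning chain in its enforced order.

    Returns the conditioned table and a processing log (feature counts,
    PQN factors, calibrated lambda).
    """
    log: dict = {"n_features_in": table.n_features}
    t = presence_filter(table, min_frac=min_frac, rule=presence_rule)
    log["n_features_after_presence"] = t.n_features
    t = scale_to_reference_feature(t, ref_position=ref_position, tol=ref_tol)
    t, factors = pqn_normalize(t)
    log["pqn_factors"] = factors
    t = knn_impute(t, k=k)
    t, lam_used = glog_table(t, replicate_group=replicate_group, lam=lam)
    log["glog_lambda"] = lam_used
    return t, log
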