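"""Stimulus-locked feature extraction and SVM-based classification.

Per stimulus, each of the 13 instantaneous estimators is restricted to the
last second of the stimulus window, normalized pointwise by the estimator's
median over the first 10 s of the initial resting phase, and summarized by
its maximum, median and median absolute deviation -- 13 x 3 = 39 dimensions.

Classification follows a leave-one-out nu-SVM (nu = 0.5, radial basis kernel,
gamma = 1/n_features) with per-fold median/MAD normalization fitted on the
training split only, plus a nonlinear SVM-RFE feature ranking with a
correlation-bias-reduction grouping of highly correlated features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.svm import NuSVC

log = logging.getLogger(__name__)

__all__ = [
    "SUMMARIES",
    "FeatureVector",
    "ClassificationResult",
    "extract_stimulus_features",
    "features_to_table",
    "remove_outliers",
    "wilcoxon_screen",
    "loo_classify",
    "svm_rfe_rank",
]

SUMMARIES = ("max", "median", "mad")


@dataclass(frozen=True)
class FeatureVector:
    """39-dimensional per-stimulus summary (13 estimators x 3 summaries)."""

    subject_id: str
    stimulus_id: str
    force_class: str
    velocity_class: str
    names: tuple
    values: np.ndarray
    baseline: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if len(self.names) != v.size:
            raise ValueError("names/values length mismatch")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite values")


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def extract_stimulus_features(estimates: pd.DataFrame, annotations,
                              estimator_columns,
                              rest_baseline_window: float = 10.0,
                              last_window: float = 1.0,
                              force_threshold: float | None = None,
                              velocity_threshold: float | None = None
                              ) -> list[FeatureVector]:
    """Extract per-stimulus feature vectors from an estimate time series.

    ``estimates`` must have a ``time`` column plus one column per estimator.
    The baseline normalizer of each estimator is its median over the first
    ``rest_baseline_window`` seconds of the initial rest window; the feature
    values are max/median/MAD of the normalized series over the last
    ``last_window`` seconds of each stimulus.

    Raises if a stimulus is shorter than ``last_window``, if the rest or
    stimulus windows are not covered by the estimates, or if any in-window
    estimate is non-finite.
    """
    t = estimates["time"].to_numpy()
    out = []
    forces = sorted({a.force_level for a in annotations})
    vels = sorted({a.velocity_level for a in annotations})
    f_thr = force_threshold if force_threshold is not None else np.mean(forces)
    v_thr = velocity_threshold if velocity_threshold is not None else np.mean(vels)

    for si, ann in enumerate(annotations):
        if ann.duration < last_window:
            raise ValueError(
                f"stimulus {si} of subject {ann.subject_id} lasts "
                f"{ann.duration:.2f}s < {last_window}s")
        if not ann.rest_windows:
            raise ValueError("annotation carries no rest windows")
        # baseline: first covered `rest_baseline_window` seconds of the
        # initial rest (estimates only exist after the model burn-in)
        rs, re_ = ann.rest_windows[0]
        lo = max(rs, float(t[0]))
        rest_mask = (t >= lo) & (t < lo + rest_baseline_window)
        if lo + rest_baseline_window > re_ or not rest_mask.any():
            raise ValueError(
                f"estimates do not cover {rest_baseline_window}s of the "
                f"initial rest for subject {ann.subject_id}")
        win_mask = (t >= ann.offset - last_window) & (t < ann.offset)
        if not win_mask.any():
            raise ValueError(
                f"estimates do not cover the last second of stimulus {si} "
                f"of subject {ann.subject_id}")
        names, values, baseline = [], [], []
        for col in estimator_columns:
            series = estimates[col].to_numpy()
            base = float(np.median(series[rest_mask]))
            seg = series[win_mask]
            if not np.all(np.isfinite(seg)) or not np.isfinite(base):
                raise ValueError(
                    f"non-finite {col} values in stimulus {si} of subject "
                    f"{ann.subject_id}")
            if abs(base) < 1e-12:
                # degenerate rest baseline (e.g. an exactly-zero entropy
                # stretch): fall back to the mean magnitude, then to 1
                base = float(np.mean(np.abs(series[rest_mask]))) or 1.0
                log.warning("rest baseline of %s is zero for subject %s; "
                            "using mean-magnitude fallback", col,
                            ann.subject_id)
            norm = seg / base
            names += [f"{col}__max", f"{col}__median", f"{col}__mad"]
            values += [float(np.max(norm)), float(np.median(norm)), _mad(norm)]
            baseline.append(base)
        out.append(FeatureVector(
            subject_id=ann.subject_id, stimulus_id=f"{ann.subject_id}_{si}",
            force_class="high" if ann.force_level > f_thr else "low",
            velocity_class="high" if ann.velocity_level > v_thr else "low",
            names=tuple(names), values=np.array(values),
            baseline=np.array(baseline)))
    return out


def features_to_table(features: list[FeatureVector]) -> pd.DataFrame:
    """Tidy table: one row per stimulus, columns estimator__summary."""
    rows = []
    for f in features:
        row = {"subject": f.subject_id, "stimulus": f.stimulus_id,
               "force_class": f.force_class, "velocity_class": f.velocity_class}
        row.update(dict(zip(f.names, f.values)))
        rows.append(row)
    return pd.DataFrame(rows)


def remove_outliers(table: pd.DataFrame, z_max: float = 4.0
                    ) -> tuple[pd.DataFrame, list]:
    """Drop rows whose z-score exceeds ``z_max`` on any feature dimension.

    z uses mean/SD over rows (sample SD); zero-variance dimensions are
    skipped.  Requires at least 3 rows.
    """
    num = table.select_dtypes(include=[np.number])
    if len(table) < 3:
        raise ValueError("outlier screen requires at least 3 rows")
    bad = np.zeros(len(table), dtype=bool)
    for col in num.columns:
        x = num[col].to_numpy(dtype=float)
        sd = np.std(x, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        z = (x - np.mean(x)) / sd
        bad |= np.abs(z) > z_max
    removed = list(table.index[bad])
    return table.loc[~bad].copy(), removed


def wilcoxon_screen(paired_a: pd.DataFrame, paired_b: pd.DataFrame
                    ) -> pd.Series:
    """Two-sided paired Wilcoxon signed-rank p-value per feature column.

    Exact distribution for n <= 25, normal approximation above; zero
    differences dropped, with an empty effective sample guarded as p = 1.
    """
    if list(paired_a.columns) != list(paired_b.columns):
        raise ValueError("paired tables must share columns")
    if len(paired_a) != len(paired_b):
        raise ValueError("paired samples must have equal length")
    pvals = {}
    n = len(paired_a)
    for col in paired_a.columns:
        x = paired_a[col].to_numpy(dtype=float)
        y = paired_b[col].to_numpy(dtype=float)
        d = x - y
        if np.all(d == 0):
            pvals[col] = 1.0
            continue
        method = "exact" if n <= 25 else "approx"
        try:
            res = sstats.wilcoxon(x, y, zero_method="wilcox",
                                  alternative="two-sided", method=method)
            pvals[col] = float(res.pvalue)
        except ValueError:
            pvals[col] = 1.0
    return pd.Series(pvals)


# ---------------------------------------------------------------------------
# nu-SVM leave-one-out classification


@dataclass(frozen=True)
class ClassificationResult:
    """Leave-one-out classification summary.

    ``confusion`` is a 2x2 row-percentage matrix (rows = true class, each row
    sums to 100); ``accuracy`` in percent.
    """

    classes: tuple
    confusion: np.ndarray
    accuracy: float
    predictions: np.ndarray
    true_labels: np.ndarray
    feature_ranks: np.ndarray | None = None
    rank_accuracy_curve: np.ndarray | None = None


#: scaled features are clipped at +-Z_CLIP MAD units: with gamma = 1/n the
#: worst single dimension then contributes at most (2*Z_CLIP)^2/n ~ 1 nat to
#: the kernel exponent, so a degenerate (zero-MAD, epsilon-floored) dimension
#: cannot saturate the radial kernel into a majority-vote classifier
Z_CLIP = 3.0


def _median_mad_scale(train: np.ndarray, mad_floor: float = 1e-12
                      ) -> tuple[np.ndarray, np.ndarray]:
    med = np.median(train, axis=0)
    mad = np.median(np.abs(train - med), axis=0)
    n_floored = int(np.sum(mad < mad_floor))
    if n_floored:
        log.warning("median/MAD normalization: %d dimension(s) floored at %g",
                    n_floored, mad_floor)
    return med, np.maximum(mad, mad_floor)


def _scale_apply(x: np.ndarray, med: np.ndarray, mad: np.ndarray,
                 z_clip: float = Z_CLIP) -> np.ndarray:
    return np.clip((x - med) / mad, -z_clip, z_clip)


def _check_classes(y: np.ndarray) -> tuple:
    classes = tuple(sorted(set(y)))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    return classes


def loo_classify(X: np.ndarray, y: np.ndarray, nu: float = 0.5,
                 gamma: float | None = None) -> ClassificationResult:
    """Leave-one-out nu-SVM with per-fold median/MAD normalization.

    ``gamma`` defaults to 1/n_features (the study's gamma = n^-1 rule).
    Deterministic for fixed inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = _check_classes(y)
    n, p = X.shape
    g = gamma if gamma is not None else 1.0 / p
    preds = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ytr = y[mask]
        if len(set(ytr)) < 2:
            raise ValueError("a training fold lost a class entirely")
        med, mad = _median_mad_scale(X[mask])
        Xtr = _scale_apply(X[mask], med, mad)
        Xte = _scale_apply(X[i], med, mad)
        clf = NuSVC(nu=nu, kernel="rbf", gamma=g)
        clf.fit(Xtr, ytr)
        preds[i] = clf.predict(Xte[None, :])[0]
    conf = np.zeros((2, 2))
    for a, ca in enumerate(classes):
        sel = y == ca
        denom = int(sel.sum())
        for b, cb in enumerate(classes):
            conf[a, b] = 100.0 * np.sum(preds[sel] == cb) / denom
    acc = 100.0 * float(np.mean(preds == y))
    return ClassificationResult(classes=classes, confusion=conf, accuracy=acc,
                                predictions=np.array([str(v) for v in preds]),
                                true_labels=np.array([str(v) for v in y]))


# ---------------------------------------------------------------------------
# nonlinear SVM-RFE with correlation-bias reduction


def _rbf_kernel(X: np.ndarray, gamma: float) -> np.ndarray:
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    return np.exp(-gamma * np.maximum(d2, 0.0))


def _rfe_fold_ranks(Xtr: np.ndarray, ytr: np.ndarray, nu: float, gamma: float,
                    corr_threshold: float) -> np.ndarray:
    """Elimination-order ranks (1 = most important) for one training fold."""
    n, p = Xtr.shape
    remaining = list(range(p))
    ranks = np.zeros(p, dtype=int)
    next_rank = p
    yy = np.where(ytr == ytr[0], 1.0, -1.0)
    while len(remaining) > 1:
        Xs = Xtr[:, remaining]
        clf = NuSVC(nu=nu, kernel="rbf", gamma=gamma)
        clf.fit(Xs, ytr)
        sv = clf.support_
        coef = clf.dual_coef_.ravel()          # alpha_i * y_i at support vectors
        Xsv = Xs[sv]
        K = _rbf_kernel(Xsv, gamma)
        base = float(coef @ K @ coef)
        crit = np.empty(len(remaining))
        for jj, f in enumerate(remaining):
            dj = Xtr[sv][:, [f]]
            dd = (dj - dj.T) ** 2
            K_minus = K * np.exp(gamma * dd)   # kernel without feature f
            crit[jj] = abs(base - float(coef @ K_minus @ coef))
        # correlation-bias reduction: average the criterion over groups of
        # highly correlated remaining features, eliminate the group together
        groups = _corr_groups(Xs, corr_threshold)
        unit_crit = crit.copy()
        for grp in groups:
            unit_crit[grp] = float(np.mean(crit[grp]))
        order = np.lexsort((remaining, unit_crit))  # ties -> original index
        drop_local = order[0]
        drop_group = None
        for grp in groups:
            if drop_local in grp:
                drop_group = grp
                break
        drop_locals = sorted(drop_group if drop_group is not None
                             else [drop_local], reverse=True)
        if len(drop_locals) >= len(remaining):
            drop_locals = drop_locals[:-1]
        for dl in drop_locals:
            ranks[remaining[dl]] = next_rank
            next_rank -= 1
            del remaining[dl]
    ranks[remaining[0]] = next_rank
    return ranks


def _corr_groups(X: np.ndarray, threshold: float) -> list[list[int]]:
    """Connected groups of columns with |pairwise correlation| > threshold."""
    p = X.shape[1]
    sd = X.std(axis=0)
    valid = sd > 0
    c = np.zeros((p, p))
    if valid.sum() >= 2:
        cc = np.corrcoef(X[:, valid].T)
        idx = np.flatnonzero(valid)
        c[np.ix_(idx, idx)] = cc
    parent = list(range(p))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(p):
        for b in range(a + 1, p):
            if abs(c[a, b]) > threshold:
                parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for a in range(p):
        groups.setdefault(find(a), []).append(a)
    return [g for g in groups.values() if len(g) > 1]


def svm_rfe_rank(X: np.ndarray, y: np.ndarray, nu: float = 0.5,
                 gamma: float | None = None, corr_threshold: float = 0.95,
                 compute_curve: bool = True
                 ) -> tuple[np.ndarray, np.ndarray | None]:
    """Median SVM-RFE feature ranks over LOO folds, plus accuracy-vs-top-k.

    Within each training fold the radial-basis SVM-RFE eliminates the feature
    (or correlated group) with the smallest kernel-space weight-criterion
    change.  The returned curve re-runs :func:`loo_classify` on the top-k
    features by overall median rank for k = 1..n_features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_classes(y)
    n, p = X.shape
    if p == 1:
        res = loo_classify(X, y, nu=nu, gamma=gamma)
        return np.array([1.0]), np.array([res.accuracy])
    g = gamma if gamma is not None else 1.0 / p
    fold_ranks = np.zeros((n, p))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        med, mad = _median_mad_scale(X[mask])
        Xtr = _scale_apply(X[mask], med, mad)
        fold_ranks[i] = _rfe_fold_ranks(Xtr, y[mask], nu, g, corr_threshold)
    median_ranks = np.median(fold_ranks, axis=0)
    curve = None
    if compute_curve:
        order = np.lexsort((np.arange(p), median_ranks))
        curve = np.empty(p)
        for k in range(1, p + 1):
            curve[k - 1] = loo_classify(X[:, order[:k]], y, nu=nu).accuracy
    return median_ranks, curve
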