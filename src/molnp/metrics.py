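"""Regression and calibration metrics.

Besides the standard R² and negative log predictive density (NLPD),
this module implements the two uncertainty diagnostics used throughout
the package:

* **Confidence percentiles** — target points are ranked by predicted
  variance and partitioned into equal groups; a well-calibrated model
  shows mean squared error rising with mean predicted variance across
  groups, quantified by the Pearson correlation of their logs.
* **Applicability-domain buckets** — test molecules are assigned to 20
  Tanimoto-distance buckets of width 0.05 relative to their closest
  training-set neighbour, and the distribution of relative errors is
  summarized per bucket.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .molrep import Fingerprint, max_similarity_to_reference
from .np_core import PredictiveGaussian, log_predictive_density

__all__ = ["PercentileSummary", "ADBucketReport", "r_squared", "nlpd",
           "relative_error", "confidence_percentiles",
           "calibration_correlation", "ad_buckets"]

N_AD_BUCKETS = 20
AD_BUCKET_WIDTH = 0.05


@dataclass
class PercentileSummary:
    """Per-group error/variance means, ordered by ascending variance."""

    mse: np.ndarray              # (n_groups,)
    variance: np.ndarray         # (n_groups,) mean predicted variance
    group_sizes: np.ndarray      # (n_groups,)


@dataclass
class ADBucketReport:
    """Relative-error distributions per Tanimoto-distance bucket."""

    edges: np.ndarray                       # (21,) bucket boundaries
    counts: np.ndarray                      # (20,) molecules per bucket
    errors: list                            # per bucket, relative errors (%)
    n_excluded: int = 0                     # molecules dropped for y == 0

    def summary(self) -> np.ndarray:
        """Median relative error per bucket (NaN where empty)."""
        return np.array([np.median(e) if len(e) else np.nan
                         for e in self.errors])


def r_squared(y, y_hat) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    if len(y) < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant labels")
    ss_res = float(((y - y_hat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def nlpd(pred: PredictiveGaussian, y) -> float:
    """Mean (per point) negative log predictive density; lower is better."""
    y = np.asarray(y, float).ravel()
    if y.shape != pred.mean.shape:
        raise ValueError("length mismatch")
    return -log_predictive_density(pred, y) / len(y)


def relative_error(y: float, y_hat: float) -> float:
    """Absolute relative error |(y - y_hat)/y| as a percentage."""
    if y == 0:
        raise ValueError("relative error undefined at y = 0")
    return abs((y - y_hat) / y) * 100.0


def confidence_percentiles(pred: PredictiveGaussian, y,
                           n_groups: int = 100) -> PercentileSummary:
    """Rank targets by predicted variance and summarize equal groups.

    Ties in variance are broken by original index (stable sort).  When
    the number of points is not divisible by ``n_groups`` the final
    group absorbs the remainder.
    """
    y = np.asarray(y, float).ravel()
    T = len(y)
    if y.shape != pred.mean.shape:
        raise ValueError("length mismatch")
    if T < n_groups:
        raise ValueError(f"need at least n_groups={n_groups} points, got {T}")
    order = np.argsort(pred.variance, kind="stable")
    size = T // n_groups
    sq_err = (y - pred.mean) ** 2
    mses, variances, sizes = [], [], []
    for g in range(n_groups):
        start = g * size
        stop = (g + 1) * size if g < n_groups - 1 else T
        idx = order[start:stop]
        mses.append(sq_err[idx].mean())
        variances.append(pred.variance[idx].mean())
        sizes.append(len(idx))
    return PercentileSummary(mse=np.array(mses), variance=np.array(variances),
                             group_sizes=np.array(sizes))


def calibration_correlation(summary: PercentileSummary) -> float:
    """Pearson correlation of log mean MSE vs log mean variance."""
    mse = np.asarray(summary.mse, float)
    var = np.asarray(summary.variance, float)
    keep = (mse > 0) & (var > 0)
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} group(s) with "
                      "non-positive mean MSE or variance", stacklevel=2)
    mse, var = mse[keep], var[keep]
    if len(mse) < 3:
        raise ValueError("need at least 3 usable groups")
    r, _ = stats.pearsonr(np.log(mse), np.log(var))
    return float(r)


def ad_buckets(test_fps: list[Fingerprint], train_fps: list[Fingerprint],
               predictions, labels) -> ADBucketReport:
    """Relative error by Tanimoto distance to the training set.

    Distance is ``1 - max Tanimoto similarity`` to any training
    molecule; bucket k covers [0.05k, 0.05(k+1)), with the final bucket
    closed at 1.0.  Molecules with label exactly zero are excluded from
    the error distributions (with a warning) since their relative error
    is undefined.
    """
    if not test_fps:
        raise ValueError("empty test set")
    if not train_fps:
        raise ValueError("empty training set")
    predictions = np.asarray(predictions, float).ravel()
    labels = np.asarray(labels, float).ravel()
    if not (len(test_fps) == len(predictions) == len(labels)):
        raise ValueError("test_fps, predictions and labels must align")
    dist = 1.0 - max_similarity_to_reference(test_fps, train_fps)
    bucket = np.minimum((dist / AD_BUCKET_WIDTH).astype(int), N_AD_BUCKETS - 1)
    zero_mask = labels == 0
    if zero_mask.any():
        warnings.warn(f"excluding {int(zero_mask.sum())} molecule(s) with "
                      "label 0 from relative-error buckets", stacklevel=2)
    errors = [[] for _ in range(N_AD_BUCKETS)]
    counts = np.zeros(N_AD_BUCKETS, dtype=int)
    for b, y, y_hat, skip in zip(bucket, labels, predictions, zero_mask):
        if skip:
            continue
        counts[b] += 1
        errors[b].append(relative_error(y, y_hat))
    edges = np.linspace(0.0, 1.0, N_AD_BUCKETS + 1)
    return ADBucketReport(edges=edges, counts=counts,
                          errors=[np.array(e) for e in errors],
                          n_excluded=int(zero_mask.sum()))
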