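"""Image-evaluation metrics: MSE, CNR, ROI-ROC/AUC and FPR at fixed TPR.

MSE and CNR compare a reconstructed chromophore image against the ground
truth::

    MSE = ||beta - beta_hat||^2 / (P/2)
    CNR = 10 log10( ||beta_hat||^2 / ||beta - beta_hat||^2 )   [dB]

The ROI-ROC pools per-voxel (or per-region) ratings across activity-present
and noise-only datasets: ratings of coefficients inside the truly active
region in activity datasets are positives, everything else (including every
coefficient of a noise-only dataset) is a negative.  Ties share one threshold
(the ROC steps jointly), so the trapezoid AUC equals the Mann-Whitney
pair statistic.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import roc_curve

from .optics import ConfigurationError

__all__ = ["mse", "cnr", "roi_roc", "fpr_at_tpr", "evaluate_image"]


def mse(truth: np.ndarray, estimate: np.ndarray) -> float:
    """Mean squared error of one chromophore's image (length P/2 vectors)."""
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if truth.shape != estimate.shape:
        raise ConfigurationError("truth and estimate lengths differ")
    return float(np.mean(np.square(truth - estimate)))


def cnr(truth: np.ndarray, estimate: np.ndarray, halved: bool = False) -> float:
    """Contrast-to-noise ratio in dB: 10 log10(||est||^2 / ||truth - est||^2).

    ``halved=True`` switches to the alternative reading with the estimate
    halved in both norms (sensitivity analysis for an ambiguous rendering of
    the definition).  An exact reconstruction has infinite CNR (+inf sentinel,
    with a warning); an all-zero estimate gives -inf (no reconstruction).
    """
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if truth.shape != estimate.shape:
        raise ConfigurationError("truth and estimate lengths differ")
    est = estimate / 2.0 if halved else estimate
    num = float(est @ est)
    err = truth - est
    den = float(err @ err)
    if den == 0.0:
        warnings.warn("estimate equals truth exactly; CNR is infinite")
        return np.inf
    if num == 0.0:
        return -np.inf
    return 10.0 * np.log10(num / den)


def roi_roc(ratings: np.ndarray, labels: np.ndarray):
    """ROC curve and trapezoid AUC from pooled ratings.

    Returns (fpr, tpr, auc).  Both classes must be present.
    """
    ratings = np.asarray(ratings, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if ratings.shape != labels.shape:
        raise ConfigurationError("ratings and labels lengths differ")
    if labels.min() == labels.max():
        raise ConfigurationError("ROC undefined: only one class present")
    fpr, tpr, _ = roc_curve(labels, ratings, drop_intermediate=False)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def fpr_at_tpr(
    active_ratings: np.ndarray,
    region_ratings: dict,
    tpr_target: float = 0.8,
):
    """Per-region false-positive rate at the threshold reaching the target TPR.

    The threshold is the smallest rating such that at least ``tpr_target`` of
    the active-region positives score at or above it; each other region's FPR
    is the fraction of its (negative) ratings at or above that threshold.  An
    unreachable target falls back to the minimum positive rating.
    """
    if not (0.0 < tpr_target <= 1.0):
        raise ConfigurationError("tpr_target must be in (0, 1]")
    pos = np.sort(np.asarray(active_ratings, dtype=float))[::-1]
    if pos.size == 0:
        raise ConfigurationError("no active-region ratings")
    k = int(np.ceil(tpr_target * pos.size))
    threshold = pos[min(k, pos.size) - 1]
    return {
        region: float(np.mean(np.asarray(r, dtype=float) >= threshold))
        for region, r in region_ratings.items()
    }


def evaluate_image(beta_true: np.ndarray, beta_est: np.ndarray, halved_cnr: bool = False):
    """Per-chromophore MSE and CNR for a stacked [HbO | HbR] image pair."""
    beta_true = np.asarray(beta_true, dtype=float)
    beta_est = np.asarray(beta_est, dtype=float)
    if beta_true.shape != beta_est.shape or beta_true.size % 2:
        raise ConfigurationError("stacked images must share an even length")
    V = beta_true.size // 2
    out = {}
    for name, sl in (("hbo", slice(0, V)), ("hbr", slice(V, 2 * V))):
        out[f"mse_{name}"] = mse(beta_true[sl], beta_est[sl])
        out[f"cnr_{name}"] = cnr(beta_true[sl], beta_est[sl], halved=halved_cnr)
    return out
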