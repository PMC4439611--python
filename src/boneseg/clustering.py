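"""Intensity-clustering baselines: Gaussian mixture (EM) and fuzzy C-means.

Both cluster the 1D intensities of the ROI pixels into k = 2 classes
(bone vs. everything else) and are used as comparison segmenters for
the level-set engines. The GMM is fitted by expectation-maximization
with K-means initialization; convergence is declared when the summed
squared parameter change drops below ``tol``. FCM minimizes

    J = sum_j sum_i u_ij^m |x_j - v_i|^2

by alternating the membership update (inverse-distance rule with
fuzzifier m) and the weighted center update. The cluster with the
higher mean intensity becomes foreground, since bone is bright on
PD-weighted slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .hough_roi import CircleROI
from .io_types import BinaryMask, Image2D

__all__ = ["GmmState", "FcmState", "gmm_fit", "fcm_fit", "labels_to_mask",
           "gmm_segment", "fcm_segment"]

_VAR_FLOOR_FRAC = 1e-10
_WEIGHT_FLOOR = 1e-6


class FitError(RuntimeError):
    """Fit failed after the allowed restarts (degenerate data)."""


@dataclass
class GmmState:
    k: int
    weights: np.ndarray        # p_i, sum to 1
    means: np.ndarray          # mu_i
    variances: np.ndarray      # sigma_i^2
    posteriors: np.ndarray     # p_ij, shape (n, k), rows sum to 1
    log_likelihoods: list[float] = field(default_factory=list)
    n_iters: int = 0
    converged: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Hard labels by maximum posterior."""
        post = _posteriors(np.asarray(x, dtype=float), self.weights,
                           self.means, self.variances)[0]
        return np.argmax(post, axis=1)


@dataclass
class FcmState:
    c: int
    m: float
    centers: np.ndarray
    memberships: np.ndarray    # u_ij, shape (n, c), rows sum to 1
    objectives: list[float] = field(default_factory=list)
    n_iters: int = 0
    converged: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        u = _fcm_memberships(np.asarray(x, dtype=float), self.centers, self.m)
        return np.argmax(u, axis=1)


def _gauss_pdf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return np.exp(-((x - mean) ** 2) / (2.0 * var)) / np.sqrt(2.0 * np.pi * var)


def _posteriors(x, weights, means, variances):
    """E-step: Bayes-rule posteriors and the data log-likelihood."""
    comp = np.stack([w * _gauss_pdf(x, m, v)
                     for w, m, v in zip(weights, means, variances)], axis=1)
    total = comp.sum(axis=1, keepdims=True)
    total = np.maximum(total, 1e-300)
    return comp / total, float(np.log(total).sum())


def _kmeans_init(x: np.ndarray, k: int, seed: int, var_floor: float):
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(x[:, None])
    weights = np.empty(k)
    means = np.empty(k)
    variances = np.empty(k)
    for i in range(k):
        sel = labels == i
        weights[i] = sel.mean() if sel.any() else 0.0
        means[i] = x[sel].mean() if sel.any() else x.mean()
        variances[i] = x[sel].var() if sel.sum() > 1 else 0.0
    variances = np.maximum(variances, var_floor)
    weights = np.maximum(weights, _WEIGHT_FLOOR)
    return weights / weights.sum(), means, variances


def gmm_fit(intensities: np.ndarray, k: int = 2, seed: int = 0,
            tol: float = 1e-6, max_iters: int = 200,
            max_restarts: int = 3) -> GmmState:
    """Fit a k-component 1D Gaussian mixture by EM.

    Initial parameters come from K-means (cluster means, within-cluster
    variances floored, cluster fractions as weights). EM alternates the
    Bayes-rule E-step and the weighted M-step until the summed squared
    parameter change falls below ``tol``. A component collapsing (weight
    < 1e-6 or variance stuck at the floor) triggers a re-seeded restart,
    at most ``max_restarts`` times.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 10 * k:
        raise ValueError(f"need >= {10 * k} samples for k={k}, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite intensities")
    data_var = x.var()
    var_floor = max(_VAR_FLOOR_FRAC * data_var, 1e-12)

    last_exc: Exception | None = None
    for attempt in range(max_restarts + 1):
        try:
            return _gmm_fit_once(x, k, seed + attempt, tol, max_iters, var_floor)
        except FitError as exc:
            last_exc = exc
    raise FitError(f"GMM failed after {max_restarts} restarts: {last_exc}")


def _gmm_fit_once(x, k, seed, tol, max_iters, var_floor) -> GmmState:
    weights, means, variances = _kmeans_init(x, k, seed, var_floor)
    n = x.size
    lls: list[float] = []
    floored_streak = 0
    post, ll = _posteriors(x, weights, means, variances)
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        # M-step
        nk = post.sum(axis=0)
        new_weights = nk / n
        safe_nk = np.maximum(nk, 1e-300)
        new_means = (post * x[:, None]).sum(axis=0) / safe_nk
        new_vars = (post * (x[:, None] - new_means) ** 2).sum(axis=0) / safe_nk
        new_vars = np.maximum(new_vars, var_floor)

        if np.any(new_weights < _WEIGHT_FLOOR):
            raise FitError("component weight collapsed")
        floored_streak = floored_streak + 1 if np.any(new_vars <= var_floor) else 0
        if floored_streak >= 5:
            raise FitError("component variance persistently at floor")

        change = (np.sum((new_weights - weights) ** 2)
                  + np.sum((new_means - means) ** 2)
                  + np.sum((new_vars - variances) ** 2))
        weights, means, variances = new_weights, new_means, new_vars
        post, ll = _posteriors(x, weights, means, variances)
        lls.append(ll)
        if change < tol:
            converged = True
            break
    return GmmState(k=k, weights=weights, means=means, variances=variances,
                    posteriors=post, log_likelihoods=lls, n_iters=it,
                    converged=converged)


def _fcm_memberships(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Inverse-distance membership update with the exact-hit rule."""
    d = np.abs(x[:, None] - centers[None, :])
    u = np.zeros((x.size, centers.size))
    exact = d < 1e-300
    hit_rows = exact.any(axis=1)
    if hit_rows.any():
        # a pixel exactly at a center belongs fully to (the first) such cluster
        first = np.argmax(exact[hit_rows], axis=1)
        u[np.flatnonzero(hit_rows), first] = 1.0
    rest = ~hit_rows
    if rest.any():
        dr = d[rest]
        power = 2.0 / (m - 1.0)
        inv = dr ** (-power)
        u[rest] = inv / inv.sum(axis=1, keepdims=True)
    return u


def _fcm_objective(x, centers, u, m) -> float:
    d2 = (x[:, None] - centers[None, :]) ** 2
    return float((u**m * d2).sum())


def fcm_fit(intensities: np.ndarray, c: int = 2, m: float = 2.0, seed: int = 0,
            tol: float = 1e-5, max_iters: int = 200,
            max_restarts: int = 3) -> FcmState:
    """Fuzzy C-means on 1D intensities with seeded random center init."""
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 10 * c:
        raise ValueError(f"need >= {10 * c} samples for c={c}, got {x.size}")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")

    span = x.max() - x.min()
    for attempt in range(max_restarts + 1):
        rng = np.random.default_rng(seed + attempt)
        centers = rng.uniform(x.min(), x.max(), size=c) if span > 0 else x[:c].copy()
        objs: list[float] = []
        converged = False
        it = 0
        ok = True
        for it in range(1, max_iters + 1):
            # coincident centers degrade to duplicate clusters; perturb apart
            if c > 1 and np.min(np.diff(np.sort(centers))) < 1e-12 * max(span, 1.0):
                if span <= 0:
                    ok = False
                    break
                centers = centers + rng.normal(0, 1e-3 * span, size=c)
            u = _fcm_memberships(x, centers, m)
            um = u**m
            denom = um.sum(axis=0)
            if np.any(denom <= 0):
                ok = False
                break
            new_centers = (um * x[:, None]).sum(axis=0) / denom
            objs.append(_fcm_objective(x, new_centers, u, m))
            shift = np.max(np.abs(new_centers - centers))
            centers = new_centers
            if shift < tol:
                converged = True
                break
        if ok:
            u = _fcm_memberships(x, centers, m)
            return FcmState(c=c, m=m, centers=centers, memberships=u,
                            objectives=objs, n_iters=it, converged=converged)
    raise FitError(f"FCM failed after {max_restarts} restarts (degenerate data)")


def labels_to_mask(assignments: np.ndarray, roi: CircleROI, image: Image2D,
                   cluster_means: np.ndarray | None = None) -> BinaryMask:
    """Map per-ROI-pixel cluster labels to a foreground mask.

    The cluster with the higher mean intensity is foreground (bone is
    bright on PD slices); on an exact tie the lower cluster index wins.
    The mask is clipped to the ROI.
    """
    sel = roi.roi_mask.astype_bool()
    assignments = np.asarray(assignments).ravel()
    if assignments.size != int(sel.sum()):
        raise ValueError("need one label per ROI pixel")
    vals = image.pixels[sel]
    labels = np.unique(assignments)
    if cluster_means is None:
        cluster_means = np.array([vals[assignments == lab].mean()
                                  if (assignments == lab).any() else -np.inf
                                  for lab in labels])
    else:
        cluster_means = np.asarray(cluster_means, dtype=float)[labels]
    # ties (within 1e-9) break toward the lower cluster index
    best = labels[np.lexsort((labels, -np.round(cluster_means / 1e-9)))[0]]
    fg = np.zeros(image.shape, dtype=bool)
    fg[sel] = assignments == best
    return BinaryMask.from_bool(fg)


def gmm_segment(image: Image2D, roi: CircleROI, seed: int = 0,
                k: int = 2, tol: float = 1e-6):
    """GMM-cluster the ROI intensities and return (mask, fitted state)."""
    sel = roi.roi_mask.astype_bool()
    vals = image.pixels[sel]
    state = gmm_fit(vals, k=k, seed=seed, tol=tol)
    labels = state.predict(vals)
    mask = labels_to_mask(labels, roi, image, cluster_means=state.means)
    return mask, state


def fcm_segment(image: Image2D, roi: CircleROI, seed: int = 0,
                c: int = 2, m: float = 2.0, tol: float = 1e-5):
    """FCM-cluster the ROI intensities and return (mask, fitted state)."""
    sel = roi.roi_mask.astype_bool()
    vals = image.pixels[sel]
    state = fcm_fit(vals, c=c, m=m, seed=seed, tol=tol)
    labels = state.predict(vals)
    mask = labels_to_mask(labels, roi, image, cluster_means=state.centers)
    return mask, state
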