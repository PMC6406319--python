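"""Functional-vessel segmentation and vascular density.

The lectin (vessel) channel is segmented by fuzzy c-means clustering of
pixel intensities into c=2 clusters; the cluster with the higher intensity
centroid is the vessel class, and hard assignment of each pixel to its
maximal-membership cluster yields a binary mask (1 = vessel).  Vascular
density is the fraction of tumor area occupied by vessel pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .section import SectionImage

__all__ = ["FCMResult", "VesselMask", "fuzzy_c_means", "segment_vessels",
           "vascular_density"]


@dataclass
class FCMResult:
    centroids: np.ndarray          # (c,) sorted ascending
    memberships: np.ndarray        # (n, c) rows sum to 1
    objective_history: list[float]
    n_iter: int
    converged: bool


@dataclass
class VesselMask:
    mask: np.ndarray                      # boolean, True = vessel
    vascular_density: float               # vessel px / tumor px, in [0, 1]
    vessel_to_nonvessel_ratio: float      # secondary convention
    fcm_centroids: np.ndarray
    fcm_membership_summary: np.ndarray    # per-cluster mean membership
    min_object_px: int = 0                # size cleanup applied, 0 = none


def _memberships(x: np.ndarray, v: np.ndarray, m: float) -> np.ndarray:
    """Optimal FCM memberships for data x (n,) and centroids v (c,)."""
    d2 = (x[:, None] - v[None, :]) ** 2
    zero = d2 < 1e-300
    u = np.empty_like(d2)
    power = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        inv = d2 ** (-power)
    # points coinciding with a centroid get crisp membership there
    any_zero = zero.any(axis=1)
    u[~any_zero] = inv[~any_zero] / inv[~any_zero].sum(axis=1, keepdims=True)
    if any_zero.any():
        u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    return u


def fcm_objective(x: np.ndarray, v: np.ndarray, m: float) -> float:
    """Sum_ij u_ij^m (x_i - v_j)^2 at the optimal memberships for v."""
    u = _memberships(x, v, m)
    d2 = (x[:, None] - v[None, :]) ** 2
    return float(np.sum(u**m * d2))


def fuzzy_c_means(values: np.ndarray, c: int = 2, m: float = 2.0,
                  tol: float = 1e-5, max_iter: int = 300,
                  seed: int = 0) -> FCMResult:
    """Fuzzy c-means on a 1-D intensity sample.

    Minimizes sum_ij u_ij^m (x_i - v_j)^2 subject to sum_j u_ij = 1 by
    alternating membership and centroid updates; stops when the largest
    centroid move falls below ``tol``.  Initial centroids are ``c``
    distinct values drawn from the data with the given seed, so runs are
    deterministic.  Raises on degenerate input (fewer than ``c`` distinct
    values).  Returns centroids sorted ascending, with membership columns
    ordered to match, and the per-iteration objective (non-increasing).
    """
    x = np.asarray(values, dtype=float).ravel()
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    distinct = np.unique(x)
    if distinct.size < c:
        raise ValueError(
            f"need at least {c} distinct values, got {distinct.size} "
            "(degenerate clustering input)")

    rng = np.random.default_rng(seed)
    v = np.sort(rng.choice(distinct, size=c, replace=False))

    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = _memberships(x, v, m)
        um = u**m
        v_new = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        history.append(float(np.sum(um * (x[:, None] - v[None, :]) ** 2)))
        shift = np.max(np.abs(v_new - v))
        v = v_new
        if shift < tol:
            converged = True
            break
    order = np.argsort(v)
    v = v[order]
    u = _memberships(x, v, m)
    history.append(fcm_objective(x, v, m))
    return FCMResult(centroids=v, memberships=u, objective_history=history,
                     n_iter=it, converged=converged)


def segment_vessels(section: SectionImage, c: int = 2, m: float = 2.0,
                    tol: float = 1e-5, max_iter: int = 300, seed: int = 0,
                    min_object_px: int = 0) -> VesselMask:
    """Segment the vessel channel into a binary functional-vessel mask.

    Pixels are hard-assigned to the cluster of maximal membership; ties
    break toward non-vessel (a pixel must be strictly closer to the vessel
    centroid).  ``min_object_px`` optionally removes connected components
    below that size; the applied value is recorded on the result.
    """
    img = section.vessel_channel
    if img.max() == img.min():
        raise ValueError("vessel channel is constant (degenerate segmentation input)")
    res = fuzzy_c_means(img.ravel(), c=c, m=m, tol=tol, max_iter=max_iter, seed=seed)
    vessel_cluster = int(np.argmax(res.centroids))
    u = res.memberships
    mask = (u[:, vessel_cluster] > np.max(np.delete(u, vessel_cluster, axis=1), axis=1))
    mask = mask.reshape(img.shape)
    if min_object_px > 0:
        labels, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes >= min_object_px
        mask = keep[labels]

    tumor = section.tumor_mask if section.tumor_mask is not None \
        else np.ones(img.shape, dtype=bool)
    density = vascular_density(mask, tumor)
    nonvessel = (tumor & ~mask).sum()
    ratio = float((mask & tumor).sum() / nonvessel) if nonvessel else float("inf")
    return VesselMask(mask=mask, vascular_density=density,
                      vessel_to_nonvessel_ratio=ratio,
                      fcm_centroids=res.centroids,
                      fcm_membership_summary=u.mean(axis=0),
                      min_object_px=min_object_px)


def vascular_density(mask: np.ndarray | VesselMask,
                     tumor_mask: np.ndarray | None = None) -> float:
    """Vessel-pixel fraction of the tumor area, in [0, 1].

    This is the bounded convention (vessel area / entire tumor area); the
    vessel/non-vessel ratio is available on :class:`VesselMask`.
    """
    m = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask, bool)
    if tumor_mask is None:
        tumor_mask = np.ones(m.shape, dtype=bool)
    total = tumor_mask.sum()
    if total == 0:
        raise ValueError("empty tumor area")
    return float((m & tumor_mask).sum() / total)
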