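"""Tumor and fibroglandular tissue segmentation gating the proximity analysis.

The tumor mask is a simple enhancement threshold: voxels whose percent
enhancement on the first post-contrast image reaches 70% (an empirical
criterion matching radiological assessment) are tumor candidates, optionally
restricted to an ROI and reduced to the largest 26-connected component.

The fibroglandular (stromal) mask separates glandular from adipose tissue by
fuzzy C-means clustering of voxel intensities.  On a fat-suppressed
T1-weighted acquisition fat is dark, so by default the cluster with the
highest intensity centroid is labelled fibroglandular.  Tumor voxels are
always removed from the stromal mask: the downstream analysis targets
normal-appearing stroma only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "EmptyTumorError",
    "FuzzyCMeans",
    "FCMResult",
    "TissueMasks",
    "segment_tumor",
    "fcm_cluster",
    "label_fibroglandular",
    "compute_breast_mask",
    "segment_tissues",
]


class EmptyTumorError(ValueError):
    """No voxel exceeds the enhancement threshold."""


# 26-connectivity in 3-D: all neighbours sharing a face, edge or corner
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TissueMasks:
    """Boolean tumor / fibroglandular / breast-support masks on one grid.

    Invariant: ``tumor & fibroglandular`` is empty (stroma excludes tumor)
    and ``fibroglandular ⊆ breast``.  ``provenance`` records the thresholds
    and seeds that produced the masks.
    """

    tumor: np.ndarray
    fibroglandular: np.ndarray
    breast: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.tumor.shape == self.fibroglandular.shape == self.breast.shape):
            raise ValueError("grid mismatch between tissue masks")
        if np.any(self.tumor & self.fibroglandular):
            raise ValueError("tumor and fibroglandular masks must be disjoint")
        if np.any(self.fibroglandular & ~self.breast):
            raise ValueError("fibroglandular mask must lie within the breast mask")


@dataclass
class FCMResult:
    """Outcome of a fuzzy C-means run.

    ``memberships`` has shape (n_samples, n_clusters), rows summing to 1;
    ``objective_trace`` is the FCM objective per iteration and is
    non-increasing for the standard alternating updates.
    """

    centroids: np.ndarray
    memberships: np.ndarray
    n_iter: int
    objective_trace: np.ndarray


def segment_tumor(
    pe: np.ndarray,
    threshold: float = 70.0,
    roi: tuple[slice, ...] | None = None,
    support_mask: np.ndarray | None = None,
    keep: Literal["largest_component", "all", "seeded"] = "largest_component",
    seed_point: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Threshold the PE map at ``threshold`` percent (inclusive, PE >= t).

    ``roi`` optionally restricts the candidate region to a box of slices and
    ``support_mask`` to an arbitrary region (typically the breast mask —
    PE is meaningless in air, where the baseline signal is pure noise).
    The component policy handles spurious supra-threshold voxels: by default
    only the largest 26-connected component survives (the cohort's lesions
    are single masses); ``"all"`` keeps every component and ``"seeded"``
    keeps the component containing ``seed_point``.

    Raises :class:`EmptyTumorError` when nothing reaches the threshold —
    distinct from I/O failures so callers can report "no tumor at threshold".
    """
    if threshold <= 0:
        raise ValueError("tumor PE threshold must be positive")
    candidates = np.zeros(pe.shape, dtype=bool)
    region = roi if roi is not None else tuple(slice(None) for _ in pe.shape)
    sub = pe[region]
    if not np.all(np.isfinite(sub) | np.isnan(sub)):
        raise ValueError("PE contains infinities inside the ROI")
    candidates[region] = np.nan_to_num(sub, nan=-np.inf) >= threshold
    if support_mask is not None:
        candidates &= np.asarray(support_mask, dtype=bool)
    if not candidates.any():
        raise EmptyTumorError(f"no tumor voxels at threshold {threshold}%")

    if keep == "all":
        return candidates
    labels, n = ndimage.label(candidates, structure=_STRUCT_26)
    if keep == "largest_component":
        sizes = ndimage.sum_labels(candidates, labels, index=np.arange(1, n + 1))
        return labels == (int(np.argmax(sizes)) + 1)
    if keep == "seeded":
        if seed_point is None:
            raise ValueError("keep='seeded' requires a seed_point")
        lab = labels[tuple(seed_point)]
        if lab == 0:
            raise EmptyTumorError(f"seed point {seed_point} is not above threshold")
        return labels == lab
    raise ValueError(f"unknown component policy {keep!r}")


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy C-means clustering of per-voxel feature vectors.

    Minimises ``sum_ik u_ik^m ||x_i - c_k||^2`` subject to memberships
    summing to one per sample, by the standard alternating updates
    (``u_ik ∝ (1/d_ik^2)^(1/(m-1))``, centroids = ``u^m``-weighted means).
    ``m`` controls softness: ``m → 1+`` approaches hard k-means, larger
    ``m`` blurs the partition.  Initialisation is k-means++-style seeded
    sampling, so runs are deterministic given ``random_state``.

    Parameters
    ----------
    n_clusters : int, default 2
        Number of clusters (glandular vs adipose for breast masking).
    m : float, default 2.0
        Fuzzifier, must exceed 1.
    tol : float, default 1e-5
        Convergence threshold on the maximum centroid shift.
    max_iter : int, default 300
    random_state : int or None
    n_retries : int, default 3
        Reinitialisations attempted if centroids collapse onto each other.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
    memberships_ : ndarray of shape (n_samples, n_clusters)
    labels_ : ndarray of shape (n_samples,)
        Argmax hard assignment of the training data.
    n_iter_ : int
    objective_trace_ : ndarray
        FCM objective after each membership/centroid update.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        m: float = 2.0,
        tol: float = 1e-5,
        max_iter: int = 300,
        random_state: int | None = 0,
        n_retries: int = 3,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.n_retries = n_retries

    def _memberships(self, X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
        # u_ik = 1 / sum_j (d_ik/d_ij)^(2/(m-1)); samples on a centroid get
        # crisp membership there
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 0
        with np.errstate(divide="ignore"):
            inv = d2 ** (-1.0 / (self.m - 1.0))
        u = np.where(zero.any(axis=1, keepdims=True), zero.astype(float), inv)
        return u / u.sum(axis=1, keepdims=True)

    def _objective(self, X: np.ndarray, u: np.ndarray, centroids: np.ndarray) -> float:
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        return float(((u**self.m) * d2).sum())

    def _init_centroids(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        # k-means++-style seeding: each next centroid drawn with probability
        # proportional to squared distance from the chosen set
        n = X.shape[0]
        centroids = [X[rng.integers(n)]]
        for _ in range(1, self.n_clusters):
            d2 = np.min(
                ((X[:, None, :] - np.asarray(centroids)[None, :, :]) ** 2).sum(axis=2),
                axis=1,
            )
            total = d2.sum()
            if total <= 0:
                centroids.append(X[rng.integers(n)])
            else:
                centroids.append(X[rng.choice(n, p=d2 / total)])
        return np.asarray(centroids, dtype=float)

    def fit(self, X: np.ndarray, y=None) -> "FuzzyCMeans":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if np.unique(X, axis=0).shape[0] < self.n_clusters:
            raise ValueError("need at least n_clusters distinct feature vectors")
        rng = np.random.default_rng(self.random_state)
        last_err: Exception | None = None
        for _ in range(self.n_retries):
            try:
                self._fit_once(X, rng)
                return self
            except _CollapsedCentroids as err:  # reinitialise from the seed stream
                last_err = err
        raise RuntimeError(f"FCM centroids collapsed after {self.n_retries} retries") from last_err

    def _fit_once(self, X: np.ndarray, rng: np.random.Generator) -> None:
        centroids = self._init_centroids(X, rng)
        trace = []
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            u = self._memberships(X, centroids)
            um = u**self.m
            denom = um.sum(axis=0)
            if np.any(denom <= 0):
                raise _CollapsedCentroids("empty cluster")
            new_centroids = (um.T @ X) / denom[:, None]
            if len(np.unique(np.round(new_centroids, 12), axis=0)) < self.n_clusters:
                raise _CollapsedCentroids("duplicate centroids")
            trace.append(self._objective(X, u, new_centroids))
            shift = np.abs(new_centroids - centroids).max()
            centroids = new_centroids
            if shift < self.tol:
                break
        self.cluster_centers_ = centroids
        self.memberships_ = self._memberships(X, centroids)
        self.labels_ = np.argmax(self.memberships_, axis=1)
        self.n_iter_ = n_iter
        self.objective_trace_ = np.asarray(trace)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard labels by maximal membership."""
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return np.argmax(self._memberships(X, self.cluster_centers_), axis=1)

    def soft_predict(self, X: np.ndarray) -> np.ndarray:
        """Membership weights in [0, 1] for new samples (rows sum to 1)."""
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self._memberships(X, self.cluster_centers_)

    def result_(self) -> FCMResult:
        check_is_fitted(self, "cluster_centers_")
        return FCMResult(
            centroids=self.cluster_centers_,
            memberships=self.memberships_,
            n_iter=self.n_iter_,
            objective_trace=self.objective_trace_,
        )


class _CollapsedCentroids(RuntimeError):
    pass


def fcm_cluster(
    features: np.ndarray,
    n_clusters: int = 2,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = 0,
) -> FCMResult:
    """Functional wrapper over :class:`FuzzyCMeans` returning an :class:`FCMResult`."""
    est = FuzzyCMeans(
        n_clusters=n_clusters, m=m, tol=tol, max_iter=max_iter, random_state=seed
    )
    est.fit(np.asarray(features, dtype=float).reshape(-1, 1) if np.ndim(features) == 1 else features)
    return est.result_()


def compute_breast_mask(s0: np.ndarray) -> np.ndarray:
    """Breast support region from the pre-contrast volume.

    Thresholds intensities with a 3-class Otsu partition (air | fat |
    gland) and keeps everything above the lowest boundary, so suppressed
    but non-zero adipose tissue stays inside the breast while air is
    excluded.  Falls back to binary Otsu when the histogram cannot support
    three classes.  A stand-in for an externally supplied breast mask;
    callers with a real mask should pass it through instead.
    """
    s0 = np.asarray(s0, dtype=float)
    try:
        air_cut = threshold_multiotsu(s0, classes=3)[0]
    except ValueError:  # fewer than 3 distinguishable grey levels
        air_cut = threshold_otsu(s0)
    return s0 > air_cut


def label_fibroglandular(
    fcm: FCMResult | FuzzyCMeans,
    breast_mask: np.ndarray,
    rule: Literal["highest_centroid", "manual"] = "highest_centroid",
    cluster_id: int | None = None,
) -> np.ndarray:
    """Map FCM clusters to a fibroglandular mask inside the breast region.

    The memberships must have been fitted on the breast-mask voxels in
    C-order.  ``highest_centroid`` assigns the brightest cluster to
    fibroglandular tissue — correct for fat-suppressed T1 imaging where
    adipose tissue is dark; ``manual`` takes an explicit ``cluster_id``.
    Ties between centroids break deterministically toward the lower cluster
    index.
    """
    if isinstance(fcm, FuzzyCMeans):
        fcm = fcm.result_()
    n_in_mask = int(np.count_nonzero(breast_mask))
    if fcm.memberships.shape[0] != n_in_mask:
        raise ValueError(
            f"FCM was fitted on {fcm.memberships.shape[0]} samples but the breast mask "
            f"holds {n_in_mask} voxels"
        )
    if rule == "highest_centroid":
        brightness = fcm.centroids.sum(axis=1)
        # argmax returns the first (lowest-index) maximiser: deterministic tie-break
        cluster_id = int(np.argmax(brightness))
    elif rule == "manual":
        if cluster_id is None:
            raise ValueError("manual rule requires an explicit cluster_id")
    else:
        raise ValueError(f"unknown labelling rule {rule!r}")
    hard = np.argmax(fcm.memberships, axis=1) == cluster_id
    mask = np.zeros(breast_mask.shape, dtype=bool)
    mask[breast_mask] = hard
    return mask


def segment_tissues(
    pe: np.ndarray,
    s0: np.ndarray,
    tumor_threshold: float = 70.0,
    breast_mask: np.ndarray | None = None,
    n_clusters: int = 2,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = 0,
    keep: Literal["largest_component", "all", "seeded"] = "largest_component",
) -> TissueMasks:
    """Full segmentation stage: tumor by PE threshold, stroma by FCM.

    FCM clusters the pre-contrast intensities of breast voxels; the
    brightest cluster becomes fibroglandular tissue, from which tumor voxels
    are then removed.  Tumor candidates are restricted to the breast mask
    (PE is undefined noise in air).
    """
    if breast_mask is None:
        breast_mask = compute_breast_mask(s0)
    tumor = segment_tumor(pe, threshold=tumor_threshold, support_mask=breast_mask, keep=keep)
    fcm = fcm_cluster(
        np.asarray(s0, dtype=float)[breast_mask],
        n_clusters=n_clusters,
        m=m,
        tol=tol,
        max_iter=max_iter,
        seed=seed,
    )
    fibro = label_fibroglandular(fcm, breast_mask) & ~tumor
    return TissueMasks(
        tumor=tumor,
        fibroglandular=fibro,
        breast=breast_mask,
        provenance={
            "tumor_threshold_pe": float(tumor_threshold),
            "component_policy": keep,
            "fcm": {
                "n_clusters": n_clusters,
                "m": m,
                "tol": tol,
                "max_iter": max_iter,
                "seed": seed,
                "n_iter": fcm.n_iter,
                "centroids": fcm.centroids.ravel().tolist(),
            },
        },
    )
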