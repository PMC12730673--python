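"""Polarity-invariant microstate clustering.

EEG microstates are quasi-stable scalp topographies.  Because the
generating dipolar sources oscillate, a topography and its negation
express the same microstate; every quantity here is therefore invariant
under sign flips of individual maps.

The workflow implemented in this module:

1. compute global field power (GFP) — the spatial SD of the
   average-referenced field at each time point;
2. take topographies at GFP peaks (moments of maximal topographic
   signal-to-noise);
3. cluster the peak maps with a polarity-invariant "modified k-means"
   (:class:`ModifiedKMeans`) whose class prototypes are the dominant
   eigenvectors of the per-class map cross-product matrices;
4. choose the number of classes K with the cross-validation (CV)
   criterion: residual variance times the penalty ((C-1)/(C-1-K))^2;
5. pool peak maps across subjects (equalized per-subject counts) into a
   single *global* template set and give its maps the canonical A-D names
   by matching against idealized reference topographies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_random_state

from .io import EEGRecording
from . import montage as _montage

_AVG_REF_TOL = 1e-6


@dataclass
class TemplateSet:
    """K unit-GFP, average-referenced template maps with labels."""

    maps: np.ndarray  # (K, n_channels)
    labels: list
    ch_names: list = None
    provenance: str = "subject"
    match_scores: dict = field(default_factory=dict)

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        gfp = np.sqrt(np.mean(self.maps**2, axis=1))
        if np.any(np.abs(gfp - 1.0) > 1e-9):
            raise ValueError("template maps must have unit GFP")
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("template labels must be unique")

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    def map_for(self, label) -> np.ndarray:
        return self.maps[list(self.labels).index(label)]

    def to_frame(self) -> pd.DataFrame:
        idx = self.ch_names if self.ch_names is not None else range(self.maps.shape[1])
        return pd.DataFrame(self.maps.T, index=idx, columns=list(self.labels))


@dataclass
class ClusterFit:
    """Diagnostics of one modified-k-means fit."""

    assignments: np.ndarray
    polarity: np.ndarray
    sigma2: float  # residual variance (uV^2)
    explained_variance: float
    n_iter: int
    converged: bool


# ---------------------------------------------------------------------------
# topographic primitives
# ---------------------------------------------------------------------------

def _check_average_referenced(data: np.ndarray) -> None:
    scale = np.max(np.abs(data)) or 1.0
    if np.max(np.abs(data.mean(axis=0))) > _AVG_REF_TOL * max(scale, 1.0):
        raise ValueError(
            "input is not average-referenced; apply average_reference() first"
        )


def global_field_power(rec) -> np.ndarray:
    """GFP(t): spatial standard deviation of the field at each sample.

    With an average-referenced map v(t), GFP(t) = sqrt(mean_c v_c(t)^2).
    Accepts an :class:`EEGRecording` or a (channels x samples) array.
    """
    data = rec.data if isinstance(rec, EEGRecording) else np.asarray(rec, float)
    if isinstance(rec, EEGRecording) and rec.reference != "average":
        raise ValueError("recording must be average-referenced")
    _check_average_referenced(data)
    return np.sqrt(np.mean(data**2, axis=0))


def find_gfp_peaks(gfp: np.ndarray, min_separation_ms: float = 10.0,
                   fs: float = 250.0) -> np.ndarray:
    """Indices of strict local GFP maxima, thinned to a minimum separation.

    When two peaks fall within ``min_separation_ms`` the larger survives.
    """
    gfp = np.asarray(gfp, float)
    if gfp.size < 3:
        raise ValueError("GFP series too short for peak detection")
    distance = max(1, int(round(min_separation_ms * fs / 1000.0)))
    peaks, _ = sps.find_peaks(gfp, distance=distance)
    return peaks


def spatial_correlation(map1, map2) -> float:
    """Pearson correlation across channels of two (centered) maps."""
    u = np.asarray(map1, float)
    v = np.asarray(map2, float)
    u = u - u.mean()
    v = v - v.mean()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("spatial correlation undefined for a flat map")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def abs_spatial_correlation(map1, map2) -> float:
    return abs(spatial_correlation(map1, map2))


def gmd(map1, map2) -> float:
    """Global map dissimilarity of two maps.

    Both maps are average-referenced and scaled to unit GFP, then
    GMD = sqrt(mean_c (u_c - v_c)^2).  Satisfies GMD^2 = 2 (1 - r) with r
    the signed spatial correlation; ranges from 0 (identical) to 2
    (identical up to polarity inversion).
    """
    out = []
    for m in (map1, map2):
        m = np.asarray(m, float)
        m = m - m.mean()
        g = np.sqrt(np.mean(m**2))
        if g == 0:
            raise ValueError("GMD undefined for a zero-GFP map")
        out.append(m / g)
    return float(np.sqrt(np.mean((out[0] - out[1]) ** 2)))


# ---------------------------------------------------------------------------
# modified k-means
# ---------------------------------------------------------------------------

class ModifiedKMeans(ClusterMixin, BaseEstimator):
    """Polarity-invariant k-means for scalp topographies.

    Each sample map x_t is assigned to the class k maximizing the squared
    projection (x_t . a_k)^2 onto the unit-norm class prototype — the
    sign of the map is irrelevant.  The prototype update sets a_k to the
    dominant eigenvector of S_k = sum_{t in k} x_t x_t^T, the
    polarity-invariant analogue of the cluster mean (``update="mean"``
    selects the alternative mean-of-sign-aligned-maps update).  The best
    of ``n_init`` random restarts by explained variance is kept.

    Parameters
    ----------
    n_clusters : int
        Number of microstate classes K.
    n_init, max_iter, tol : int, int, float
        Restart count, iteration cap, and the convergence threshold on
        the relative change of explained variance.
    random_state : int, RandomState or None
        Seed for the restarts (initial prototypes are random samples).
    update : {"eigen", "mean"}
        Prototype update rule.

    Attributes
    ----------
    cluster_centers_ : ndarray (K, n_channels)
        Unit-GFP prototype maps.
    labels_ : ndarray (n_samples,)
        Class assignment of each training map.
    polarity_ : ndarray (n_samples,)
        Sign of the winning projection per training map.
    sigma2_ : float
        Residual variance sum_t (||x_t||^2 - proj_t^2) / (T (C-1)).
    explained_variance_ : float
        sum_t proj_t^2 / sum_t ||x_t||^2.
    n_iter_ : int, converged_ : bool
        Iterations used by, and convergence of, the winning restart.
    """

    def __init__(self, n_clusters=4, n_init=10, max_iter=500, tol=1e-5,
                 random_state=None, update="eigen"):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.update = update

    # -- internals -------------------------------------------------------
    @staticmethod
    def _dominant_eigvec(S: np.ndarray) -> np.ndarray:
        w, v = np.linalg.eigh(S)
        return v[:, -1]

    def _update_prototype(self, X_k: np.ndarray, current: np.ndarray) -> np.ndarray:
        if self.update == "eigen":
            a = self._dominant_eigvec(X_k.T @ X_k)
        elif self.update == "mean":
            signs = np.sign(X_k @ current)
            signs[signs == 0] = 1.0
            a = (signs[:, None] * X_k).mean(axis=0)
        else:
            raise ValueError(f"unknown update rule {self.update!r}")
        n = np.linalg.norm(a)
        return a / n if n > 0 else current

    def _single_fit(self, X, rng):
        T, C = X.shape
        K = self.n_clusters
        total_ss = float(np.sum(X**2))
        idx = rng.choice(T, size=K, replace=False)
        A = X[idx].astype(float).copy()
        norms = np.linalg.norm(A, axis=1)
        norms[norms == 0] = 1.0
        A /= norms[:, None]

        ev_prev = -np.inf
        converged = False
        labels = np.zeros(T, dtype=int)
        for it in range(1, self.max_iter + 1):
            proj = X @ A.T  # (T, K)
            labels = np.argmax(proj**2, axis=1)
            # prototype update; re-seed empty clusters from the worst-fit map
            win = proj[np.arange(T), labels]
            for k in range(K):
                members = labels == k
                if not members.any():
                    worst = np.argmin(np.abs(win))
                    A[k] = X[worst] / (np.linalg.norm(X[worst]) or 1.0)
                    labels[worst] = k
                    members = labels == k
                A[k] = self._update_prototype(X[members], A[k])
            proj = X @ A.T
            labels = np.argmax(proj**2, axis=1)
            win = proj[np.arange(T), labels]
            ev = float(np.sum(win**2) / total_ss) if total_ss > 0 else 1.0
            if ev_prev > -np.inf and abs(ev - ev_prev) <= self.tol * max(ev_prev, 1e-300):
                converged = True
                ev_prev = ev
                break
            ev_prev = ev
        sigma2 = (total_ss - ev_prev * total_ss) / (T * (C - 1))
        return A, labels, np.sign(win), sigma2, ev_prev, it, converged

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_channels)")
        T, C = X.shape
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if T < self.n_clusters:
            raise ValueError(
                f"n_samples={T} < n_clusters={self.n_clusters}"
            )
        _check_average_referenced(X.T)
        rng = check_random_state(self.random_state)

        best = None
        for _ in range(self.n_init):
            result = self._single_fit(X, rng)
            if best is None or result[4] > best[4]:
                best = result
        A, labels, signs, sigma2, ev, n_iter, converged = best
        # report prototypes at unit GFP (mean-square 1 across channels)
        gfp = np.sqrt(np.mean(A**2, axis=1))
        self.cluster_centers_ = A / gfp[:, None]
        self.labels_ = labels
        self.polarity_ = signs.astype(int)
        self.sigma2_ = float(sigma2)
        self.explained_variance_ = float(np.clip(ev, 0.0, 1.0))
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def predict(self, X):
        """Assign maps to classes by maximal squared projection."""
        X = np.asarray(X, dtype=float)
        proj = X @ self.cluster_centers_.T
        return np.argmax(proj**2, axis=1)

    def transform(self, X):
        """Absolute spatial correlation of each map to each prototype."""
        X = np.asarray(X, dtype=float)
        Xc = X - X.mean(axis=1, keepdims=True)
        Tc = self.cluster_centers_ - self.cluster_centers_.mean(axis=1, keepdims=True)
        num = Xc @ Tc.T
        den = np.linalg.norm(Xc, axis=1)[:, None] * np.linalg.norm(Tc, axis=1)[None, :]
        den[den == 0] = np.inf
        return np.abs(num / den)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def modified_kmeans(samples, K, n_init=10, max_iter=500, tol=1e-5, seed=None,
                    ch_names=None, update="eigen"):
    """Functional wrapper returning (:class:`TemplateSet`, :class:`ClusterFit`)."""
    est = ModifiedKMeans(n_clusters=K, n_init=n_init, max_iter=max_iter,
                         tol=tol, random_state=seed, update=update).fit(samples)
    ts = TemplateSet(maps=est.cluster_centers_, labels=list(range(K)),
                     ch_names=ch_names, provenance="subject")
    fit = ClusterFit(assignments=est.labels_, polarity=est.polarity_,
                     sigma2=est.sigma2_, explained_variance=est.explained_variance_,
                     n_iter=est.n_iter_, converged=est.converged_)
    return ts, fit


# ---------------------------------------------------------------------------
# model-order selection
# ---------------------------------------------------------------------------

def cv_criterion(sigma2: float, n_channels: int, K: int) -> float:
    """Cross-validation criterion: sigma2 * ((C-1)/(C-1-K))^2.

    Penalizes the residual variance by the degrees of freedom consumed by
    K template maps on C channels; minimized over K to choose the model
    order.  Requires K <= C - 2.
    """
    if K >= n_channels - 1:
        raise ValueError(f"K={K} must be < n_channels-1 ({n_channels - 1})")
    factor = (n_channels - 1) / (n_channels - 1 - K)
    return float(sigma2) * factor**2


def select_k(samples, k_range, n_init=10, max_iter=500, tol=1e-5, seed=None):
    """Fit each K in ``k_range`` and return (argmin-CV K, CV curve)."""
    samples = np.asarray(samples, float)
    C = samples.shape[1]
    curve = {}
    for K in k_range:
        est = ModifiedKMeans(n_clusters=K, n_init=n_init, max_iter=max_iter,
                             tol=tol, random_state=seed).fit(samples)
        curve[K] = cv_criterion(est.sigma2_, C, K)
    series = pd.Series(curve, name="cv")
    series.index.name = "K"
    return int(series.idxmin()), series


# ---------------------------------------------------------------------------
# global templates and canonical labeling
# ---------------------------------------------------------------------------

def extract_peak_maps(rec: EEGRecording, min_separation_ms: float = 10.0):
    """GFP-peak topographies of one recording, (n_peaks, n_channels)."""
    gfp = global_field_power(rec)
    peaks = find_gfp_peaks(gfp, min_separation_ms, rec.fs)
    return rec.data[:, peaks].T


def pool_global_template(recordings, K=4, min_separation_ms=10.0, n_init=10,
                         max_iter=500, tol=1e-5, seed=None, provenance="resting-global",
                         reference: "TemplateSet | None" = None,
                         return_pooled: bool = False):
    """Cluster pooled GFP-peak maps from a cohort into one global template.

    Every subject contributes the same number of peak maps (random
    subsampling to the minimum count, seeded), so long recordings cannot
    dominate the template.  The result is labeled canonically (A-D) by
    matching against ``reference`` (idealized archetypes by default).
    """
    recordings = list(recordings)
    if len(recordings) < 2:
        raise ValueError("global template needs at least 2 recordings")
    names0 = list(recordings[0].ch_names)
    for rec in recordings:
        if list(rec.ch_names) != names0:
            raise ValueError("all recordings must share one montage")
    rng = np.random.default_rng(seed)
    peak_sets = [extract_peak_maps(r, min_separation_ms) for r in recordings]
    n_min = min(p.shape[0] for p in peak_sets)
    if n_min < K:
        raise ValueError("too few GFP peaks to cluster")
    pooled = np.vstack([
        p[rng.choice(p.shape[0], size=n_min, replace=False)] for p in peak_sets
    ])
    ts, _ = modified_kmeans(pooled, K, n_init=n_init, max_iter=max_iter, tol=tol,
                            seed=int(rng.integers(2**31 - 1)), ch_names=names0)
    ts.provenance = provenance
    if reference is None and K <= 4 and names0 and all(
        c in _montage.DEFAULT_32 for c in names0
    ):
        positions = _montage.channel_positions(names0)
        reference = TemplateSet(
            maps=_montage.canonical_maps(positions, 4),
            labels=list(_montage.CANONICAL_LABELS),
            ch_names=names0, provenance="canonical",
        )
    if reference is not None:
        ts = label_canonical(ts, reference)
        ts.provenance = provenance
    if return_pooled:
        return ts, pooled
    return ts


def label_canonical(templates: TemplateSet, reference: TemplateSet) -> TemplateSet:
    """Name template maps after the best-matching reference maps.

    Finds the one-to-one assignment maximizing the total absolute spatial
    correlation, by exhaustive search over permutations (K <= 6).  Ties
    are broken toward the lowest reference index.  Matching scores are
    kept on the returned set so the labeling can be audited.
    """
    K = templates.K
    if K > reference.K:
        raise ValueError("reference has fewer maps than the templates")
    if K > 6:
        raise ValueError("exhaustive canonical labeling supported for K <= 6")
    corr = np.array([
        [abs_spatial_correlation(t, r) for r in reference.maps]
        for t in templates.maps
    ])
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(reference.K), K):
        score = corr[np.arange(K), list(perm)].sum()
        if score > best_score + 1e-12:
            best_perm, best_score = perm, score
    labels = [reference.labels[j] for j in best_perm]
    order = np.argsort([list(reference.labels).index(l) for l in labels])
    return TemplateSet(
        maps=templates.maps[order],
        labels=[labels[i] for i in order],
        ch_names=templates.ch_names,
        provenance=templates.provenance,
        match_scores={labels[i]: float(corr[i, best_perm[i]]) for i in order},
    )
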