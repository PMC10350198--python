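"""Consensus clustering of saliency maps into morphometry subtypes.

Pipeline: eta-squared-distance k-means (k-means++ seeding, best of many
replicates) on random 60% voxel subsamples, repeated to build a
subject-by-subject consensus matrix per candidate cluster count; Hartigan's
dip test screens out candidates whose consensus values are consistent with
unimodality (no real co-clustering structure); the proportion of ambiguously
clustered pairs (PAC) scores the survivors and the largest sufficiently
reliable k wins; affinity propagation on the consensus matrix extracts the
final clusters and their exemplar subjects.

The eta-squared coefficient compares two maps point by point, penalizing
scale AND offset differences (unlike Pearson correlation):
``eta2 = 1 - SS_within / SS_total`` with per-voxel pair means as the within
reference and the grand mean of both maps as the total reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .errors import (ArgumentError, ConvergenceError, SelectionError,
                     UndefinedSimilarityError)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# eta-squared similarity
# ---------------------------------------------------------------------------

def eta_squared_similarity(map_a, map_b) -> float:
    """Pointwise eta^2 similarity in (-inf, 1]; 1 means identical maps.

    ``SS_within`` measures each map against the per-voxel pair mean,
    ``SS_total`` against the grand mean of both maps.  Unlike Pearson
    correlation the coefficient is NOT invariant to offsets: ``b = a + c``
    scores below 1 for ``c != 0``.
    """
    a = np.asarray(map_a, dtype=np.float64).ravel()
    b = np.asarray(map_b, dtype=np.float64).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ArgumentError("maps must share a shape with >= 2 voxels")
    grand = 0.5 * (a.mean() + b.mean())
    ss_total = ((a - grand) ** 2).sum() + ((b - grand) ** 2).sum()
    if ss_total == 0.0:
        raise UndefinedSimilarityError("both maps are constant")
    ss_within = 0.5 * ((a - b) ** 2).sum()  # sum of squared gaps to pair means
    return 1.0 - ss_within / ss_total


def _eta_sq_cross(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """eta^2 between every row of A (n,p) and every row of B (k,p)."""
    sa = A.sum(axis=1)
    sb = B.sum(axis=1)
    qa = (A ** 2).sum(axis=1)
    qb = (B ** 2).sum(axis=1)
    p = A.shape[1]
    grand = (sa[:, None] / p + sb[None, :] / p) / 2.0
    ss_total = (qa[:, None] - 2 * grand * sa[:, None]
                + qb[None, :] - 2 * grand * sb[None, :]
                + 2 * p * grand ** 2)
    ss_within = 0.5 * (qa[:, None] - 2 * A @ B.T + qb[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = 1.0 - ss_within / ss_total
    eta[ss_total <= 0] = 1.0  # identical constant rows
    return eta


# ---------------------------------------------------------------------------
# k-means under the eta^2 distance
# ---------------------------------------------------------------------------

def kmeans_eta(
    maps: np.ndarray, k: int, n_replicates: int = 250, seed: int = 0,
    max_iter: int = 100, medoid_update: bool = False,
) -> tuple[np.ndarray, float, list[float]]:
    """k-means with distance ``1 - eta^2`` and k-means++ seeding.

    Assignment minimizes ``1 - eta^2`` to the centroid; the update step takes
    the arithmetic mean of members (relaxed k-means; pass
    ``medoid_update=True`` for medoids).  The best of ``n_replicates``
    restarts by total distance is returned along with every replicate's
    total, so callers can assert the best is no worse than any single run.
    """
    X = np.asarray(maps, dtype=np.float64).reshape(len(maps), -1)
    n = len(X)
    if k < 1:
        raise ArgumentError("k must be >= 1")
    if k > n:
        raise ArgumentError(f"k={k} exceeds n_subjects={n}")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 71])
    best_labels, best_total = None, np.inf
    totals = []
    for _ in range(n_replicates):
        centroids = _kmeanspp_seed(X, k, rng)
        labels = np.zeros(n, dtype=np.int64)
        for _ in range(max_iter):
            dist = 1.0 - _eta_sq_cross(X, centroids)
            new_labels = dist.argmin(axis=1)
            # re-seed empty clusters at distinct farthest points
            farthest = np.argsort(dist.min(axis=1))[::-1]
            next_far = 0
            for c in range(k):
                if not np.any(new_labels == c):
                    new_labels[farthest[next_far]] = c
                    next_far += 1
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
            if medoid_update:
                centroids = np.stack([
                    X[labels == c][
                        _eta_sq_cross(X[labels == c], X[labels == c])
                        .sum(axis=1).argmax()]
                    for c in range(k)])
            else:
                centroids = np.stack([
                    X[labels == c].mean(axis=0) if np.any(labels == c)
                    else centroids[c]
                    for c in range(k)])
        total = float((1.0 - _eta_sq_cross(X, centroids))[
            np.arange(n), labels].sum())
        totals.append(total)
        if total < best_total:
            best_total, best_labels = total, labels.copy()
    return best_labels, best_total, totals


def _kmeanspp_seed(X, k, rng):
    n = len(X)
    idx = [int(rng.integers(n))]
    for _ in range(1, k):
        d = 1.0 - _eta_sq_cross(X, X[idx]).max(axis=1)
        d = np.clip(d, 0.0, None) ** 2
        if d.sum() <= 0:
            idx.append(int(rng.integers(n)))
            continue
        idx.append(int(rng.choice(n, p=d / d.sum())))
    return X[idx].copy()


# ---------------------------------------------------------------------------
# Consensus matrices
# ---------------------------------------------------------------------------

@dataclass
class ConsensusMatrix:
    values: np.ndarray
    k: int
    n_runs: int
    subsample_fraction: float

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.values), k=1)
        return self.values[iu]


def consensus_matrix(
    maps: np.ndarray, k: int, n_runs: int = 1000,
    subsample_fraction: float = 0.6, seed: int = 0,
    kmeans_replicates: int = 250,
) -> ConsensusMatrix:
    """Co-clustering proportions over random voxel subsamples.

    Every run clusters ALL subjects on a random ``subsample_fraction`` of the
    voxels (the denominator is therefore simply ``n_runs``); the diagonal is
    set to 1.
    """
    if n_runs < 1:
        raise ArgumentError("n_runs must be >= 1")
    if not (0.0 < subsample_fraction <= 1.0):
        raise ArgumentError("subsample_fraction must be in (0, 1]")
    X = np.asarray(maps, dtype=np.float64).reshape(len(maps), -1)
    n, p = X.shape
    m = max(2, int(round(subsample_fraction * p)))
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 73])
    counts = np.zeros((n, n))
    for _ in range(n_runs):
        voxels = rng.choice(p, size=m, replace=False)
        labels, _, _ = kmeans_eta(X[:, voxels], k,
                                  n_replicates=kmeans_replicates,
                                  seed=int(rng.integers(2 ** 31 - 1)))
        same = labels[:, None] == labels[None, :]
        counts += same
    C = counts / n_runs
    np.fill_diagonal(C, 1.0)
    return ConsensusMatrix(values=C, k=k, n_runs=n_runs,
                           subsample_fraction=subsample_fraction)


# ---------------------------------------------------------------------------
# Hartigan's dip test
# ---------------------------------------------------------------------------

def dip_statistic(values) -> float:
    """Hartigan-Hartigan dip of a sample: the minimax sup-distance between
    its ECDF and the closest unimodal CDF.

    Computed by the iterative greatest-convex-minorant / least-concave-
    majorant refinement: within the current modal interval the maximal gap
    between the two hulls either certifies the current dip or shrinks the
    interval, accumulating the tail deviations.  Equals 1/(2n) for perfectly
    spread data and approaches 1/4 for two equal point masses.
    """
    x = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0
    low, high = 0, n - 1
    D = 1.0  # in ECDF count units; final dip = D / (2n)
    for _ in range(n):
        g_idx = _lower_hull(x, low, high)            # GCM of (x_i, i)
        l_idx = _upper_hull(x, low, high)            # LCM of (x_i, i + 1)
        bp = np.array(sorted(set(g_idx) | set(l_idx)))
        gv = _hull_eval(x, g_idx, np.asarray(g_idx, dtype=np.float64), bp)
        lv = _hull_eval(x, l_idx, np.asarray(l_idx, dtype=np.float64) + 1.0, bp)
        gaps = lv - gv
        j = int(np.argmax(gaps))
        d = float(gaps[j])
        if d <= D:
            break
        pivot = bp[j]
        new_low = max(i for i in g_idx if i <= pivot)
        new_high = min(i for i in l_idx if i >= pivot)
        left = np.arange(low, new_low + 1)
        right = np.arange(new_high, high + 1)
        dl = float(np.max((left + 1.0)
                          - _hull_eval(x, g_idx, np.asarray(g_idx, float), left)))
        du = float(np.max(_hull_eval(x, l_idx, np.asarray(l_idx, float) + 1.0,
                                     right) - right))
        D = max(D, dl, du)
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high
    return D / (2.0 * n)


def _lower_hull(x, low, high):
    """Indices of the lower convex hull of (x_i, i) for i in [low, high]."""
    hull = []
    for i in range(low, high + 1):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            if (x[i] - x[i1]) * (i2 - i1) >= (x[i2] - x[i1]) * (i - i1):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _upper_hull(x, low, high):
    """Indices of the upper concave hull of (x_i, i+1) for i in [low, high]."""
    hull = []
    for i in range(low, high + 1):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            if (x[i] - x[i1]) * (i2 - i1) <= (x[i2] - x[i1]) * (i - i1):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _hull_eval(x, hull_idx, hull_y, query_idx):
    """Evaluate a piecewise-linear hull at the x-positions of data indices."""
    hx = x[np.asarray(hull_idx)]
    out = np.empty(len(query_idx))
    for pos, q in enumerate(np.asarray(query_idx)):
        seg = int(np.searchsorted(np.asarray(hull_idx), q, side="right")) - 1
        seg = min(max(seg, 0), len(hull_idx) - 2) if len(hull_idx) > 1 else 0
        if len(hull_idx) == 1:
            out[pos] = hull_y[0]
            continue
        x1, x2 = hx[seg], hx[seg + 1]
        y1, y2 = hull_y[seg], hull_y[seg + 1]
        frac = 1.0 if x2 == x1 else (x[q] - x1) / (x2 - x1)
        if q <= hull_idx[seg]:
            frac = 0.0
        out[pos] = y1 + (y2 - y1) * np.clip(frac, 0.0, 1.0)
    return out


@lru_cache(maxsize=32)
def _dip_null(n: int, n_boot: int, seed: int) -> tuple:
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 79])
    return tuple(dip_statistic(rng.uniform(size=n)) for _ in range(n_boot))


def dip_test(values, n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value against a uniform null.

    Small p rejects unimodality.  Constant input returns (0, 1).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 4:
        raise ArgumentError("dip test needs at least 4 values")
    if np.all(values == values[0]):
        return 0.0, 1.0
    d = dip_statistic(values)
    null = np.array(_dip_null(values.size, n_boot, int(seed)))
    p = (1.0 + np.sum(null >= d)) / (1.0 + n_boot)
    return float(d), float(p)


# ---------------------------------------------------------------------------
# Model-order selection
# ---------------------------------------------------------------------------

def pac_score(consensus: ConsensusMatrix | np.ndarray,
              lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguously clustered pairs: off-diagonal consensus
    values strictly inside (lower, upper)."""
    if lower >= upper:
        raise ArgumentError("lower bound must be below upper bound")
    if isinstance(consensus, ConsensusMatrix):
        vals = consensus.off_diagonal()
    else:
        iu = np.triu_indices(len(consensus), k=1)
        vals = np.asarray(consensus)[iu]
    return float(np.mean((vals > lower) & (vals < upper)))


def select_solution(
    consensus_by_k: dict[int, ConsensusMatrix],
    pac_threshold: float = 0.1,
    dip_alpha: float = 0.05,
    pac_lower: float = 0.1, pac_upper: float = 0.9,
    n_boot: int = 1000, seed: int = 0,
    max_dip_values: int = 2000,
) -> dict:
    """Pick the most complex reliable cluster count.

    Candidates whose consensus distribution is consistent with unimodality
    (dip p > ``dip_alpha``) are excluded; among survivors the LARGEST k with
    PAC <= ``pac_threshold`` wins.  If no survivor passes the PAC bar (or the
    dip screen excludes everything) the candidate with the smallest PAC is
    returned with a warning.
    """
    if not consensus_by_k:
        raise SelectionError("no candidate solutions supplied")
    diag = {}
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 83])
    for k, cm in sorted(consensus_by_k.items()):
        vals = cm.off_diagonal()
        if vals.size > max_dip_values:
            vals = rng.choice(vals, size=max_dip_values, replace=False)
        dip, p = dip_test(vals, n_boot=n_boot, seed=seed)
        diag[k] = {"dip": dip, "dip_p": p, "pac": pac_score(cm, pac_lower, pac_upper)}
    survivors = [k for k, d in diag.items() if d["dip_p"] <= dip_alpha]
    pool = survivors if survivors else list(diag)
    if not survivors:
        log.warning("every candidate is consistent with unimodality; "
                    "falling back to argmin PAC over all candidates")
    reliable = [k for k in pool if diag[k]["pac"] <= pac_threshold]
    if reliable:
        k_selected = max(reliable)
        fallback = False
    else:
        log.warning("no candidate met PAC <= %.3f; falling back to argmin PAC",
                    pac_threshold)
        k_selected = min(pool, key=lambda k: diag[k]["pac"])
        fallback = True
    return {"k_selected": int(k_selected), "diagnostics": diag,
            "fallback": fallback}


# ---------------------------------------------------------------------------
# Exemplar extraction and summaries
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    assignments: np.ndarray
    exemplars: np.ndarray          # per-cluster subject index
    k_selected: int
    pac: float
    dip_p: float


def affinity_propagation_consensus(
    consensus: ConsensusMatrix | np.ndarray,
    target_k: int,
    damping: float = 0.9,
    max_iter: int = 2000,
    convergence_iter: int = 100,
    pac: float = np.nan,
    dip_p: float = np.nan,
) -> ClusterSolution:
    """Affinity propagation on the consensus matrix, with the preference
    tuned by bisection so the emergent cluster count matches ``target_k``
    (nearest achievable otherwise, flagged with a warning)."""
    S = consensus.values if isinstance(consensus, ConsensusMatrix) else np.asarray(consensus)
    n = len(S)
    if n == 1:
        return ClusterSolution(assignments=np.zeros(1, dtype=np.int64),
                               exemplars=np.zeros(1, dtype=np.int64),
                               k_selected=1, pac=pac, dip_p=dip_p)

    def run(preference):
        ap = AffinityPropagation(affinity="precomputed", damping=damping,
                                 max_iter=max_iter,
                                 convergence_iter=convergence_iter,
                                 preference=preference, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            ap.fit(S)
        if len(ap.cluster_centers_indices_) == 0:
            return None
        return ap

    lo, hi = -2.0, float(S.max())
    best, best_gap = None, np.inf
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        ap = run(mid)
        if ap is None:
            lo = mid
            continue
        k = len(ap.cluster_centers_indices_)
        gap = abs(k - target_k)
        if gap < best_gap:
            best, best_gap = ap, gap
        if k == target_k:
            break
        if k < target_k:
            lo = mid
        else:
            hi = mid
    if best is None:
        raise ConvergenceError(
            f"affinity propagation failed to converge (damping={damping}, "
            f"max_iter={max_iter}); try increasing damping")
    if best_gap > 0:
        log.warning("affinity propagation reached %d clusters, not the "
                    "requested %d", len(best.cluster_centers_indices_), target_k)
    labels = best.labels_.astype(np.int64)
    exemplars = best.cluster_centers_indices_.astype(np.int64)
    return ClusterSolution(assignments=labels, exemplars=exemplars,
                           k_selected=len(exemplars), pac=pac, dip_p=dip_p)


def cluster_similarity_summary(maps: np.ndarray, assignments) -> dict:
    """Mean within- and between-cluster eta^2 plus per-subject contrast."""
    X = np.asarray(maps, dtype=np.float64).reshape(len(maps), -1)
    labels = np.asarray(assignments)
    if np.unique(labels).size < 2:
        raise ArgumentError("need at least two clusters")
    eta = _eta_sq_cross(X, X)
    n = len(X)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(n, dtype=bool)
    within_mask = same & off
    between_mask = ~same
    per_subject = np.full(n, np.nan)
    flagged_singletons = []
    for i in range(n):
        w = eta[i, within_mask[i]]
        b = eta[i, between_mask[i]]
        if w.size == 0:
            flagged_singletons.append(i)
            continue
        per_subject[i] = w.mean() - b.mean()
    return {
        "mean_within": float(eta[within_mask].mean()),
        "mean_between": float(eta[between_mask].mean()),
        "per_subject_contrast": per_subject,
        "singletons": flagged_singletons,
    }
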