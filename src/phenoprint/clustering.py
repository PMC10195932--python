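"""K-means clustering of blurred temporal images.

Patients are clustered by Lloyd's algorithm on the row-major flattened
blurred images under plain Euclidean distance, with a seeded
k-means++-style initialization and independent restarts (best SSE
kept).  The number of clusters is scanned over a k range; the "elbow
area" of the SSE curve — the neighbourhood of the maximum discrete
curvature — is reported as advisory guidance, with the final k left to
the analyst.  Cluster fingerprints are per-cluster means of the
ORIGINAL (unblurred) images.

The in-house Lloyd loop (rather than an off-the-shelf fit) exposes the
per-iteration SSE path, deterministic tie-breaking (nearest-centroid
ties go to the lowest centroid index) and farthest-point reseeding of
empty clusters; tests cross-check it against an independent library
implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .encoding import ImageStack

__all__ = [
    "ClusterModel",
    "SSECurve",
    "Fingerprint",
    "InfeasibleKError",
    "kmeans_fit",
    "sse_scan",
    "suggest_elbow",
    "fingerprints",
]


class InfeasibleKError(ValueError):
    """Requested more clusters than there are distinct points."""


@dataclass
class ClusterModel:
    """Fitted K-means state.

    ``labels`` are 1..k, aligned with ``patient_ids``; ``sse_path`` is
    the per-iteration SSE of the winning restart (non-increasing).
    """

    k: int
    centroids: np.ndarray          # (k, F*W)
    patient_ids: list[str]
    labels: np.ndarray             # (n,), values 1..k
    sse: float
    seed: int
    n_restarts: int
    sse_path: list[float] = field(default_factory=list)

    @property
    def assignments(self) -> dict[str, int]:
        return {pid: int(lab) for pid, lab in zip(self.patient_ids, self.labels)}


@dataclass
class SSECurve:
    """SSE as a function of the cluster count k."""

    points: list[tuple[int, float]]

    def __post_init__(self) -> None:
        ks = [k for k, _ in self.points]
        if any(k2 <= k1 for k1, k2 in zip(ks, ks[1:])):
            raise ValueError("k values must be strictly increasing")
        if any(s < 0 for _, s in self.points):
            raise ValueError("SSE must be >= 0")

    @property
    def ks(self) -> list[int]:
        return [k for k, _ in self.points]

    @property
    def sses(self) -> list[float]:
        return [s for _, s in self.points]


@dataclass
class Fingerprint:
    """Per-cluster phenotype fingerprint: mean original image."""

    cluster_label: int
    mean_image: np.ndarray  # (F, W)
    n_patients: int


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, ImageStack):
        return np.asarray(data.flat(), dtype=float), list(data.patient_ids)
    X = np.asarray(data, dtype=float)
    if X.ndim == 3:
        X = X.reshape(X.shape[0], -1)
    return X, [str(i) for i in range(X.shape[0])]


def _sq_dists(X: np.ndarray, C: np.ndarray, x2: np.ndarray | None = None) -> np.ndarray:
    """Squared Euclidean distances (n, k) via the expanded inner product."""
    if x2 is None:
        x2 = np.einsum("ij,ij->i", X, X)
    D = X @ C.T
    D *= -2.0
    D += x2[:, None]
    D += np.einsum("ij,ij->i", C, C)[None, :]
    np.maximum(D, 0.0, out=D)
    return D


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator, x2: np.ndarray) -> np.ndarray:
    """Greedy k-means++ seeding.

    Each new seed is drawn from several candidates sampled with
    probability proportional to the squared distance to the nearest
    chosen seed; the candidate that most reduces the total potential is
    kept.  The greedy variant is markedly more reliable than plain
    k-means++ when clusters differ strongly in spread.
    """
    n = X.shape[0]
    n_candidates = 2 + int(np.log(k))
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = _sq_dists(X, centers[:1], x2).ravel()
    for c in range(1, k):
        total = d2.sum()
        if total > 0:
            cand = rng.choice(n, size=n_candidates, p=d2 / total)
        else:  # all remaining points coincide with chosen centers
            cand = rng.integers(n, size=n_candidates)
        cand_d2 = _sq_dists(X, X[cand], x2)
        potentials = np.minimum(cand_d2, d2[:, None]).sum(axis=0)
        best = int(np.argmin(potentials))
        centers[c] = X[cand[best]]
        np.minimum(d2, cand_d2[:, best], out=d2)
    return centers


def _lloyd(
    X: np.ndarray,
    centers: np.ndarray,
    x2: np.ndarray,
    max_iter: int = 300,
    rtol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    n, k = X.shape[0], centers.shape[0]
    prev_labels = None
    prev_sse = np.inf
    path: list[float] = []
    for _ in range(max_iter):
        D = _sq_dists(X, centers, x2)
        labels = D.argmin(axis=1)  # argmin breaks ties toward lowest index
        # reseed empty clusters from the farthest point
        for _ in range(k):
            counts = np.bincount(labels, minlength=k)
            empty = np.flatnonzero(counts == 0)
            if empty.size == 0:
                break
            point_d = D[np.arange(n), labels]
            far = int(point_d.argmax())
            centers[empty[0]] = X[far]
            D = _sq_dists(X, centers, x2)
            labels = D.argmin(axis=1)
        sse = float(D[np.arange(n), labels].sum())
        path.append(sse)
        if prev_labels is not None and (
            np.array_equal(labels, prev_labels)
            or (prev_sse - sse) <= rtol * max(prev_sse, 1e-300)
        ):
            prev_labels, prev_sse = labels, sse
            break
        for c in range(k):
            members = labels == c
            centers[c] = X[members].mean(axis=0)
        prev_labels, prev_sse = labels, sse
    return centers, prev_labels, prev_sse, path


def _relabel_by_mass(centroids: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters 1..k by ascending centroid mean pixel value.

    K-means labels are arbitrary; ordering clusters by the mean mass of
    their centroid in blurred-image space gives a deterministic
    convention in which label 1 is the least-active ("least prodrome")
    cluster.
    """
    mass = centroids.mean(axis=1)
    order = np.argsort(mass, kind="stable")      # order[new] = old
    inverse = np.empty_like(order)
    inverse[order] = np.arange(order.size)       # inverse[old] = new
    return centroids[order], inverse[labels] + 1


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def kmeans_fit(
    blurred,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
    relabel: bool = True,
) -> ClusterModel:
    """Fit K-means to flattened blurred images.

    Runs ``n_restarts`` independent seeded k-means++ initializations,
    Lloyd iterations to convergence each, and keeps the best-SSE fit.
    Deterministic given (data, k, seed, n_restarts).  With
    ``relabel=True`` cluster labels are ordered by ascending centroid
    mass (label 1 = least active cluster).
    """
    X, ids = _as_matrix(blurred)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise InfeasibleKError(
            f"k={k} exceeds the {n_distinct} distinct flattened images"
        )
    x2 = np.einsum("ij,ij->i", X, X)
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    root = np.random.default_rng(seed)
    for streams in [root.spawn(n_restarts)]:
        for rng in streams:
            centers = _kmeanspp_init(X, k, rng, x2)
            centers, labels, sse, path = _lloyd(X, centers, x2, max_iter=max_iter)
            if best is None or sse < best[0]:
                best = (sse, centers, labels, path)
    sse, centers, labels, path = best
    if relabel:
        centers, labels1 = _relabel_by_mass(centers, labels)
    else:
        labels1 = labels + 1
    return ClusterModel(
        k=k,
        centroids=centers,
        patient_ids=ids,
        labels=labels1,
        sse=sse,
        seed=seed,
        n_restarts=n_restarts,
        sse_path=path,
    )


def sse_scan(
    blurred,
    k_min: int = 2,
    k_max: int = 20,
    seed: int = 0,
    n_restarts: int = 10,
) -> SSECurve:
    """SSE of independent K-means fits for each k in k_min..k_max.

    Each k gets a fresh fit under the same seed policy as
    :func:`kmeans_fit` (no warm starts), so ``sse_scan`` at a given k
    matches ``kmeans_fit`` at that k.
    """
    X, _ = _as_matrix(blurred)
    if k_max > X.shape[0]:
        raise InfeasibleKError(f"k_max={k_max} exceeds n={X.shape[0]}")
    points = []
    for k in range(k_min, k_max + 1):
        model = kmeans_fit(X, k, seed=seed, n_restarts=n_restarts, relabel=False)
        points.append((k, model.sse))
    return SSECurve(points)


def suggest_elbow(curve: SSECurve) -> tuple[int, int]:
    """Advisory elbow area of an SSE curve.

    Returns the contiguous k range bracketing the point of maximum
    discrete curvature (largest second difference of SSE over k).  On
    an (effectively) straight curve there is no elbow; the full scanned
    range is returned with a warning.  The final choice of k remains an
    analyst decision.
    """
    ks, sses = curve.ks, curve.sses
    if len(ks) < 4:
        raise ValueError("need at least 4 curve points to locate an elbow")
    second = [
        sses[i - 1] - 2.0 * sses[i] + sses[i + 1] for i in range(1, len(ks) - 1)
    ]
    scale = max(abs(max(sses) - min(sses)), 1e-300)
    if max(second) <= 1e-8 * scale:
        warnings.warn("SSE curve has no discernible elbow; returning full range")
        return ks[0], ks[-1]
    i_star = 1 + int(np.argmax(second))
    lo = ks[max(i_star - 1, 0)]
    hi = ks[min(i_star + 1, len(ks) - 1)]
    return lo, hi


def fingerprints(original, assignments) -> list[Fingerprint]:
    """Per-cluster mean of members' ORIGINAL (unblurred) images.

    ``original`` is an ImageStack (or (n, F, W) array); ``assignments``
    maps patient_id -> label (dict or a ClusterModel).  Labels without
    members are skipped with a warning.  The size-weighted mean of all
    fingerprints equals the cohort mean image.
    """
    if isinstance(assignments, ClusterModel):
        assignments = assignments.assignments
    if isinstance(original, ImageStack):
        ids, arr = original.patient_ids, original.array
    else:
        arr = np.asarray(original, dtype=float)
        ids = [str(i) for i in range(arr.shape[0])]
    missing = [pid for pid in ids if pid not in assignments]
    if missing:
        raise ValueError(f"no cluster assignment for patients {missing[:5]!r}...")
    labels = np.array([assignments[pid] for pid in ids])
    out: list[Fingerprint] = []
    for lab in sorted(set(assignments.values())):
        members = labels == lab
        n = int(members.sum())
        if n == 0:
            warnings.warn(f"cluster {lab} has no members; skipped")
            continue
        out.append(Fingerprint(int(lab), arr[members].mean(axis=0), n))
    return out
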