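"""k-means clustering of normalized expression profiles under Pearson
correlation distance.

The distance between two stage profiles is 1 − r, their Pearson
correlation subtracted from one, so clusters group genes by the *shape*
of their temporal trajectory regardless of amplitude. Centroids are
arithmetic means of member rows (the closed-form update used by
MeV-style correlation k-means), Lloyd iterations run to label
convergence, and the best of several seeded restarts by within-cluster
distance sum is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .differential import NormalizedMatrix

MAX_ITER = 300


def _standardize(rows: np.ndarray) -> np.ndarray:
    """Center and scale each row to zero mean, unit population sd.

    A zero-variance row maps to the zero vector, which makes its
    correlation with anything 0 (distance 1); callers that forbid
    zero-variance input must check beforehand.
    """
    rows = np.asarray(rows, dtype=float)
    centered = rows - rows.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)
    out = np.zeros_like(centered)
    np.divide(centered, sd, out=out, where=sd > 0)
    return out


def pearson_distance(x, y) -> float:
    """1 − Pearson r between two equal-length profiles; range [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape or x.size < 2:
        raise ValueError("profiles must be equal-length 1-D arrays of length ≥ 2")
    for name, v in (("x", x), ("y", y)):
        if np.std(v) == 0:
            raise ValueError(f"profile {name} has zero variance")
    zx = _standardize(x[None, :])[0]
    zy = _standardize(y[None, :])[0]
    r = float(zx @ zy) / x.size
    return 1.0 - r


@dataclass
class ClusterAssignment:
    """Result of correlation k-means on a normalized matrix."""

    gene_ids: list[str]
    stage_labels: list[str]
    label: dict[str, int]  # gene -> cluster id in 1..k
    centroids: np.ndarray  # k × n_stages mean normalized profiles
    k: int
    seed: int
    n_iter: int
    objective: float  # within-cluster Pearson-distance sum

    def members(self, cluster_id: int) -> list[str]:
        return [g for g in self.gene_ids if self.label[g] == cluster_id]

    def labels_array(self) -> np.ndarray:
        return np.array([self.label[g] for g in self.gene_ids])


def _distances_to_centroids(z_rows: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """n × k matrix of 1 − r between standardized rows and centroids."""
    s = z_rows.shape[1]
    zc = _standardize(centroids)
    return 1.0 - (z_rows @ zc.T) / s


def _plusplus_init(values: np.ndarray, z: np.ndarray, k: int,
                   rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under Pearson distance (D² sampling)."""
    n = values.shape[0]
    chosen = [int(rng.integers(n))]
    d2 = _distances_to_centroids(z, values[chosen])[:, 0] ** 2
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            pick = int(rng.integers(n))
        else:
            pick = int(rng.choice(n, p=d2 / total))
        chosen.append(pick)
        d_new = _distances_to_centroids(z, values[[pick]])[:, 0] ** 2
        d2 = np.minimum(d2, d_new)
    return values[chosen].copy()


def _lloyd(values: np.ndarray, k: int, rng: np.random.Generator):
    n = values.shape[0]
    z = _standardize(values)
    centroids = _plusplus_init(values, z, k, rng)
    labels = np.full(n, -1)
    for iteration in range(1, MAX_ITER + 1):
        dist = _distances_to_centroids(z, centroids)
        new_labels = dist.argmin(axis=1)
        # repair empty clusters with the point farthest from its centroid
        for c in range(k):
            if not np.any(new_labels == c):
                assigned = dist[np.arange(n), new_labels].copy()
                counts = np.bincount(new_labels, minlength=k)
                assigned[counts[new_labels] <= 1] = -np.inf
                new_labels[int(assigned.argmax())] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = values[labels == c].mean(axis=0)
    dist = _distances_to_centroids(z, centroids)
    objective = float(dist[np.arange(n), labels].sum())
    return labels, centroids, objective, iteration


def kmeans_cluster(
    nm: NormalizedMatrix, k: int = 9, seed: int = 0, restarts: int = 10
) -> ClusterAssignment:
    """Cluster genes into k temporal-pattern groups.

    Runs ``restarts`` seeded Lloyd passes (seeds ``seed .. seed+restarts-1``,
    initial centroids by k-means++ D² sampling under the correlation
    distance) and keeps the run with
    the lowest within-cluster Pearson-distance sum; ties go to the lowest
    seed. Deterministic for fixed (matrix, k, seed, restarts).

    Raises for k outside [1, n_genes] and for zero-variance genes, which
    have no defined correlation to any centroid.
    """
    values = nm.value
    n = values.shape[0]
    if k <= 0 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if restarts < 1:
        raise ValueError("restarts must be ≥ 1")
    flat = np.where(values.std(axis=1) == 0)[0]
    if flat.size:
        names = [nm.gene_ids[i] for i in flat[:10]]
        raise ValueError(f"zero-variance genes cannot be clustered: {names}")

    best = None
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        labels, centroids, objective, n_iter = _lloyd(values, k, rng)
        if best is None or objective < best[2]:
            best = (labels, centroids, objective, n_iter, seed + r)
    labels, centroids, objective, n_iter, _ = best
    return ClusterAssignment(
        gene_ids=list(nm.gene_ids),
        stage_labels=list(nm.stage_labels),
        label={g: int(c) + 1 for g, c in zip(nm.gene_ids, labels)},
        centroids=centroids,
        k=k,
        seed=seed,
        n_iter=n_iter,
        objective=objective,
    )


# shape-tag thresholds: an interior extremum counts as a dip/peak when the
# profile recovers by ≥ 20% of the centroid's range on both sides; a rise
# counts as "late" when a single step carries ≥ 50% of the range and lands
# at stage 3 or later
_RECOVERY_FRAC = 0.2
_JUMP_FRAC = 0.5


def _shape_tag(c: np.ndarray) -> str:
    rng_ = float(c.max() - c.min())
    if rng_ == 0:
        return "drift-up"
    imin = int(c.argmin())
    imax = int(c.argmax())
    last = len(c) - 1
    if 0 < imin < last:
        if (c[0] - c[imin] >= _RECOVERY_FRAC * rng_) and (
            c[last] - c[imin] >= _RECOVERY_FRAC * rng_
        ):
            return "early-dip"
    if 0 < imax < last:
        if (c[imax] - c[0] >= _RECOVERY_FRAC * rng_) and (
            c[imax] - c[last] >= _RECOVERY_FRAC * rng_
        ):
            return "rise-fall"
    diffs = np.diff(c)
    if c[last] >= c[0]:
        jump = int(diffs.argmax())
        if diffs[jump] >= _JUMP_FRAC * rng_ and jump + 1 >= 2:
            return "late-rise"
        return "drift-up"
    return "drift-down"


def cluster_trends(a: ClusterAssignment) -> list[dict]:
    """Per-cluster trajectory summary.

    For each centroid reports the stage of its minimum and maximum (first
    occurrence on ties) and a shape tag in {early-dip, late-rise,
    rise-fall, drift-down, drift-up} by the documented slope rules.
    """
    out = []
    for c in range(a.k):
        profile = a.centroids[c]
        out.append(
            {
                "cluster": c + 1,
                "size": len(a.members(c + 1)),
                "min_stage": a.stage_labels[int(profile.argmin())],
                "max_stage": a.stage_labels[int(profile.argmax())],
                "tag": _shape_tag(profile),
            }
        )
    return out
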