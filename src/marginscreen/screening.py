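"""Centroid thresholding and three-group triage.

Training specimens (paired cancerous/noncancerous tissue from several
patients) are reduced to points in the (nitroreductase, viscosity) intensity
plane.  The K-means centroid of that scatter — with the default k=1 this is
simply the grand mean — becomes the dual-channel threshold (t_ntr, t_vis).
A test specimen is then triaged by which quadrant it falls in:

* ``++`` definitely positive: strong fluorescence in both channels,
* ``+``  suspiciously positive: strong fluorescence in exactly one channel,
* ``-``  negative: weak fluorescence in both channels,

where "strong" means intensity >= threshold.  A value exactly at the
threshold counts as strong: a pre-screen must err toward flagging tumor.

Thresholds are cancer-type- and instrument-specific, so they are always
inputs or derived from a training scatter — never constants of the code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from marginscreen.image_quant import SampleRecord

__all__ = [
    "Threshold", "TriageCall", "KMeansResult",
    "lloyd_kmeans", "derive_threshold", "classify", "classify_cohort",
    "DEFINITE_POS", "SUSPECT_POS", "NEG",
]

DEFINITE_POS = "++"
SUSPECT_POS = "+"
NEG = "-"


@dataclass(frozen=True)
class Threshold:
    """Dual-channel decision point (gray-scale units, x = ntr, y = vis)."""

    t_ntr: float
    t_vis: float

    def __post_init__(self) -> None:
        for name, v in (("t_ntr", self.t_ntr), ("t_vis", self.t_vis)):
            if not (0.0 <= v <= 255.0):
                raise ValueError(f"{name}={v} outside the 8-bit gray scale")


@dataclass(frozen=True)
class TriageCall:
    """One of the three pre-screening outcomes."""

    value: str

    def __post_init__(self) -> None:
        if self.value not in (DEFINITE_POS, SUSPECT_POS, NEG):
            raise ValueError(f"invalid triage call {self.value!r}")

    @property
    def screen_positive(self) -> bool:
        return self.value in (DEFINITE_POS, SUSPECT_POS)


@dataclass(frozen=True)
class KMeansResult:
    k: int
    centroids: tuple[tuple[float, float], ...]
    assignments: tuple[int, ...]
    inertia: float
    iterations: int
    inertia_history: tuple[float, ...] = ()


def _inertia(pts: np.ndarray, centroids: np.ndarray, assign: np.ndarray) -> float:
    diff = pts - centroids[assign]
    return float(np.sum(diff * diff))


def _assign(pts: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def _kmeanspp_init(pts: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centroids by squared distance."""
    n = pts.shape[0]
    centroids = np.empty((k, 2), dtype=float)
    centroids[0] = pts[rng.integers(n)]
    for j in range(1, k):
        d2 = ((pts[:, None, :] - centroids[None, :j, :]) ** 2).sum(axis=2).min(axis=1)
        total = d2.sum()
        if total == 0:
            centroids[j] = pts[rng.integers(n)]
        else:
            centroids[j] = pts[rng.choice(n, p=d2 / total)]
    return centroids


def lloyd_kmeans(
    points: Sequence[tuple[float, float]],
    k: int,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 300,
) -> KMeansResult:
    """Lloyd's K-means on 2-D points with k-means++-style initialization.

    Iterates assign/update until the maximal centroid shift falls below
    ``tol`` or ``max_iter`` is reached.  An empty cluster is re-seeded to
    the point farthest from its assigned centroid.  Deterministic for a
    fixed seed.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (x, y) pairs")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    n = pts.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} must satisfy 1 <= k <= n={n}")

    rng = np.random.default_rng(seed)
    centroids = _kmeanspp_init(pts, k, rng)
    history: list[float] = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        assign = _assign(pts, centroids)
        history.append(_inertia(pts, centroids, assign))
        new_centroids = centroids.copy()
        for j in range(k):
            members = pts[assign == j]
            if members.shape[0] == 0:
                # re-seed to the globally worst-fit point
                far = np.argmax(((pts - centroids[assign]) ** 2).sum(axis=1))
                new_centroids[j] = pts[far]
            else:
                new_centroids[j] = members.mean(axis=0)
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            break
    assign = _assign(pts, centroids)
    inertia = _inertia(pts, centroids, assign)
    history.append(inertia)
    return KMeansResult(
        k=k,
        centroids=tuple((float(x), float(y)) for x, y in centroids),
        assignments=tuple(int(a) for a in assign),
        inertia=inertia,
        iterations=iterations,
        inertia_history=tuple(history),
    )


def derive_threshold(training: Sequence[SampleRecord], k: int = 1, seed: int = 0) -> Threshold:
    """Derive the dual-channel threshold from a training scatter.

    All training points — cancerous and noncancerous together — are pooled
    and the K-means centroid is taken as the threshold.  With the default
    k=1 the centroid is the componentwise mean of the scatter, which is the
    single printed (x, y) threshold convention; larger k returns the
    centroid of the biggest cluster and is provided for sensitivity
    analysis only.  The threshold is reported to 1 decimal, matching how
    such thresholds are quoted.
    """
    if len(training) < 2:
        raise ValueError("need at least 2 training records")
    pts = [(float(r.i_ntr), float(r.i_vis)) for r in training]
    result = lloyd_kmeans(pts, k=k, seed=seed)
    if k == 1:
        cx, cy = result.centroids[0]
    else:
        sizes = np.bincount(np.asarray(result.assignments), minlength=k)
        cx, cy = result.centroids[int(np.argmax(sizes))]
    return Threshold(t_ntr=round(cx, 1), t_vis=round(cy, 1))


def classify(record: SampleRecord, thr: Threshold) -> TriageCall:
    """Quadrant triage of one specimen against the dual-channel threshold."""
    high_ntr = record.i_ntr >= thr.t_ntr
    high_vis = record.i_vis >= thr.t_vis
    if high_ntr and high_vis:
        return TriageCall(DEFINITE_POS)
    if high_ntr or high_vis:
        return TriageCall(SUSPECT_POS)
    return TriageCall(NEG)


def classify_cohort(records: Sequence[SampleRecord], thr: Threshold) -> list[SampleRecord]:
    """Classify every record, returning new records with the call filled in."""
    out = []
    for r in records:
        out.append(SampleRecord(
            sample_id=r.sample_id, i_ntr=r.i_ntr, i_vis=r.i_vis,
            he_label=r.he_label, call=classify(r, thr).value,
        ))
    return out
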