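"""Descriptor matching and individual identification.

A query image is matched to a database image by finding, for every query
descriptor, its two nearest database descriptors (Euclidean distance) and
keeping the match only when the nearest distance is strictly below 0.75
times the second-nearest ("ratio test").  The number of surviving matches is
the similarity score between the two images.  A query is identified as the
individual owning the database image with the highest score ("marked
population re-sighting" by argmax).

Nearest-neighbour search is exact by default; an approximate kd-tree backend
is available for large databases and must agree with the exact search on
virtually all accepted matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sift import FeatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "MatchConfig",
    "NeighbourSet",
    "MatchResult",
    "FeatureDatabase",
    "IdentificationResult",
    "knn_search",
    "ratio_filter",
    "match_images",
    "identify",
]


@dataclass(frozen=True)
class MatchConfig:
    """Matching parameters: k = 2 nearest neighbours with a 0.75 distance
    ratio threshold by default; ``min_match_count`` is the smallest best
    score still accepted as an identification (0 = always predict)."""

    knn_k: int = 2
    ratio_threshold: float = 0.75
    min_match_count: int = 0
    backend: str = "exact"          # "exact" | "kdtree"
    cross_check: bool = False
    pool_by_individual: bool = False

    def __post_init__(self) -> None:
        if self.knn_k < 2:
            raise ValueError("knn_k must be >= 2 for the ratio test")
        if not 0.0 < self.ratio_threshold < 1.0:
            raise ValueError("ratio_threshold must lie in (0, 1)")
        if self.backend not in ("exact", "kdtree"):
            raise ValueError(f"unknown backend {self.backend!r}")

    def digest(self) -> str:
        import hashlib
        import json
        from dataclasses import asdict
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class NeighbourSet:
    """k nearest targets per query descriptor.

    ``indices``/``distances`` have shape (n_query, k), sorted by ascending
    distance; ``valid`` is False for every query when the target set was too
    small to provide k neighbours.
    """

    indices: np.ndarray
    distances: np.ndarray
    valid: np.ndarray


@dataclass
class MatchResult:
    """Accepted matches between a query and a target image."""

    query_image_id: str
    target_image_id: str
    n_matches: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def total_distance(self) -> float:
        return float(sum(p[2] for p in self.pairs))


@dataclass
class FeatureDatabase:
    """Labelled collection of feature sets — the marked population."""

    entries: list[FeatureSet] = field(default_factory=list)
    sift_digest: str = ""
    match_digest: str = ""

    def __post_init__(self) -> None:
        for e in self.entries:
            if not e.individual_id:
                raise ValueError(
                    f"database entry {e.image_id!r} lacks an individual_id")
        digests = {e.config_digest for e in self.entries if e.config_digest}
        if len(digests) > 1:
            raise ValueError("mixed extraction configs in database")
        if digests and not self.sift_digest:
            self.sift_digest = next(iter(digests))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def individuals(self) -> list[str]:
        return sorted({e.individual_id for e in self.entries})


@dataclass
class IdentificationResult:
    """Prediction for one query image with per-database-image scores."""

    query_image_id: str
    predicted_individual: str | None
    best_image_id: str | None
    scores: dict[str, int]
    tie_broken: bool = False


# ---------------------------------------------------------------------------
# Nearest-neighbour search
# ---------------------------------------------------------------------------


def knn_search(query: np.ndarray, target: np.ndarray, k: int = 2,
               backend: str = "exact") -> NeighbourSet:
    """k smallest Euclidean distances (and target indices) per query
    descriptor, sorted ascending.

    Exact by default (full distance matrix); ``backend="kdtree"`` uses a
    kd-tree (scipy) instead.  A target set smaller than k flags every query
    as unmatched.
    """
    q = np.atleast_2d(np.asarray(query, dtype=np.float64))
    t = np.atleast_2d(np.asarray(target, dtype=np.float64))
    nq = q.shape[0]
    if t.shape[0] < k:
        return NeighbourSet(indices=np.zeros((nq, k), dtype=int),
                            distances=np.full((nq, k), np.inf),
                            valid=np.zeros(nq, dtype=bool))
    if backend == "kdtree":
        from scipy.spatial import cKDTree
        dist, idx = cKDTree(t).query(q, k=k)
        return NeighbourSet(indices=np.atleast_2d(idx),
                            distances=np.atleast_2d(dist),
                            valid=np.ones(nq, dtype=bool))
    d2 = (np.sum(q * q, axis=1)[:, None] + np.sum(t * t, axis=1)[None, :]
          - 2.0 * (q @ t.T))
    np.maximum(d2, 0.0, out=d2)
    if k < t.shape[0]:
        part = np.argpartition(d2, k - 1, axis=1)[:, :k]
    else:
        part = np.broadcast_to(np.arange(t.shape[0]), (nq, t.shape[0])).copy()
    pd = np.take_along_axis(d2, part, axis=1)
    order = np.argsort(pd, axis=1, kind="stable")
    idx = np.take_along_axis(part, order, axis=1)
    dist = np.sqrt(np.take_along_axis(pd, order, axis=1))
    return NeighbourSet(indices=idx, distances=dist,
                        valid=np.ones(nq, dtype=bool))


def ratio_filter(neighbours: NeighbourSet, cfg: MatchConfig = MatchConfig()
                 ) -> list[tuple[int, int, float]]:
    """Lowe's ratio test: accept query i iff d1 < ratio_threshold * d2
    (strict); degenerate d2 = 0 (duplicate descriptors) is rejected.

    Returns (query index, target index, d1) triples.
    """
    out = []
    d = neighbours.distances
    for i in range(d.shape[0]):
        if not neighbours.valid[i]:
            continue
        d1, d2 = float(d[i, 0]), float(d[i, 1])
        if d2 <= 0.0:
            continue
        if d1 < cfg.ratio_threshold * d2:
            out.append((i, int(neighbours.indices[i, 0]), d1))
    return out


def match_images(a: FeatureSet, b: FeatureSet,
                 cfg: MatchConfig = MatchConfig()) -> MatchResult:
    """Match image a's descriptors against image b's and count ratio-test
    survivors.

    Matching is one-directional (a -> b) unless ``cfg.cross_check`` is set,
    in which case a pair is kept only if it is also b's best match for that
    target descriptor.  When both feature sets come from the same image the
    zero-distance self-neighbour is excluded before the ratio test.
    """
    if a.config_digest and b.config_digest and a.config_digest != b.config_digest:
        raise ValueError("feature sets come from different extraction configs")
    if len(a) == 0 or len(b) == 0:
        return MatchResult(a.image_id, b.image_id, 0, [])

    same_image = a.image_id == b.image_id and a.image_id != ""
    k = cfg.knn_k + 1 if same_image else cfg.knn_k
    nn = knn_search(a.descriptors, b.descriptors, k=k, backend=cfg.backend)

    if same_image and nn.valid.any():
        # drop each query's own entry (identical index), keep the rest
        nq = nn.indices.shape[0]
        idx = np.empty((nq, cfg.knn_k), dtype=int)
        dist = np.empty((nq, cfg.knn_k))
        for i in range(nq):
            keep = [j for j in range(k) if nn.indices[i, j] != i]
            keep = (keep + list(range(k)))[:cfg.knn_k]
            idx[i] = nn.indices[i, keep]
            dist[i] = nn.distances[i, keep]
        nn = NeighbourSet(indices=idx, distances=dist, valid=nn.valid)

    pairs = ratio_filter(nn, cfg)
    if cfg.cross_check and pairs:
        back = knn_search(b.descriptors, a.descriptors, k=1,
                          backend=cfg.backend)
        pairs = [p for p in pairs
                 if back.valid[p[1]] and int(back.indices[p[1], 0]) == p[0]]
    return MatchResult(a.image_id, b.image_id, len(pairs), pairs)


def identify(query: FeatureSet, db: FeatureDatabase,
             cfg: MatchConfig = MatchConfig()) -> IdentificationResult:
    """Identify the individual in a query image.

    The query is matched against every database image; the predicted
    individual is the owner of the image with the maximal match count.
    Ties are broken by (1) the smallest summed match distance and (2) the
    lexicographically smallest image id, and flagged.  If the best score is
    below ``cfg.min_match_count`` no individual is predicted.

    With ``cfg.pool_by_individual`` the scores of all images of each
    individual are summed before the argmax.
    """
    if len(db) == 0:
        raise ValueError("cannot identify against an empty database")
    results = [match_images(query, e, cfg) for e in db.entries]
    scores = {r.target_image_id: r.n_matches for r in results}

    if cfg.pool_by_individual:
        pooled: dict[str, int] = {}
        pooled_dist: dict[str, float] = {}
        for e, r in zip(db.entries, results):
            pooled[e.individual_id] = pooled.get(e.individual_id, 0) + r.n_matches
            pooled_dist[e.individual_id] = (
                pooled_dist.get(e.individual_id, 0.0) + r.total_distance)
        best_score = max(pooled.values())
        cands = sorted(k for k, v in pooled.items() if v == best_score)
        tie = len(cands) > 1
        cands.sort(key=lambda ind: (pooled_dist[ind], ind))
        pred = cands[0]
        best_image = None
        for e, r in zip(db.entries, results):
            if e.individual_id == pred and (
                    best_image is None or r.n_matches > scores[best_image]):
                best_image = e.image_id
    else:
        best_score = max(r.n_matches for r in results)
        cands = [(e, r) for e, r in zip(db.entries, results)
                 if r.n_matches == best_score]
        tie = len(cands) > 1
        cands.sort(key=lambda er: (er[1].total_distance, er[0].image_id))
        best_entry, _ = cands[0]
        pred = best_entry.individual_id
        best_image = best_entry.image_id

    if best_score < cfg.min_match_count:
        return IdentificationResult(query.image_id, None, None, scores, tie)
    return IdentificationResult(query.image_id, pred, best_image, scores, tie)
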