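"""Ensemble hierarchical clustering by one-hot cosine-similarity consensus.

The procedure combines a battery of agglomerative clusterings into one
robust partition:

1. **Battery** — each feature group is clustered with each linkage criterion
   (default: single, complete, average, Ward) on Euclidean distances of the
   standardised group features, the tree cut at ``k`` clusters (default 4).
2. **One-hot consensus** — the label matrix is one-hot encoded per run; the
   cosine similarity of two series' encodings equals the fraction of runs in
   which they land in the same cluster, a label-permutation-invariant
   co-membership score.
3. **Similarity levels** — the multiset of pairwise similarities is split
   into high / middle / low by an exact 1-D k-means (dynamic program over
   contiguous splits of the sorted values, so no initialisation randomness).
4. **Graph consensus** — series joined by high-level edges form a graph;
   connected components are the consensus groups.  Sparse bridges (a single
   series whose few cross-edges glue two dense groups together) can be
   pruned, and very small groups can be merged towards the neighbouring
   group with *fewer* low-similarity links (fewer low links = less evidence
   of dissimilarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .features import FeatureMatrix

__all__ = [
    "ConsensusResult",
    "LabelMatrix",
    "PruneConfig",
    "SimilarityPartition",
    "LEVEL_LOW",
    "LEVEL_MIDDLE",
    "LEVEL_HIGH",
    "build_consensus",
    "cosine_similarity",
    "one_hot_encode",
    "partition_similarity",
    "reassign_small_groups",
    "run_battery",
]

LEVEL_LOW, LEVEL_MIDDLE, LEVEL_HIGH = 0, 1, 2
LEVEL_NAMES = {LEVEL_LOW: "low", LEVEL_MIDDLE: "middle", LEVEL_HIGH: "high"}

DEFAULT_LINKAGES = ("single", "complete", "average", "ward")


class DegeneratePartitionError(ValueError):
    """Too few distinct similarity values to form three levels."""


@dataclass(frozen=True)
class LabelMatrix:
    """Base-clustering labels: one column per (feature group, linkage) run."""

    series_ids: tuple[str, ...]
    runs: tuple[tuple[str, str], ...]
    labels: np.ndarray = field(repr=False)  # (n_series, n_runs), values 1..k
    k: int = 4

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        if lab.shape != (len(self.series_ids), len(self.runs)):
            raise ValueError("label matrix shape mismatch")
        if lab.size and (lab.min() < 1 or lab.max() > self.k):
            raise ValueError(f"labels must lie in 1..{self.k}")
        object.__setattr__(self, "labels", lab)

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def run_battery(
    fm: FeatureMatrix,
    linkages: Sequence[str] = DEFAULT_LINKAGES,
    k: int = 4,
) -> LabelMatrix:
    """Run agglomerative clustering for every (feature group, linkage) pair.

    Uses standardised group features with Euclidean distances (Ward's
    criterion requires them); each tree is cut at ``k`` clusters.  Fully
    deterministic.
    """
    n = len(fm.series_ids)
    if not linkages:
        raise ValueError("need at least one linkage")
    if n < k:
        raise ValueError(f"need at least k={k} series, got {n}")
    runs: list[tuple[str, str]] = []
    cols: list[np.ndarray] = []
    for group in fm.group_names:
        X = fm.standardized[group].to_numpy(dtype=float)
        d = pdist(X, metric="euclidean")
        for method in linkages:
            Z = linkage(d, method=method)
            cols.append(fcluster(Z, t=k, criterion="maxclust"))
            runs.append((group, method))
    return LabelMatrix(
        series_ids=fm.series_ids,
        runs=tuple(runs),
        labels=np.column_stack(cols),
        k=k,
    )


def one_hot_encode(lm: LabelMatrix) -> np.ndarray:
    """One-hot encode the label matrix: (n_series, n_runs * k) 0/1 vectors.

    Label ``c`` in run ``r`` sets position ``r*k + (c-1)``.  Every row has
    exactly ``n_runs`` ones, so its Euclidean norm is ``sqrt(n_runs)``.
    """
    n, R = lm.labels.shape
    out = np.zeros((n, R * lm.k), dtype=float)
    rows = np.repeat(np.arange(n), R)
    cols = (np.tile(np.arange(R), n) * lm.k) + (lm.labels.ravel() - 1)
    out[rows, cols] = 1.0
    return out


def cosine_similarity(vectors: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity, clipped to [0, 1] with unit diagonal.

    For one-hot encoded label rows this equals (number of runs in which the
    two series share a cluster) / (number of runs).
    """
    v = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    if (norms == 0).any():
        raise ValueError("zero vector has no cosine similarity")
    sim = _sk_cosine(v)
    sim = np.clip(sim, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


# ---------------------------------------------------------------------------
# exact 1-D k-means on the similarity multiset

def _exact_kmeans_1d(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Optimal k-cluster partition of a 1-D multiset by SSE.

    Dynamic program over contiguous splits of the sorted values (for 1-D
    data an SSE-optimal partition is always contiguous).  Returns
    (sorted_values, centroids ascending).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def seg_cost(a: np.ndarray, b: int) -> np.ndarray:
        # SSE of x[a:b] for array of starts a (a < b)
        m = b - a
        s = s1[b] - s1[a]
        return (s2[b] - s2[a]) - s * s / m

    # D[m][j] = best cost of splitting x[:j] into m segments
    D = np.full((k + 1, n + 1), np.inf)
    cut = np.zeros((k + 1, n + 1), dtype=np.int64)
    D[0, 0] = 0.0
    starts = np.arange(n)
    for m in range(1, k + 1):
        for j in range(m, n - (k - m) + 1):
            a = starts[m - 1 : j]
            cand = D[m - 1, m - 1 : j] + seg_cost(a, j)
            i = int(np.argmin(cand))  # first optimum -> deterministic
            D[m, j] = cand[i]
            cut[m, j] = a[i]
    bounds = [n]
    j = n
    for m in range(k, 0, -1):
        j = int(cut[m, j])
        bounds.append(j)
    bounds = bounds[::-1]  # [0, c1, c2, ..., n]
    centroids = np.array([x[bounds[i] : bounds[i + 1]].mean() for i in range(k)])
    return x, centroids


@dataclass(frozen=True)
class SimilarityPartition:
    """Pairwise cosine similarities with a 3-level (low/middle/high) split.

    ``level`` holds LEVEL_LOW/MIDDLE/HIGH for off-diagonal pairs (diagonal
    set to LEVEL_HIGH by convention); ``centroids`` are the (low, middle,
    high) level centres from the exact 1-D k-means.
    """

    series_ids: tuple[str, ...]
    similarity: np.ndarray = field(repr=False)
    level: np.ndarray = field(repr=False)
    centroids: tuple[float, float, float]


def partition_similarity(
    sim: np.ndarray,
    series_ids: Sequence[str],
    k: int = 3,
    seed: int | None = None,
) -> SimilarityPartition:
    """Split the off-diagonal similarity multiset into k=3 named levels.

    The 1-D k-means is solved exactly (dynamic program over contiguous
    splits), so ``seed`` has no effect and is accepted only for API
    symmetry.  Values equidistant between two centroids go to the lower
    level (conservative edges).  Fewer than 3 distinct off-diagonal values
    raise :class:`DegeneratePartitionError`.
    """
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = sim[iu]
    if np.unique(vals).size < k:
        raise DegeneratePartitionError(
            f"need >= {k} distinct off-diagonal similarity values to form "
            f"{k} levels; got {np.unique(vals).size}"
        )
    _, centroids = _exact_kmeans_1d(vals, k)
    if np.unique(centroids).size < k:
        raise DegeneratePartitionError("level centroids are not distinct")

    # nearest centroid, ties to the lower level
    dist = np.abs(vals[:, None] - centroids[None, :])
    lev_vals = np.argmin(dist, axis=1)  # argmin takes the first (= lower) level

    level = np.full((n, n), LEVEL_HIGH, dtype=np.int64)
    level[iu] = lev_vals
    level[(iu[1], iu[0])] = lev_vals
    return SimilarityPartition(
        series_ids=tuple(series_ids),
        similarity=sim,
        level=level,
        centroids=(float(centroids[0]), float(centroids[1]), float(centroids[2])),
    )


# ---------------------------------------------------------------------------
# graph consensus

@dataclass(frozen=True)
class PruneConfig:
    """Sparse-bridge pruning settings.

    An edge is pruned when one endpoint acts as the only glue between two
    sufficiently large groups and has at most ``min_support`` neighbours on
    the far side.  ``enabled=False`` turns pruning off.
    """

    enabled: bool = True
    min_component: int = 3
    min_support: int = 2


@dataclass(frozen=True)
class ConsensusResult:
    """Groups from the high-similarity graph.

    ``fine_groups`` are the connected components after pruning (members
    sorted); ``pattern_groups`` additionally merge small groups into their
    most-similar neighbour (identical to ``fine_groups`` until
    :func:`reassign_small_groups` is applied).
    """

    series_ids: tuple[str, ...]
    high_graph: nx.Graph = field(repr=False)
    fine_groups: tuple[tuple[str, ...], ...]
    pattern_groups: tuple[tuple[str, ...], ...]
    pruned_edges: tuple[tuple[str, str], ...] = ()
    reassignments: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] = ()
    unresolved: tuple[tuple[str, ...], ...] = ()

    def group_of(self, pattern: bool = True) -> dict[str, int]:
        """Map series id -> group index (pattern groups by default)."""
        groups = self.pattern_groups if pattern else self.fine_groups
        return {sid: gi for gi, grp in enumerate(groups) for sid in grp}


def _bridge_edges(G: nx.Graph, cfg: PruneConfig) -> set[tuple]:
    """Edges qualifying for sparse-bridge pruning, evaluated simultaneously.

    For an edge (u, v) and candidate bridge endpoint w in {u, v} with far
    endpoint x: remove w from the graph; the edge is prunable through w if
    the component of x ("far side") differs from the component holding most
    of w's other neighbours ("near side" — the denser side where w is
    retained), both components have at least ``min_component`` nodes, and w
    has at most ``min_support`` neighbours on the far side.
    """
    to_prune: set[tuple] = set()
    comp_cache: dict = {}

    def comps_without(w):
        if w not in comp_cache:
            H = G.copy()
            H.remove_node(w)
            comp_id = {}
            sizes = []
            for ci, comp in enumerate(nx.connected_components(H)):
                sizes.append(len(comp))
                for node in comp:
                    comp_id[node] = ci
            comp_cache[w] = (comp_id, sizes)
        return comp_cache[w]

    for u, v in G.edges():
        for w, x in ((u, v), (v, u)):
            comp_id, sizes = comps_without(w)
            nbrs = [nb for nb in G.neighbors(w)]
            counts: dict[int, int] = {}
            for nb in nbrs:
                counts[comp_id[nb]] = counts.get(comp_id[nb], 0) + 1
            far = comp_id[x]
            # near side: component holding the most of w's neighbours
            near = max(counts, key=lambda c: (counts[c], -c))
            if far == near:
                continue
            if sizes[far] < cfg.min_component or sizes[near] < cfg.min_component:
                continue
            if counts[far] <= cfg.min_support:
                to_prune.add((u, v) if u <= v else (v, u))
                break
    return to_prune


def build_consensus(
    sp: SimilarityPartition,
    prune: PruneConfig | None = None,
) -> ConsensusResult:
    """Build the high-similarity graph and read groups off its components.

    All series pairs whose similarity sits in the high level become edges;
    sparse bridges are pruned (simultaneously, on the unpruned graph); the
    connected components, members sorted, are the consensus groups.
    """
    prune = prune or PruneConfig()
    ids = sp.series_ids
    n = len(ids)
    G = nx.Graph()
    G.add_nodes_from(ids)
    iu = np.triu_indices(n, k=1)
    for i, j in zip(*iu):
        if sp.level[i, j] == LEVEL_HIGH:
            G.add_edge(ids[i], ids[j], similarity=float(sp.similarity[i, j]))

    pruned: list[tuple[str, str]] = []
    if prune.enabled:
        for u, v in sorted(_bridge_edges(G, prune)):
            G.remove_edge(u, v)
            pruned.append((u, v))

    groups = tuple(
        tuple(sorted(comp))
        for comp in sorted(nx.connected_components(G), key=lambda c: sorted(c)[0])
    )
    return ConsensusResult(
        series_ids=ids,
        high_graph=G,
        fine_groups=groups,
        pattern_groups=groups,
        pruned_edges=tuple(pruned),
    )


def reassign_small_groups(
    cr: ConsensusResult,
    sp: SimilarityPartition,
    max_small: int = 2,
) -> ConsensusResult:
    """Merge tiny groups into the neighbour they share the fewest low links with.

    A group of ``max_small`` or fewer series carries little evidence of its
    own; for pattern labelling it is compared against every larger group by
    counting pairwise *low*-level similarities — more low links mean more
    disagreement across the battery, so the small group is merged into the
    candidate with the fewest.  Ties are flagged unresolved and the group is
    left standing.  Fine groups are retained unchanged.
    """
    idx = {sid: i for i, sid in enumerate(sp.series_ids)}
    small = [g for g in cr.fine_groups if len(g) <= max_small]
    large = [g for g in cr.fine_groups if len(g) > max_small]
    if not small or not large:
        return cr

    merged: dict[tuple[str, ...], list[str]] = {g: list(g) for g in large}
    reassignments: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    unresolved: list[tuple[str, ...]] = []
    for g in small:
        counts = []
        for cand in large:
            c = sum(
                1
                for a in g
                for b in cand
                if sp.level[idx[a], idx[b]] == LEVEL_LOW
            )
            counts.append(c)
        best = min(counts)
        if counts.count(best) > 1:
            unresolved.append(g)
            continue
        target = large[counts.index(best)]
        merged[target].extend(g)
        reassignments.append((g, target))

    pattern_groups = tuple(
        sorted(
            [tuple(sorted(members)) for members in merged.values()]
            + [g for g in unresolved],
            key=lambda grp: grp[0],
        )
    )
    return replace(
        cr,
        pattern_groups=pattern_groups,
        reassignments=tuple(reassignments),
        unresolved=tuple(unresolved),
    )
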