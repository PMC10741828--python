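"""Laterality-state discovery via three-stage temporal clustering.

Stage 1 clusters each subject's window-by-ROI laterality series with
spherical (cosine) k-means; stage 2 pools the per-subject centroids into
a cosine-similarity graph and sweeps a multi-resolution community
detection (uniform self-loops of strength r added before modularity
maximisation) to pick the most persistent community count k; stage 3
re-clusters the pooled centroids with k fixed and assigns every window
to its nearest final centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .laterality import LateralitySeries


class StateError(ValueError):
    pass


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


# ------------------------------------------------------- spherical k-means


def _normalize_rows(x: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms <= 0.0):
        bad = int(np.flatnonzero(norms <= 0.0)[0])
        raise StateError(f"zero-norm {what} at row {bad}")
    return x / norms[:, None]


def _kmeanspp_cosine(xn: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under cosine distance d = 1 - x.c."""
    n = xn.shape[0]
    centers = np.empty((k, xn.shape[1]))
    idx = int(rng.integers(n))
    centers[0] = xn[idx]
    d = np.maximum(1.0 - xn @ centers[0], 0.0)
    for j in range(1, k):
        total = d.sum()
        if total <= 0.0:
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d / total))
        centers[j] = xn[idx]
        d = np.minimum(d, np.maximum(1.0 - xn @ centers[j], 0.0))
    return centers


def spherical_kmeans(x: np.ndarray, k: int, seed, max_iter: int = 500,
                     tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray, float]:
    """Cosine-distance k-means on the rows of ``x``.

    Rows and centroids are L2-normalised; empty clusters are re-seeded
    from the point farthest from its centroid.  Returns (centroids,
    labels, inertia) with unit-norm centroids.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise StateError("input must be 2-D")
    if k < 1 or k > x.shape[0]:
        raise StateError(f"k={k} invalid for {x.shape[0]} rows")
    rng = np.random.default_rng(seed)
    xn = _normalize_rows(x, "window")
    centers = _kmeanspp_cosine(xn, k, rng)
    prev_inertia = np.inf
    labels = np.zeros(xn.shape[0], dtype=int)
    for _ in range(max_iter):
        sims = xn @ centers.T
        labels = np.argmax(sims, axis=1)
        dist = 1.0 - sims[np.arange(xn.shape[0]), labels]
        # re-seed empty clusters from the globally farthest point
        for j in range(k):
            if not np.any(labels == j):
                far = int(np.argmax(dist))
                labels[far] = j
                dist[far] = 0.0
        inertia = float(dist.sum())
        new_centers = np.empty_like(centers)
        for j in range(k):
            mean = xn[labels == j].mean(axis=0)
            norm = np.linalg.norm(mean)
            new_centers[j] = mean / norm if norm > 0 else centers[j]
        converged = (
            np.isfinite(prev_inertia)
            and prev_inertia - inertia <= tol * max(prev_inertia, 1e-12)
        )
        centers = new_centers
        if converged:
            break
        prev_inertia = inertia
    sims = xn @ centers.T
    labels = np.argmax(sims, axis=1)
    inertia = float(np.sum(1.0 - sims[np.arange(xn.shape[0]), labels]))
    return centers, labels, inertia


def subject_kmeans(ls: LateralitySeries, k1: int, seed) -> np.ndarray:
    """Stage-1 per-subject centroids (k1 x N, unit norm)."""
    if k1 > ls.n_windows:
        raise StateError(
            f"k1={k1} exceeds {ls.n_windows} windows for subject {ls.subject_id!r}"
        )
    centers, _, _ = spherical_kmeans(ls.values, k1, seed)
    return centers


def pool_centroids(per_subject: list[np.ndarray]) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Row-concatenate per-subject centroid matrices.

    Returns the pooled M x N matrix and (subject index, local row)
    provenance for every pooled row.
    """
    if not per_subject:
        raise StateError("no centroid matrices to pool")
    width = per_subject[0].shape[1]
    for i, c in enumerate(per_subject):
        if c.ndim != 2 or c.shape[1] != width:
            raise StateError(f"centroid matrix {i} has incompatible shape {c.shape}")
    provenance = [
        (si, li) for si, c in enumerate(per_subject) for li in range(c.shape[0])
    ]
    return np.vstack(per_subject), provenance


def centroid_similarity_graph(pooled: np.ndarray) -> nx.Graph:
    """Weighted graph on centroids; w_ij = max(0, cosine similarity)."""
    pooled = np.asarray(pooled, dtype=float)
    if pooled.shape[0] < 2:
        raise StateError("need at least 2 centroids")
    xn = _normalize_rows(pooled, "centroid")
    sim = np.clip(xn @ xn.T, 0.0, None)
    np.fill_diagonal(sim, 0.0)
    g = nx.Graph()
    g.add_nodes_from(range(pooled.shape[0]))
    ii, jj = np.nonzero(np.triu(sim, 1))
    g.add_weighted_edges_from(
        (int(i), int(j), float(sim[i, j])) for i, j in zip(ii, jj)
    )
    return g


# ------------------------------------------- modularity / community sweep


def modularity(weights: np.ndarray, communities: np.ndarray) -> float:
    """Newman-Girvan modularity of a weighted graph with self-loops.

    Q = (1/2m) sum_ij (W_ij - k_i k_j / 2m) delta(c_i, c_j) over ordered
    pairs including the diagonal; k_i is the row sum (self-loops counted
    once) and 2m the total of all entries.
    """
    w = np.asarray(weights, dtype=float)
    strengths = w.sum(axis=1)
    m2 = strengths.sum()
    if m2 <= 0.0:
        return 0.0
    q = 0.0
    for c in np.unique(communities):
        idx = communities == c
        q += w[np.ix_(idx, idx)].sum() / m2 - (strengths[idx].sum() / m2) ** 2
    return float(q)


def _local_move(w: np.ndarray, rng: np.random.Generator,
                order: np.ndarray, init: np.ndarray | None = None) -> np.ndarray:
    """One Louvain level: greedy node moves until no move improves Q.

    Nodes are visited in ``order``; exact score ties are broken with the
    seeded generator.  Empty community slots score 0, so a node whose
    best option is isolation becomes a singleton naturally.  ``init``
    seeds the partition (default: all singletons).
    """
    n = w.shape[0]
    strengths = w.sum(axis=1)
    m2 = strengths.sum()
    comm = np.arange(n) if init is None else init.copy()
    sigma = np.bincount(comm, weights=strengths, minlength=n)
    if m2 <= 0.0:
        return comm
    while True:
        moved = False
        for i in order:
            ci = comm[i]
            sigma[ci] -= strengths[i]
            wi = np.bincount(comm, weights=w[i], minlength=n)
            wi[ci] -= w[i, i]
            score = wi - strengths[i] * sigma / m2
            best = score.max()
            cand = np.flatnonzero(score >= best - 1e-12)
            target = int(cand[0]) if cand.size == 1 else int(rng.choice(cand))
            if score[target] <= score[ci] + 1e-15:
                target = ci
            sigma[target] += strengths[i]
            if target != ci:
                comm[i] = target
                moved = True
        if not moved:
            return comm


def _aggregate(w: np.ndarray, comm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels, dense = np.unique(comm, return_inverse=True)
    nc = labels.size
    onehot = np.zeros((w.shape[0], nc))
    onehot[np.arange(w.shape[0]), dense] = 1.0
    return onehot.T @ w @ onehot, dense


def _merge_pass(w: np.ndarray, comm: np.ndarray) -> np.ndarray:
    """Greedily merge community pairs while any merge increases Q."""
    strengths = w.sum(axis=1)
    m2 = strengths.sum()
    if m2 <= 0.0:
        return comm
    comm = np.unique(comm, return_inverse=True)[1]
    while True:
        nc = comm.max() + 1
        if nc < 2:
            return comm
        onehot = np.zeros((w.shape[0], nc))
        onehot[np.arange(w.shape[0]), comm] = 1.0
        between = onehot.T @ w @ onehot
        sig = np.bincount(comm, weights=strengths, minlength=nc)
        # delta-Q of merging (a, b): 2*w_ab/m2 - 2*sig_a*sig_b/m2^2
        gain = 2.0 * between / m2 - 2.0 * np.outer(sig, sig) / m2**2
        np.fill_diagonal(gain, -np.inf)
        a, b = np.unravel_index(np.argmax(gain), gain.shape)
        if gain[a, b] <= 1e-13:
            return comm
        comm = np.where(comm == max(a, b), min(a, b), comm)
        comm = np.unique(comm, return_inverse=True)[1]


_SWAP_REFINE_MAX_NODES = 12


def _swap_refine(w: np.ndarray, comm: np.ndarray) -> np.ndarray:
    """Exchange community labels of node pairs while any swap raises Q.

    Escapes local optima that single-node moves cannot leave; only
    applied to small graphs (cost grows steeply with node count).
    """
    n = w.shape[0]
    if n > _SWAP_REFINE_MAX_NODES:
        return comm
    comm = comm.copy()
    improved = True
    while improved:
        improved = False
        q0 = modularity(w, comm)
        for i in range(n):
            for j in range(i + 1, n):
                if comm[i] == comm[j]:
                    continue
                comm[i], comm[j] = comm[j], comm[i]
                if modularity(w, comm) > q0 + 1e-13:
                    improved = True
                    q0 = modularity(w, comm)
                else:
                    comm[i], comm[j] = comm[j], comm[i]
    return comm


def _split_refine(w: np.ndarray, comm: np.ndarray, rng: np.random.Generator,
                  order: np.ndarray) -> np.ndarray:
    """Try all 2-way splits of each community; keep any that raises Q.

    Each candidate split is polished with a local-move pass before
    scoring, so splits that only pay off after a subsequent relocation
    are still found.  Enumerative, hence limited to small graphs and
    small communities.
    """
    n = w.shape[0]
    if n > _SWAP_REFINE_MAX_NODES:
        return comm
    comm = np.unique(comm, return_inverse=True)[1]
    improved = True
    while improved:
        improved = False
        q0 = modularity(w, comm)
        for c in np.unique(comm):
            members = np.flatnonzero(comm == c)
            if members.size < 2 or members.size > 12:
                continue
            new_label = comm.max() + 1
            for bits in range(1, 1 << (members.size - 1)):
                trial = comm.copy()
                sel = [members[j] for j in range(members.size)
                       if bits >> j & 1]
                trial[sel] = new_label
                trial = _local_move(w, rng, order, init=trial)
                q = modularity(w, trial)
                if q > q0 + 1e-13:
                    comm = np.unique(trial, return_inverse=True)[1]
                    q0 = q
                    improved = True
                    break
            if improved:
                break
    return comm


def louvain_partition(weights: np.ndarray, rng: np.random.Generator,
                      order: np.ndarray | None = None,
                      init: np.ndarray | None = None) -> np.ndarray:
    """Multi-level greedy modularity maximisation; returns node labels.

    After the aggregation hierarchy converges the partition is polished
    by leaf-level single-node moves, a greedy community-merge pass, and
    (on small graphs) pairwise label swaps.
    """
    w0 = np.asarray(weights, dtype=float)
    w = w0
    n = w.shape[0]
    assign = np.arange(n)
    leaf_order = np.arange(n) if order is None else np.asarray(order)
    level_order = leaf_order
    init = init if init is None else np.asarray(init)
    while True:
        comm = _local_move(w, rng, level_order, init=init)
        init = None
        w2, dense = _aggregate(w, comm)
        if w2.shape[0] == w.shape[0]:
            break
        assign = dense[assign]
        w = w2
        level_order = np.arange(w.shape[0])
    assign = np.unique(assign, return_inverse=True)[1]
    while True:
        refined = _local_move(w0, rng, leaf_order, init=assign)
        refined = _merge_pass(w0, refined)
        refined = _swap_refine(w0, refined)
        refined = _split_refine(w0, refined, rng, leaf_order)
        refined = _local_move(w0, rng, leaf_order, init=refined)
        if modularity(w0, refined) <= modularity(w0, assign) + 1e-13:
            break
        assign = np.unique(refined, return_inverse=True)[1]
    return assign


@dataclass(frozen=True)
class AfgSweepRecord:
    """Multi-resolution sweep: per-resolution partition, count, modularity."""

    resolutions: np.ndarray
    partitions: list[np.ndarray]
    community_counts: np.ndarray
    modularities: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.resolutions, dtype=float)
        if r.size == 0:
            raise StateError("empty sweep")
        if np.any(np.diff(r) <= 0):
            raise StateError("resolutions must be strictly increasing")
        object.__setattr__(self, "resolutions", r)
        object.__setattr__(self, "community_counts",
                           np.asarray(self.community_counts, dtype=int))
        object.__setattr__(self, "modularities",
                           np.asarray(self.modularities, dtype=float))

    def persistence_table(self) -> dict[int, int]:
        """Longest run of consecutive resolutions per community count."""
        runs: dict[int, int] = {}
        current = None
        length = 0
        for c in self.community_counts:
            c = int(c)
            length = length + 1 if c == current else 1
            current = c
            runs[c] = max(runs.get(c, 0), length)
        return runs

    def to_dict(self) -> dict:
        return {
            "resolutions": self.resolutions.tolist(),
            "community_counts": self.community_counts.tolist(),
            "modularities": self.modularities.tolist(),
            "partitions": [p.tolist() for p in self.partitions],
        }


def afg_sweep(graph, r_min: float = 0.1, r_max: float = 1.5, r_step: float = 0.1,
              seed=0, n_restarts: int = 8) -> AfgSweepRecord:
    """Sweep the self-loop resolution r over a grid.

    At each r a self-loop of weight r is added to every node and weighted
    modularity of the augmented graph is maximised by the multi-level
    greedy optimiser: one deterministic ascending-order run plus
    ``n_restarts - 1`` seeded random-order restarts, keeping the best
    partition.
    """
    if isinstance(graph, nx.Graph):
        if graph.number_of_nodes() == 0:
            raise StateError("empty graph")
        adj = nx.to_numpy_array(graph, nodelist=sorted(graph.nodes()), weight="weight")
    else:
        adj = np.asarray(graph, dtype=float)
        if adj.size == 0:
            raise StateError("empty graph")
    if adj.shape[0] != adj.shape[1]:
        raise StateError("adjacency must be square")
    n = adj.shape[0]
    steps = int(round((r_max - r_min) / r_step))
    if steps < 0 or r_min <= 0:
        raise StateError("invalid resolution grid")
    resolutions = np.round(r_min + r_step * np.arange(steps + 1), 10)

    ss = _as_seedseq(seed)
    partitions, counts, mods = [], [], []
    for r in resolutions:
        w = adj + r * np.eye(n)
        best_part, best_q = None, -np.inf
        child = np.random.default_rng(ss.spawn(1)[0])
        for restart in range(max(1, n_restarts)):
            order = np.arange(n) if restart == 0 else child.permutation(n)
            # odd restarts explore from a random coarse partition instead
            # of all-singletons, reaching basins the greedy pass misses
            init = None
            if restart % 2 == 1 and n > 2:
                n_labels = int(child.integers(2, max(3, min(n, 12))))
                init = child.integers(n_labels, size=n)
            part = louvain_partition(w, child, order, init=init)
            q = modularity(w, part)
            if q > best_q + 1e-13:
                best_part, best_q = part, q
        partitions.append(best_part)
        counts.append(int(best_part.max()) + 1)
        mods.append(best_q)
    return AfgSweepRecord(
        resolutions=resolutions,
        partitions=partitions,
        community_counts=np.array(counts),
        modularities=np.array(mods),
    )


def select_persistent_k(sweep: AfgSweepRecord) -> int:
    """Community count with the longest consecutive-resolution run.

    Ties break toward the smaller count.
    """
    table = sweep.persistence_table()
    best_len = max(table.values())
    return min(k for k, run in table.items() if run == best_len)


# ------------------------------------------------------------ final model


@dataclass(frozen=True)
class StateModel:
    """Final centroids plus per-subject window-state assignments."""

    k: int
    centroids: np.ndarray
    assignments: dict[str, np.ndarray]
    occupancy: np.ndarray
    sweep: AfgSweepRecord | None = None
    column_ids: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.centroids.shape[0] != self.k:
            raise StateError("centroid count does not match k")
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.size != self.k or not np.isclose(occ.sum(), 1.0):
            raise StateError("occupancy must have k entries summing to 1")


def final_centroids(pooled: np.ndarray, k: int, seed, n_restarts: int = 20) -> np.ndarray:
    """Stage-3 spherical k-means on pooled centroids, best of seeded restarts."""
    pooled = np.asarray(pooled, dtype=float)
    if k > pooled.shape[0]:
        raise StateError(f"k={k} exceeds {pooled.shape[0]} pooled centroids")
    ss = _as_seedseq(seed)
    best = None
    best_inertia = np.inf
    for child in ss.spawn(n_restarts):
        centers, _, inertia = spherical_kmeans(pooled, k, child)
        if inertia < best_inertia - 1e-12:
            best, best_inertia = centers, inertia
    return best


def assign_windows(ls_all: list[LateralitySeries], centroids: np.ndarray,
                   sweep: AfgSweepRecord | None = None) -> StateModel:
    """Assign every window to its nearest centroid by cosine distance.

    State ids are 1-based; exact ties go to the lowest id.  Occupancy is
    the per-state fraction of all windows pooled over subjects.
    """
    c = _normalize_rows(np.asarray(centroids, dtype=float), "centroid")
    k = c.shape[0]
    assignments: dict[str, np.ndarray] = {}
    counts = np.zeros(k)
    column_ids: tuple = ()
    for ls in ls_all:
        if ls.values.shape[1] != c.shape[1]:
            raise StateError(
                f"subject {ls.subject_id!r} has {ls.values.shape[1]} columns, "
                f"centroids have {c.shape[1]}"
            )
        xn = _normalize_rows(ls.values, f"window of {ls.subject_id!r}")
        labels = np.argmax(xn @ c.T, axis=1) + 1
        assignments[ls.subject_id] = labels
        counts += np.bincount(labels - 1, minlength=k)
        column_ids = ls.column_ids
    total = counts.sum()
    if total == 0:
        raise StateError("no windows to assign")
    return StateModel(
        k=k,
        centroids=c,
        assignments=assignments,
        occupancy=counts / total,
        sweep=sweep,
        column_ids=column_ids,
    )


def fit_states(ls_all: list[LateralitySeries], k1: int = 5, seed=0,
               r_min: float = 0.1, r_max: float = 1.5, r_step: float = 0.1,
               n_restarts: int = 8) -> StateModel:
    """Run the full three-stage clustering on a cohort's laterality series.

    Stage-1 seeds derive from each subject's id, so reordering subjects
    leaves the per-subject centroids unchanged.
    """
    import zlib

    ss = _as_seedseq(seed)

    def child(key: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=ss.entropy,
                                      spawn_key=(*ss.spawn_key, key))

    per_subject = [
        subject_kmeans(ls, k1, child(zlib.crc32(ls.subject_id.encode())))
        for ls in ls_all
    ]
    pooled, _ = pool_centroids(per_subject)
    graph = centroid_similarity_graph(pooled)
    sweep = afg_sweep(graph, r_min, r_max, r_step, seed=child(0xAF6),
                      n_restarts=n_restarts)
    k = select_persistent_k(sweep)
    centroids = final_centroids(pooled, k, child(0xF17A))
    return assign_windows(ls_all, centroids, sweep)
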