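"""Per-taxon neighborhood dynamics, taxa ranking, and consensus clustering.

A taxon's *neighborhood dynamic* is the cosine distance

    d_cos(A, B) = 1 - (A . B) / (|A| |B|)        in [0, 2]

between its embedding vectors A and B in two layers of the joint
embedding space (two time points of the same multiplex).  A taxon whose
local co-occurrence neighborhood is unchanged has identical neighbor
vectors in both layers, hence identical embeddings and distance exactly
0; a rewired taxon drifts.

Because the encoder-decoder has a non-convex loss, different training
seeds give different embedding spaces.  Robust conclusions therefore come
from ensembles: :func:`ensemble_dynamics` retrains per seed and averages
the distances, and :func:`consensus_cluster` clusters the (node, layer)
points of each repeat and aggregates the partitions into a co-clustering
frequency matrix which is then cut by hierarchical clustering.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .ednn import EDNN, EDNNConfig, EmbeddingSet, TrainingSet, assemble_training_set, train_ednn
from .multiplex import MultiplexNetwork, WalkProfileSet, walk_profiles

__all__ = [
    "cosine_distance",
    "embedding_distance",
    "node_dynamics",
    "run_mnda",
    "MNDAResult",
    "ensemble_dynamics",
    "consensus_cluster",
    "ConsensusResult",
    "cluster_transitions",
    "TransitionTable",
    "extreme_dynamics",
    "build_feature_matrix",
]


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cosine similarity; ranges over [0, 2].

    Undefined for zero-norm vectors (raises); use
    :func:`embedding_distance` for the bounded convention applied to
    embeddings with dead rectifier units.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance is undefined for zero-norm vectors")
    return float(np.clip(1.0 - (a @ b) / (na * nb), 0.0, 2.0))


def embedding_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine distance with a bounded convention for zero-norm embeddings.

    Rectifier hidden units can die, leaving an all-zero embedding.  Both
    vectors zero -> 0 (nothing moved); exactly one zero -> 2 (maximal
    change).  The convention is monotone and keeps values in [0, 2].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 and nb == 0:
        return 0.0
    if na == 0 or nb == 0:
        warnings.warn("zero-norm embedding; distance set to 2 by convention")
        return 2.0
    return cosine_distance(a, b)


def node_dynamics(
    embeddings: EmbeddingSet, layer_pair: tuple | None = None
) -> pd.DataFrame:
    """Cosine distance per (owner, node) between two layers.

    Returns a DataFrame indexed by (owner, node) with a ``distance``
    column.  Both layers must be present for every (owner, node) pair.
    """
    layers = embeddings.layers
    if layer_pair is None:
        if len(layers) != 2:
            raise ValueError(f"specify layer_pair; found layers {layers}")
        layer_pair = (layers[0], layers[1])
    la, lb = layer_pair
    frame = embeddings.frame
    a = frame.xs(la, level="layer")
    b = frame.xs(lb, level="layer")
    if not a.index.equals(b.index):
        missing = a.index.symmetric_difference(b.index).tolist()
        raise ValueError(f"(owner, node) pairs missing one layer: {missing[:10]}")
    va, vb = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    dist = np.array([embedding_distance(x, y) for x, y in zip(va, vb)])
    out = pd.DataFrame({"distance": dist}, index=a.index)
    out.index.names = ["owner", "node"]
    return out


@dataclasses.dataclass
class MNDAResult:
    """Everything one end-to-end run produces."""

    model: EDNN
    embeddings: EmbeddingSet
    dynamics: pd.DataFrame  # (owner, node) -> distance
    profiles: dict  # owner -> WalkProfileSet
    training_set: TrainingSet


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def compute_profiles(
    multiplexes: Sequence[MultiplexNetwork],
    walk_length: int = 5,
    n_walks: int = 100,
    walk_mode: str = "monte_carlo",
    weighted: bool = True,
    seed: int = 0,
) -> dict:
    """Walk profiles for each multiplex, with per-multiplex derived seeds."""
    out = {}
    for i, mpx in enumerate(multiplexes):
        out[mpx.owner] = walk_profiles(
            mpx,
            walk_length=walk_length,
            n_repeats=n_walks,
            seed=_derived_seed(seed, i),
            mode=walk_mode,
            weighted=weighted,
        )
    return out


def run_mnda(
    multiplexes: Sequence[MultiplexNetwork],
    layer_pair: tuple | None = None,
    walk_length: int = 5,
    n_walks: int = 100,
    walk_mode: str = "monte_carlo",
    weighted: bool = True,
    config: EDNNConfig | None = None,
    seed: int = 0,
    profiles: Mapping[str, WalkProfileSet] | None = None,
) -> MNDAResult:
    """Full pipeline on prepared multiplexes: profiles -> EDNN -> distances.

    One EDNN is trained jointly on all multiplexes so that every
    embedding lives in the same space.  ``seed`` drives both the walk
    simulation and the network initialization/shuffling (pass
    ``profiles`` to reuse previously computed walks).
    """
    multiplexes = list(multiplexes)
    if profiles is None:
        profiles = compute_profiles(
            multiplexes, walk_length, n_walks, walk_mode, weighted, seed
        )
    rows = assemble_training_set(multiplexes, profiles, weighted=weighted)
    cfg = config or EDNNConfig()
    cfg = dataclasses.replace(cfg, seed=_derived_seed(seed, 10_007))
    model, embeddings = train_ednn(rows, cfg)
    dyn = node_dynamics(embeddings, layer_pair)
    return MNDAResult(model, embeddings, dyn, dict(profiles), rows)


def ensemble_dynamics(
    multiplexes: Sequence[MultiplexNetwork],
    profiles: Mapping[str, WalkProfileSet] | None = None,
    config: EDNNConfig | None = None,
    n_repeats: int = 50,
    seeds: Sequence[int] | None = None,
    layer_pair: tuple | None = None,
    weighted: bool = True,
    walk_length: int = 5,
    n_walks: int = 100,
    walk_mode: str = "monte_carlo",
    base_seed: int = 0,
) -> tuple[pd.DataFrame, list[EmbeddingSet]]:
    """Retrain the EDNN per seed; per-repeat distances plus their mean.

    Walk profiles are computed once and shared across repeats (the
    ensemble targets the non-convexity of the EDNN loss, not the
    Monte-Carlo walk error).  Returns a DataFrame with one ``rep_i``
    column per repeat and a ``mean`` column, and the per-repeat
    embedding sets for consensus clustering.
    """
    if seeds is not None:
        seeds = [int(s) for s in seeds]
        n_repeats = len(seeds)
    if n_repeats < 2:
        raise ValueError("an ensemble needs n_repeats >= 2")
    if seeds is None:
        seeds = [_derived_seed(base_seed, r) for r in range(n_repeats)]
    multiplexes = list(multiplexes)
    if profiles is None:
        profiles = compute_profiles(
            multiplexes, walk_length, n_walks, walk_mode, weighted, base_seed
        )
    rows = assemble_training_set(multiplexes, profiles, weighted=weighted)
    base_cfg = config or EDNNConfig()
    columns = {}
    embeddings_per_repeat = []
    index = None
    for r, s in enumerate(seeds):
        cfg = dataclasses.replace(base_cfg, seed=s)
        _, emb = train_ednn(rows, cfg)
        dyn = node_dynamics(emb, layer_pair)
        columns[f"rep_{r}"] = dyn["distance"]
        embeddings_per_repeat.append(emb)
        index = dyn.index
    out = pd.DataFrame(columns, index=index)
    out["mean"] = out.mean(axis=1)
    return out, embeddings_per_repeat


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ConsensusResult:
    """Co-clustering frequencies and the final consensus partition."""

    matrix: pd.DataFrame  # items x items, symmetric, diagonal 1
    labels: pd.Series  # item -> cluster id
    k: int
    n_repeats: int

    def pair_similarity(self, item_a, item_b) -> float:
        return float(self.matrix.loc[item_a, item_b])


def _best_kmeans(x: np.ndarray, k_range: Sequence[int], seed: int) -> np.ndarray:
    best_labels, best_score = None, -np.inf
    for k in k_range:
        if k < 2 or k >= x.shape[0]:
            continue
        km = KMeans(n_clusters=k, n_init=5, random_state=seed)
        labels = km.fit_predict(x)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(x, labels)
        if score > best_score:
            best_score, best_labels = score, labels
    if best_labels is None:  # degenerate geometry: single cluster
        best_labels = np.zeros(x.shape[0], dtype=int)
    return best_labels


def consensus_cluster(
    per_repeat,
    k_range: Sequence[int] = (2, 3, 4, 5, 6),
    n_repeats: int | None = None,
    subsample: float | None = None,
    seed: int = 0,
) -> ConsensusResult:
    """Ensemble consensus clustering of items in an embedding space.

    Two usage modes:

    * ``per_repeat`` is a *list* of aligned (items x dims) DataFrames,
      one per ensemble repeat (e.g. per retrained EDNN): each repeat is
      partitioned with k-means (k chosen by silhouette over ``k_range``)
      and the consensus entry is the fraction of repeats in which two
      items co-cluster.
    * ``per_repeat`` is a *single* DataFrame: ``n_repeats`` resampled
      partitions are generated per candidate k by k-means on random item
      subsamples (fraction ``subsample``, default 0.8), co-clustering
      frequencies are normalized by how often a pair was co-sampled, and
      k is chosen by the proportion of ambiguous co-clustering (PAC:
      consensus entries strictly between 0.1 and 0.9): the smallest k
      whose PAC is within 0.02 of the minimum (parsimony margin).

    The final partition cuts the consensus dissimilarity (1 - frequency)
    with average-linkage hierarchical clustering.
    """
    rng = np.random.default_rng(seed)
    if isinstance(per_repeat, pd.DataFrame):
        if n_repeats is None or n_repeats < 2:
            raise ValueError("resampling mode requires n_repeats >= 2")
        frac = 0.8 if subsample is None else subsample
        items = per_repeat.index
        x = per_repeat.to_numpy(dtype=float)
        n = len(items)
        candidates = []
        for k in k_range:
            if k < 2 or k >= n:
                continue
            co = np.zeros((n, n))
            cnt = np.zeros((n, n))
            for r in range(n_repeats):
                size = max(4, int(round(frac * n)))
                chosen = rng.choice(n, size=min(size, n), replace=False)
                km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31)))
                labels = km.fit_predict(x[chosen])
                same = labels[:, None] == labels[None, :]
                cnt[np.ix_(chosen, chosen)] += 1
                co[np.ix_(chosen, chosen)] += same
            with np.errstate(invalid="ignore"):
                mk = np.where(cnt > 0, co / np.maximum(cnt, 1), 0.0)
            np.fill_diagonal(mk, 1.0)
            iu = np.triu_indices(n, k=1)
            pac = float(np.mean((mk[iu] > 0.1) & (mk[iu] < 0.9)))
            candidates.append((k, pac, mk))
        if not candidates:
            raise ValueError("no feasible k in k_range")
        min_pac = min(pac for _, pac, _ in candidates)
        best_k_pac, _, consensus = next(
            (k, pac, mk) for k, pac, mk in candidates if pac <= min_pac + 0.02
        )
        consensus = (consensus + consensus.T) / 2.0
        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        link = hierarchy.linkage(squareform(dist, checks=False), method="average")
        labels = hierarchy.fcluster(link, t=best_k_pac, criterion="maxclust") - 1
        if len(np.unique(labels)) < 2:
            warnings.warn("degenerate consensus: a single cluster fits best")
        return ConsensusResult(
            matrix=pd.DataFrame(consensus, index=items, columns=items),
            labels=pd.Series(labels, index=items, name="cluster"),
            k=len(np.unique(labels)),
            n_repeats=n_repeats,
        )
    else:
        repeats = list(per_repeat)
        if len(repeats) < 2:
            raise ValueError("need at least two repeats for a consensus")
        items = repeats[0].index
        n = len(items)
        co = np.zeros((n, n))
        for r, frame in enumerate(repeats):
            if not frame.index.equals(items):
                raise ValueError("per-repeat frames must share one item index")
            labels = _best_kmeans(
                frame.to_numpy(dtype=float), k_range, int(rng.integers(2**31))
            )
            co += labels[:, None] == labels[None, :]
        consensus = co / len(repeats)
        total = len(repeats)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    best_labels, best_score, best_k = np.zeros(n, dtype=int), -np.inf, 1
    for k in k_range:
        if k < 2 or k >= n:
            continue
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust") - 1
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(dist, labels, metric="precomputed")
        if score > best_score:
            best_score, best_labels, best_k = score, labels, k
    if best_k == 1:
        warnings.warn("degenerate consensus: a single cluster fits best")
    matrix = pd.DataFrame(consensus, index=items, columns=items)
    labels = pd.Series(best_labels, index=items, name="cluster")
    return ConsensusResult(matrix=matrix, labels=labels, k=best_k, n_repeats=total)


@dataclasses.dataclass
class TransitionTable:
    """Cluster membership flow between two layers."""

    counts: pd.DataFrame  # layer-1 clusters x layer-2 clusters
    probabilities: pd.DataFrame  # rows sum to 1


def cluster_transitions(labels: pd.Series, layer_pair: tuple | None = None) -> TransitionTable:
    """P(cluster j at layer 2 | cluster i at layer 1) from per-layer labels.

    ``labels`` is indexed by (node, layer).  Every node must carry a
    label in both layers.
    """
    if labels.index.nlevels != 2:
        raise ValueError("labels must be indexed by (node, layer)")
    layers = labels.index.get_level_values(1).unique().tolist()
    if layer_pair is None:
        if len(layers) != 2:
            raise ValueError(f"specify layer_pair; found layers {layers}")
        layer_pair = (layers[0], layers[1])
    la, lb = layer_pair
    a = labels.xs(la, level=1)
    b = labels.xs(lb, level=1)
    if not a.index.sort_values().equals(b.index.sort_values()):
        missing = a.index.symmetric_difference(b.index).tolist()
        raise ValueError(f"nodes missing a layer label: {missing}")
    b = b.loc[a.index]
    counts = pd.crosstab(a, b)
    counts.index.name = f"cluster@{la}"
    counts.columns.name = f"cluster@{lb}"
    probs = counts.div(counts.sum(axis=1), axis=0)
    return TransitionTable(counts=counts, probabilities=probs)


def extreme_dynamics(scores: pd.Series, q: float = 0.25) -> dict[str, list]:
    """Flag nodes beyond the first large jump at either extreme.

    ``scores`` is any per-node dynamics score (mean cosine distance, or
    1 - co-clustering similarity).  Within the top and bottom ``q``
    fractions of the sorted scores, the largest consecutive gap is
    located; nodes beyond it are flagged ``high_ids`` (large values) or
    ``low_ids`` (small values).  Ties in the gap break toward smaller
    flagged sets, and a zero gap flags nothing.
    """
    if not 0 < q <= 0.5:
        raise ValueError("q must be in (0, 0.5]")
    n = len(scores)
    if n < 4:
        raise ValueError("need at least 4 nodes")
    s = scores.sort_values(kind="mergesort")
    vals = s.to_numpy(dtype=float)
    c = int(np.floor(q * n))
    high_ids: list = []
    low_ids: list = []
    if c >= 1:
        gaps = np.diff(vals)
        tol = 1e-12 * max(1.0, float(np.abs(vals).max()))
        # high end: gaps between positions [n-c-1, n-2]; ties (within float
        # tolerance) break toward the extreme, i.e. the smallest flagged set
        cand = gaps[n - c - 1 : n - 1]
        if cand.size and cand.max() > tol:
            tied = np.flatnonzero(cand >= cand.max() - tol)
            i = n - c - 1 + int(tied[-1])
            high_ids = s.index[i + 1 :].tolist()
        cand = gaps[:c]
        if cand.size and cand.max() > tol:
            tied = np.flatnonzero(cand >= cand.max() - tol)
            i = int(tied[0])
            low_ids = s.index[: i + 1].tolist()
    return {"high_ids": high_ids, "low_ids": low_ids}


# ---------------------------------------------------------------------------
# feature matrices for downstream modelling
# ---------------------------------------------------------------------------


def build_feature_matrix(
    mode: str,
    abundance=None,
    isns: Mapping | None = None,
    dynamics: pd.DataFrame | None = None,
    individuals: Sequence | None = None,
) -> pd.DataFrame:
    """Individuals x features design matrix in one of three views.

    * ``node``: abundances (typically CLR) of every taxon at every layer
      — columns ``taxon@layer`` (2K columns for two time points).
      ``abundance`` is an :class:`~mnda.io.AbundanceTable` with metadata.
    * ``edge``: ISN edge weights of every layer — columns
      ``a--b@layer``, undirected edges enumerated once in lexicographic
      (min, max) order, restricted to pairs with any nonzero weight in
      that layer.  ``isns`` maps layer label to an ISNSet.
    * ``dynamic``: one cosine distance per taxon — columns
      ``taxon.dyn`` (K columns regardless of the number of layers).
      ``dynamics`` is a wide individuals x taxa DataFrame.
    """
    if mode == "node":
        if abundance is None or abundance.metadata is None:
            raise ValueError("node mode needs an abundance table with metadata")
        meta = abundance.metadata
        blocks = []
        for layer in abundance.time_points():
            sub = meta[meta["time_point"] == layer]
            block = abundance.counts.loc[sub.index]
            block.index = sub["individual_id"].values
            block.columns = [f"{t}@{layer}" for t in abundance.taxon_ids]
            blocks.append(block)
        out = pd.concat(blocks, axis=1, join="inner")
        if out.isna().any().any() or len(out) == 0:
            raise ValueError("some individuals lack samples at a time point")
    elif mode == "edge":
        if not isns:
            raise ValueError("edge mode needs per-layer ISN sets")
        blocks = []
        common = None
        for layer, isnset in isns.items():
            ids = isnset.individual_ids
            common = ids if common is None else [i for i in common if i in ids]
        for layer, isnset in isns.items():
            nodes = isnset.node_ids
            order = np.argsort(np.asarray(nodes, dtype=object))
            pairs = []
            for ai in range(len(nodes)):
                for bi in range(ai + 1, len(nodes)):
                    i, j = order[ai], order[bi]
                    if any(isnset.networks[:, i, j] != 0):
                        pairs.append((i, j))
            cols = [f"{nodes[i]}--{nodes[j]}@{layer}" for i, j in pairs]
            rows = [isnset.network(ind)[tuple(zip(*pairs))] for ind in common]
            blocks.append(pd.DataFrame(rows, index=common, columns=cols))
        out = pd.concat(blocks, axis=1)
    elif mode == "dynamic":
        if dynamics is None:
            raise ValueError("dynamic mode needs an individuals x taxa dynamics frame")
        out = dynamics.copy()
        out.columns = [f"{t}.dyn" for t in out.columns]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if individuals is not None:
        missing = [i for i in individuals if i not in out.index]
        if missing:
            raise ValueError(f"individuals missing from the {mode} view: {missing}")
        out = out.loc[list(individuals)]
    return out
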