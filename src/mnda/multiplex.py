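"""Multiplex networks and random-walk neighborhood profiles.

A multiplex network stacks several symmetric, non-negative adjacency
matrices ("layers" — here typically one per time point) over a single
shared node set.  For every node of every layer two vectors are derived:

* the **neighbor vector** — the node's direct (graph distance 1)
  neighborhood, either binary or weighted, with no self-loop entry; and
* the **walk-reach profile** — for a fixed-length random walk started at
  the node, the probability that each other node is visited at least once
  within ``walk_length`` steps (the start node itself is excluded).

The pair (neighbor vector, reach profile) is the training example the
encoder-decoder consumes: the encoder sees only the immediate
neighborhood and must predict the wider reach profile, which forces the
hidden layer to encode local topology.

Transition probabilities are weight-proportional: from u the walk moves
to v with probability ``w_uv / sum_x w_ux``.  A walk that lands on a
zero-degree node terminates early; its visits still count.  Profiles can
be estimated by repeated simulated walks (``monte_carlo``, the default)
or computed exactly (``exact``) via one absorbing Markov chain per target
node: making target j absorbing, the probability mass on j after
``walk_length`` steps equals the probability that j was visited within
that many steps.  The exact mode is the oracle the Monte-Carlo path is
tested against.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GlobalNetwork
from .isn import ISNSet

__all__ = [
    "MultiplexNetwork",
    "WalkProfileSet",
    "build_multiplex",
    "multiplex_from_isnsets",
    "neighbor_vector",
    "walk_profile",
    "walk_profiles",
]


@dataclasses.dataclass
class MultiplexNetwork:
    """Ordered layers of symmetric non-negative adjacency over shared nodes."""

    node_ids: list
    layers: list  # list of K x K ndarrays
    layer_labels: list
    owner: str = "global"

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.layers = [np.asarray(m, dtype=float) for m in self.layers]
        self.layer_labels = list(self.layer_labels)
        k = len(self.node_ids)
        if len(self.layers) != len(self.layer_labels):
            raise ValueError("one label per layer required")
        if len(set(self.layer_labels)) != len(self.layer_labels):
            raise ValueError("layer labels must be unique")
        for label, m in zip(self.layer_labels, self.layers):
            if m.shape != (k, k):
                raise ValueError(f"layer {label!r} has shape {m.shape}, expected ({k},{k})")
            if not np.allclose(m, m.T, rtol=1e-8, atol=1e-12):
                raise ValueError(f"layer {label!r} is not symmetric")
            if (m < 0).any():
                raise ValueError(
                    f"layer {label!r} has negative weights; apply the absolute-value "
                    "transform before stacking"
                )
            if np.abs(np.diag(m)).max(initial=0.0) > 1e-12:
                raise ValueError(f"layer {label!r} has nonzero diagonal entries")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer(self, label) -> np.ndarray:
        return self.layers[self.layer_index(label)]

    def layer_index(self, label) -> int:
        if isinstance(label, (int, np.integer)) and label not in self.layer_labels:
            return int(label)
        return self.layer_labels.index(label)

    def node_index(self, node) -> int:
        try:
            return self.node_ids.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None


def build_multiplex(networks_by_layer: Mapping, owner: str = "global") -> MultiplexNetwork:
    """Stack matched networks into a multiplex, aligning nodes by ID.

    ``networks_by_layer`` maps layer label to a :class:`GlobalNetwork` or
    a labelled DataFrame.  All layers must share the same node set (an
    error lists the symmetric difference otherwise); node *order* may
    differ and is aligned to the first layer.
    """
    if len(networks_by_layer) < 2:
        raise ValueError("a multiplex needs at least two layers")
    labels = list(networks_by_layer)
    frames = []
    for label in labels:
        net = networks_by_layer[label]
        frame = net.to_frame() if isinstance(net, GlobalNetwork) else pd.DataFrame(net)
        frames.append(frame)
    node_ids = list(frames[0].index)
    for label, frame in zip(labels[1:], frames[1:]):
        if set(frame.index) != set(node_ids):
            diff = sorted(set(frame.index) ^ set(node_ids))
            raise ValueError(
                f"layer {label!r} node set differs; symmetric difference: {diff}"
            )
    layers = [f.loc[node_ids, node_ids].to_numpy(dtype=float) for f in frames]
    return MultiplexNetwork(node_ids, layers, labels, owner=owner)


def multiplex_from_isnsets(
    isnsets: Mapping, individual
) -> MultiplexNetwork:
    """One individual's multiplex from per-layer :class:`~mnda.isn.ISNSet` objects."""
    nets = {}
    for label, isns in isnsets.items():
        if not isns.abs_applied:
            raise ValueError(
                f"ISNs for layer {label!r} carry signed weights; apply "
                "absolute_weights before stacking"
            )
        nets[label] = isns.to_frame(individual)
    return build_multiplex(nets, owner=str(individual))


# ---------------------------------------------------------------------------
# per-node vectors
# ---------------------------------------------------------------------------


def neighbor_vector(
    mpx: MultiplexNetwork, layer, node, weighted: bool = True
) -> np.ndarray:
    """Direct-neighbor vector of length K; the self entry is always 0."""
    row = mpx.layer(layer)[mpx.node_index(node)].copy()
    if not weighted:
        row = (row > 0).astype(float)
    return row


def _transitions(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized transition matrix and the zero-degree (dead) mask."""
    deg = w.sum(axis=1)
    dead = deg == 0
    p = np.zeros_like(w)
    nz = ~dead
    p[nz] = w[nz] / deg[nz, None]
    return p, dead


def _reach_exact(w: np.ndarray, start: int, walk_length: int) -> np.ndarray:
    k = w.shape[0]
    p, dead = _transitions(w)
    p = p.copy()
    # early-terminating walks: dead nodes absorb in place
    for i in np.flatnonzero(dead):
        p[i] = 0.0
        p[i, i] = 1.0
    reach = np.zeros(k)
    for j in range(k):
        if j == start:
            continue
        pj = p.copy()
        pj[j] = 0.0
        pj[j, j] = 1.0  # absorb at the target: mass on j == "visited by now"
        v = np.zeros(k)
        v[start] = 1.0
        for _ in range(walk_length):
            v = v @ pj
        reach[j] = v[j]
    return reach


def _reach_monte_carlo(
    w: np.ndarray, start: int, walk_length: int, n_repeats: int, rng: np.random.Generator
) -> np.ndarray:
    k = w.shape[0]
    p, dead = _transitions(w)
    cum = np.cumsum(p, axis=1)
    pos = np.full(n_repeats, start)
    visited = np.zeros((n_repeats, k), dtype=bool)
    alive = ~dead[pos]
    for _ in range(walk_length):
        if not alive.any():
            break
        u = rng.random(alive.sum())
        rows = cum[pos[alive]]
        nxt = (u[:, None] > rows).sum(axis=1)
        visited[np.flatnonzero(alive), nxt] = True
        pos[alive] = nxt
        alive[alive] = ~dead[nxt]
    reach = visited.mean(axis=0)
    reach[start] = 0.0
    return reach


def walk_profile(
    mpx: MultiplexNetwork,
    layer,
    node,
    walk_length: int = 5,
    n_repeats: int = 100,
    seed: int | None = 0,
    mode: str = "monte_carlo",
    weighted: bool = True,
) -> np.ndarray:
    """Reach probabilities of a fixed-length random walk started at ``node``.

    Entry j is the probability (``exact``) or the fraction of simulated
    walks (``monte_carlo``) in which node j is visited at least once
    within ``walk_length`` steps.  Binary mode (``weighted=False``) walks
    uniformly over neighbors.  A zero-degree start returns an all-zero
    vector with a warning.
    """
    if walk_length < 1:
        raise ValueError("walk_length must be >= 1")
    w = mpx.layer(layer)
    if not weighted:
        w = (w > 0).astype(float)
    start = mpx.node_index(node)
    if w[start].sum() == 0:
        warnings.warn(f"node {node!r} has zero degree in layer {layer!r}; zero profile")
        return np.zeros(mpx.n_nodes)
    if mode == "exact":
        return _reach_exact(w, start, walk_length)
    if mode == "monte_carlo":
        if n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        rng = np.random.default_rng(seed)
        return _reach_monte_carlo(w, start, walk_length, n_repeats, rng)
    raise ValueError(f"unknown mode {mode!r}")


@dataclasses.dataclass
class WalkProfileSet:
    """Reach profiles for every (layer, node) of one multiplex.

    ``profiles`` maps layer label to a K x K array whose row i is the
    reach profile of start node i.  Entries lie in [0, 1].
    """

    owner: str
    node_ids: list
    profiles: dict
    walk_length: int
    n_repeats: int
    mode: str
    weighted: bool

    def profile(self, layer, node) -> np.ndarray:
        return self.profiles[layer][self.node_ids.index(node)]


def walk_profiles(
    mpx: MultiplexNetwork,
    walk_length: int = 5,
    n_repeats: int = 100,
    seed: int = 0,
    mode: str = "monte_carlo",
    weighted: bool = True,
) -> WalkProfileSet:
    """Profiles for all nodes of all layers of one multiplex.

    Each (layer, node) pair gets its own deterministic random stream
    derived from ``seed``, so results do not depend on evaluation order.
    """
    profiles = {}
    for li, label in enumerate(mpx.layer_labels):
        w = mpx.layers[li]
        if not weighted:
            w = (w > 0).astype(float)
        k = mpx.n_nodes
        mat = np.zeros((k, k))
        p_dead = w.sum(axis=1) == 0
        if p_dead.any():
            warnings.warn(
                f"{int(p_dead.sum())} zero-degree node(s) in layer {label!r}; "
                "their profiles are zero"
            )
        for ni in range(k):
            if p_dead[ni]:
                continue
            if mode == "exact":
                mat[ni] = _reach_exact(w, ni, walk_length)
            else:
                rng = np.random.default_rng(np.random.SeedSequence([int(seed), li, ni]))
                mat[ni] = _reach_monte_carlo(w, ni, walk_length, n_repeats, rng)
        profiles[label] = mat
    return WalkProfileSet(
        owner=mpx.owner,
        node_ids=mpx.node_ids,
        profiles=profiles,
        walk_length=walk_length,
        n_repeats=n_repeats,
        mode=mode,
        weighted=weighted,
    )
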