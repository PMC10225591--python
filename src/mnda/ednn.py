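"""Shallow encoder-decoder network mapping neighborhoods to walk profiles.

The embedding at the heart of the framework is the hidden layer of a
single-hidden-layer network trained to predict each node's random-walk
reach profile from its direct-neighbor vector:

    input  x  (length K, neighbor vector, no self entry)
    hidden h = relu(x W1 + b1)          (hidden_dim units, default 10)
    output y = sigmoid(h W2 + b2)       (length K, reach probabilities)

trained by mean squared error.  All nodes of all layers of all supplied
multiplexes are pooled into one training set, so every embedding lives in
a single joint space and cosine distances are comparable across layers
and individuals.  Because the encoder parameters are shared across nodes,
it can embed a node never seen in training from its neighbor vector alone
(:func:`embed_node`).

The network is implemented directly on numpy with Adam updates: it is a
deliberately tiny model (K -> 10 -> K) for which single-threaded CPU
training takes seconds, and a plain implementation keeps runs
bit-reproducible for a given seed.  Training is stochastic only through
the seeded weight initialization and minibatch shuffling; reruns with a
different seed give different embeddings, which is what motivates the
ensemble averaging in :mod:`mnda.dynamics`.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .multiplex import MultiplexNetwork, WalkProfileSet, neighbor_vector

__all__ = [
    "EDNNConfig",
    "EDNN",
    "TrainingSet",
    "EmbeddingSet",
    "assemble_training_set",
    "train_ednn",
    "embed_node",
    "hidden_dim_sweep",
    "write_embeddings",
    "read_embeddings",
]


@dataclasses.dataclass
class EDNNConfig:
    """Hyperparameters of the encoder-decoder.

    Defaults: 10 hidden rectifier units (the dimension picked by the
    least-MSE sweep over {2, 5, 10, 15, 20}), logistic outputs, MSE
    loss, Adam with learning rate 3e-3, batch size 32, 2000 epochs.
    The long default schedule trains small problems to near-
    interpolation, which node-level change detection needs: an underfit
    encoder collapses toward degree-like features and blurs which
    specific neighborhoods changed.  Cohort-scale analyses that compare
    individuals rather than single nodes work well (and much faster) in
    a compressed regime around 100 epochs; see the methods note.
    """

    hidden_dim: int = 10
    epochs: int = 2000
    batch_size: int = 32
    learning_rate: float = 3e-3
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.hidden_dim < 2:
            raise ValueError("hidden_dim must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclasses.dataclass
class TrainingSet:
    """Paired (neighbor vector, reach profile) rows for the EDNN."""

    X: np.ndarray
    Y: np.ndarray
    index: list  # (owner, layer, node) per row
    node_ids: list


def assemble_training_set(
    multiplexes: Sequence[MultiplexNetwork],
    profiles: Mapping[str, WalkProfileSet],
    weighted: bool = True,
) -> TrainingSet:
    """One row per (multiplex, layer, node): input neighbors, target reach.

    ``profiles`` maps each multiplex owner to its
    :class:`~mnda.multiplex.WalkProfileSet`; a missing profile raises.
    """
    multiplexes = list(multiplexes)
    if not multiplexes:
        raise ValueError("no multiplexes supplied")
    node_ids = multiplexes[0].node_ids
    xs, ys, index = [], [], []
    for mpx in multiplexes:
        if mpx.node_ids != node_ids:
            raise ValueError("all multiplexes must share one node set and order")
        try:
            pset = profiles[mpx.owner]
        except KeyError:
            raise KeyError(f"no walk profiles for multiplex owner {mpx.owner!r}") from None
        for label in mpx.layer_labels:
            if label not in pset.profiles:
                raise KeyError(
                    f"walk profiles for owner {mpx.owner!r} lack layer {label!r}"
                )
            target = pset.profiles[label]
            layer_w = mpx.layer(label)
            inputs = layer_w if weighted else (layer_w > 0).astype(float)
            for ni, node in enumerate(node_ids):
                xs.append(inputs[ni])
                ys.append(target[ni])
                index.append((mpx.owner, label, node))
    return TrainingSet(np.array(xs), np.array(ys), index, list(node_ids))


class EDNN:
    """K -> hidden_dim -> K encoder-decoder with ReLU / logistic units."""

    def __init__(self, n_inputs: int, config: EDNNConfig):
        self.config = config
        self.n_inputs = n_inputs
        rng = np.random.default_rng(config.seed)
        # Glorot-uniform initialization
        lim1 = np.sqrt(6.0 / (n_inputs + config.hidden_dim))
        lim2 = np.sqrt(6.0 / (config.hidden_dim + n_inputs))
        self.W1 = rng.uniform(-lim1, lim1, (n_inputs, config.hidden_dim))
        self.b1 = np.zeros(config.hidden_dim)
        self.W2 = rng.uniform(-lim2, lim2, (config.hidden_dim, n_inputs))
        self.b2 = np.zeros(n_inputs)
        self._rng = rng
        self.loss_history: list[float] = []

    # -- forward -----------------------------------------------------------

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Hidden-layer activations (the embedding); accepts 1-D or 2-D input."""
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.n_inputs:
            raise ValueError(
                f"input length {x.shape[-1]} does not match {self.n_inputs} nodes"
            )
        return np.maximum(x @ self.W1 + self.b1, 0.0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        h = self.encode(x)
        z = h @ self.W2 + self.b2
        return 1.0 / (1.0 + np.exp(-z))

    def mse(self, x: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean((self.predict(x) - y) ** 2))

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "EDNN":
        cfg = self.config
        if cfg.hidden_dim >= self.n_inputs:
            warnings.warn(
                "hidden_dim >= number of nodes: the embedding does not compress"
            )
        n = X.shape[0]
        params = [self.W1, self.b1, self.W2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        self.loss_history = [self.mse(X, Y)]
        order = np.arange(n)
        for _ in range(cfg.epochs):
            if cfg.shuffle:
                self._rng.shuffle(order)
            for start in range(0, n, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                xb, yb = X[batch], Y[batch]
                h_pre = xb @ self.W1 + self.b1
                h = np.maximum(h_pre, 0.0)
                z = h @ self.W2 + self.b2
                out = 1.0 / (1.0 + np.exp(-z))
                # MSE gradient through the logistic output
                d_out = 2.0 * (out - yb) / out.size
                d_z = d_out * out * (1.0 - out)
                g_W2 = h.T @ d_z
                g_b2 = d_z.sum(axis=0)
                d_h = d_z @ self.W2.T
                d_pre = d_h * (h_pre > 0)
                g_W1 = xb.T @ d_pre
                g_b1 = d_pre.sum(axis=0)
                grads = [g_W1, g_b1, g_W2, g_b2]
                t += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi += (1 - beta1) * (g - mi)
                    vi += (1 - beta2) * (g * g - vi)
                    mhat = mi / (1 - beta1**t)
                    vhat = vi / (1 - beta2**t)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            loss = self.mse(X, Y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (loss={loss}) after {t} updates; "
                    f"config={dataclasses.asdict(cfg)}"
                )
            self.loss_history.append(loss)
        return self

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "n_inputs": self.n_inputs,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "loss_history": self.loss_history,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "EDNN":
        payload = json.loads(Path(path).read_text())
        model = cls(payload["n_inputs"], EDNNConfig(**payload["config"]))
        model.W1 = np.array(payload["W1"])
        model.b1 = np.array(payload["b1"])
        model.W2 = np.array(payload["W2"])
        model.b2 = np.array(payload["b2"])
        model.loss_history = payload["loss_history"]
        return model


@dataclasses.dataclass
class EmbeddingSet:
    """Hidden-layer vectors for every (owner, layer, node), one joint space.

    ``frame`` is indexed by a (owner, layer, node) MultiIndex with one
    column per embedding dimension.
    """

    frame: pd.DataFrame
    config: EDNNConfig
    final_loss: float

    def vector(self, owner, layer, node) -> np.ndarray:
        return self.frame.loc[(owner, layer, node)].to_numpy(dtype=float)

    def layer_matrix(self, owner, layer) -> pd.DataFrame:
        return self.frame.xs((owner, layer), level=("owner", "layer"))

    @property
    def owners(self) -> list:
        return self.frame.index.get_level_values("owner").unique().tolist()

    @property
    def layers(self) -> list:
        return self.frame.index.get_level_values("layer").unique().tolist()


def train_ednn(rows: TrainingSet, config: EDNNConfig | None = None) -> tuple[EDNN, EmbeddingSet]:
    """Train the encoder-decoder and return it with the training embeddings."""
    if config is None:
        config = EDNNConfig()
    if rows.X.shape[0] == 0:
        raise ValueError("empty training set")
    model = EDNN(rows.X.shape[1], config).fit(rows.X, rows.Y)
    hidden = model.encode(rows.X)
    index = pd.MultiIndex.from_tuples(rows.index, names=["owner", "layer", "node"])
    frame = pd.DataFrame(
        hidden, index=index, columns=[f"e{i}" for i in range(config.hidden_dim)]
    )
    return model, EmbeddingSet(frame=frame, config=config, final_loss=model.final_loss)


def embed_node(model: EDNN, neighbor_vec: np.ndarray) -> np.ndarray:
    """Embed a (possibly unseen) node from its neighbor vector."""
    return model.encode(np.asarray(neighbor_vec, dtype=float))


def hidden_dim_sweep(
    rows: TrainingSet,
    dims: Sequence[int] = (2, 5, 10, 15, 20),
    config: EDNNConfig | None = None,
    validation_fraction: float = 0.1,
) -> pd.DataFrame:
    """Final MSE per hidden dimension (train and held-out validation).

    Utility for choosing the embedding dimension by least reconstruction
    error; splits off ``validation_fraction`` of the rows for an honest
    comparison.
    """
    base = dataclasses.asdict(config) if config else dataclasses.asdict(EDNNConfig())
    rng = np.random.default_rng(base["seed"])
    n = rows.X.shape[0]
    perm = rng.permutation(n)
    n_val = int(round(validation_fraction * n))
    val, train = perm[:n_val], perm[n_val:]
    records = []
    for dim in dims:
        cfg = EDNNConfig(**{**base, "hidden_dim": dim})
        model = EDNN(rows.X.shape[1], cfg).fit(rows.X[train], rows.Y[train])
        rec = {"hidden_dim": dim, "train_mse": model.final_loss}
        if n_val:
            rec["val_mse"] = model.mse(rows.X[val], rows.Y[val])
        records.append(rec)
    return pd.DataFrame(records).set_index("hidden_dim")


def write_embeddings(embeddings: EmbeddingSet, path) -> None:
    """TSV export: owner, layer, node, then one column per dimension."""
    embeddings.frame.reset_index().to_csv(path, sep="\t", index=False)


def read_embeddings(path, config: EDNNConfig | None = None) -> EmbeddingSet:
    df = pd.read_csv(path, sep="\t")
    frame = df.set_index(["owner", "layer", "node"])
    dim = frame.shape[1]
    cfg = config or EDNNConfig(hidden_dim=max(dim, 2))
    return EmbeddingSet(frame=frame, config=cfg, final_loss=float("nan"))
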