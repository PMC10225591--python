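"""Synthetic benchmarks and cohorts for validating dynamics detection.

Two generators live here.

**Planted-rewiring benchmark** (:func:`make_benchmark_multiplex`): a
sparse weighted graph with degree and weight distributions in the range
typical of sparse microbial co-occurrence networks (default 95 nodes,
mean degree 4, weights |N(0.3, 0.15)| truncated to (0, 1]) is copied
into a second layer in which ``m_control`` randomly chosen "control"
nodes have every incident edge deleted and replaced by the same number
of edges to freshly drawn non-control partners with re-sampled weights.
Control nodes therefore keep their degree but change their entire
neighbor set; all other neighborhoods are untouched except where a
control edge touched them.  Degrees are drawn as 2 + Poisson(mean - 2)
so every node keeps at least two partners and thus a well-defined
neighborhood in both layers.  Detection methods are scored by the
Jaccard index between their top-m nodes and the planted control set,
optionally under uniform edge noise (:func:`add_uniform_noise`) with
amplitudes e^-10 .. e^-2.

**Synthetic cohort** (:func:`make_synthetic_cohort`): a two-time-point
cohort whose counts are zero-inflated negative binomial draws coupled
through a latent Gaussian copula with block correlation structure.  One
subgroup keeps the same structure at both time points; the other's
designated taxa are reassigned to different correlation blocks at the
second time point, so their co-occurrence neighborhoods rewire.  A
binary phenotype equals the subgroup up to label noise (flip probability
1 - coupling).  This emulates the noisiness, compositionality and
sparseness of real abundance data while providing planted truth for
end-to-end pipeline tests; see the methods note for what it does not
emulate.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import run_mnda, embedding_distance
from .ednn import EDNNConfig
from .io import AbundanceTable
from .multiplex import MultiplexNetwork

__all__ = [
    "SimulationSpec",
    "SyntheticCohortSpec",
    "make_benchmark_multiplex",
    "add_uniform_noise",
    "jaccard",
    "detect_topm",
    "laplacian_baseline",
    "make_synthetic_cohort",
    "run_benchmark",
]

#: default uniform-noise amplitudes: e^-10 .. e^-2
DEFAULT_NOISE_LEVELS = tuple(float(np.exp(p)) for p in range(-10, -1))


@dataclasses.dataclass
class SimulationSpec:
    """Parameters of the planted-rewiring benchmark generator."""

    n_nodes: int = 95
    mean_degree: float = 4.0
    weight_mean: float = 0.3
    weight_sd: float = 0.15
    m_control: int = 10
    noise_levels: tuple = DEFAULT_NOISE_LEVELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_control >= self.n_nodes:
            raise ValueError("m_control must be smaller than the number of nodes")
        if any(x < 0 for x in self.noise_levels):
            raise ValueError("noise levels must be >= 0")
        if self.mean_degree <= 2 or self.mean_degree >= self.n_nodes - 1:
            raise ValueError("mean degree must lie in (2, n_nodes - 1)")


def _sample_weights(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """|N(mean, sd)| truncated to (0, 1], rejection-sampled."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = np.abs(rng.normal(mean, sd, size=2 * (n - filled) + 8))
        draw = draw[(draw > 0) & (draw <= 1)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def make_benchmark_multiplex(
    spec: SimulationSpec | None = None, seed: int | None = None
) -> tuple[MultiplexNetwork, set]:
    """Two-layer multiplex with ``m_control`` planted rewired nodes.

    Returns the multiplex (layers ``"layer1"``, ``"layer2"``) and the set
    of control node IDs whose neighborhoods differ between the layers.
    With ``m_control=0`` the layers are identical.
    """
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    k = spec.n_nodes
    degrees = 2 + rng.poisson(spec.mean_degree - 2.0, size=k)
    degrees = np.minimum(degrees, k - 1)
    if degrees.sum() % 2:
        degrees[rng.integers(k)] += 1
    g = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)  # collapse parallel edges
    g.remove_edges_from(nx.selfloop_edges(g))

    w1 = np.zeros((k, k))
    edges = list(g.edges())
    weights = _sample_weights(rng, len(edges), spec.weight_mean, spec.weight_sd)
    for (i, j), w in zip(edges, weights):
        w1[i, j] = w1[j, i] = w

    controls = set(rng.choice(k, size=spec.m_control, replace=False).tolist())
    non_control = np.array(sorted(set(range(k)) - controls))
    w2 = w1.copy()
    # drop every control-incident edge, then rebuild each control's degree
    for c in controls:
        w2[c, :] = 0.0
        w2[:, c] = 0.0
    for c in controls:
        old_partners = set(np.flatnonzero(w1[c]))
        degree = len(old_partners)
        candidates = np.array(
            [p for p in non_control if p not in old_partners and p != c]
        )
        if len(candidates) < degree:
            raise ValueError("not enough non-control partners to rewire; increase K")
        new_partners = rng.choice(candidates, size=degree, replace=False)
        new_weights = _sample_weights(rng, degree, spec.weight_mean, spec.weight_sd)
        for p, w in zip(new_partners, new_weights):
            w2[c, p] = w2[p, c] = w

    node_ids = [f"n{i:03d}" for i in range(k)]
    mpx = MultiplexNetwork(node_ids, [w1, w2], ["layer1", "layer2"], owner="benchmark")
    return mpx, {node_ids[c] for c in controls}


def add_uniform_noise(
    mpx: MultiplexNetwork, noise_max: float, seed: int = 0
) -> MultiplexNetwork:
    """Add Uniform(0, noise_max) to every off-diagonal adjacency entry.

    The noise is drawn independently per upper-triangle entry of every
    layer and mirrored to keep symmetry; zero entries are perturbed too,
    so the operation densifies the graph (it acts on the adjacency
    matrix, not the edge set).
    """
    if noise_max < 0:
        raise ValueError("noise_max must be >= 0")
    rng = np.random.default_rng(seed)
    layers = []
    k = mpx.n_nodes
    iu = np.triu_indices(k, k=1)
    for w in mpx.layers:
        noisy = w.copy()
        noise = rng.uniform(0.0, noise_max, size=len(iu[0]))
        noisy[iu] += noise
        noisy.T[iu] = noisy[iu]
        layers.append(noisy)
    return MultiplexNetwork(mpx.node_ids, layers, mpx.layer_labels, owner=mpx.owner)


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """|A n B| / |A u B|; two empty sets have Jaccard 1 by convention."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def detect_topm(dynamics, m: int) -> set:
    """Nodes carrying the m largest dynamics values (ties broken by node ID).

    ``dynamics`` is a Series indexed by node, or a one-owner DataFrame
    from :func:`mnda.dynamics.node_dynamics`.
    """
    if isinstance(dynamics, pd.DataFrame):
        series = dynamics["distance"]
        if series.index.nlevels == 2:
            series = series.droplevel("owner")
    else:
        series = dynamics
    if m <= 0:
        raise ValueError("m must be positive")
    if m > len(series):
        raise ValueError(f"m={m} exceeds the {len(series)} available nodes")
    order = sorted(series.index, key=lambda node: (-series[node], str(node)))
    return set(order[:m])


def laplacian_baseline(mpx: MultiplexNetwork, n_eigvecs: int = 10) -> pd.DataFrame:
    """Eigenvector-embedding baseline for neighborhood-change detection.

    Each layer's nodes are represented by their rows in the matrix of
    the ``n_eigvecs`` smallest non-trivial eigenvectors of the
    combinatorial Laplacian L = D - W (null-space vectors, one per
    connected component, are skipped).  Eigenvector signs are aligned
    across layers by maximizing per-vector correlation, then each node
    is scored by the cosine distance between its two representations.
    """
    if mpx.n_layers != 2:
        raise ValueError("baseline is defined for two-layer multiplexes")
    reps = []
    for w in mpx.layers:
        deg = w.sum(axis=1)
        if (deg == 0).any():
            warnings.warn(f"{int((deg == 0).sum())} zero-degree node(s) in a layer")
        lap = np.diag(deg) - w
        eigvals, eigvecs = np.linalg.eigh(lap)
        nontrivial = np.flatnonzero(eigvals > 1e-9)
        take = nontrivial[:n_eigvecs]
        reps.append(eigvecs[:, take])
    r1, r2 = reps
    d = min(r1.shape[1], r2.shape[1])
    r1, r2 = r1[:, :d], r2[:, :d]
    signs = np.sign(np.einsum("ij,ij->j", r1, r2))
    signs[signs == 0] = 1.0
    r2 = r2 * signs
    dist = [embedding_distance(a, b) for a, b in zip(r1, r2)]
    return pd.DataFrame({"distance": dist}, index=pd.Index(mpx.node_ids, name="node"))


# ---------------------------------------------------------------------------
# synthetic cohort
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SyntheticCohortSpec:
    """Parameters of the two-time-point synthetic cohort generator.

    Taxa are organized into co-occurrence *guilds* of ``factor_size``
    taxa driven by one latent factor each; within a guild, half the taxa
    load positively and half negatively (a zero-sum contrast, so the
    structure survives the compositional CLR normalization instead of
    being absorbed into the geometric mean).  ``rho`` is the variance
    share of the guild factor, i.e. |latent correlation| between guild
    mates.  ``stability`` is the within-individual autocorrelation of
    the latent states between the two time points: subgroup 1 keeps an
    (almost) frozen co-occurrence pattern, while subgroup 2's designated
    taxa move to a different guild at the second time point with fresh
    idiosyncratic levels, reorganizing their association partners.

    The defaults define a deliberately strong-coupling validation
    regime: 60 individuals, 40 taxa in 8 guilds of 5, 32 rewired taxa,
    latent correlation 0.95, stability 0.995, plain negative-binomial
    marginals (dispersion 50; no structural zero inflation — sampling
    zeros of rare taxa provide sparsity, and the ``zero_inflation`` knob
    exists for stress tests), depths uniform in [20k, 30k], and a
    phenotype equal to the subgroup (coupling 1 = no label noise).
    """

    n_individuals: int = 60
    n_taxa: int = 40
    factor_size: int = 5
    rho: float = 0.95
    n_rewired: int = 32
    rewire_prob: float = 1.0
    stability: float = 0.995
    subgroup2_fraction: float = 0.5
    coupling: float = 1.0
    zero_inflation: float = 0.0
    dispersion: float = 50.0
    abundance_sigma: float = 1.0
    depth_range: tuple = (20_000, 30_000)
    time_labels: tuple = ("t1", "t2")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must be in [0, 1]")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        if self.n_rewired >= self.n_taxa:
            raise ValueError("n_rewired must be smaller than n_taxa")
        if self.n_taxa % self.factor_size:
            raise ValueError("n_taxa must be a multiple of factor_size")
        if not 0 <= self.stability <= 1:
            raise ValueError("stability must be in [0, 1]")


def _compose_latent(
    f: np.ndarray, eps: np.ndarray, factor: np.ndarray, sign: np.ndarray, rho: float
) -> np.ndarray:
    """z_k = sqrt(rho) s_k f_{g(k)} + sqrt(1-rho) eps_k.

    Unit variance per taxon; corr(z_i, z_j) = rho * s_i * s_j within a
    guild and 0 across guilds.
    """
    return np.sqrt(rho) * sign * f[factor] + np.sqrt(1.0 - rho) * eps


def _persist(x: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1)-style carry-over of a latent draw to the next time point."""
    return phi * x + np.sqrt(1.0 - phi**2) * rng.standard_normal(x.shape)


def _zinb_counts(
    u: np.ndarray, mu: np.ndarray, dispersion: float, zero_inflation: float
) -> np.ndarray:
    """Zero-inflated NB quantile transform of copula uniforms."""
    if zero_inflation > 0:
        scaled = np.clip((u - zero_inflation) / (1 - zero_inflation), 0.0, 1 - 1e-12)
    else:
        scaled = np.clip(u, 1e-12, 1 - 1e-12)
    p = dispersion / (dispersion + mu)
    counts = stats.nbinom.ppf(scaled, dispersion, p)
    if zero_inflation > 0:
        counts = np.where(u < zero_inflation, 0.0, counts)
    return counts


def make_synthetic_cohort(
    spec: SyntheticCohortSpec | None = None, seed: int | None = None
) -> tuple[AbundanceTable, dict]:
    """Two-time-point cohort with subgroup-specific neighborhood rewiring.

    Returns the abundance table (metadata: ``individual_id``,
    ``time_point``, ``phenotype``) and a truth dict with the planted
    ``subgroup`` per individual, the ``rewired_taxa`` IDs and the
    noise-free phenotype coupling.
    """
    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    k, n = spec.n_taxa, spec.n_individuals
    taxa = [f"taxon{i:03d}" for i in range(k)]
    individuals = [f"ind{i:03d}" for i in range(n)]

    # guild membership: factor index + loading sign (half +, half - per guild)
    base_factor = np.arange(k) // spec.factor_size
    n_factors = base_factor.max() + 1
    base_sign = np.where((np.arange(k) % spec.factor_size) < spec.factor_size // 2, 1.0, -1.0)
    rewired = np.sort(rng.choice(k, size=spec.n_rewired, replace=False))
    rew_factor, rew_sign = base_factor.copy(), base_sign.copy()
    for t in rewired:
        if rng.random() < spec.rewire_prob:
            if n_factors > 1:
                shift = 1 + rng.integers(n_factors - 1)
                rew_factor[t] = (base_factor[t] + shift) % n_factors
            rew_sign[t] = rng.choice([-1.0, 1.0])

    subgroup = (rng.random(n) < spec.subgroup2_fraction).astype(int)
    phenotype = subgroup.copy()
    flip = rng.random(n) > spec.coupling
    phenotype[flip] = 1 - phenotype[flip]

    base_props = rng.lognormal(mean=0.0, sigma=spec.abundance_sigma, size=k)
    base_props /= base_props.sum()

    # per-individual latent states; the second time point carries over the
    # first with autocorrelation `stability`, so persistent individuals keep
    # their co-occurrence pattern while subgroup 2's rewired taxa reorganize
    n_factors_total = base_factor.max() + 1
    z_by_time: dict[tuple, np.ndarray] = {}
    for i in range(n):
        f1 = rng.standard_normal(n_factors_total)
        e1 = rng.standard_normal(k)
        f2 = _persist(f1, spec.stability, rng)
        e2 = _persist(e1, spec.stability, rng)
        z_by_time[(i, 0)] = _compose_latent(f1, e1, base_factor, base_sign, spec.rho)
        if subgroup[i] == 1:
            # rewired taxa reorganize fully at the second time point: new
            # guild membership and fresh idiosyncratic levels
            moved = rew_factor != base_factor
            moved |= rew_sign != base_sign
            e2 = np.where(moved, rng.standard_normal(k), e2)
            z_by_time[(i, 1)] = _compose_latent(f2, e2, rew_factor, rew_sign, spec.rho)
        else:
            z_by_time[(i, 1)] = _compose_latent(f2, e2, base_factor, base_sign, spec.rho)

    rows, sample_ids, meta_rows = [], [], []
    for t_i, t_label in enumerate(spec.time_labels):
        for i, ind in enumerate(individuals):
            u = stats.norm.cdf(z_by_time[(i, t_i)])
            depth = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1)
            mu = depth * base_props
            rows.append(_zinb_counts(u, mu, spec.dispersion, spec.zero_inflation))
            sample_ids.append(f"{ind}_{t_label}")
            meta_rows.append(
                {
                    "individual_id": ind,
                    "time_point": t_label,
                    "phenotype": int(phenotype[i]),
                }
            )
    counts = pd.DataFrame(rows, index=sample_ids, columns=taxa)
    metadata = pd.DataFrame(meta_rows, index=sample_ids)
    table = AbundanceTable(counts, metadata)
    truth = {
        "subgroup": pd.Series(subgroup, index=individuals, name="subgroup"),
        "phenotype": pd.Series(phenotype, index=individuals, name="phenotype"),
        "rewired_taxa": [taxa[t] for t in rewired],
        "coupling": spec.coupling,
    }
    return table, truth


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------


def run_benchmark(
    spec: SimulationSpec | None = None,
    methods: Sequence[str] = ("mnda", "laplacian"),
    noise_levels: Sequence[float] | None = None,
    n_replicates: int = 5,
    seed: int = 0,
    walk_length: int = 5,
    n_walks: int = 100,
    config: EDNNConfig | None = None,
    n_eigvecs: int = 10,
) -> pd.DataFrame:
    """Full factorial benchmark: methods x noise levels x replicates.

    Each replicate draws a fresh planted benchmark; each method detects
    the top-m most dynamic nodes and is scored by Jaccard against the
    planted controls.  Returns a tidy DataFrame (method, noise,
    replicate, jaccard) ready for plotting.
    """
    spec = spec or SimulationSpec()
    unknown = set(methods) - {"mnda", "laplacian"}
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    if noise_levels is None:
        noise_levels = spec.noise_levels
    records = []
    for rep in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % 2**31)
        mpx, controls = make_benchmark_multiplex(spec, seed=rep_seed)
        for noise_i, noise in enumerate(noise_levels):
            if noise > 0:
                noisy = add_uniform_noise(mpx, noise, seed=rep_seed + noise_i + 1)
            else:
                noisy = mpx
            for method in methods:
                if method == "mnda":
                    result = run_mnda(
                        [noisy],
                        walk_length=walk_length,
                        n_walks=n_walks,
                        config=config,
                        seed=rep_seed,
                    )
                    detected = detect_topm(result.dynamics, spec.m_control)
                else:
                    detected = detect_topm(
                        laplacian_baseline(noisy, n_eigvecs)["distance"],
                        spec.m_control,
                    )
                records.append(
                    {
                        "method": method,
                        "noise": float(noise),
                        "replicate": rep,
                        "jaccard": jaccard(detected, controls),
                    }
                )
    return pd.DataFrame.from_records(records)
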