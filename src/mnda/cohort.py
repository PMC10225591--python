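"""Individual-level analyses built on neighborhood dynamics.

This module turns per-(individual, taxon) dynamics into cohort-level
statements: consensus clustering of individuals, phenotype prediction
from the three feature views (abundances, ISN edges, dynamics),
discriminative-taxon ranking by forward-selection counts, phylum-level
edge aggregation, group-averaged difference networks, graph filtration
curves, and a permutation chi-square comparison of two clusterings.

Prediction follows a leave-one-out protocol: for each left-out
individual, the majority class of the *training* individuals is
undersampled to balance the classes, greedy forward feature selection is
driven by inner cross-validated AUC, an RBF-kernel SVM is fitted on the
selected features, and the left-out individual is scored.  One ROC/AUC is
computed per repeat from the pooled held-out decision scores (with one
sample per fold there is no per-fold ROC).  Balancing and selection
happen strictly inside each training fold, so the left-out sample never
leaks into them.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dynamics import ConsensusResult, consensus_cluster, ensemble_dynamics, node_dynamics, run_mnda
from .ednn import EDNNConfig
from .io import AbundanceTable, GlobalNetwork, clr_transform
from .isn import ISNSet, absolute_weights, lioness_isn, make_estimator
from .multiplex import multiplex_from_isnsets

__all__ = [
    "individual_dynamics_pipeline",
    "cluster_individuals",
    "compare_clusterings",
    "predict_phenotype",
    "PredictionReport",
    "rank_discriminators",
    "aggregate_phyla",
    "PhylumAggregate",
    "difference_network",
    "DifferenceNetwork",
    "filtration_curve",
    "FiltrationCurve",
]


# ---------------------------------------------------------------------------
# end-to-end per-individual dynamics
# ---------------------------------------------------------------------------


def individual_dynamics_pipeline(
    table: AbundanceTable,
    estimator: Callable | None = None,
    n_embeddings: int = 1,
    config: EDNNConfig | None = None,
    walk_length: int = 5,
    n_walks: int = 100,
    weighted: bool = True,
    seed: int = 0,
) -> dict:
    """Abundances -> per-time-point ISNs -> multiplexes -> dynamics.

    Builds leave-one-out ISNs independently per time point (each time
    point is its own reference population), takes absolute weights,
    pairs each individual's two ISNs into a multiplex, embeds all
    multiplexes jointly and returns the individuals x taxa matrix of
    cosine distances (averaged over ``n_embeddings`` EDNN seeds when
    > 1), along with the intermediate objects.
    """
    if estimator is None:
        estimator = make_estimator("pearson_clr", sparsify_quantile=0.0)
    times = table.time_points()
    if len(times) != 2:
        raise ValueError(f"exactly two time points required, found {times}")
    isnsets = {}
    for t in times:
        sub = table.samples_at(t)
        isnsets[t] = absolute_weights(lioness_isn(sub, estimator))
    common = [
        i for i in isnsets[times[0]].individual_ids
        if i in isnsets[times[1]].individual_ids
    ]
    multiplexes = [multiplex_from_isnsets(isnsets, ind) for ind in common]
    if n_embeddings > 1:
        dyn_long, embeddings = ensemble_dynamics(
            multiplexes,
            config=config,
            n_repeats=n_embeddings,
            layer_pair=(times[0], times[1]),
            weighted=weighted,
            walk_length=walk_length,
            n_walks=n_walks,
            base_seed=seed,
        )
        per_node = dyn_long["mean"]
    else:
        result = run_mnda(
            multiplexes,
            layer_pair=(times[0], times[1]),
            walk_length=walk_length,
            n_walks=n_walks,
            weighted=weighted,
            config=config,
            seed=seed,
        )
        per_node = result.dynamics["distance"]
        embeddings = [result.embeddings]
    wide = per_node.unstack("node")
    wide = wide.loc[[str(i) for i in common] if wide.index.dtype == object else common]
    return {
        "dynamics": wide,
        "isns": isnsets,
        "multiplexes": multiplexes,
        "embeddings": embeddings,
        "individuals": common,
        "times": times,
    }


def cluster_individuals(
    dynamics: pd.DataFrame,
    k_range: Sequence[int] = (2, 3, 4, 5, 6),
    n_repeats: int = 50,
    subsample: float = 0.8,
    rank_normalize: bool = True,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of individuals by their dynamics profiles.

    ``dynamics`` is the individuals x taxa distance matrix; clusters are
    time-invariant because the features already summarize change across
    time points.  Cosine-distance profiles are strongly right-skewed
    (a few individuals reorganize a lot), which makes raw Euclidean
    k-means split the long tail rather than the groups; by default each
    feature is therefore rank-normalized across individuals first.
    """
    if len(dynamics) < 4:
        raise ValueError("need at least 4 individuals to cluster")
    if rank_normalize:
        ranked = dynamics.rank(axis=0) / len(dynamics)
        dynamics = ranked
    return consensus_cluster(
        dynamics, k_range=k_range, n_repeats=n_repeats, subsample=subsample, seed=seed
    )


def compare_clusterings(
    labels_a: Sequence, labels_b: Sequence, n_perm: int = 10_000, seed: int = 0
) -> dict:
    """Chi-square association between two labelings with a permutation p-value.

    ``p_perm = (1 + #{permuted chi2 >= observed}) / (1 + n_perm)``,
    permuting ``labels_b``.  The chi-square statistic is computed on the
    contingency table without continuity correction.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same individuals")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("each labeling needs at least two clusters")

    codes_a = pd.factorize(a)[0]
    codes_b = pd.factorize(b)[0]
    n_a, n_b = codes_a.max() + 1, codes_b.max() + 1
    # marginals are invariant under permutation, so the expected table is fixed
    row = np.bincount(codes_a, minlength=n_a).astype(float)
    col = np.bincount(codes_b, minlength=n_b).astype(float)
    expected = np.outer(row, col) / len(a)

    def _chi2(y_codes: np.ndarray) -> float:
        table = np.bincount(codes_a * n_b + y_codes, minlength=n_a * n_b).reshape(
            n_a, n_b
        )
        return float(((table - expected) ** 2 / expected).sum())

    observed = _chi2(codes_b)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = codes_b.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _chi2(perm) >= observed - 1e-12:
            exceed += 1
    return {
        "chi2": observed,
        "p_perm": (1 + exceed) / (1 + n_perm),
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# phenotype prediction
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PredictionReport:
    """Leave-one-out prediction results for one feature view."""

    aucs: list
    mean_auc: float
    se_auc: float
    selection_counts: pd.Series
    n_repeats: int
    config: dict


def _undersample(
    y: np.ndarray, rng: np.random.Generator, per_class: int | None = None
) -> np.ndarray:
    """Indices balancing the two classes by downsampling to ``per_class``.

    When ``per_class`` is given, every call returns exactly that many
    samples of each class.  Inside leave-one-out cross-validation this
    keeps the training composition identical across folds — otherwise
    folds that drop a minority sample train on a different balance than
    folds that drop a majority sample, which biases pooled held-out
    scores pessimistically under null labels.
    """
    classes, counts = np.unique(y, return_counts=True)
    n_target = counts.min() if per_class is None else min(per_class, counts.min())
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) > n_target:
            idx = rng.choice(idx, size=n_target, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def _fast_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney), ties averaged."""
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores))
    ranks[order] = np.arange(1, len(scores) + 1)
    # average ranks over ties
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = (i + 1 + j + 1) / 2.0
        i = j + 1
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        return 0.5
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def _cv_splits(y: np.ndarray, n_splits: int, seed: int) -> list:
    _, counts = np.unique(y, return_counts=True)
    n_splits = min(n_splits, counts.min())
    if n_splits < 2:
        return []
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _lda_scores(x_tr, y_tr, x_te, ridge: float = 1e-2) -> np.ndarray:
    """Decision scores of a ridge-regularized linear discriminant."""
    mu0 = x_tr[y_tr == 0].mean(axis=0)
    mu1 = x_tr[y_tr == 1].mean(axis=0)
    centered = np.concatenate([x_tr[y_tr == 0] - mu0, x_tr[y_tr == 1] - mu1])
    cov = centered.T @ centered / max(len(x_tr) - 2, 1)
    cov.flat[:: cov.shape[0] + 1] += ridge
    w = np.linalg.solve(cov, mu1 - mu0)
    return x_te @ w


def _inner_cv_auc(x: np.ndarray, y: np.ndarray, splits: list) -> float:
    """Pooled decision-score AUC over a stratified inner CV.

    Scored with a closed-form regularized linear discriminant: the
    selection loop evaluates thousands of candidate subsets per fold,
    where a kernel solver per candidate would dominate the runtime by
    orders of magnitude without changing which features look useful.
    """
    if not splits:
        return 0.5
    scores = np.empty(len(y))
    for tr, te in splits:
        scores[te] = _lda_scores(x[tr], y[tr], x[te])
    return _fast_auc(y, scores)


def _forward_select(
    x: np.ndarray,
    y: np.ndarray,
    max_features: int,
    inner_folds: int,
    seed: int,
) -> list[int]:
    """Greedy forward selection by inner-CV AUC; stops when nothing improves."""
    n_features = x.shape[1]
    splits = _cv_splits(y, inner_folds, seed)
    selected: list[int] = []
    best_auc = -np.inf
    while len(selected) < min(max_features, n_features):
        best_candidate, best_candidate_auc = None, best_auc
        for f in range(n_features):
            if f in selected:
                continue
            auc = _inner_cv_auc(x[:, selected + [f]], y, splits)
            if auc > best_candidate_auc + 1e-12:
                best_candidate, best_candidate_auc = f, auc
        if best_candidate is None:
            break
        selected.append(best_candidate)
        best_auc = best_candidate_auc
    return selected


def predict_phenotype(
    features: pd.DataFrame,
    labels: pd.Series,
    classifier: Callable | None = None,
    n_repeats: int = 100,
    max_features: int = 10,
    inner_folds: int = 5,
    undersample: bool = True,
    seed: int = 0,
) -> PredictionReport:
    """Leave-one-out phenotype prediction with in-fold balancing/selection.

    ``features`` is an individuals x features view (node, edge, or
    dynamic); ``labels`` a binary series over the same individuals.
    ``classifier`` is a zero-argument factory returning an estimator
    with ``fit`` and ``decision_function`` (defaults to an RBF-kernel
    SVM with standard hyperparameters).  Feature selection counts are
    accumulated across folds and repeats, one increment per selection.
    """
    labels = labels.loc[features.index]
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"binary labels required, found classes {classes}")
    counts = labels.value_counts()
    if counts.min() < 3:
        raise ValueError("each class needs at least 3 members")
    make_clf = classifier or (lambda: SVC(kernel="rbf", C=1.0, gamma="scale"))
    x_all = features.to_numpy(dtype=float)
    y_all = (labels.to_numpy() == classes[1]).astype(int)
    n = len(y_all)
    # fixed per-class training size so every LOO fold sees the same balance
    per_class = int(np.bincount(y_all).min()) - 1
    sel_counts = np.zeros(x_all.shape[1], dtype=int)
    aucs = []
    for rep in range(n_repeats):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(rep_seed)
        held_out = np.empty(n)
        for i in range(n):
            train = np.delete(np.arange(n), i)
            y_tr = y_all[train]
            if undersample:
                train = train[_undersample(y_tr, rng, per_class)]
                y_tr = y_all[train]
            scaler = StandardScaler().fit(x_all[train])
            x_tr = scaler.transform(x_all[train])
            x_te = scaler.transform(x_all[i : i + 1])
            selected = _forward_select(
                x_tr, y_tr, max_features, inner_folds, (rep_seed + i) % 2**31
            )
            if not selected:
                selected = [0]
            sel_counts[selected] += 1
            clf = make_clf()
            clf.fit(x_tr[:, selected], y_tr)
            held_out[i] = clf.decision_function(x_te[:, selected])[0]
        aucs.append(roc_auc_score(y_all, held_out))
    aucs_arr = np.array(aucs)
    se = float(aucs_arr.std(ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 else 0.0
    return PredictionReport(
        aucs=aucs,
        mean_auc=float(aucs_arr.mean()),
        se_auc=se,
        selection_counts=pd.Series(sel_counts, index=features.columns, name="count"),
        n_repeats=n_repeats,
        config={
            "classifier": "svm_rbf" if classifier is None else getattr(classifier, "__name__", "custom"),
            "undersample": undersample,
            "max_features": max_features,
            "inner_folds": inner_folds,
            "seed": seed,
        },
    )


def rank_discriminators(report: PredictionReport) -> pd.Series:
    """Features ordered by selection count (descending, ties lexicographic)."""
    if report.selection_counts.empty:
        raise ValueError("report has no selection counts")
    counts = report.selection_counts
    order = sorted(counts.index, key=lambda f: (-counts[f], str(f)))
    return counts.loc[order]


# ---------------------------------------------------------------------------
# interpretation aids
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PhylumAggregate:
    """Phylum-level aggregation of a taxon network.

    ``eta`` holds raw inter-phylum edge counts (binary mode) or weight
    sums (weighted mode), with intra-phylum values on the diagonal;
    ``eta_norm`` divides by n1*n2 for phylum pairs and n(n-1)/2 for a
    phylum's own (self-loop) entry, so binary-mode values are occupancy
    fractions in [0, 1].
    """

    sizes: pd.Series
    eta: pd.DataFrame
    eta_norm: pd.DataFrame
    mode: str


def aggregate_phyla(
    net: GlobalNetwork, taxonomy: Mapping, mode: str = "binary"
) -> PhylumAggregate:
    """Aggregate taxon-level edges into phylum meta-nodes.

    ``taxonomy`` maps taxon ID to phylum.  ``binary`` counts nonzero
    edges; ``weighted`` sums edge weights; both use the same
    normalizers.  A taxon without a phylum annotation raises.
    """
    if mode not in {"binary", "weighted"}:
        raise ValueError(f"mode must be binary or weighted, got {mode!r}")
    missing = [t for t in net.node_ids if t not in taxonomy or pd.isna(taxonomy[t])]
    if missing:
        raise ValueError(f"taxa without phylum annotation: {missing}")
    phyla = sorted({taxonomy[t] for t in net.node_ids}, key=str)
    assign = np.array([phyla.index(taxonomy[t]) for t in net.node_ids])
    sizes = pd.Series(
        [int((assign == p).sum()) for p in range(len(phyla))], index=phyla, name="size"
    )
    w = net.weights
    value = (w != 0).astype(float) if mode == "binary" else w
    p = len(phyla)
    eta = np.zeros((p, p))
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    for i, j in zip(iu, ju):
        eta[assign[i], assign[j]] += value[i, j]
        if assign[i] != assign[j]:
            eta[assign[j], assign[i]] += value[i, j]
    denom = np.outer(sizes.to_numpy(), sizes.to_numpy()).astype(float)
    n_vec = sizes.to_numpy().astype(float)
    np.fill_diagonal(denom, n_vec * (n_vec - 1) / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        eta_norm = np.where(denom > 0, eta / denom, 0.0)
    return PhylumAggregate(
        sizes=sizes,
        eta=pd.DataFrame(eta, index=phyla, columns=phyla),
        eta_norm=pd.DataFrame(eta_norm, index=phyla, columns=phyla),
        mode=mode,
    )


@dataclasses.dataclass
class DifferenceNetwork:
    """Signed later-minus-earlier mean edge differences around seed taxa."""

    node_ids: list
    values: pd.DataFrame  # symmetric, signed
    group: str
    seed_taxa: list

    def edge_list(self) -> pd.DataFrame:
        rows = []
        ids = self.node_ids
        v = self.values.to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if v[i, j] != 0:
                    rows.append((ids[i], ids[j], v[i, j]))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "difference"])


def difference_network(
    isns: Mapping[str, ISNSet],
    group_members: Sequence,
    layer_pair: tuple,
    seed_taxa: Sequence,
    group: str = "",
) -> DifferenceNetwork:
    """Group-mean ISN change between two layers, around seed taxa.

    ISNs of the group's members are averaged per layer; the earlier
    layer's mean is subtracted from the later one; the result is
    restricted to the seed taxa plus their distance-1 neighbors in
    either averaged layer.  Positive values mean the association grew.
    """
    group_members = list(group_members)
    if not group_members:
        raise ValueError("empty group")
    earlier, later = layer_pair
    means = {}
    node_ids = None
    for layer in (earlier, later):
        isnset = isns[layer]
        node_ids = isnset.node_ids
        idx = [isnset.individual_ids.index(m) for m in group_members]
        means[layer] = isnset.networks[idx].mean(axis=0)
    seed_taxa = list(seed_taxa)
    unknown = [t for t in seed_taxa if t not in node_ids]
    if unknown:
        raise ValueError(f"seed taxa not in the network: {unknown}")
    seed_idx = [node_ids.index(t) for t in seed_taxa]
    neighbor_mask = np.zeros(len(node_ids), dtype=bool)
    neighbor_mask[seed_idx] = True
    for layer in (earlier, later):
        nz = means[layer][seed_idx] != 0
        neighbor_mask |= nz.any(axis=0)
    keep = np.flatnonzero(neighbor_mask)
    diff = (means[later] - means[earlier])[np.ix_(keep, keep)]
    kept_ids = [node_ids[i] for i in keep]
    return DifferenceNetwork(
        node_ids=kept_ids,
        values=pd.DataFrame(diff, index=kept_ids, columns=kept_ids),
        group=group,
        seed_taxa=seed_taxa,
    )


@dataclasses.dataclass
class FiltrationCurve:
    """A graph descriptor evaluated along an edge-weight threshold sweep."""

    thresholds: np.ndarray
    values: np.ndarray
    descriptor: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, self.descriptor: self.values}
        )


def filtration_curve(net, descriptor: str = "edge_count") -> FiltrationCurve:
    """Descriptor of the subgraph with |weight| >= t, for every observed t.

    ``net`` is a GlobalNetwork, DifferenceNetwork, labelled DataFrame or
    raw matrix; thresholds are the sorted unique absolute edge weights.
    Descriptors: ``edge_count``, ``total_weight`` (sum of retained
    |weights|) and ``n_components`` (connected components, isolated
    nodes included).
    """
    if descriptor not in {"edge_count", "total_weight", "n_components"}:
        raise ValueError(f"unknown descriptor {descriptor!r}")
    if isinstance(net, GlobalNetwork):
        w = net.weights
    elif isinstance(net, DifferenceNetwork):
        w = net.values.to_numpy()
    elif isinstance(net, pd.DataFrame):
        w = net.to_numpy(dtype=float)
    else:
        w = np.asarray(net, dtype=float)
    if w.size == 0:
        raise ValueError("empty network")
    absw = np.abs(w)
    iu = np.triu_indices_from(absw, k=1)
    weights = absw[iu]
    weights = weights[weights > 0]
    if weights.size == 0:
        raise ValueError("network has no edges")
    thresholds = np.unique(weights)
    values = np.empty(len(thresholds))
    for t_i, t in enumerate(thresholds):
        mask = absw >= t
        np.fill_diagonal(mask, False)
        if descriptor == "edge_count":
            values[t_i] = mask[iu].sum()
        elif descriptor == "total_weight":
            values[t_i] = absw[iu][mask[iu]].sum()
        else:
            values[t_i] = connected_components(
                sparse.csr_matrix(mask.astype(int)), directed=False
            )[0]
    return FiltrationCurve(thresholds=thresholds, values=values, descriptor=descriptor)
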