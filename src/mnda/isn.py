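"""Individual-specific networks via leave-one-out perturbation.

An individual-specific network (ISN) estimates one individual's
contribution to every edge of a population-level association network.
Given a global network with edge weights ``w`` estimated on all N
reference samples and the leave-one-out network ``w_loo`` estimated with
individual n removed, the nth ISN edge is the linear interpolation

    w_n = N * w - (N - 1) * w_loo

so that the global network is (for estimators linear in per-sample
contributions, exactly) the average of the ISNs.  Note that ``w_n`` can be
negative even when both ``w`` and ``w_loo`` are positive — precisely when
``w < (N - 1) * w_loo / N`` — which is why downstream analyses that only
care about association *strength* apply :func:`absolute_weights` as an
explicit separate step.

The association estimator is pluggable: any callable mapping an
:class:`~mnda.io.AbundanceTable` to a :class:`~mnda.io.GlobalNetwork`
works, including one that reads pre-computed networks from files (for
external inference tools whose models are not reimplemented here).
:func:`fallback_estimator` provides a simple CLR + correlation +
quantile-threshold estimator for testing and demos; it is NOT a
substitute model for dedicated compositional inference tools such as
MAGMA or SparCC and is documented as such.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable, GlobalNetwork, clr_transform, read_network, write_network

__all__ = [
    "ISNSet",
    "lioness_isn",
    "absolute_weights",
    "isn_average_check",
    "fallback_estimator",
    "make_estimator",
    "directory_estimator",
    "write_isns",
    "read_isns",
]


@dataclasses.dataclass
class ISNSet:
    """Per-individual K x K symmetric edge-weight matrices.

    ``networks`` has shape (m, K, K), one slice per entry of
    ``individual_ids``.  ``n_reference`` is N, the size of the reference
    population the leave-one-out construction ran on.  ``abs_applied``
    records whether :func:`absolute_weights` has been applied.
    """

    node_ids: list
    individual_ids: list
    networks: np.ndarray
    n_reference: int
    abs_applied: bool = False
    provenance: str = ""

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.individual_ids = list(self.individual_ids)
        self.networks = np.asarray(self.networks, dtype=float)
        m, k = len(self.individual_ids), len(self.node_ids)
        if self.networks.shape != (m, k, k):
            raise ValueError(
                f"networks shape {self.networks.shape} does not match "
                f"{m} individuals x {k} nodes"
            )
        if self.abs_applied and (self.networks < 0).any():
            raise ValueError("abs_applied is set but negative weights present")

    def network(self, individual) -> np.ndarray:
        return self.networks[self.individual_ids.index(individual)]

    def to_frame(self, individual) -> pd.DataFrame:
        return pd.DataFrame(
            self.network(individual), index=self.node_ids, columns=self.node_ids
        )

    def to_global(self, individual) -> GlobalNetwork:
        return GlobalNetwork(
            self.node_ids, self.network(individual), provenance=self.provenance
        )


def _one_sample_per_individual(table: AbundanceTable) -> dict:
    if table.metadata is None:
        raise ValueError("metadata mapping samples to individuals is required")
    mapping: dict = {}
    for sample, ind in table.metadata["individual_id"].items():
        if ind in mapping:
            raise ValueError(
                f"individual {ind!r} has more than one sample in the table; "
                "ISNs are built per time point on one sample per individual"
            )
        mapping[ind] = sample
    return mapping


def lioness_isn(
    table: AbundanceTable,
    estimator: Callable[[AbundanceTable], GlobalNetwork],
    individuals: Sequence | None = None,
) -> ISNSet:
    """Construct ISNs for the requested individuals.

    ``table`` must hold exactly one sample per reference individual (i.e.
    a single time point or condition).  Costs exactly N + 1 estimator
    calls: one global network plus one leave-one-out network per
    reference individual that is requested.
    """
    sample_of = _one_sample_per_individual(table)
    reference = list(sample_of)
    n = len(reference)
    if n < 3:
        raise ValueError(f"need at least 3 reference individuals, got {n}")
    if individuals is None:
        individuals = reference
    else:
        individuals = list(individuals)
        missing = [i for i in individuals if i not in sample_of]
        if missing:
            raise ValueError(f"individuals not in the reference set: {missing}")

    global_net = estimator(table)
    if list(global_net.node_ids) != list(table.taxon_ids):
        raise ValueError("estimator returned a node set differing from the input taxa")
    w = global_net.weights

    isns = np.empty((len(individuals), table.n_taxa, table.n_taxa))
    for pos, ind in enumerate(individuals):
        loo_table = table.drop_sample(sample_of[ind])
        try:
            loo_net = estimator(loo_table)
        except Exception as err:  # name the offending individual
            raise RuntimeError(
                f"estimator failed on the leave-one-out subset for {ind!r}: {err}"
            ) from err
        if list(loo_net.node_ids) != list(table.taxon_ids):
            raise ValueError(
                f"leave-one-out estimator for {ind!r} changed the node set"
            )
        isns[pos] = n * w - (n - 1) * loo_net.weights
        np.fill_diagonal(isns[pos], 0.0)
    return ISNSet(
        node_ids=table.taxon_ids,
        individual_ids=list(individuals),
        networks=isns,
        n_reference=n,
        abs_applied=False,
        provenance=f"lioness(N={n}) over {global_net.provenance or 'estimator'}",
    )


def absolute_weights(isns: ISNSet) -> ISNSet:
    """Replace all edge weights with their absolute values.

    Kept as an explicit step (not fused into construction) because it
    discards the sign of associations on purpose: only unidirectional
    association strength is of interest downstream.  Idempotent; a second
    application warns and returns an equivalent set.
    """
    if isns.abs_applied:
        warnings.warn("absolute_weights applied twice; result unchanged")
    return ISNSet(
        node_ids=isns.node_ids,
        individual_ids=isns.individual_ids,
        networks=np.abs(isns.networks),
        n_reference=isns.n_reference,
        abs_applied=True,
        provenance=isns.provenance + " |.|",
    )


def isn_average_check(isns: ISNSet, global_net: GlobalNetwork) -> dict:
    """Compare the across-individual mean ISN with the global network.

    The global network is a weighted average of the ISNs; equality is
    exact when the estimator is linear in per-sample contributions and
    approximate otherwise.  Returns summary statistics of the per-edge
    absolute deviation |mean_n(w_n) - w| over off-diagonal entries.
    """
    if isns.abs_applied:
        raise ValueError("run the check on raw (signed) ISNs, before absolute_weights")
    if list(isns.node_ids) != list(global_net.node_ids):
        raise ValueError("node sets differ between ISNs and the global network")
    dev = np.abs(isns.networks.mean(axis=0) - global_net.weights)
    off = dev[~np.eye(dev.shape[0], dtype=bool)]
    return {
        "max": float(off.max(initial=0.0)),
        "mean": float(off.mean()) if off.size else 0.0,
        "q50": float(np.quantile(off, 0.5)) if off.size else 0.0,
        "q90": float(np.quantile(off, 0.9)) if off.size else 0.0,
        "n_individuals": len(isns.individual_ids),
    }


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def fallback_estimator(
    table: AbundanceTable,
    method: str = "pearson_clr",
    sparsify_quantile: float = 0.0,
    pseudocount: float = 0.5,
) -> GlobalNetwork:
    """Simple correlation-based association network for testing and demos.

    ``pearson_clr`` computes Pearson correlation on CLR-transformed
    counts; ``spearman`` computes rank correlation on the raw counts.
    Entries whose absolute weight falls at or below the
    ``sparsify_quantile`` quantile of the nonzero absolute weights are
    zeroed.  Constant taxa yield undefined associations, which are set to
    0 with a warning.

    This is NOT MAGMA (and not SparCC): it models neither zero inflation
    nor overdispersion and removes no indirect associations.  Use it as a
    stand-in estimator only; real analyses should supply networks from a
    dedicated compositional inference tool.
    """
    if not 0 <= sparsify_quantile < 1:
        raise ValueError("sparsify_quantile must be in [0, 1)")
    if method == "pearson_clr":
        data = clr_transform(table, pseudocount).counts.to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.corrcoef(data, rowvar=False)
    elif method == "spearman":
        data = table.counts.to_numpy(dtype=float)
        rho = stats.spearmanr(data).statistic
        if np.ndim(rho) == 0:  # scipy collapses the two-taxon case to a scalar
            w = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        else:
            w = np.asarray(rho)
    else:
        raise ValueError(f"unknown method {method!r}")
    w = np.asarray(w, dtype=float)
    if np.isnan(w).any():
        warnings.warn("constant taxa produced undefined associations; set to 0")
        w = np.nan_to_num(w, nan=0.0)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0  # exact symmetry before any thresholding
    if sparsify_quantile > 0:
        nz = np.abs(w[np.triu_indices_from(w, k=1)])
        nz = nz[nz > 0]
        if nz.size:
            thr = np.quantile(nz, sparsify_quantile)
            w[np.abs(w) <= thr] = 0.0
    return GlobalNetwork(
        table.taxon_ids,
        w,
        provenance=(
            f"fallback {method} (sparsify_quantile={sparsify_quantile}); "
            "simple correlation stand-in, not MAGMA/SparCC"
        ),
    )


def make_estimator(
    method: str = "pearson_clr",
    sparsify_quantile: float = 0.0,
    pseudocount: float = 0.5,
) -> Callable[[AbundanceTable], GlobalNetwork]:
    """Bind :func:`fallback_estimator` parameters into a pluggable callable."""

    def estimator(table: AbundanceTable) -> GlobalNetwork:
        return fallback_estimator(table, method, sparsify_quantile, pseudocount)

    estimator.name = f"fallback_{method}"  # type: ignore[attr-defined]
    return estimator


def directory_estimator(path) -> Callable[[AbundanceTable], GlobalNetwork]:
    """Estimator that serves pre-computed networks from a directory.

    Directory convention: ``global.tsv`` holds the network over the full
    reference population and ``loo_<individual>.tsv`` the leave-one-out
    network with that individual removed (edge-list or matrix dialect).
    The served file is chosen by comparing the individuals present in the
    queried table with the full set recorded in ``manifest.json``
    (``{"individual_ids": [...]}``).
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    full = set(manifest["individual_ids"])

    def estimator(table: AbundanceTable) -> GlobalNetwork:
        present = set(table.metadata["individual_id"])
        missing = full - present
        if not missing:
            fname = "global.tsv"
        elif len(missing) == 1:
            fname = f"loo_{next(iter(missing))}.tsv"
        else:
            raise ValueError(
                f"directory estimator cannot serve a subset missing {sorted(missing)}"
            )
        return read_network(
            path / fname, nodes=table.taxon_ids, provenance=f"from {fname}"
        )

    estimator.name = f"from-dir {path}"  # type: ignore[attr-defined]
    return estimator


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_isns(isns: ISNSet, directory) -> None:
    """One edge-list TSV per individual plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ind in isns.individual_ids:
        write_network(isns.to_global(ind), directory / f"isn_{ind}.tsv", fmt="edgelist")
    manifest = {
        "individual_ids": [str(i) for i in isns.individual_ids],
        "node_ids": [str(n) for n in isns.node_ids],
        "n_reference": isns.n_reference,
        "abs_applied": isns.abs_applied,
        "provenance": isns.provenance,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_isns(directory) -> ISNSet:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    node_ids = manifest["node_ids"]
    nets = []
    for ind in manifest["individual_ids"]:
        net = read_network(directory / f"isn_{ind}.tsv", fmt="edgelist", nodes=node_ids)
        frame = net.to_frame().loc[node_ids, node_ids]
        nets.append(frame.to_numpy())
    return ISNSet(
        node_ids=node_ids,
        individual_ids=manifest["individual_ids"],
        networks=np.array(nets),
        n_reference=manifest["n_reference"],
        abs_applied=manifest["abs_applied"],
        provenance=manifest.get("provenance", ""),
    )
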