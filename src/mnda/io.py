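"""Abundance tables, association networks, and compositional pre-processing.

This module holds the two data containers everything else consumes — the
sample-by-taxon :class:`AbundanceTable` and the symmetric weighted
:class:`GlobalNetwork` — together with the pre-processing rules used
throughout the pipeline: the centered log-ratio (CLR) transform for
compositional counts, prevalence filtering, and the classification of
*appearing*/*disappearing* taxa between two time points.

File dialects
-------------
Abundance tables are plain TSV/CSV with a header row of taxon IDs and a
sample-ID first column (rows = samples by default; a flag flips the
orientation).  Sample metadata is a TSV keyed by sample ID with at least
``individual_id`` and ``time_point`` columns.  Networks are either a square
matrix CSV (header + index of node IDs) or a 3-column edge-list TSV
(``node_a``, ``node_b``, ``weight``), undirected, each edge listed once.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "GlobalNetwork",
    "read_abundance",
    "write_abundance",
    "clr_transform",
    "prevalence",
    "prevalence_filter",
    "appearing_disappearing",
    "read_network",
    "write_network",
]

REQUIRED_METADATA = ("individual_id", "time_point")

#: relative tolerance used when checking that a weight matrix is symmetric
SYMMETRY_RTOL = 1e-8


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class AbundanceTable:
    """Sample-by-taxon abundance matrix with optional metadata and taxonomy.

    Parameters
    ----------
    counts
        DataFrame of shape (samples, taxa).  Non-negative finite values
        unless ``transformed`` is set (CLR output is real-valued).
    metadata
        Per-sample table indexed by sample ID; must contain
        ``individual_id`` and ``time_point`` when present.  No two samples
        may share the same (individual_id, time_point) pair.
    taxonomy
        Optional per-taxon annotation (e.g. phylum..species), indexed by
        taxon ID.
    transformed
        True once the values are no longer raw counts (e.g. after CLR).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None
    taxonomy: pd.DataFrame | None = None
    transformed: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dup}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon IDs: {dup}")
        values = self.counts.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance values must be finite")
        if not self.transformed and (values < 0).any():
            raise ValueError("raw counts must be non-negative")
        if self.metadata is not None:
            missing_cols = [c for c in REQUIRED_METADATA if c not in self.metadata.columns]
            if missing_cols:
                raise ValueError(f"metadata is missing required columns {missing_cols}")
            unmatched = self.metadata.index.difference(self.counts.index)
            if len(unmatched) > 0:
                raise ValueError(
                    f"metadata rows without matching samples: {unmatched.tolist()}"
                )
            pairs = self.metadata[list(REQUIRED_METADATA)].apply(tuple, axis=1)
            if pairs.duplicated().any():
                dup = pairs[pairs.duplicated()].tolist()
                raise ValueError(f"duplicate (individual_id, time_point) pairs: {dup}")

    # -- convenience -------------------------------------------------------

    @property
    def sample_ids(self) -> list:
        return self.counts.index.tolist()

    @property
    def taxon_ids(self) -> list:
        return self.counts.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def select_samples(self, sample_ids: Sequence) -> "AbundanceTable":
        sample_ids = list(sample_ids)
        meta = self.metadata.loc[self.metadata.index.intersection(sample_ids)] if self.metadata is not None else None
        return AbundanceTable(
            self.counts.loc[sample_ids], meta, self.taxonomy, self.transformed
        )

    def select_taxa(self, taxon_ids: Sequence) -> "AbundanceTable":
        taxon_ids = list(taxon_ids)
        taxo = self.taxonomy.loc[self.taxonomy.index.intersection(taxon_ids)] if self.taxonomy is not None else None
        return AbundanceTable(
            self.counts.loc[:, taxon_ids], self.metadata, taxo, self.transformed
        )

    def drop_sample(self, sample_id) -> "AbundanceTable":
        keep = [s for s in self.sample_ids if s != sample_id]
        return self.select_samples(keep)

    def time_points(self) -> list:
        if self.metadata is None:
            raise ValueError("table has no metadata; time points unknown")
        return sorted(self.metadata["time_point"].unique().tolist(), key=str)

    def samples_at(self, time_point) -> "AbundanceTable":
        if self.metadata is None:
            raise ValueError("table has no metadata")
        ids = self.metadata.index[self.metadata["time_point"] == time_point].tolist()
        return self.select_samples(ids)

    def individuals(self) -> list:
        if self.metadata is None:
            raise ValueError("table has no metadata")
        return self.metadata["individual_id"].unique().tolist()


@dataclasses.dataclass
class GlobalNetwork:
    """Symmetric weighted association network over labelled taxa.

    ``weights`` is a K x K real matrix with zero diagonal; ``node_ids``
    labels its rows/columns.  ``provenance`` is free text naming the
    estimator that produced the network (e.g. "pearson_clr fallback").
    """

    node_ids: list
    weights: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        k = len(self.node_ids)
        if self.weights.shape != (k, k):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match {k} node IDs"
            )
        if len(set(self.node_ids)) != k:
            raise ValueError("node IDs must be unique")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")
        if not np.allclose(self.weights, self.weights.T, rtol=SYMMETRY_RTOL, atol=1e-12):
            raise ValueError("weight matrix is asymmetric beyond tolerance")
        if np.abs(np.diag(self.weights)).max(initial=0.0) > 1e-12:
            raise ValueError("diagonal must be zero (no self-associations)")
        # exact symmetry / zero diagonal from here on
        self.weights = (self.weights + self.weights.T) / 2.0
        np.fill_diagonal(self.weights, 0.0)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_ids, columns=self.node_ids)

    def edge_list(self, include_zeros: bool = False) -> pd.DataFrame:
        """Each undirected edge once, nodes in lexicographic order."""
        rows = []
        order = np.argsort(np.asarray(self.node_ids, dtype=object))
        ids = [self.node_ids[i] for i in order]
        w = self.weights[np.ix_(order, order)]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if include_zeros or w[i, j] != 0.0:
                    rows.append((ids[i], ids[j], w[i, j]))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])


# ---------------------------------------------------------------------------
# abundance I/O
# ---------------------------------------------------------------------------


def read_abundance(
    path,
    metadata_path=None,
    taxonomy_path=None,
    taxa_rows: bool = False,
    transformed: bool = False,
) -> AbundanceTable:
    """Read an abundance TSV/CSV (and optional metadata/taxonomy TSVs).

    Orientation defaults to rows = samples; pass ``taxa_rows=True`` when
    taxa are on rows.  When metadata is supplied the orientation is
    auto-corrected if the metadata sample IDs match the columns instead of
    the rows.
    """
    path = Path(path)
    counts = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if taxa_rows:
        counts = counts.T
    metadata = None
    if metadata_path is not None:
        mpath = Path(metadata_path)
        metadata = pd.read_csv(mpath, sep=_sep_for(mpath), index_col=0)
        in_rows = metadata.index.isin(counts.index).sum()
        in_cols = metadata.index.isin(counts.columns).sum()
        if in_cols > in_rows:  # samples sit on the columns: flip
            counts = counts.T
    taxonomy = None
    if taxonomy_path is not None:
        tpath = Path(taxonomy_path)
        taxonomy = pd.read_csv(tpath, sep=_sep_for(tpath), index_col=0)
    return AbundanceTable(counts, metadata, taxonomy, transformed=transformed)


def write_abundance(table: AbundanceTable, path, metadata_path=None) -> None:
    path = Path(path)
    table.counts.to_csv(path, sep=_sep_for(path))
    if metadata_path is not None and table.metadata is not None:
        mpath = Path(metadata_path)
        table.metadata.to_csv(mpath, sep=_sep_for(mpath))


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------


def clr_transform(table: AbundanceTable, pseudocount: float = 0.5) -> AbundanceTable:
    """Centered log-ratio transform, sample by sample.

    Each sample row x is mapped to ``log(x + pseudocount) - mean(log(x +
    pseudocount))``, so every output row has mean zero across taxa.  The
    default pseudocount of 0.5 is the common half-count convention for
    count data; pass 0 only for strictly positive tables.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    x = table.counts.to_numpy(dtype=float) + pseudocount
    if (x <= 0).any():
        raise ValueError(
            "zero abundances with pseudocount 0: the log is undefined; "
            "use a positive pseudocount"
        )
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    out = pd.DataFrame(clr, index=table.counts.index, columns=table.counts.columns)
    return AbundanceTable(out, table.metadata, table.taxonomy, transformed=True)


def prevalence(table: AbundanceTable) -> pd.Series:
    """Fraction of samples in which each taxon has a nonzero count."""
    return (table.counts > 0).mean(axis=0)


def prevalence_filter(
    table: AbundanceTable, threshold: float = 0.15
) -> tuple[AbundanceTable, list, list]:
    """Retain taxa whose prevalence strictly exceeds ``threshold``.

    Prevalence is computed on the full sample set passed in (merge the
    time points first if the filter should act jointly).  Returns the
    filtered table plus the kept and dropped taxon IDs, order preserved.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    if table.n_samples == 0 or table.n_taxa == 0:
        raise ValueError("cannot filter an empty table")
    prev = prevalence(table)
    kept = [t for t in table.taxon_ids if prev[t] > threshold]
    dropped = [t for t in table.taxon_ids if prev[t] <= threshold]
    return table.select_taxa(kept), kept, dropped


def appearing_disappearing(
    table: AbundanceTable, threshold: float = 0.15
) -> dict[str, list]:
    """Classify taxa that pass the prevalence threshold at only one time point.

    *Appearing* taxa exceed the threshold among the later time point's
    samples but not on the merged sample set; *disappearing* taxa are the
    mirror image at the earlier time point.  Requires metadata with exactly
    two time points.
    """
    if table.metadata is None:
        raise ValueError("metadata with time points is required")
    times = table.time_points()
    if len(times) != 2:
        raise ValueError(f"exactly two time points required, found {times}")
    earlier, later = times
    prev_merged = prevalence(table)
    prev_early = prevalence(table.samples_at(earlier))
    prev_late = prevalence(table.samples_at(later))
    appearing = [
        t for t in table.taxon_ids
        if prev_late[t] > threshold and prev_merged[t] <= threshold
    ]
    disappearing = [
        t for t in table.taxon_ids
        if prev_early[t] > threshold and prev_merged[t] <= threshold
    ]
    return {"appearing_ids": appearing, "disappearing_ids": disappearing}


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------


def read_network(
    path,
    fmt: str = "auto",
    nodes: Sequence | None = None,
    symmetrize: bool = False,
    provenance: str = "",
) -> GlobalNetwork:
    """Read a network from a square matrix CSV or an edge-list TSV.

    ``fmt`` is one of ``{"auto", "matrix", "edgelist"}``.  For edge lists,
    ``nodes`` fixes the node universe (unknown nodes raise); without it the
    universe is the set of listed nodes.  ``symmetrize`` averages an
    asymmetric matrix instead of raising.
    """
    path = Path(path)
    sep = _sep_for(path)
    if fmt == "auto":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        fmt = "edgelist" if [h.strip().lower() for h in header] == ["node_a", "node_b", "weight"] else "matrix"
    if fmt == "matrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError("matrix network must have identical row and column labels")
        w = df.to_numpy(dtype=float)
        if symmetrize:
            w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        return GlobalNetwork(list(df.index), w, provenance=provenance)
    if fmt == "edgelist":
        df = pd.read_csv(path, sep=sep)
        expected = ["node_a", "node_b", "weight"]
        if list(df.columns) != expected:
            raise ValueError(f"edge list must have columns {expected}")
        df["node_a"] = df["node_a"].astype(str)
        df["node_b"] = df["node_b"].astype(str)
        if nodes is None:
            node_ids = sorted(set(df["node_a"]) | set(df["node_b"]))
        else:
            node_ids = [str(n) for n in nodes]
            unknown = (set(df["node_a"]) | set(df["node_b"])) - set(node_ids)
            if unknown:
                raise ValueError(f"unknown nodes in edge list: {sorted(unknown)}")
        idx = {n: i for i, n in enumerate(node_ids)}
        k = len(node_ids)
        w = np.zeros((k, k))
        seen: dict[tuple, float] = {}
        for a, b, weight in df.itertuples(index=False):
            key = (min(a, b), max(a, b))
            if key in seen:
                if seen[key] != weight:
                    raise ValueError(f"edge {key} listed twice with conflicting weights")
                warnings.warn(f"edge {key} listed twice with identical weight")
                continue
            seen[key] = weight
            w[idx[a], idx[b]] = weight
            w[idx[b], idx[a]] = weight
        return GlobalNetwork(node_ids, w, provenance=provenance)
    raise ValueError(f"unknown network format {fmt!r}")


def write_network(net: GlobalNetwork, path, fmt: str = "matrix") -> None:
    """Write a network as a square matrix CSV or an edge-list TSV.

    The edge-list writer emits each undirected edge once, nodes in
    lexicographic order, omitting zero-weight pairs.
    """
    path = Path(path)
    if fmt == "matrix":
        net.to_frame().to_csv(path, sep=_sep_for(path))
    elif fmt == "edgelist":
        net.edge_list().to_csv(path, sep=_sep_for(path), index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")
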