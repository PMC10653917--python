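"""Core containers and I/O for community-assembly analyses.

The canonical objects are a sample x taxon integer count table
(:class:`CommunityTable`), a rooted phylogeny over the taxa (a
:class:`skbio.TreeNode`), a per-taxon functional trait table
(:class:`TraitTable`), and per-sample measured community function
(:class:`FunctionMeasurements`).  Count tables stay integer throughout;
relative abundances are always derived on the fly, because rarefaction and
the Raup-Crick null both operate on integer read counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("ecoassembly")

__all__ = [
    "DataValidationError",
    "CommunityTable",
    "TraitTable",
    "FunctionMeasurements",
    "read_community_table",
    "write_community_table",
    "read_trait_table",
    "write_trait_table",
    "read_function_measurements",
    "write_function_measurements",
    "read_newick",
    "align_taxa",
    "rarefy",
    "relative_abundance",
]


class DataValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise DataValidationError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class CommunityTable:
    """Sample x taxon non-negative integer count matrix.

    Parameters
    ----------
    sample_ids : list of str
        Row identifiers (communities).
    taxon_ids : list of str
        Column identifiers (ASVs / species).
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative integer read counts.
    group_labels : dict, optional
        Mapping sample id -> group name (e.g. electron-donor group or
        dilution level).
    """

    sample_ids: list
    taxon_ids: list
    counts: np.ndarray
    group_labels: dict | None = None

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise DataValidationError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.taxon_ids)})"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, atol=0, rtol=0):
                raise DataValidationError("counts must be integers")
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            raise DataValidationError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.taxon_ids, "taxon ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def totals(self) -> np.ndarray:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    @property
    def richness(self) -> np.ndarray:
        """Number of taxa with non-zero count per sample."""
        return (self.counts > 0).sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_labels: dict | None = None) -> "CommunityTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(), group_labels)

    def select_samples(self, sample_ids) -> "CommunityTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        groups = None
        if self.group_labels is not None:
            groups = {s: self.group_labels[s] for s in sample_ids if s in self.group_labels}
        return CommunityTable(list(sample_ids), list(self.taxon_ids),
                              self.counts[idx], groups)

    def select_taxa(self, taxon_ids) -> "CommunityTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return CommunityTable(list(self.sample_ids), list(taxon_ids),
                              self.counts[:, idx], self.group_labels)


@dataclass
class TraitTable:
    """Per-taxon functional activities measured over a fixed incubation.

    ``sulfate_production`` and ``nitrate_consumption`` are in the same
    concentration units (e.g. mg/L of sulfate produced and nitrate consumed
    over the incubation).  ``tetrathionate_producer`` flags taxa whose
    thiosulfate oxidation stops at tetrathionate.
    """

    taxon_ids: list
    sulfate_production: np.ndarray
    nitrate_consumption: np.ndarray
    tetrathionate_producer: np.ndarray = None
    trait_type: list | None = None

    def __post_init__(self):
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        _check_unique(self.taxon_ids, "taxon ids")
        n = len(self.taxon_ids)
        self.sulfate_production = np.asarray(self.sulfate_production, dtype=float)
        self.nitrate_consumption = np.asarray(self.nitrate_consumption, dtype=float)
        if self.tetrathionate_producer is None:
            self.tetrathionate_producer = np.zeros(n, dtype=bool)
        self.tetrathionate_producer = np.asarray(self.tetrathionate_producer, dtype=bool)
        for name, arr in (("sulfate_production", self.sulfate_production),
                          ("nitrate_consumption", self.nitrate_consumption)):
            if arr.shape != (n,):
                raise DataValidationError(f"{name} must have one value per taxon")
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise DataValidationError(f"{name} must be finite and >= 0")
        if self.trait_type is not None and len(self.trait_type) != n:
            raise DataValidationError("trait_type must have one label per taxon")

    def trait(self, which: str) -> pd.Series:
        """Return one activity column indexed by taxon id."""
        return pd.Series(getattr(self, which), index=self.taxon_ids, name=which)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sulfate_production": self.sulfate_production,
                "nitrate_consumption": self.nitrate_consumption,
                "tetrathionate_producer": self.tetrathionate_producer,
            },
            index=pd.Index(self.taxon_ids, name="taxon_id"),
        )
        if self.trait_type is not None:
            df["trait_type"] = self.trait_type
        return df


@dataclass
class FunctionMeasurements:
    """Measured community function (one value per sample)."""

    sample_ids: list
    measured_function: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample ids")
        self.measured_function = np.asarray(self.measured_function, dtype=float)
        if self.measured_function.shape != (len(self.sample_ids),):
            raise DataValidationError("one measurement required per sample")
        if not np.isfinite(self.measured_function).all():
            raise DataValidationError("measurements must be finite")

    def to_series(self) -> pd.Series:
        return pd.Series(self.measured_function, index=self.sample_ids,
                         name="measured_function")


# ---------------------------------------------------------------------------
# I/O

def read_community_table(path, group_labels: dict | None = None) -> CommunityTable:
    """Read a TSV count table (first column ``sample_id``, taxa in columns)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2 or df.columns[0] != "sample_id":
        raise DataValidationError(
            f"{path}: expected a TSV whose first column is 'sample_id'"
        )
    df = df.set_index("sample_id")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise DataValidationError(f"{path}: non-numeric counts")
    if not np.allclose(values, np.rint(values), atol=0, rtol=0):
        raise DataValidationError(f"{path}: counts must be integers")
    if (values < 0).any():
        raise DataValidationError(f"{path}: counts must be non-negative")
    return CommunityTable.from_dataframe(df, group_labels)


def write_community_table(table: CommunityTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t")


def read_trait_table(path) -> TraitTable:
    df = pd.read_csv(path, dtype={"taxon_id": str}).set_index("taxon_id")
    required = {"sulfate_production", "nitrate_consumption"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing columns {sorted(missing)}")
    tetra = df["tetrathionate_producer"].astype(bool).to_numpy() \
        if "tetrathionate_producer" in df.columns else None
    types = list(df["trait_type"]) if "trait_type" in df.columns else None
    return TraitTable(list(df.index), df["sulfate_production"].to_numpy(),
                      df["nitrate_consumption"].to_numpy(), tetra, types)


def write_trait_table(traits: TraitTable, path) -> None:
    traits.to_dataframe().to_csv(path)


def read_function_measurements(path) -> FunctionMeasurements:
    df = pd.read_csv(path, dtype={"sample_id": str}).set_index("sample_id")
    if "measured_function" not in df.columns:
        raise DataValidationError(f"{path}: missing column 'measured_function'")
    return FunctionMeasurements(list(df.index), df["measured_function"].to_numpy())


def write_function_measurements(m: FunctionMeasurements, path) -> None:
    m.to_series().to_frame().rename_axis("sample_id").to_csv(path)


def read_newick(path) -> TreeNode:
    """Read a rooted Newick tree; unset branch lengths become 0 (warned)."""
    tree = TreeNode.read(str(path), format="newick")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise DataValidationError("negative branch length in tree")
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        logger.warning("%d branches had no length; set to 0", n_missing)
    tips = [t.name for t in tree.tips()]
    if any(t is None for t in tips):
        raise DataValidationError("tree contains unlabeled tips")
    _check_unique(tips, "tip labels")
    return tree


# ---------------------------------------------------------------------------
# Alignment, rarefaction, normalization

def align_taxa(table: CommunityTable, tree: TreeNode):
    """Restrict table and tree to their shared taxa (table order).

    Returns the pruned ``(table, tree)`` pair; dropped taxa are logged.
    Raises if the taxon sets are disjoint.
    """
    tips = {t.name for t in tree.tips()}
    shared = [t for t in table.taxon_ids if t in tips]
    if not shared:
        raise DataValidationError(
            "table and tree share no taxa "
            f"(table has {table.n_taxa}, tree has {len(tips)})"
        )
    dropped_table = [t for t in table.taxon_ids if t not in tips]
    dropped_tree = sorted(tips - set(shared))
    if dropped_table:
        logger.warning("dropping %d table taxa absent from tree: %s",
                       len(dropped_table), dropped_table)
    if dropped_tree:
        logger.warning("pruning %d tree tips absent from table: %s",
                       len(dropped_tree), dropped_tree)
    new_table = table if not dropped_table else table.select_taxa(shared)
    if dropped_tree:
        new_tree = tree.shear(shared)
        new_tree.prune()
    else:
        new_tree = tree
    return new_table, new_tree


def rarefy(table: CommunityTable, depth: int, seed: int | None = None) -> CommunityTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning,
    mirroring common amplicon practice.  Reproducible given ``seed``.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    keep, rows = [], []
    for i, sid in enumerate(table.sample_ids):
        total = int(table.counts[i].sum())
        if total < depth:
            logger.warning("dropping sample %s: %d reads < depth %d", sid, total, depth)
            continue
        if total == depth:
            rows.append(table.counts[i].copy())
        else:
            rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
        keep.append(sid)
    if not keep:
        raise DataValidationError(f"no sample reaches rarefaction depth {depth}")
    groups = None
    if table.group_labels is not None:
        groups = {s: g for s, g in table.group_labels.items() if s in keep}
    return CommunityTable(keep, list(table.taxon_ids),
                          np.asarray(rows, dtype=np.int64), groups)


def relative_abundance(table: CommunityTable) -> np.ndarray:
    """Row-normalized proportions; every row sums to 1."""
    totals = table.totals
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [table.sample_ids[i] for i in zero]
        raise DataValidationError(f"samples with zero total reads: {bad}")
    return table.counts / totals[:, None]
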