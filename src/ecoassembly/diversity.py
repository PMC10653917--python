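"""Alpha diversity, dissimilarity matrices, ordination and group tests.

Standard community-ecology descriptive statistics: Shannon diversity,
binary Jaccard and abundance-weighted Bray-Curtis dissimilarities,
classical principal coordinates analysis (PCoA), and PERMANOVA for testing
group differences in a distance matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova

from .core import CommunityTable, DataValidationError, relative_abundance

logger = logging.getLogger("ecoassembly")

__all__ = [
    "shannon",
    "jaccard_matrix",
    "bray_curtis_matrix",
    "OrdinationResult",
    "pcoa",
    "PermanovaResult",
    "permanova",
]


def shannon(table: CommunityTable) -> pd.Series:
    """Shannon diversity H = -sum p_i ln p_i per sample (natural log)."""
    p = relative_abundance(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=1), index=table.sample_ids, name="shannon")


def _condensed_to_dm(vec: np.ndarray, ids, what: str) -> DistanceMatrix:
    if np.isnan(vec).any():
        logger.warning("%s undefined for all-empty sample pairs; set to 0", what)
        vec = np.nan_to_num(vec, nan=0.0)
    return DistanceMatrix(squareform(vec, checks=False), ids=ids)


def jaccard_matrix(table: CommunityTable) -> DistanceMatrix:
    """Binary Jaccard distance: 1 - |shared| / |union| on presence/absence."""
    if table.n_samples < 2:
        raise DataValidationError("need >= 2 samples for a distance matrix")
    presence = table.counts > 0
    vec = pdist(presence, metric="jaccard")
    return _condensed_to_dm(vec, table.sample_ids, "Jaccard")


def bray_curtis_matrix(table: CommunityTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum x + sum y) on counts."""
    if table.n_samples < 2:
        raise DataValidationError("need >= 2 samples for a distance matrix")
    vec = pdist(table.counts.astype(float), metric="braycurtis")
    return _condensed_to_dm(vec, table.sample_ids, "Bray-Curtis")


@dataclass
class OrdinationResult:
    """Classical-scaling ordination of a distance matrix."""

    sample_ids: list
    coordinates: np.ndarray          # samples x axes, positive-eigenvalue axes
    eigenvalues: np.ndarray          # all eigenvalues, descending (may be < 0)
    proportion_explained: np.ndarray  # over positive eigenvalues only

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis (Gower-centered classical scaling).

    Negative eigenvalues are reported as-is and excluded from
    ``proportion_explained``; no Cailliez/Lingoes correction is applied.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n_axes is None:
        n_axes = n - 1
    if n_axes > n - 1:
        logger.warning("n_axes=%d clipped to %d (samples - 1)", n_axes, n - 1)
        n_axes = n - 1
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-12 * max(abs(eigvals[0]), 1.0)
    k = min(n_axes, int(pos.sum())) or 1
    lam = np.clip(eigvals[:k], 0.0, None)
    coords = eigvecs[:, :k] * np.sqrt(lam)
    pos_sum = eigvals[pos].sum()
    prop = (lam / pos_sum) if pos_sum > 0 else np.zeros(k)
    return OrdinationResult(list(dm.ids), coords, eigvals, prop)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """PERMANOVA with free permutation of sample labels (no strata).

    ``groups`` is a label per sample, aligned to ``dm.ids`` (a sequence or a
    mapping sample id -> label).  The p-value uses the standard
    (count + 1) / (n_perm + 1) estimator.
    """
    if isinstance(groups, dict):
        labels = [groups[s] for s in dm.ids]
    else:
        labels = list(groups)
    if len(labels) != len(dm.ids):
        raise DataValidationError("need one group label per sample")
    if len(set(labels)) < 2:
        raise DataValidationError("PERMANOVA needs >= 2 groups")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_permanova(dm, labels, permutations=n_perm, seed=seed)
    return PermanovaResult(float(res["test statistic"]), float(res["p-value"]),
                           n_perm, len(labels), len(set(labels)))
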