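"""Null-model quantification of ecological assembly processes.

Implements the two-step null-model framework used to partition pairwise
community turnover into five ecological processes:

1. Phylogenetic turnover.  beta-mean-nearest-taxon-distance (betaMNTD) is
   computed for every sample pair and standardized against a null that
   shuffles taxon identities across the tips of the phylogeny, giving the
   beta nearest taxon index (betaNTI).  betaNTI < -2 indicates homogeneous
   selection, betaNTI > 2 heterogeneous selection.
2. Taxonomic turnover.  Pairs with |betaNTI| <= 2 are further split with a
   Raup-Crick test built on Bray-Curtis (RC_bray): null communities preserve
   each sample's observed richness (taxa drawn without replacement with
   probability proportional to occurrence frequency) and observed read
   total (reads allocated proportionally to pool-wide relative abundances).
   RC_bray > 0.95 indicates dispersal limitation, RC_bray < -0.95
   homogenizing dispersal, and anything else is "undominated" (mainly
   drift).

Null draws are shared across pairs within an iteration by default (one tip
shuffle / one set of per-sample null assemblies per iteration); fully
independent per-pair nulls are available via ``shared_null=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import CommunityTable, DataValidationError, relative_abundance

logger = logging.getLogger("ecoassembly")

__all__ = [
    "PROCESSES",
    "cophenetic_distances",
    "beta_mntd",
    "beta_mntd_matrix",
    "BetaNTIResult",
    "beta_nti",
    "raup_crick_bray",
    "partition_processes",
    "PairwiseAssembly",
    "pairwise_assembly",
    "ProcessFractions",
    "process_fractions",
]

#: Assignable ecological processes, plus the degenerate "unassigned" label
#: used when the null distribution collapses (zero null standard deviation).
PROCESSES = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


def cophenetic_distances(tree: TreeNode, taxon_order=None):
    """Tip-to-tip patristic distance matrix.

    Returns ``(matrix, taxon_ids)`` with rows/columns ordered by
    ``taxon_order`` when given (otherwise tree tip order).
    """
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    mat = np.asarray(dm.data, dtype=float)
    if taxon_order is not None:
        missing = [t for t in taxon_order if t not in set(ids)]
        if missing:
            raise DataValidationError(f"taxa absent from tree: {missing}")
        idx = [ids.index(t) for t in taxon_order]
        mat = mat[np.ix_(idx, idx)]
        ids = list(taxon_order)
    return mat, ids


def _weights(counts: np.ndarray, weighted: bool) -> np.ndarray:
    """Per-sample taxon weights: relative abundance, or uniform over present."""
    counts = np.asarray(counts, dtype=float)
    present = counts > 0
    if weighted:
        w = counts / counts.sum(axis=-1, keepdims=True)
    else:
        w = present / present.sum(axis=-1, keepdims=True)
    return w


def beta_mntd(x, y, d: np.ndarray, weighted: bool = True) -> float:
    """betaMNTD between two abundance vectors over a cophenetic matrix.

    The mean (abundance-weighted by default) distance from each taxon in one
    community to its nearest taxon in the other, averaged over the two
    directions.  A taxon present in both communities is its own nearest
    neighbour (distance 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() <= 0 or y.sum() <= 0:
        raise DataValidationError("betaMNTD requires two non-empty communities")
    ix, iy = np.flatnonzero(x), np.flatnonzero(y)
    wx = _weights(x, weighted)[ix]
    wy = _weights(y, weighted)[iy]
    nn_x_to_y = d[np.ix_(ix, iy)].min(axis=1)
    nn_y_to_x = d[np.ix_(iy, ix)].min(axis=1)
    return 0.5 * (float(wx @ nn_x_to_y) + float(wy @ nn_y_to_x))


def _nearest_taxon_dists(d: np.ndarray, present_idx: list) -> np.ndarray:
    """nn[i, s] = min over taxa j present in sample s of d[i, j]."""
    n_taxa = d.shape[0]
    nn = np.empty((n_taxa, len(present_idx)))
    for s, idx in enumerate(present_idx):
        nn[:, s] = d[:, idx].min(axis=1)
    return nn


def _pairwise_bmntd_from_nn(nn: np.ndarray, present_idx, w: np.ndarray) -> np.ndarray:
    n_s = len(present_idx)
    out = np.zeros((n_s, n_s))
    for k in range(n_s):
        for m in range(k + 1, n_s):
            ik, im = present_idx[k], present_idx[m]
            v = 0.5 * (w[k, ik] @ nn[ik, m] + w[m, im] @ nn[im, k])
            out[k, m] = out[m, k] = v
    return out


def beta_mntd_matrix(table: CommunityTable, d: np.ndarray,
                     weighted: bool = True) -> np.ndarray:
    """Pairwise betaMNTD matrix for all samples of a table."""
    if d.shape != (table.n_taxa, table.n_taxa):
        raise DataValidationError("cophenetic matrix does not match table taxa")
    counts = table.counts
    if (counts.sum(axis=1) == 0).any():
        raise DataValidationError("betaMNTD requires non-empty samples")
    present_idx = [np.flatnonzero(row) for row in counts]
    w = _weights(counts, weighted)
    nn = _nearest_taxon_dists(d, present_idx)
    return _pairwise_bmntd_from_nn(nn, present_idx, w)


@dataclass
class BetaNTIResult:
    """Observed betaMNTD and its standardized effect size per sample pair."""

    sample_ids: list
    beta_mntd_obs: np.ndarray
    beta_nti: np.ndarray       # NaN where the null sd is 0 (undefined)
    null_mean: np.ndarray
    null_sd: np.ndarray


def _null_bmntd_stats(counts, d, weighted, n_null, rng, chunk=128):
    """Mean/sd of betaMNTD under uniform tip-label shuffles (shared null)."""
    n_s, n_t = counts.shape
    present_idx = [np.flatnonzero(row) for row in counts]
    w = _weights(counts, weighted)
    sums = np.zeros((n_s, n_s))
    sqsums = np.zeros((n_s, n_s))
    done = 0
    while done < n_null:
        b = min(chunk, n_null - done)
        perms = rng.permuted(np.tile(np.arange(n_t), (b, 1)), axis=1)
        # nn[b, i, s]: distance from taxon i to its nearest taxon of sample s
        # after relabeling taxa by perms[b].
        nn = np.empty((b, n_t, n_s))
        for s, idx in enumerate(present_idx):
            nn[:, :, s] = d[perms[:, :, None], perms[:, None, idx]].min(axis=2)
        for k in range(n_s):
            ik = present_idx[k]
            for m in range(k + 1, n_s):
                im = present_idx[m]
                v = 0.5 * (nn[:, ik, m] @ w[k, ik] + nn[:, im, k] @ w[m, im])
                sums[k, m] += v.sum()
                sqsums[k, m] += (v * v).sum()
        done += b
    mean = sums / n_null
    var = np.maximum(sqsums / n_null - mean ** 2, 0.0)
    mean += mean.T
    sd = np.sqrt(var)
    sd += sd.T
    return mean, sd


def beta_nti(table: CommunityTable, tree: TreeNode, n_null: int = 999,
             weighted: bool = True, seed: int | None = None,
             shared_null: bool = True) -> BetaNTIResult:
    """betaNTI for all sample pairs via tip-label randomization.

    Each null iteration reassigns taxa to tree tips uniformly at random and
    recomputes betaMNTD.  ``betaNTI = (obs - null mean) / null sd``; pairs
    whose null sd is zero (e.g. identical communities) are NaN.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    d, _ = cophenetic_distances(tree, taxon_order=table.taxon_ids)
    obs = beta_mntd_matrix(table, d, weighted=weighted)
    rng = np.random.default_rng(seed)
    if shared_null:
        mean, sd = _null_bmntd_stats(table.counts, d, weighted, n_null, rng)
    else:
        n_s = table.n_samples
        mean = np.zeros((n_s, n_s))
        sd = np.zeros((n_s, n_s))
        for k in range(n_s):
            for m in range(k + 1, n_s):
                sub = table.counts[[k, m]]
                mu, sg = _null_bmntd_stats(sub, d, weighted, n_null, rng)
                mean[k, m] = mean[m, k] = mu[0, 1]
                sd[k, m] = sd[m, k] = sg[0, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        nti = (obs - mean) / sd
    nti[sd == 0] = np.nan
    np.fill_diagonal(nti, np.nan)
    n_undef = int(np.isnan(nti[np.triu_indices_from(nti, k=1)]).sum())
    if n_undef:
        logger.warning("betaNTI undefined (zero null sd) for %d pairs", n_undef)
    return BetaNTIResult(list(table.sample_ids), obs, nti, mean, sd)


def _pairwise_min_sums(counts: np.ndarray) -> np.ndarray:
    """S[k, m] = sum_i min(counts[k, i], counts[m, i]) (Bray-Curtis core)."""
    n_s = counts.shape[0]
    out = np.zeros((n_s, n_s), dtype=np.int64)
    for k in range(n_s):
        np.minimum(counts[k], counts[k + 1:]).sum(axis=1, out=out[k, k + 1:])
    return out + out.T


def raup_crick_bray(table: CommunityTable, n_null: int = 999,
                    seed: int | None = None, chunk: int = 256) -> np.ndarray:
    """Raup-Crick standardized Bray-Curtis (RC_bray) for all sample pairs.

    Null communities preserve each sample's observed richness (taxa drawn
    without replacement with probability proportional to occurrence
    frequency across all samples) and observed read total (reads allocated
    multinomially, proportional to each taxon's summed relative abundance
    across samples).  ``RC = 2 * (P(null BC < obs) + 0.5 P(=) - 0.5)``,
    bounded in [-1, 1].  Because null totals equal observed totals,
    Bray-Curtis comparisons reduce to exact integer comparisons of the
    shared-read sums, so ties are counted exactly.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    counts = table.counts
    totals = table.totals
    if (totals == 0).any():
        raise DataValidationError("RC_bray requires positive sample totals")
    n_s, n_t = counts.shape
    occ = (counts > 0).sum(axis=0).astype(float)
    pool = occ > 0
    n_pool = int(pool.sum())
    richness = table.richness
    if (richness > n_pool).any():
        raise DataValidationError("sample richness exceeds occurring-taxon pool")
    log_occ = np.full(n_t, -np.inf)
    log_occ[pool] = np.log(occ[pool])
    abund = relative_abundance(table).sum(axis=0)
    abund = np.where(pool, abund, 0.0)

    rng = np.random.default_rng(seed)
    obs_sums = _pairwise_min_sums(counts)
    lower = np.zeros((n_s, n_s))
    ties = np.zeros((n_s, n_s))
    iu = np.triu_indices(n_s, k=1)

    done = 0
    while done < n_null:
        b = min(chunk, n_null - done)
        null_counts = np.zeros((b, n_s, n_t), dtype=np.int64)
        for s in range(n_s):
            r = int(richness[s])
            # Gumbel top-k == successive weighted draws without replacement.
            keys = log_occ[None, :] + rng.gumbel(size=(b, n_t))
            sel = np.argpartition(-keys, r - 1, axis=1)[:, :r]
            mask = np.zeros((b, n_t), dtype=bool)
            np.put_along_axis(mask, sel, True, axis=1)
            p = np.where(mask, abund[None, :], 0.0)
            p /= p.sum(axis=1, keepdims=True)
            null_counts[:, s, :] = rng.multinomial(int(totals[s]), p)
        for k, m in zip(*iu):
            smin = np.minimum(null_counts[:, k, :], null_counts[:, m, :]).sum(axis=1)
            # null BC < obs BC  <=>  null shared reads > observed shared reads
            lower[k, m] += (smin > obs_sums[k, m]).sum()
            ties[k, m] += (smin == obs_sums[k, m]).sum()
        done += b

    rc = np.full((n_s, n_s), np.nan)
    rc_raw = (lower[iu] + 0.5 * ties[iu]) / n_null
    rc[iu] = 2.0 * (rc_raw - 0.5)
    rc.T[iu] = rc[iu]
    return rc


def partition_processes(beta_nti: float, rc_bray: float | None = None) -> str:
    """Assign the ecological process for one pair from (betaNTI, RC_bray).

    betaNTI < -2: homogeneous selection; betaNTI > 2: heterogeneous
    selection.  Otherwise RC_bray > 0.95: dispersal limitation;
    RC_bray < -0.95: homogenizing dispersal; else undominated.  Boundary
    values fall to the stochastic/undominated side (the thresholds are
    strict inequalities).  Undefined (NaN/missing) inputs -> "unassigned".
    """
    if beta_nti is None or np.isnan(beta_nti):
        return "unassigned"
    if beta_nti < -2:
        return "homogeneous_selection"
    if beta_nti > 2:
        return "heterogeneous_selection"
    if rc_bray is None or np.isnan(rc_bray):
        return "unassigned"
    if rc_bray > 0.95:
        return "dispersal_limitation"
    if rc_bray < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


@dataclass
class PairwiseAssembly:
    """Per-pair turnover metrics and the assigned ecological process."""

    sample_pair: tuple
    beta_mntd_obs: float
    beta_nti: float
    bray_curtis_obs: float
    rc_bray: float
    process: str


def pairwise_assembly(table: CommunityTable, tree: TreeNode, n_null: int = 999,
                      weighted: bool = True, seed: int | None = None,
                      shared_null: bool = True) -> pd.DataFrame:
    """Run the full two-step framework for every sample pair.

    Returns a tidy DataFrame with one row per unordered sample pair:
    ``sample_i, sample_j, beta_mntd, beta_nti, bray_curtis, rc_bray,
    process``.  The two null models consume independent substreams derived
    from ``seed``.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    res = beta_nti(table, tree, n_null=n_null, weighted=weighted,
                   seed=ss[0], shared_null=shared_null)
    rc = raup_crick_bray(table, n_null=n_null, seed=ss[1])
    totals = table.totals.astype(float)
    smin = _pairwise_min_sums(table.counts).astype(float)
    bc = 1.0 - 2.0 * smin / (totals[:, None] + totals[None, :])
    rows = []
    for k in range(table.n_samples):
        for m in range(k + 1, table.n_samples):
            rows.append({
                "sample_i": table.sample_ids[k],
                "sample_j": table.sample_ids[m],
                "beta_mntd": res.beta_mntd_obs[k, m],
                "beta_nti": res.beta_nti[k, m],
                "bray_curtis": bc[k, m],
                "rc_bray": rc[k, m],
                "process": partition_processes(res.beta_nti[k, m], rc[k, m]),
            })
    return pd.DataFrame(rows)


@dataclass
class ProcessFractions:
    """Fraction of assigned pairs attributed to each process within a group."""

    group: str
    n_pairs: int
    n_unassigned: int
    fractions: dict

    def to_series(self) -> pd.Series:
        return pd.Series(self.fractions, name=self.group)


def process_fractions(pairs: pd.DataFrame, group: str = "all",
                      pair_filter=None) -> ProcessFractions:
    """Summarize per-pair process assignments into per-process fractions.

    ``pair_filter``, if given, is a boolean mask or a callable applied to
    the pairs DataFrame selecting which pairs belong to the group (e.g.
    both samples from one dilution level).  Fractions are over assigned
    pairs only; unassigned pairs are counted separately.
    """
    df = pairs
    if pair_filter is not None:
        mask = pair_filter(df) if callable(pair_filter) else pair_filter
        df = df[np.asarray(mask, dtype=bool)]
    n_unassigned = int((df["process"] == "unassigned").sum())
    assigned = df[df["process"] != "unassigned"]
    if len(assigned) == 0:
        raise DataValidationError(f"group {group!r} has no assigned pairs")
    fractions = {p: float((assigned["process"] == p).mean()) for p in PROCESSES}
    return ProcessFractions(group, len(assigned), n_unassigned, fractions)
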