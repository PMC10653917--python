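"""Trait-based structure-function linkage.

Community function is estimated as the abundance-weighted sum of species'
functional activities,

    F_est = sum_i f(x_i) * a(x_i),

where f(x_i) is taxon i's measured activity (e.g. sulfate produced over a
fixed incubation) and a(x_i) its relative abundance in the community.
Agreement between estimated and measured community function is tested by
ordinary least squares.  Taxa are also classifiable into three qualitative
thiosulfate-oxidation types: high sulfate yield with high nitrate
consumption (I), tetrathionate producers with low sulfate yield (II), and
low sulfate yield with little nitrate consumption (III).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import (CommunityTable, DataValidationError, FunctionMeasurements,
                   TraitTable, relative_abundance)

__all__ = [
    "FunctionEstimate",
    "estimate_community_function",
    "ConsistencyReport",
    "consistency_regression",
    "classify_trait_types",
]


@dataclass
class FunctionEstimate:
    """Abundance-weighted trait-sum estimate of community function.

    ``coverage`` is the summed relative abundance of taxa that have a trait
    value; taxa without traits contribute nothing to the estimate and only
    lower the coverage.
    """

    sample_ids: list
    estimated_function: np.ndarray
    coverage: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimated_function": self.estimated_function, "coverage": self.coverage},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def estimate_community_function(table: CommunityTable, traits: TraitTable,
                                which: str = "sulfate_production") -> FunctionEstimate:
    """Estimate per-sample community function as sum_i f(x_i) a(x_i).

    ``a(x_i)`` is the relative abundance in the full community (not
    renormalized over trait-bearing taxa); ``which`` selects the activity
    column of the trait table.
    """
    trait = traits.trait(which)
    shared = [t for t in table.taxon_ids if t in trait.index]
    if not shared:
        raise DataValidationError("table and trait table share no taxa")
    rel = relative_abundance(table)
    f = np.zeros(table.n_taxa)
    has = np.zeros(table.n_taxa, dtype=bool)
    for j, t in enumerate(table.taxon_ids):
        if t in trait.index:
            f[j] = trait[t]
            has[j] = True
    est = rel @ f
    cov = rel[:, has].sum(axis=1)
    return FunctionEstimate(list(table.sample_ids), est, cov)


@dataclass
class ConsistencyReport:
    """OLS fit of measured on estimated community function."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float   # coefficient test on the slope
    n: int
    slope_ci: tuple  # 95% confidence interval for the slope


def consistency_regression(estimate: FunctionEstimate,
                           measured: FunctionMeasurements) -> ConsistencyReport:
    """Regress measured community function on the trait-sum estimate."""
    est = pd.Series(estimate.estimated_function, index=estimate.sample_ids)
    obs = measured.to_series()
    shared = [s for s in est.index if s in obs.index]
    if len(shared) < 3:
        raise DataValidationError(
            f"need >= 3 overlapping samples, got {len(shared)}")
    x = est[shared].to_numpy()
    y = obs[shared].to_numpy()
    if np.ptp(x) == 0:
        raise DataValidationError("estimates have zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    ci = fit.conf_int(alpha=0.05)[1]
    return ConsistencyReport(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        n=len(shared),
        slope_ci=(float(ci[0]), float(ci[1])),
    )


def classify_trait_types(traits: TraitTable, sulfate_high_threshold: float,
                         nitrate_high_threshold: float) -> TraitTable:
    """Assign each taxon a thiosulfate-oxidation type (I, II or III).

    Type II: tetrathionate producers (thiosulfate oxidized only to
    tetrathionate, little sulfate).  Type I: sulfate production and nitrate
    consumption both at or above their thresholds.  Type III: the rest (low
    sulfate yield, little nitrate consumption).  Thresholds are
    user-supplied; the type boundaries are qualitative.
    """
    if sulfate_high_threshold <= 0 or nitrate_high_threshold <= 0:
        raise ValueError("trait-type thresholds must be positive")
    types = []
    for s, n, tetra in zip(traits.sulfate_production, traits.nitrate_consumption,
                           traits.tetrathionate_producer):
        if tetra:
            types.append("II")
        elif s >= sulfate_high_threshold and n >= nitrate_high_threshold:
            types.append("I")
        else:
            types.append("III")
    return replace(traits, trait_type=types)
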