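"""Phenotype adjustment: covariate residualisation, medication exclusion, scaling.

The scan consumes the residual of HDL on intercept + covariates (sex, age),
computed after excluding lipid-lowering-medication users, and optionally
standardised to mean 0 / SD 1 (population SD, denominator n). Interaction
t-scores are invariant under any affine transform of the phenotype, so the
scaled and unscaled analyses share t and p while the interaction coefficient
changes scale with the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genodata import GenotypeMatrix
from .synthcohort import CohortData

__all__ = ["AdjustedPhenotype", "adjust_phenotype", "scale_residuals", "adjusted_cohort"]


@dataclass(frozen=True)
class AdjustedPhenotype:
    """OLS residuals of the phenotype on intercept + covariates.

    ``keep_mask`` maps residuals back to the original individual columns
    (False where a medicated individual was excluded). Residuals are
    orthogonal to every covariate column by construction.
    """

    residuals: np.ndarray
    scaled: bool
    covariates_used: tuple[str, ...]
    keep_mask: np.ndarray

    @property
    def n(self) -> int:
        return self.residuals.size


def adjust_phenotype(
    hdl: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None,
    medication: np.ndarray | pd.Series | None = None,
    exclude_medicated: bool = True,
) -> AdjustedPhenotype:
    """Residualise HDL on intercept + covariates after medication exclusion.

    Raises on missing phenotype among retained individuals and on
    rank-deficient covariates (naming the collinear columns).
    """
    y = np.asarray(hdl, dtype=float)
    n_all = y.size
    keep = np.ones(n_all, dtype=bool)
    if exclude_medicated and medication is not None:
        keep = np.asarray(medication).astype(int) == 0
    y = y[keep]
    if np.isnan(y).any():
        raise ValueError("missing phenotype among retained individuals")

    names: tuple[str, ...] = ()
    X = np.ones((y.size, 1))
    if covariates is not None and len(covariates.columns):
        names = tuple(covariates.columns)
        C = covariates.to_numpy(dtype=float)[keep]
        X = np.column_stack([X, C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            # identify offending columns by incremental rank
            bad = []
            r = 1
            for k, col in enumerate(names):
                rk = np.linalg.matrix_rank(X[:, : k + 2])
                if rk == r:
                    bad.append(col)
                r = rk
            raise ValueError(f"collinear covariate columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return AdjustedPhenotype(resid, scaled=False, covariates_used=names, keep_mask=keep)


def scale_residuals(adj: AdjustedPhenotype) -> AdjustedPhenotype:
    """Standardise to mean 0, SD 1 (denominator n); idempotent."""
    if adj.n < 2:
        raise ValueError("need at least 2 individuals to scale")
    r = adj.residuals - adj.residuals.mean()
    sd = r.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance residuals cannot be scaled")
    return replace(adj, residuals=r / sd, scaled=True)


def adjusted_cohort(
    cohort: CohortData,
    scaled: bool = True,
    exclude_medicated: bool = True,
    covariates: tuple[str, ...] = ("sex", "age"),
) -> tuple[GenotypeMatrix, AdjustedPhenotype]:
    """Prepare one cohort for the scan: exclude, residualise, align, impute.

    Returns the genotype matrix restricted to retained individuals with
    missing calls mean-imputed, and the (optionally scaled) adjusted
    phenotype in the same individual order. Cohorts flagged
    ``include_medicated`` keep treated individuals regardless of the flag.
    """
    med = cohort.table["medication"] if "medication" in cohort.table else None
    if cohort.include_medicated:
        exclude_medicated = False
    adj = adjust_phenotype(
        cohort.table["hdl"],
        cohort.table[list(covariates)],
        medication=med,
        exclude_medicated=exclude_medicated,
    )
    if scaled:
        adj = scale_residuals(adj)
    G = cohort.genotypes
    sub = GenotypeMatrix(
        list(G.snp_names),
        G.counts[:, adj.keep_mask],
        [s for s, k in zip(G.sample_ids, adj.keep_mask) if k],
    )
    complete, _ = sub.impute_missing_mean()
    return complete, adj
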