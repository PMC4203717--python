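"""Stage-2 filtering: per-cohort refits, fixed-effects meta-analysis,
p < 1e-8 filtering, LD pruning of interaction terms, Bonferroni arithmetic.

Candidate pairs from the discovery scan are refit in every cohort, pooled by
inverse-variance fixed-effects meta-analysis (pooled beta = sum w_i b_i /
sum w_i with w_i = 1/se_i^2, pooled se = (sum w_i)^(-1/2), p from the
normal tail of |beta/se|), and filtered at a strict p < 1e-8. Surviving
terms are then collapsed on linkage disequilibrium between interaction
terms: two terms are redundant when their SNPs can be matched across terms
with both matched genotype r^2 values above the cut (default 0.8). The
count of kept terms sets the Bonferroni replication threshold 0.05/m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import GenotypeMatrix
from .pairscan import InteractionResult, t_to_p
from .phenoprep import adjusted_cohort
from .synthcohort import CohortData

__all__ = [
    "MetaResult",
    "PruneResult",
    "refit_pair",
    "fit_single_pair",
    "fixed_effects_meta",
    "filter_candidates",
    "ld_r2",
    "prune_interaction_terms",
    "meta_to_frame",
]


@dataclass(frozen=True)
class MetaResult:
    """Pooled interaction estimate across cohorts.

    ``direction_string`` has one character per requested cohort in the
    declared cohort order: '+', '-', or '?' where the pair was untestable.
    """

    snp1: str
    snp2: str
    beta: float
    se: float
    p: float
    k: int
    direction_string: str


@dataclass(frozen=True)
class PruneResult:
    kept: list[MetaResult]
    removed: list[tuple[MetaResult, MetaResult]]  # (dropped term, its kept representative)

    @property
    def m_effective(self) -> int:
        return len(self.kept)

    @property
    def bonferroni_alpha(self) -> float:
        return 0.05 / self.m_effective


def fit_single_pair(
    g1: np.ndarray, g2: np.ndarray, y: np.ndarray
) -> InteractionResult | None:
    """Four-parameter OLS for one pair; None when the design is degenerate."""
    n = y.size
    X = np.column_stack([np.ones(n), g1, g2, g1 * g2])
    XtX = X.T @ X
    if np.linalg.cond(XtX) > 1e12:
        return None
    inv = np.linalg.inv(XtX)
    beta = inv @ (X.T @ y)
    rss = float(y @ y - beta @ (X.T @ y))
    sigma2 = max(rss, 0.0) / (n - 4)
    se = float(np.sqrt(sigma2 * inv[3, 3]))
    t = float(beta[3] / se) if se > 0 else np.inf
    return InteractionResult(
        snp1="", snp2="", beta_int=float(beta[3]), se=se, t=t,
        p=float(t_to_p(t, n - 4)), n=n,
    )


def refit_pair(
    cohort: CohortData, pair: tuple[str, str], scaled: bool = True
) -> InteractionResult | None:
    """Refit one interaction term in one cohort; None marks untestable.

    Untestable means one or both SNPs are absent from the cohort's post-QC
    genotypes (mirroring replication cohorts where a SNP was never
    genotyped), not an exception. With ``scaled=False`` the refit uses the
    unscaled adjusted phenotype, giving the cross-cohort-comparable
    interaction coefficient.
    """
    s1, s2 = pair
    names = cohort.genotypes.snp_names
    if s1 not in names or s2 not in names:
        return None
    G, adj = adjusted_cohort(cohort, scaled=scaled)
    dose = G.dosage()
    i, j = names.index(s1), names.index(s2)
    res = fit_single_pair(dose[i], dose[j], adj.residuals)
    if res is None:
        return None
    return InteractionResult(s1, s2, res.beta_int, res.se, res.t, res.p, res.n)


def fixed_effects_meta(
    results: list[InteractionResult | None],
    snp1: str = "",
    snp2: str = "",
) -> MetaResult:
    """Inverse-variance fixed-effects pooling over cohorts.

    ``results`` is ordered by the declared cohort order; None entries
    (untestable) are skipped in the pooling but recorded as '?' in the
    direction string. Pooled p is the two-sided normal tail of |beta/se|.
    """
    testable = [r for r in results if r is not None]
    if not testable:
        raise ValueError("no testable cohort results to pool")
    if any(r.se <= 0 for r in testable):
        raise ValueError("all standard errors must be positive")
    w = np.array([1.0 / r.se**2 for r in testable])
    b = np.array([r.beta_int for r in testable])
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    directions = "".join(
        "?" if r is None else ("+" if r.beta_int >= 0 else "-") for r in results
    )
    if not snp1 and testable[0].snp1:
        snp1, snp2 = testable[0].snp1, testable[0].snp2
    return MetaResult(snp1, snp2, beta, se, p, len(testable), directions)


def filter_candidates(meta: list[MetaResult], p_max: float = 1e-8) -> list[MetaResult]:
    """Keep terms with pooled p strictly below p_max, sorted ascending by p."""
    kept = [m for m in meta if m.p < p_max]
    kept.sort(key=lambda m: (m.p, m.snp1, m.snp2))
    return kept


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of genotype counts (composite r^2).

    Phase is unavailable in the 0/1/2 data model, so this is count
    correlation, not haplotype r^2; it is invariant to allele flips.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if g1.std() == 0 or g2.std() == 0:
        raise ValueError("r^2 undefined for a constant genotype vector")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def prune_interaction_terms(
    terms: list[MetaResult], G: GenotypeMatrix, r2_min: float = 0.8
) -> PruneResult:
    """Collapse interaction terms redundant under LD into unique terms.

    Terms (A,B) and (C,D) are redundant iff some matching of their SNPs has
    both matched r^2 above ``r2_min``: (r2(A,C) > c and r2(B,D) > c) or
    (r2(A,D) > c and r2(B,C) > c). Greedy pruning in ascending pooled-p
    order keeps the most significant representative of each redundancy
    class; the kept count sets bonferroni_alpha = 0.05 / m_effective.
    """
    idx = {n: i for i, n in enumerate(G.snp_names)}
    for t in terms:
        if t.snp1 not in idx or t.snp2 not in idx:
            raise ValueError(f"SNP of term ({t.snp1}, {t.snp2}) missing from genotypes")
    dose = G.counts.astype(float)

    cache: dict[tuple[str, str], float] = {}

    def r2(a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a < b else (b, a)
        if key not in cache:
            cache[key] = ld_r2(dose[idx[a]], dose[idx[b]])
        return cache[key]

    def redundant(t1: MetaResult, t2: MetaResult) -> bool:
        a, b = t1.snp1, t1.snp2
        c, d = t2.snp1, t2.snp2
        return (r2(a, c) > r2_min and r2(b, d) > r2_min) or (
            r2(a, d) > r2_min and r2(b, c) > r2_min
        )

    ordered = sorted(terms, key=lambda m: (m.p, m.snp1, m.snp2))
    kept: list[MetaResult] = []
    removed: list[tuple[MetaResult, MetaResult]] = []
    for t in ordered:
        rep = next((k for k in kept if redundant(t, k)), None)
        if rep is None:
            kept.append(t)
        else:
            removed.append((t, rep))
    return PruneResult(kept, removed)


def meta_to_frame(meta: list[MetaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp1": m.snp1,
                "snp2": m.snp2,
                "beta": m.beta,
                "se": m.se,
                "p": m.p,
                "k": m.k,
                "directions": m.direction_string,
            }
            for m in meta
        ],
        columns=["snp1", "snp2", "beta", "se", "p", "k", "directions"],
    )
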