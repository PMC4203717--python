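"""Stage-3 replication: unscaled per-cohort refits, replication-only
meta-analysis, Bonferroni decisions, direction concordance, forest plots.

Each candidate term is refit with the unscaled adjusted phenotype in every
replication cohort (medication users excluded unless a cohort is flagged to
keep them), the per-cohort estimates are pooled by fixed-effects
meta-analysis over the replication cohorts only — discovery cohorts never
enter the replication pool — and the term is called replicated when the
pooled p falls strictly below the Bonferroni threshold 0.05/m set by the LD
pruning, or nominal at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metafilter import MetaResult, fixed_effects_meta, refit_pair
from .pairscan import InteractionResult
from .synthcohort import CohortData

__all__ = [
    "ReplicationEntry",
    "replicate_term",
    "replicate_all",
    "direction_concordance",
    "report_to_frame",
    "forest_plot",
]


@dataclass(frozen=True)
class ReplicationEntry:
    """Replication record for one interaction term.

    ``direction_string`` concatenates the replication-cohort signs with the
    discovery-cohort signs in the declared cohort order. Flags are pure
    functions of the stored p-values: replicated (pooled replication
    p < bonferroni_alpha) implies nominal (p < 0.05).
    """

    snp1: str
    snp2: str
    per_cohort: tuple[InteractionResult | None, ...]
    replication: MetaResult | None  # None when untestable everywhere
    discovery: MetaResult
    direction_string: str
    bonferroni_alpha: float

    @property
    def untestable(self) -> bool:
        return self.replication is None

    @property
    def replicated(self) -> bool:
        return self.replication is not None and self.replication.p < self.bonferroni_alpha

    @property
    def nominal(self) -> bool:
        return self.replication is not None and self.replication.p < 0.05


def replicate_term(
    discovery_meta: MetaResult,
    cohorts: list[CohortData],
    bonferroni_alpha: float,
) -> ReplicationEntry:
    """Test one term in the replication cohorts.

    Per-cohort OLS on the unscaled adjusted phenotype; cohorts where a SNP
    was not genotyped contribute '?' to the direction string and are skipped
    in the pooling. A term testable in no cohort is reported untestable.
    """
    pair = (discovery_meta.snp1, discovery_meta.snp2)
    fits = tuple(refit_pair(c, pair, scaled=False) for c in cohorts)
    testable = [f for f in fits if f is not None]
    rep_meta = (
        fixed_effects_meta(list(fits), *pair) if testable else None
    )
    rep_dirs = (
        rep_meta.direction_string
        if rep_meta is not None
        else "?" * len(cohorts)
    )
    direction = rep_dirs + discovery_meta.direction_string
    return ReplicationEntry(
        snp1=pair[0],
        snp2=pair[1],
        per_cohort=fits,
        replication=rep_meta,
        discovery=discovery_meta,
        direction_string=direction,
        bonferroni_alpha=bonferroni_alpha,
    )


def replicate_all(
    terms: list[MetaResult],
    cohorts: list[CohortData],
    bonferroni_alpha: float,
) -> list[ReplicationEntry]:
    entries = [replicate_term(t, cohorts, bonferroni_alpha) for t in terms]
    entries.sort(
        key=lambda e: (
            e.replication.p if e.replication is not None else np.inf,
            e.snp1,
            e.snp2,
        )
    )
    return entries


def direction_concordance(entry: ReplicationEntry) -> tuple[int, int]:
    """(concordant, testable) cohort signs vs the discovery pooled sign.

    Counts over the full direction string; '?' entries are excluded from
    both counts. All-untestable gives (0, 0).
    """
    ref = "+" if entry.discovery.beta >= 0 else "-"
    signs = [c for c in entry.direction_string if c != "?"]
    return sum(1 for c in signs if c == ref), len(signs)


def report_to_frame(entries: list[ReplicationEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        conc, total = direction_concordance(e)
        rows.append(
            {
                "snp1": e.snp1,
                "snp2": e.snp2,
                "directions": e.direction_string,
                "disc_beta": e.discovery.beta,
                "disc_se": e.discovery.se,
                "disc_p": e.discovery.p,
                "rep_beta": e.replication.beta if e.replication else np.nan,
                "rep_se": e.replication.se if e.replication else np.nan,
                "rep_p": e.replication.p if e.replication else np.nan,
                "replicated": e.replicated,
                "nominal": e.nominal,
                "concordant": conc,
                "testable": total,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp1", "snp2", "directions", "disc_beta", "disc_se", "disc_p",
            "rep_beta", "rep_se", "rep_p", "replicated", "nominal",
            "concordant", "testable",
        ],
    )


def forest_plot(entry: ReplicationEntry, cohort_names: list[str], ax=None):
    """Forest plot of per-cohort interaction estimates with 95% CIs."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.4 * (len(cohort_names) + 2) + 1))
    ys, labels = [], []
    y = 0
    for name, fit in zip(cohort_names, entry.per_cohort):
        if fit is not None:
            ax.errorbar(fit.beta_int, y, xerr=1.96 * fit.se, fmt="s", color="k")
        labels.append(name if fit is not None else f"{name} (untestable)")
        ys.append(y)
        y += 1
    if entry.replication is not None:
        ax.errorbar(
            entry.replication.beta, y, xerr=1.96 * entry.replication.se,
            fmt="D", color="tab:blue",
        )
        labels.append("pooled (replication)")
        ys.append(y)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(ys, labels)
    ax.invert_yaxis()
    ax.set_xlabel("interaction coefficient (95% CI)")
    ax.set_title(f"{entry.snp1} x {entry.snp2}")
    return ax
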