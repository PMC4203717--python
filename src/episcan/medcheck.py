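"""Medication case-control check and directional-consistency triage.

Does an interaction term predict lipid-lowering-medication use? Cases are
medication users with HDL available; controls are the (phenotype-
unrestricted, unmedicated) individuals of the discovery/filtering stage.
The logistic model is

    logit P(case) = b0 + b1*g1 + b2*g2 + b_int*g1*g2 [+ cohort indicators]

fit by maximum likelihood; the combined fit pools raw individuals across
cohorts with cohort-membership indicator columns, which is deliberately not
the same number as an inverse-variance meta-analysis of the per-cohort
fits.

The triage classifies each term by three signs: discovery HDL effect,
replication HDL effect, medication effect. Discovery/replication
disagreement marks a probable false positive (sign-discordant); an HDL
effect and a medication effect with the same sign is biologically
counterintuitive (raising HDL should not raise treatment odds); the
remaining pattern — e.g. lower HDL with higher medication odds — is
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .synthcohort import CohortData

__all__ = [
    "LogisticFit",
    "SeparationError",
    "ConsistencyCall",
    "fit_logistic",
    "casecontrol_term",
    "casecontrol_combined",
    "wald_p",
    "classify_consistency",
]


class SeparationError(RuntimeError):
    """Perfect (quasi-)separation: the MLE does not exist."""


@dataclass(frozen=True)
class LogisticFit:
    coef: np.ndarray
    se: np.ndarray
    names: tuple[str, ...]
    n_cases: int
    n_controls: int
    n_iter: int
    converged: bool

    def z(self) -> np.ndarray:
        return self.coef / self.se

    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z()))

    def __getitem__(self, name: str) -> tuple[float, float, float]:
        """(coef, se, p) for a named column."""
        i = self.names.index(name)
        return float(self.coef[i]), float(self.se[i]), float(self.p()[i])


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    names: tuple[str, ...] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton scoring (IRLS).

    ``X`` must include the intercept column. Converges when the largest
    coefficient change falls below ``tol``; Wald standard errors come from
    the inverse observed information. Divergence of the linear predictor
    (|eta| beyond ~30 while cases and controls are perfectly split by the
    fitted score) raises :class:`SeparationError` instead of returning a
    silently diverged fit.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("case labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    for j in range(1, X.shape[1]):
        if X[:, j].std() == 0:
            raise ValueError(f"constant non-intercept column {j}")

    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = mu * (1.0 - mu)
        if np.abs(eta).max() > 30:
            fitted_case = eta > 0
            if np.array_equal(fitted_case, y.astype(bool)):
                raise SeparationError("perfect separation: MLE diverges")
        info = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"information matrix singular: {exc}") from exc
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    se = np.sqrt(np.diag(cov))
    if names is None:
        names = tuple(f"x{j}" for j in range(X.shape[1]))
    return LogisticFit(
        coef=beta,
        se=se,
        names=tuple(names),
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        n_iter=it,
        converged=converged,
    )


def _casecontrol_design(
    cohorts: list[CohortData], pair: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack (y, g1, g2, cohort index) over cohorts for one term."""
    ys, g1s, g2s, cix = [], [], [], []
    for k, c in enumerate(cohorts):
        names = c.genotypes.snp_names
        if pair[0] not in names or pair[1] not in names:
            raise ValueError(f"pair {pair} not genotyped in cohort {c.name}")
        if "medication" not in c.table:
            raise ValueError(f"cohort {c.name} has no medication flag")
        med = c.table["medication"].to_numpy().astype(int)
        hdl_ok = ~pd.isna(c.table["hdl"].to_numpy())
        keep = hdl_ok  # cases need HDL available; controls are the scan sample
        dose = c.genotypes.counts.astype(float)
        i, j = names.index(pair[0]), names.index(pair[1])
        ys.append(med[keep])
        g1s.append(dose[i, keep])
        g2s.append(dose[j, keep])
        cix.append(np.full(keep.sum(), k))
    return (
        np.concatenate(ys),
        np.column_stack([np.concatenate(g1s), np.concatenate(g2s)]),
        np.concatenate(cix),
    )


def casecontrol_term(cohort: CohortData, pair: tuple[str, str]) -> LogisticFit:
    """Single-cohort case-control fit of one interaction term."""
    y, G2, _ = _casecontrol_design([cohort], pair)
    g1, g2 = G2[:, 0], G2[:, 1]
    X = np.column_stack([np.ones(y.size), g1, g2, g1 * g2])
    return fit_logistic(y, X, names=("intercept", "g1", "g2", "interaction"))


def casecontrol_combined(cohorts: list[CohortData], pair: tuple[str, str]) -> LogisticFit:
    """Pooled individual-level fit with cohort-membership indicators.

    With k cohorts the design gains k-1 indicator columns (first cohort is
    the reference). With a single cohort this reduces exactly to
    :func:`casecontrol_term`.
    """
    y, G2, cix = _casecontrol_design(cohorts, pair)
    g1, g2 = G2[:, 0], G2[:, 1]
    cols = [np.ones(y.size), g1, g2, g1 * g2]
    names = ["intercept", "g1", "g2", "interaction"]
    for k in range(1, len(cohorts)):
        cols.append((cix == k).astype(float))
        names.append(f"cohort_{cohorts[k].name}")
    return fit_logistic(y, np.column_stack(cols), names=tuple(names))


def wald_p(beta: float, se: float) -> float:
    """Two-sided normal-tail p for a Wald statistic beta/se."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(2.0 * stats.norm.sf(abs(beta / se)))


Verdict = Literal["consistent", "counterintuitive", "sign-discordant"]


@dataclass(frozen=True)
class ConsistencyCall:
    snp1: str
    snp2: str
    hdl_discovery_sign: str
    hdl_replication_sign: str
    medication_sign: str
    verdict: Verdict


def classify_consistency(
    hdl_discovery_sign: str,
    hdl_replication_sign: str,
    medication_sign: str,
    snp1: str = "",
    snp2: str = "",
) -> ConsistencyCall:
    """Directional triage of one term from its three effect signs.

    sign-discordant: discovery and replication HDL signs differ (probable
    false positive). counterintuitive: HDL and medication effects share a
    sign (e.g. raises HDL yet raises treatment odds). consistent: opposite
    HDL/medication signs — the term lowers HDL and raises the odds of
    lipid-lowering treatment, or vice versa.
    """
    for s in (hdl_discovery_sign, hdl_replication_sign, medication_sign):
        if s not in "+-":
            raise ValueError(f"sign must be '+' or '-', got {s!r}")
    if hdl_discovery_sign != hdl_replication_sign:
        verdict: Verdict = "sign-discordant"
    elif hdl_discovery_sign == medication_sign:
        verdict = "counterintuitive"
    else:
        verdict = "consistent"
    return ConsistencyCall(
        snp1, snp2, hdl_discovery_sign, hdl_replication_sign, medication_sign, verdict
    )
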