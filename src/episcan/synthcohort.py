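"""Synthetic multi-cohort genotype/phenotype/medication data.

Generates cohorts with the statistical structure the interaction scan
assumes: genotypes under Hardy-Weinberg equilibrium with a configurable MAF
spectrum and LD blocks, an HDL-like quantitative phenotype (mmol/L) with sex
and age covariate effects, marginal SNP effects, planted SNP x SNP
interaction effects and Gaussian noise, and a logistic lipid-lowering
medication-use process in which lower HDL raises the probability of
treatment.

LD blocks are generated by per-individual allele copy-with-flip from a block
founder SNP; the flip probability is solved numerically from the target
squared correlation, which makes the block structure oracle-checkable with a
sample correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genodata import GenotypeMatrix, write_glide_matrix

__all__ = [
    "MedModel",
    "SimSpec",
    "CohortData",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_medication",
    "simulate_cohort",
    "simulate_cohorts",
]


@dataclass(frozen=True)
class MedModel:
    """Logistic medication-use process.

    P(medicated) = logistic(intercept + hdl_slope * HDL [+ interaction_coef
    * g_a * g_b for the optional direct genotype-product term]). Defaults
    give roughly a 12% treated fraction at HDL ~ 1.45 mmol/L, with lower HDL
    raising the treatment probability.
    """

    intercept: float = 1.0
    hdl_slope: float = -2.0
    interaction_pair: tuple[int, int] | None = None
    interaction_coef: float = 0.0


@dataclass(frozen=True)
class SimSpec:
    """Full description of one synthetic cohort draw.

    Effects are in phenotype units (mmol/L of HDL): ``marginal_effects`` per
    minor-allele copy, ``interaction_effects`` per allele-count product
    (the generative analogue of the scanned interaction coefficient).
    ``ld_blocks`` lists (block size, within-block squared-correlation
    target); blocks occupy consecutive SNP indices from 0.
    """

    n_individuals: int = 1000
    n_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_blocks: tuple[tuple[int, float], ...] = ()
    marginal_effects: dict[int, float] = field(default_factory=dict)
    interaction_effects: dict[tuple[int, int], float] = field(default_factory=dict)
    noise_sd: float = 0.35
    intercept: float = 1.2
    sex_effect: float = 0.25
    age_effect: float = 0.002
    age_range: tuple[float, float] = (55.0, 80.0)
    med_model: MedModel = MedModel()
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.n_individuals < 8:
            raise ValueError("need at least 8 individuals")
        if self.n_snps < 0:
            raise ValueError("n_snps must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        total_block = sum(size for size, _ in self.ld_blocks)
        if total_block > self.n_snps:
            raise ValueError("LD blocks cover more SNPs than n_snps")
        for size, r2 in self.ld_blocks:
            if size < 1 or not (0.0 <= r2 <= 1.0):
                raise ValueError(f"invalid LD block ({size}, {r2})")
        for i, eff in self.marginal_effects.items():
            if not (0 <= i < self.n_snps):
                raise ValueError(f"marginal effect on unknown SNP index {i}")
        for (i, j) in self.interaction_effects:
            if i == j:
                raise ValueError("interaction pairs must reference distinct SNPs")
            if not (0 <= i < self.n_snps and 0 <= j < self.n_snps):
                raise ValueError(f"interaction effect on unknown SNP pair ({i}, {j})")


@dataclass
class CohortData:
    """One cohort: genotypes plus the phenotype/covariate/medication table.

    ``table`` columns: id, hdl (mmol/L), sex (0/1), age (years), medication
    (0/1, absent until :func:`simulate_medication` runs). ``include_medicated``
    marks cohorts that keep treated individuals in the replication analysis.
    """

    name: str
    genotypes: GenotypeMatrix
    table: pd.DataFrame
    include_medicated: bool = False

    @property
    def n(self) -> int:
        return len(self.table)

    def write(self, genotype_path, snp_names_path, pheno_path) -> None:
        write_glide_matrix(self.genotypes, genotype_path, snp_names_path)
        self.table.to_csv(pheno_path, sep="\t", index=False)


def _flip_prob_for_r2(maf: float, r2_target: float) -> float:
    """Allele flip probability achieving a given genotype r^2 with the founder.

    For founder allele frequency p and flip probability e, the copied allele
    has frequency q = p + e(1-2p) and allele (hence genotype) correlation
    r = (1-2e) sqrt(p(1-p) / (q(1-q))); solve r^2 = target on e in [0, 1/2].
    """
    if r2_target >= 1.0:
        return 0.0
    if r2_target <= 0.0:
        return 0.5
    p = maf

    def gap(e: float) -> float:
        q = p + e * (1 - 2 * p)
        return (1 - 2 * e) ** 2 * p * (1 - p) / (q * (1 - q)) - r2_target

    return brentq(gap, 0.0, 0.5, xtol=1e-12)


def simulate_genotypes(spec: SimSpec, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw a genotype matrix under HWE with the requested LD-block structure.

    Each SNP is the sum of two independent allele draws; within a block,
    non-founder SNPs copy the founder's alleles with a flip probability
    solved from the block's squared-correlation target.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n, m = spec.n_individuals, spec.n_snps
    mafs = rng.uniform(*spec.maf_range, size=m)
    alleles = np.empty((m, n, 2), dtype=np.int8)

    block_start = 0
    copies: list[tuple[int, int, float]] = []  # (copy SNP, founder, flip prob)
    block_members: set[int] = set()
    for size, r2 in spec.ld_blocks:
        founder = block_start
        for k in range(block_start, block_start + size):
            block_members.add(k)
            if k != founder:
                copies.append((k, founder, _flip_prob_for_r2(mafs[founder], r2)))
                mafs[k] = mafs[founder]  # marginal frequency shifts only via flips
        block_start += size

    for i in range(m):
        if not any(i == snp for snp, _, _ in copies):
            alleles[i] = rng.random((n, 2)) < mafs[i]
    for snp, founder, eps in copies:
        flips = rng.random((n, 2)) < eps
        alleles[snp] = alleles[founder] ^ flips

    counts = alleles.sum(axis=2).astype(np.int8)
    names = [f"rs{i + 1:06d}" for i in range(m)]
    return GenotypeMatrix(names, counts)


def simulate_phenotype(
    G: GenotypeMatrix,
    spec: SimSpec,
    rng: np.random.Generator | None = None,
    effect_scale: float = 1.0,
    name: str = "cohort",
) -> CohortData:
    """Attach the HDL-like phenotype and covariates to a genotype draw.

    hdl = intercept + sex_effect*sex + age_effect*age
          + sum marginal_j * g_j + sum interaction_(a,b) * g_a * g_b
          + Normal(0, noise_sd),
    with sex ~ Bernoulli(1/2) and age ~ Uniform(age_range). ``effect_scale``
    multiplies every genetic effect (0 gives a pure-null cohort with the
    same covariate structure, mimicking a failed replication).
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    for i in spec.marginal_effects:
        if i >= G.n_snps:
            raise ValueError(f"marginal effect on unknown SNP index {i}")
    for (i, j) in spec.interaction_effects:
        if max(i, j) >= G.n_snps:
            raise ValueError(f"interaction effect on unknown SNP pair ({i}, {j})")
    n = G.n_individuals
    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.uniform(*spec.age_range, size=n)
    dose = G.counts.astype(float)
    y = spec.intercept + spec.sex_effect * sex + spec.age_effect * age
    for i, eff in spec.marginal_effects.items():
        y = y + effect_scale * eff * dose[i]
    for (i, j), eff in spec.interaction_effects.items():
        y = y + effect_scale * eff * dose[i] * dose[j]
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n)
    table = pd.DataFrame(
        {
            "id": [f"{name}_ind{k}" for k in range(n)],
            "hdl": y,
            "sex": sex.astype(int),
            "age": age,
        }
    )
    return CohortData(name=name, genotypes=G, table=table)


def simulate_medication(
    cohort: CohortData, spec: SimSpec, rng: np.random.Generator | None = None
) -> CohortData:
    """Draw the medication flag from the logistic treatment process."""
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    if "hdl" not in cohort.table:
        raise ValueError("phenotype must be simulated before medication")
    mm = spec.med_model
    eta = mm.intercept + mm.hdl_slope * cohort.table["hdl"].to_numpy()
    if mm.interaction_pair is not None:
        a, b = mm.interaction_pair
        dose = cohort.genotypes.counts.astype(float)
        eta = eta + mm.interaction_coef * dose[a] * dose[b]
    prob = 1.0 / (1.0 + np.exp(-eta))
    med = (rng.random(cohort.n) < prob).astype(int)
    table = cohort.table.copy()
    table["medication"] = med
    return CohortData(cohort.name, cohort.genotypes, table, cohort.include_medicated)


def simulate_cohort(spec: SimSpec, name: str = "cohort", effect_scale: float = 1.0) -> CohortData:
    """One cohort end to end: genotypes, phenotype, medication flag."""
    rng = np.random.default_rng(spec.seed)
    G = simulate_genotypes(spec, rng)
    cohort = simulate_phenotype(G, spec, rng, effect_scale=effect_scale, name=name)
    return simulate_medication(cohort, spec, rng)


def simulate_cohorts(
    spec: SimSpec,
    names: list[str],
    replication_effect_scale: float = 1.0,
    n_replication_from: int | None = None,
    n_individuals: dict[str, int] | None = None,
) -> list[CohortData]:
    """Emit several cohorts with identical effects but independent draws.

    Cohorts from index ``n_replication_from`` onward have their genetic
    effects multiplied by ``replication_effect_scale`` (0 gives pure-null
    replication cohorts). Per-cohort sample sizes can override the spec.
    Seeds are spawned deterministically from ``spec.seed``.
    """
    children = np.random.SeedSequence(spec.seed).spawn(len(names))
    out = []
    for k, (name, ss) in enumerate(zip(names, children)):
        sub_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        sub = replace(
            spec,
            seed=sub_seed,
            n_individuals=(n_individuals or {}).get(name, spec.n_individuals),
        )
        scale = 1.0
        if n_replication_from is not None and k >= n_replication_from:
            scale = replication_effect_scale
        out.append(simulate_cohort(sub, name=name, effect_scale=scale))
    return out
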