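"""Genotype matrices in the GLIDE text layout, plus per-SNP quality control.

The scan engine consumes a plain-text genotype matrix with one row per SNP
and one column per individual, minor-allele counts coded 0/1/2, no headers,
and SNP names in a parallel one-column file. QC follows the Rotterdam rules:
exclude SNPs with MAF < 0.05 (optionally computed on pooled cohorts),
call rate < 0.95, or Hardy-Weinberg exact-test p < 1e-7, applied in that
fixed order so each exclusion names exactly one triggering rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeMatrix",
    "QcReport",
    "GenotypeFormatError",
    "read_glide_matrix",
    "write_glide_matrix",
    "hwe_exact_test",
    "qc_filter",
]

MISSING = -1  # internal sentinel for a missing call


class GenotypeFormatError(ValueError):
    """Raised when a genotype file violates the 0/1/2 text layout."""


@dataclass
class GenotypeMatrix:
    """SNP-by-individual minor-allele-count matrix.

    ``counts`` is an int8 array of shape (n_snps, n_individuals) with values
    in {0, 1, 2} or :data:`MISSING`. SNP names are unique, ordered, and row
    counts agree with the name list by construction.
    """

    snp_names: list[str]
    counts: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.counts.ndim != 2:
            self.counts = self.counts.reshape(len(self.snp_names), -1)
        if len(self.snp_names) != self.counts.shape[0]:
            raise ValueError(
                f"{len(self.snp_names)} SNP names for {self.counts.shape[0]} genotype rows"
            )
        if len(set(self.snp_names)) != len(self.snp_names):
            raise ValueError("SNP names are not unique")
        valid = np.isin(self.counts, (0, 1, 2, MISSING))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise GenotypeFormatError(
                f"genotype {self.counts[i, j]} at SNP row {i}, individual {j} "
                "is not in {0, 1, 2, missing}"
            )
        if not self.sample_ids:
            self.sample_ids = [f"ind{j}" for j in range(self.counts.shape[1])]
        if len(self.sample_ids) != self.counts.shape[1]:
            raise ValueError("sample_ids length does not match individual count")

    @property
    def n_snps(self) -> int:
        return self.counts.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.counts == MISSING

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        if self.n_individuals == 0:
            return np.ones(self.n_snps)
        return 1.0 - self.missing_mask().mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (minor-oriented) allele per SNP."""
        c = np.ma.masked_equal(self.counts, MISSING)
        with np.errstate(invalid="ignore"):
            f = np.ma.filled(c.mean(axis=1), np.nan) / 2.0
        return f

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def recode_to_minor(self) -> "GenotypeMatrix":
        """Flip SNPs whose counted allele has frequency > 0.5 to 2 - g."""
        counts = self.counts.copy()
        flip = self.allele_freq() > 0.5
        rows = counts[flip]
        miss = rows == MISSING
        rows = 2 - rows
        rows[miss] = MISSING
        counts[flip] = rows
        return GenotypeMatrix(list(self.snp_names), counts, list(self.sample_ids))

    def genotype_counts(self) -> np.ndarray:
        """(n_snps, 3) table of 0/1/2 counts, missing excluded."""
        out = np.empty((self.n_snps, 3), dtype=np.int64)
        for k in range(3):
            out[:, k] = (self.counts == k).sum(axis=1)
        return out

    def hwe_p(self) -> np.ndarray:
        gc = self.genotype_counts()
        return np.array(
            [
                hwe_exact_test(a, b, c) if a + b + c > 0 else np.nan
                for a, b, c in gc
            ]
        )

    def impute_missing_mean(self) -> tuple["GenotypeMatrix", float]:
        """Replace missing calls with the per-SNP rounded mean genotype.

        The scan requires a complete matrix; call-rate QC bounds the imputed
        fraction. Returns the completed matrix and the fraction imputed.
        """
        miss = self.missing_mask()
        frac = float(miss.mean()) if miss.size else 0.0
        if frac == 0.0:
            return self, 0.0
        counts = self.counts.astype(np.float64)
        counts[miss] = np.nan
        means = np.nanmean(counts, axis=1)
        means = np.where(np.isnan(means), 0.0, means)
        fill = np.clip(np.rint(means), 0, 2).astype(np.int8)
        filled = self.counts.copy()
        for i in np.flatnonzero(miss.any(axis=1)):
            filled[i, miss[i]] = fill[i]
        return GenotypeMatrix(list(self.snp_names), filled, list(self.sample_ids)), frac

    def dosage(self) -> np.ndarray:
        """float64 view of the counts; raises if any call is missing."""
        if self.missing_mask().any():
            raise ValueError("matrix contains missing calls; impute before the scan")
        return self.counts.astype(np.float64)

    def subset_snps(self, names: list[str]) -> "GenotypeMatrix":
        idx = {n: i for i, n in enumerate(self.snp_names)}
        rows = [idx[n] for n in names]
        return GenotypeMatrix(list(names), self.counts[rows], list(self.sample_ids))


def read_glide_matrix(
    genotype_path,
    snp_names_path,
    missing_token: str = "NA",
) -> GenotypeMatrix:
    """Read the GLIDE text layout: one row per SNP, one column per individual.

    Whitespace-delimited, no headers; genotypes are 0/1/2 with
    ``missing_token`` (default ``"NA"``) marking missing calls.
    """
    with open(snp_names_path) as fh:
        names = [line.strip() for line in fh if line.strip()]
    rows: list[list[int]] = []
    width = None
    with open(genotype_path) as fh:
        for i, line in enumerate(fh):
            tokens = line.split()
            if not tokens:
                continue
            if width is None:
                width = len(tokens)
            elif len(tokens) != width:
                raise GenotypeFormatError(
                    f"row {i} has {len(tokens)} fields, expected {width}"
                )
            row = []
            for j, tok in enumerate(tokens):
                if tok == missing_token:
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise GenotypeFormatError(
                        f"invalid genotype token {tok!r} at row {i}, column {j}"
                    )
            rows.append(row)
    if len(rows) != len(names):
        raise GenotypeFormatError(
            f"{len(names)} SNP names but {len(rows)} genotype rows"
        )
    counts = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, width or 0), dtype=np.int8)
    )
    return GenotypeMatrix(names, counts)


def write_glide_matrix(
    G: GenotypeMatrix, genotype_path, snp_names_path, missing_token: str = "NA"
) -> None:
    """Write the matrix back to the GLIDE text layout (round-trip exact)."""
    with open(genotype_path, "w") as fh:
        for row in G.counts:
            fh.write(
                " ".join(missing_token if v == MISSING else str(v) for v in row) + "\n"
            )
    with open(snp_names_path, "w") as fh:
        for name in G.snp_names:
            fh.write(name + "\n")


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote configuration no more probable than the observed one
    (plain exact two-sided test, no mid-p). The conditional distribution of
    the heterozygote count n_het given n individuals and n_minor copies of
    the minor allele is

        P(n_het) = n! / (n_hom_min! n_het! n_hom_maj!) *
                   2^n_het * n_minor! n_major! / (2n)!

    computed in log space for stability at large n.
    """
    a, b, c = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(a, b, c) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = a + b + c
    if n < 1:
        raise ValueError("HWE test undefined for zero individuals")
    n_minor = min(2 * a + b, 2 * c + b)
    # heterozygote count shares the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == b][0]
    # tolerance absorbs round-off when comparing equal probabilities
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


@dataclass
class QcReport:
    """Per-SNP QC metrics with pass/fail flags and the first failing rule."""

    table: pd.DataFrame  # columns: snp, maf, call_rate, hwe_p, passed, fail_rule

    @property
    def excluded(self) -> pd.DataFrame:
        return self.table[~self.table["passed"]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def qc_filter(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    callrate_min: float = 0.95,
    hwe_min: float = 1e-7,
    maf_pooled_over: list[GenotypeMatrix] | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the MAF / call-rate / HWE exclusion rules.

    MAF is computed on the samples pooled across ``maf_pooled_over`` (which
    must share G's SNP ordering) when given, else on ``G`` alone; call rate
    and HWE are always per-cohort. Rules are checked in the fixed order
    MAF -> call rate -> HWE so each excluded SNP reports one rule.
    """
    if maf_pooled_over:
        for other in maf_pooled_over:
            if other.snp_names != G.snp_names:
                raise ValueError("pooled cohorts must share the SNP set and order")
        pooled = np.concatenate(
            [G.counts] + [other.counts for other in maf_pooled_over], axis=1
        )
        maf = GenotypeMatrix(list(G.snp_names), pooled).maf()
    else:
        maf = G.maf()
    call_rate = G.call_rate()
    hwe_p = G.hwe_p()

    fail_rule = np.array([""] * G.n_snps, dtype=object)
    with np.errstate(invalid="ignore"):
        bad_maf = ~(maf >= maf_min)  # NaN MAF (all-missing SNP) fails too
        bad_cr = call_rate < callrate_min
        bad_hwe = hwe_p < hwe_min
    fail_rule[bad_hwe] = "hwe"
    fail_rule[bad_cr] = "call_rate"
    fail_rule[bad_maf] = "maf"
    passed = fail_rule == ""

    report = QcReport(
        pd.DataFrame(
            {
                "snp": G.snp_names,
                "maf": maf,
                "call_rate": call_rate,
                "hwe_p": hwe_p,
                "passed": passed,
                "fail_rule": fail_rule,
            }
        )
    )
    kept = [n for n, ok in zip(G.snp_names, passed) if ok]
    return G.subset_snps(kept), report
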