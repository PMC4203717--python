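"""Shared study design for the analysis drivers.

Six synthetic cohorts mirror the study layout: one discovery cohort, two
filter cohorts of similar size, and three larger replication cohorts. All
six share one planted SNP x SNP interaction (0.45 mmol/L per allele-count
product, SNPs rs000006 x rs000021) plus an LD duplicate of the first block
SNP, on 30 SNPs — sized so the full flow runs in seconds while every stage
has work to do.
"""

from episcan.synthcohort import SimSpec

SEED = 2014

SPEC = SimSpec(
    n_individuals=700,
    n_snps=30,
    noise_sd=0.35,
    interaction_effects={(5, 20): 0.45},
    ld_blocks=((2, 0.95),),
    seed=SEED,
)

DISCOVERY = "RS-I"
FILTER = ("RS-II", "RS-III")
REPLICATION = ("REP-A", "REP-B", "REP-C")
ALL_COHORTS = [DISCOVERY, *FILTER, *REPLICATION]
COHORT_SIZES = {DISCOVERY: 700, "RS-II": 700, "RS-III": 700,
                "REP-A": 1500, "REP-B": 1500, "REP-C": 1500}

COHORT_DIR = "scratch/cohorts"
RESULTS_DIR = "results"


def cohort_paths(name: str):
    base = f"{COHORT_DIR}/{name}"
    return f"{base}.geno", f"{base}.snps", f"{base}.pheno"


def load_all():
    from episcan.pipeline import load_cohort

    return [load_cohort(*cohort_paths(n), n) for n in ALL_COHORTS]
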