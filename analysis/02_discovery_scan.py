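"""Discovery stage: QC the discovery/filter cohorts, scan all SNP pairs.

QC applies the MAF >= 0.05 (pooled over the three discovery/filter
cohorts), call rate >= 0.95 and HWE p >= 1e-7 rules; the scan then fits the
four-parameter interaction model for every unique SNP pair of the discovery
cohort on sex/age-adjusted, standardised HDL residuals and keeps |t| >= 5.
"""

import pandas as pd

from episcan.genodata import qc_filter
from episcan.pairscan import ScanConfig, results_to_frame, scan_pairs, t_to_p, unique_pair_count
from episcan.phenoprep import adjusted_cohort
from episcan.synthcohort import CohortData
from studydesign import DISCOVERY, FILTER, RESULTS_DIR, load_all

cohorts = {c.name: c for c in load_all()}
stage = [cohorts[DISCOVERY], *(cohorts[n] for n in FILTER)]

keep = None
for c in stage:
    others = [o.genotypes for o in stage if o is not c]
    kept, report = qc_filter(c.genotypes, maf_pooled_over=others)
    report.to_csv(f"{RESULTS_DIR}/02_qc_{c.name}.tsv")
    names = set(kept.snp_names)
    keep = names if keep is None else keep & names
    print(f"qc[{c.name}]: {len(kept.snp_names)}/{c.genotypes.n_snps} SNPs pass")

keep_ordered = [n for n in stage[0].genotypes.snp_names if n in keep]
disc = CohortData(
    DISCOVERY, cohorts[DISCOVERY].genotypes.subset_snps(keep_ordered),
    cohorts[DISCOVERY].table,
)
G, adj = adjusted_cohort(disc, scaled=True)
hits = scan_pairs(G, adj, ScanConfig(t_threshold=5.0))
results_to_frame(hits).to_csv(f"{RESULTS_DIR}/02_scan_hits.tsv", sep="\t", index=False)

m = unique_pair_count(len(keep_ordered))
print(f"\nscan[{DISCOVERY}]: {len(hits)} of {m} unique pairs at |t| >= 5 "
      f"(p < {t_to_p(5.0, adj.n - 4):.3g}, n = {adj.n})")
for h in hits:
    print(f"  {h.snp1} x {h.snp2}: beta_int = {h.beta_int:+.3f}, t = {h.t:+.2f}, p = {h.p:.3g}")
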