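"""Filtering stage: refit scan hits in all three discovery/filter cohorts,
pool by fixed-effects meta-analysis, filter at p < 1e-8, LD-prune the
surviving interaction terms and set the Bonferroni replication threshold.
"""

import json

import pandas as pd

from episcan.metafilter import (
    filter_candidates,
    fixed_effects_meta,
    meta_to_frame,
    prune_interaction_terms,
    refit_pair,
)
from studydesign import DISCOVERY, FILTER, RESULTS_DIR, load_all

cohorts = {c.name: c for c in load_all()}
stage = [cohorts[DISCOVERY], *(cohorts[n] for n in FILTER)]

hits = pd.read_csv(f"{RESULTS_DIR}/02_scan_hits.tsv", sep="\t")
meta = []
for row in hits.itertuples():
    fits = [refit_pair(c, (row.snp1, row.snp2), scaled=True) for c in stage]
    meta.append(fixed_effects_meta(fits, row.snp1, row.snp2))
meta_to_frame(meta).to_csv(f"{RESULTS_DIR}/03_meta_all.tsv", sep="\t", index=False)

filtered = filter_candidates(meta, p_max=1e-8)
meta_to_frame(filtered).to_csv(f"{RESULTS_DIR}/03_meta_filtered.tsv", sep="\t", index=False)
print(f"meta filter: {len(filtered)}/{len(meta)} terms with pooled p < 1e-8")
for m in filtered:
    print(f"  {m.snp1} x {m.snp2}: beta = {m.beta:+.3f} (se {m.se:.3f}), "
          f"p = {m.p:.3g}, directions {m.direction_string}")

prune = prune_interaction_terms(filtered, stage[0].genotypes, r2_min=0.8)
meta_to_frame(prune.kept).to_csv(f"{RESULTS_DIR}/03_terms_pruned.tsv", sep="\t", index=False)
summary = {
    "filtered_terms": len(filtered),
    "m_effective": prune.m_effective,
    "bonferroni_alpha": prune.bonferroni_alpha if prune.m_effective else None,
    "removed_as_ld_duplicates": len(prune.removed),
}
with open(f"{RESULTS_DIR}/03_prune_summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)
print(f"\nLD pruning (r^2 > 0.8): {prune.m_effective} unique terms; "
      f"Bonferroni alpha = {summary['bonferroni_alpha']:.3g}"
      if prune.m_effective else "no terms survived")
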