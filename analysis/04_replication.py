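"""Replication stage: unscaled refits in the held-out cohorts, replication
meta-analysis, Bonferroni and nominal calls, direction strings, forest plot.
"""

import json
from pathlib import Path

import pandas as pd

from episcan.metafilter import MetaResult
from episcan.replicate import forest_plot, replicate_all, report_to_frame
from studydesign import REPLICATION, RESULTS_DIR, load_all

cohorts = {c.name: c for c in load_all()}
rep_cohorts = [cohorts[n] for n in REPLICATION]

pruned = pd.read_csv(f"{RESULTS_DIR}/03_terms_pruned.tsv", sep="\t")
bonferroni = json.load(open(f"{RESULTS_DIR}/03_prune_summary.json"))["bonferroni_alpha"]
terms = [
    MetaResult(r.snp1, r.snp2, r.beta, r.se, r.p, int(r.k), str(r.directions))
    for r in pruned.itertuples()
]

entries = replicate_all(terms, rep_cohorts, bonferroni)
frame = report_to_frame(entries)
frame.to_csv(f"{RESULTS_DIR}/04_replication.tsv", sep="\t", index=False)

print(f"replication in {', '.join(REPLICATION)} at Bonferroni alpha = {bonferroni:.3g}:")
for e in entries:
    if e.replication is None:
        print(f"  {e.snp1} x {e.snp2}: untestable in every replication cohort")
        continue
    from episcan.replicate import direction_concordance

    conc, tot = direction_concordance(e)
    status = "REPLICATED" if e.replicated else ("nominal" if e.nominal else "not replicated")
    print(f"  {e.snp1} x {e.snp2}: rep beta = {e.replication.beta:+.4f} "
          f"(se {e.replication.se:.4f}), p = {e.replication.p:.3g} -> {status}; "
          f"directions {e.direction_string} ({conc}/{tot} concordant)")

if entries and entries[0].replication is not None:
    Path("scratch/figures").mkdir(parents=True, exist_ok=True)
    ax = forest_plot(entries[0], list(REPLICATION))
    ax.figure.savefig("scratch/figures/forest_top_term.png", dpi=150, bbox_inches="tight")
    print("\nforest plot of the top term -> scratch/figures/forest_top_term.png")
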