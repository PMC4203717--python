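"""Medication case-control stage: does each surviving interaction term
predict lipid-lowering-medication use in the discovery/filter cohorts, and
is its direction pattern consistent (lower HDL with higher treatment odds)?
"""

import pandas as pd

from episcan.medcheck import casecontrol_combined, classify_consistency, wald_p
from studydesign import DISCOVERY, FILTER, RESULTS_DIR, load_all

cohorts = {c.name: c for c in load_all()}
stage = [cohorts[DISCOVERY], *(cohorts[n] for n in FILTER)]

replication = pd.read_csv(f"{RESULTS_DIR}/04_replication.tsv", sep="\t")
rows = []
for r in replication.itertuples():
    fit = casecontrol_combined(stage, (r.snp1, r.snp2))
    b, se, _ = fit["interaction"]
    p = wald_p(b, se)
    verdict = ""
    if pd.notna(r.rep_beta):
        verdict = classify_consistency(
            "+" if r.disc_beta >= 0 else "-",
            "+" if r.rep_beta >= 0 else "-",
            "+" if b >= 0 else "-",
        ).verdict
    rows.append({"snp1": r.snp1, "snp2": r.snp2, "cc_beta": b, "cc_se": se,
                 "cc_p": p, "verdict": verdict,
                 "n_cases": fit.n_cases, "n_controls": fit.n_controls})
    print(f"{r.snp1} x {r.snp2}: medication beta_int = {b:+.3f} (se {se:.3f}), "
          f"p = {p:.3g} [{fit.n_cases} cases / {fit.n_controls} controls] -> {verdict or 'n/a'}")

pd.DataFrame(rows).to_csv(f"{RESULTS_DIR}/05_casecontrol.tsv", sep="\t", index=False)
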