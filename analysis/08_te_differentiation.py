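"""Classify TE insertions, compute their F_ST and call candidates.

Loads the T-lex-style presence/absence table, computes per-population
insertion frequencies, classifies TEs (fixed in both / low frequency in
both / undetermined / testable), scores testable TEs with the same
Weir & Cockerham theta as SNPs, and calls candidates against the
SNP-derived per-arm critical values.

Usage: python analysis/08_te_differentiation.py [--cohort scratch/cohort]
"""

import argparse
from pathlib import Path

import pandas as pd

from eurodiff.te import classify_tes, load_te_calls, te_candidates, te_fst
from eurodiff.vcfio import read_populations


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="scratch/cohort")
    ap.add_argument("--snp-thresholds", default="results/04_arm_thresholds.tsv")
    args = ap.parse_args()
    cohort = Path(args.cohort)

    populations = read_populations(cohort / "populations.tsv")
    table = load_te_calls(cohort / "te_calls.tsv", strains=list(populations))
    pops = sorted(set(populations.values()))
    classified = classify_tes(table, populations, pops[0], pops[1])
    counts = classified["classification"].value_counts()
    print("TE classification:")
    for kind, n in counts.items():
        print(f"  {kind:<14} {n}")

    scored = te_fst(table, classified, populations, pops[0], pops[1])
    thresholds = pd.read_csv(args.snp_thresholds, sep="\t")
    called = te_candidates(scored, thresholds)
    testable = called[called["classification"] == "testable"]
    n_cand = int(testable["candidate_top5"].fillna(False).sum())
    print(
        f"{len(testable)} testable TEs; {n_cand} candidates at the arm-wise "
        "SNP top-5% critical value"
    )
    for _, row in testable[testable["candidate_top5"].fillna(False)].iterrows():
        print(
            f"  {row['te_id']} ({row['family']}, {row['arm']}:{row['pos']}) "
            f"theta={row['fst']:.3f}, higher in {row['direction']}"
        )

    results = Path("results")
    results.mkdir(exist_ok=True)
    called.to_csv(results / "08_te_classified.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
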