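"""Annotate SNPs with functional categories and test tier enrichment.

Assigns each scanned SNP one category (coding syn/nonsyn, splice site,
UTRs, small-intron background, other intron, core promoter, promoter,
intergenic) from the gene models, then tests each category's over/under
representation of outlier-tier SNPs against the small-intron neutral
background with the stratified CMH test (pooled-MAF decile x arm x
inversion status).

Usage: python analysis/05_functional_categories.py [--cohort scratch/cohort]
"""

import argparse
from pathlib import Path

import pandas as pd

from eurodiff.categories import annotate_sites, enrichment_test, load_gene_models


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="scratch/cohort")
    ap.add_argument("--sitestats", default="scratch/sitestats.tsv")
    args = ap.parse_args()
    cohort = Path(args.cohort)

    scan = pd.read_csv(args.sitestats, sep="\t")
    genes, features, cds = load_gene_models(cohort / "genes.tsv", cohort / "cds.fasta")
    calls = annotate_sites(scan[["arm", "pos", "ref", "alt"]], genes, features, cds)
    counts = calls["category"].value_counts()
    print("category assignment:")
    for cat, n in counts.items():
        print(f"  {cat:<16} {n}")
    if calls.attrs["n_unresolved"]:
        print(f"  ({calls.attrs['n_unresolved']} coding SNPs with unresolved codons)")

    results = Path("results")
    results.mkdir(exist_ok=True)
    frames = []
    for tier_col in ("in_top5", "in_top1", "in_top0.5"):
        res = enrichment_test(calls, scan, tier_col)
        frames.append(res)
    enrichment = pd.concat(frames, ignore_index=True)
    enrichment.to_csv(results / "05_category_enrichment.tsv", sep="\t", index=False)
    top5 = enrichment[enrichment["tier"] == "in_top5"]
    print("\ntop-5% tier enrichment vs small-intron background (CMH):")
    for _, row in top5.sort_values("p_cmh").iterrows():
        print(
            f"  {row['category']:<16} OR {row['or_cmh']:.2f}  p {row['p_cmh']:.3g} "
            f"({row['n_category_tier']}/{row['n_category']} in tier)"
        )
    counts.rename("n").to_csv(results / "05_category_counts.tsv", sep="\t")


if __name__ == "__main__":
    main()
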