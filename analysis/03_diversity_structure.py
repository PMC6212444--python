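"""Nucleotide diversity in SNP windows and the global pairwise F_ST.

Computes per-population windowed pi (per-bp and per-SNP), repeats the
estimate after pseudo-haploid one-allele sampling (one allele per strain,
weighted by allelic read depths), and the global weighted Weir & Cockerham
F_ST between the two populations.

Usage: python analysis/03_diversity_structure.py [--cohort scratch/cohort]
"""

import argparse
from pathlib import Path

import pandas as pd

from eurodiff.diversity import pairwise_fst_matrix, pseudo_haploid_sample, windowed_pi
from eurodiff.filters import apply_site_filters
from eurodiff.vcfio import load_masks, load_vcf, read_populations


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="scratch/cohort")
    ap.add_argument("--window-snps", type=int, default=2_000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    cohort = Path(args.cohort)

    matrix = load_vcf(
        cohort / "cohort.vcf", populations=read_populations(cohort / "populations.tsv")
    )
    masks = load_masks(
        cohort / "euchromatin.bed", cohort / "repeats.bed", cohort / "indels.tsv"
    )
    matrix, _ = apply_site_filters(matrix, masks)
    haploid = pseudo_haploid_sample(matrix, seed=args.seed)

    results = Path("results")
    results.mkdir(exist_ok=True)
    frames = []
    for pop in pd.unique(matrix.populations):
        for label, m in (("diploid", matrix), ("pseudo_haploid", haploid)):
            w = windowed_pi(m, pop, window_snps=args.window_snps)
            w.insert(0, "population", pop)
            w.insert(1, "estimator", label)
            frames.append(w)
            print(
                f"{pop:>6} {label:<15} mean pi/SNP "
                f"{w['pi_per_snp'].mean():.4f}, mean pi/bp {w['pi_per_bp'].mean():.6f} "
                f"({len(w)} windows of {args.window_snps} SNPs)"
            )
    pd.concat(frames, ignore_index=True).to_csv(
        results / "03_diversity_windows.tsv", sep="\t", index=False
    )

    pw = pairwise_fst_matrix(matrix)
    pw.to_csv(results / "03_pairwise_fst.tsv", sep="\t", index=False)
    print("global weighted F_ST:")
    for _, row in pw.iterrows():
        print(f"  {row['pop_a']} - {row['pop_b']}: {row['fst']:.4f}")


if __name__ == "__main__":
    main()
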