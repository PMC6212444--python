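"""Apply the site/genotype filter cascade to the cohort VCF.

Reads the simulated multi-sample VCF plus the euchromatin, repeat and
indel masks, runs the full cascade (euchromatin, repeats, indel +-5 bp,
biallelic SNV, non-singleton, depth QC at DP >= 10 and the per-strain
0.975 depth quantile, call rate >= 70%, pooled MAF >= 5%) and writes the
surviving matrix plus the stage-by-stage log.

Usage: python analysis/02_filter_variants.py [--cohort scratch/cohort]
"""

import argparse
from pathlib import Path

from eurodiff.filters import apply_site_filters
from eurodiff.vcfio import load_masks, load_vcf, read_populations, write_vcf


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="scratch/cohort")
    ap.add_argument("--out", default="scratch/filtered.vcf")
    args = ap.parse_args()
    cohort = Path(args.cohort)

    matrix = load_vcf(
        cohort / "cohort.vcf", populations=read_populations(cohort / "populations.tsv")
    )
    masks = load_masks(
        cohort / "euchromatin.bed", cohort / "repeats.bed", cohort / "indels.tsv"
    )
    filtered, log = apply_site_filters(matrix, masks)

    print(f"filter cascade on {matrix.n_sites} input sites:")
    for stage, n_in, n_out in log.stages:
        print(f"  {stage:<16} {n_in:>7} -> {n_out}")
    print(f"{filtered.n_sites} SNPs pass all filters")

    write_vcf(filtered, args.out)
    results = Path("results")
    results.mkdir(exist_ok=True)
    log.to_tsv(results / "02_filter_log.tsv")


if __name__ == "__main__":
    main()
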