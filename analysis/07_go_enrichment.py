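"""GO biological-process enrichment of the candidate genes and Z_ST scores.

Runs the classic one-sided Fisher test on the candidate-gene list, the
KS-like score test on the full Z_ST distribution, and the elim
decorrelation variant of each (children tested first; genes of significant
terms removed from their ancestors).

Usage: python analysis/07_go_enrichment.py [--cohort scratch/cohort]
"""

import argparse
from pathlib import Path

import pandas as pd

from eurodiff.go import annotate_genes, classic_fisher, elim, ks_score_test, load_obo


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="scratch/cohort")
    ap.add_argument("--scores", default="results/06_gene_scores.tsv")
    ap.add_argument("--min-genes", type=int, default=5)
    args = ap.parse_args()
    cohort = Path(args.cohort)

    dag = load_obo(cohort / "go.obo")
    gene2go = pd.read_csv(cohort / "gene2go.tsv", sep="\t")
    annotation = annotate_genes(gene2go, dag)
    scores_df = pd.read_csv(args.scores, sep="\t")
    universe = set(scores_df["gene_id"])
    candidates = set(scores_df.loc[scores_df["candidate"], "gene_id"])
    z_st = pd.Series(scores_df["z_st"].to_numpy(), index=scores_df["gene_id"])

    fisher = classic_fisher(candidates, universe, annotation, min_sig=args.min_genes)
    fisher_elim = elim(
        dag, annotation, "fisher", candidates=candidates, universe=universe,
        min_sig=args.min_genes,
    )
    ks = ks_score_test(z_st, annotation, min_size=args.min_genes)
    ks_elim = elim(dag, annotation, "ks", scores=z_st, min_sig=args.min_genes)

    results = Path("results")
    results.mkdir(exist_ok=True)
    for name, frame in (
        ("fisher_classic", fisher),
        ("fisher_elim", fisher_elim),
        ("ks_classic", ks),
        ("ks_elim", ks_elim),
    ):
        frame.to_csv(results / f"07_go_{name}.tsv", sep="\t", index=False)
        hits = frame[frame["p_value"] < 0.05]
        print(f"{name}: {len(frame)} terms tested, {len(hits)} with p < 0.05")
        for _, row in hits.head(5).iterrows():
            print(
                f"  {row['go_id']}  p={row['p_value']:.3g} "
                f"({row['n_significant']}/{row['n_annotated']})"
            )


if __name__ == "__main__":
    main()
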