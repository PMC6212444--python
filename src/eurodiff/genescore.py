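"""Gene-level Z_ST differentiation scores.

Each gene takes the maximum SNP F_ST over its transcribed region plus the
1 kb strand-aware upstream region, is normalized within its chromosome arm
by a rank-based inverse-normal transform (Z), and is then centered by the
median Z of its SNP-count bin (16 equal-occupancy bins), removing the
systematic increase of max-F_ST with the number of SNPs per gene.  The top
5% of the genome-wide Z_ST distribution are the candidate differentiated
genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["gene_max_fst", "z_normalize_per_arm", "bin_correct", "candidate_genes", "score_genes"]


def gene_max_fst(
    scan: pd.DataFrame, genes: pd.DataFrame, upstream_bp: int = 1_000
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene (max F_ST, n_snps) over transcript + strand-aware upstream.

    A SNP may contribute to several overlapping gene regions.  Genes with
    no usable SNP in their scoring region are excluded from the scores and
    returned in the exclusion list.
    """
    usable = scan[scan["usable"]]
    rows, excluded = [], []
    by_arm = {
        arm: (grp["pos"].to_numpy(), grp["fst"].to_numpy())
        for arm, grp in usable.groupby("arm", sort=False)
    }
    for _, g in genes.iterrows():
        lo, hi = int(g["tx_start"]), int(g["tx_end"])
        if g["strand"] == "+":
            lo -= upstream_bp
        else:
            hi += upstream_bp
        pos, fst = by_arm.get(g["arm"], (np.array([]), np.array([])))
        i0 = np.searchsorted(pos, lo, side="left")
        i1 = np.searchsorted(pos, hi, side="right")
        if i1 <= i0:
            excluded.append(g["gene_id"])
            continue
        window = fst[i0:i1]
        rows.append(
            {
                "gene_id": g["gene_id"],
                "arm": g["arm"],
                "n_snps": int(i1 - i0),
                "max_fst": float(window.max()),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "arm", "n_snps", "max_fst"]), excluded


def z_normalize_per_arm(scores: pd.DataFrame, mode: str = "rank") -> pd.DataFrame:
    """Arm-wise normalization of max F_ST to a Z score.

    ``rank`` (default): inverse-normal transform Z = Phi^-1((rank-0.5)/n)
    with average ranks for ties, giving a standard-normal-like arm-wise
    distribution regardless of the skew of max-F_ST.  ``meansd``:
    conventional (x - mean)/sd standardization.
    """
    out = scores.copy()
    out["z"] = np.nan
    for arm, grp in out.groupby("arm", sort=False):
        x = grp["max_fst"].to_numpy()
        if len(x) < 2:
            out.loc[grp.index, "z"] = 0.0
            continue
        if mode == "rank":
            ranks = stats.rankdata(x, method="average")
            out.loc[grp.index, "z"] = stats.norm.ppf((ranks - 0.5) / len(x))
        elif mode == "meansd":
            sd = x.std(ddof=1)
            out.loc[grp.index, "z"] = (x - x.mean()) / sd if sd > 0 else 0.0
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
    return out


def bin_correct(scores: pd.DataFrame, n_bins: int = 16) -> pd.DataFrame:
    """Median-center Z within SNP-count bins: Z_ST = Z - median(Z | bin).

    Genes are sorted by n_snps and split into ``n_bins`` equal-occupancy
    bins; genes sharing an n_snps value that straddles a boundary are kept
    together in the earlier bin.  With fewer genes than bins the bins
    collapse to the number of distinct n_snps values available.
    """
    out = scores.copy()
    order = out.sort_values(["n_snps", "gene_id"], kind="mergesort").index
    n = len(out)
    bins = min(n_bins, max(1, n))
    raw_bin = np.minimum((np.arange(n) * bins) // n, bins - 1)
    bin_by_gene = pd.Series(raw_bin, index=order)
    # ties across a boundary collapse into the earlier (lower) bin
    nsnps_sorted = out.loc[order, "n_snps"].to_numpy()
    first_bin_of_value: dict[int, int] = {}
    for k, v in enumerate(nsnps_sorted):
        if v not in first_bin_of_value:
            first_bin_of_value[v] = int(raw_bin[k])
    bin_by_gene = out.loc[order, "n_snps"].map(first_bin_of_value)
    out["bin"] = bin_by_gene.reindex(out.index)
    out["z_st"] = out["z"] - out.groupby("bin")["z"].transform("median")
    return out


def candidate_genes(scores: pd.DataFrame, tail: float = 0.05) -> pd.DataFrame:
    """Top floor(tail*N) genes by Z_ST, genome-wide; ties broken by gene_id."""
    if scores.empty:
        raise ValueError("no scored genes")
    k = int(np.floor(tail * len(scores)))
    order = scores.sort_values(["z_st", "gene_id"], ascending=[False, True], kind="mergesort")
    out = scores.copy()
    out["candidate"] = False
    out.loc[order.index[:k], "candidate"] = True
    return out


def score_genes(
    scan: pd.DataFrame,
    genes: pd.DataFrame,
    upstream_bp: int = 1_000,
    n_bins: int = 16,
    tail: float = 0.05,
    mode: str = "rank",
) -> tuple[pd.DataFrame, list[str]]:
    """Full gene scoring pipeline: max F_ST -> Z -> Z_ST -> candidates."""
    scores, excluded = gene_max_fst(scan, genes, upstream_bp=upstream_bp)
    if scores.empty:
        return scores, excluded
    scores = z_normalize_per_arm(scores, mode=mode)
    scores = bin_correct(scores, n_bins=n_bins)
    scores = candidate_genes(scores, tail=tail)
    return scores, excluded
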