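"""Nucleotide diversity and the global pairwise F_ST network.

Per-site pi is the unbiased mean pairwise difference
c_ref * c_alt / C(n, 2) over called chromosomes; windows hold a fixed
number of SNPs (not a fixed span) and report both per-bp and per-SNP
values.  The pseudo-haploid estimator resamples one allele per strain per
site, weighted by allelic read depths, acknowledging that an isofemale
strain genome may effectively carry more or fewer than two alleles per
locus.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from eurodiff import fst as fstmod
from eurodiff.matrix import GenotypeMatrix

__all__ = ["site_pi", "windowed_pi", "pseudo_haploid_sample", "global_fst", "pairwise_fst_matrix"]


def site_pi(c_ref: np.ndarray, c_alt: np.ndarray) -> np.ndarray:
    """Unbiased per-site pi from ref/alt called-allele counts.

    pi = c_ref * c_alt / C(n, 2); sites with fewer than two called
    chromosomes return NaN (skipped by callers).
    """
    c_ref = np.asarray(c_ref, dtype=float)
    c_alt = np.asarray(c_alt, dtype=float)
    n = c_ref + c_alt
    pairs = n * (n - 1) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n >= 2, c_ref * c_alt / np.where(pairs == 0, np.nan, pairs), np.nan)


def windowed_pi(
    matrix: GenotypeMatrix, population: str, window_snps: int = 10_000
) -> pd.DataFrame:
    """Non-overlapping windows of ``window_snps`` SNPs per arm.

    Trailing partial windows are reported with ``partial=True``.  Columns:
    arm, start, end, n_snps, pi_sum, span_bp, pi_per_bp, pi_per_snp,
    partial.
    """
    alt, total = matrix.allele_counts(population)
    pi = site_pi(total - alt, alt)
    rows = []
    for arm, grp in matrix.sites.groupby("arm", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        ok = np.isfinite(pi[idx])
        idx, pos = idx[ok], pos[ok]
        for w0 in range(0, len(idx), window_snps):
            w = slice(w0, w0 + window_snps)
            wi, wp = idx[w], pos[w]
            if len(wi) == 0:
                continue
            span = int(wp[-1] - wp[0] + 1)
            psum = float(pi[wi].sum())
            rows.append(
                {
                    "arm": arm,
                    "start": int(wp[0]),
                    "end": int(wp[-1]),
                    "n_snps": len(wi),
                    "pi_sum": psum,
                    "span_bp": span,
                    "pi_per_bp": psum / span,
                    "pi_per_snp": psum / len(wi),
                    "partial": len(wi) < window_snps,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "arm",
            "start",
            "end",
            "n_snps",
            "pi_sum",
            "span_bp",
            "pi_per_bp",
            "pi_per_snp",
            "partial",
        ],
    )


def pseudo_haploid_sample(matrix: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Keep one allele per strain per site, AD-weighted; deterministic by seed.

    Heterozygous calls draw ref/alt with probability AD_allele / (AD_ref +
    AD_alt); homozygous calls keep their carried allele (both alleles are
    identical, so the weighted draw is degenerate).  Hets with no
    informative reads fall back to a uniform draw.  Missing calls stay
    missing.  Only meaningful for diploid input.
    """
    if matrix.ploidy != 2:
        raise ValueError("pseudo-haploid sampling needs a diploid matrix")
    rng = np.random.default_rng(seed)
    gt = matrix.gt
    hap = np.where(gt == 2, 1, np.where(gt == 0, 0, -1)).astype(np.int8)
    het = gt == 1
    adr = np.where(matrix.ad_ref < 0, 0, matrix.ad_ref).astype(float)
    ada = np.where(matrix.ad_alt < 0, 0, matrix.ad_alt).astype(float)
    tot = adr + ada
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(tot > 0, ada / np.where(tot == 0, np.nan, tot), 0.5)
    draw = (rng.random(gt.shape) < p_alt).astype(np.int8)
    hap[het] = draw[het]
    hap[gt < 0] = -1
    return replace(
        matrix,
        sites=matrix.sites.copy(),
        gt=hap,
        dp=matrix.dp.copy(),
        ad_ref=matrix.ad_ref.copy(),
        ad_alt=matrix.ad_alt.copy(),
        ploidy=1,
    )


def global_fst(matrix: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Global weighted Weir & Cockerham theta: sum(a)/sum(a+b+c)."""
    scan = fstmod.fst_scan(matrix, pop_a, pop_b)
    return fstmod.global_fst_from_scan(scan)


def pairwise_fst_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Global weighted theta for every population pair (network edges)."""
    pops = list(pd.unique(matrix.populations))
    rows = []
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            rows.append({"pop_a": pa, "pop_b": pb, "fst": global_fst(matrix, pa, pb)})
    return pd.DataFrame(rows, columns=["pop_a", "pop_b", "fst"])
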