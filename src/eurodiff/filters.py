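"""Site- and genotype-level filtering of the cohort.

The cascade, in applied order: euchromatin inclusion, repeat-mask
exclusion, indel-proximity exclusion (distance <= 5 bp), biallelic-SNV
restriction, non-singleton restriction, per-call depth QC (DP < 10 or
above the strain's 0.975 depth quantile -> missing), call rate >= 70%, and
pooled minor allele frequency >= 5%.  Boundary conventions: "lower than
10x" is DP < 10 (DP = 10 kept); "higher than the quantile" is strict (the
quantile itself kept); MAF and call-rate thresholds keep equality.
Quantiles use the nearest-rank convention throughout for exact
reproducibility.
"""

from __future__ import annotations

import numpy as np

from eurodiff.matrix import FilterLog, GenotypeMatrix
from eurodiff.vcfio import MaskSet

__all__ = [
    "nearest_rank_quantile",
    "compute_coverage_threshold",
    "apply_genotype_qc",
    "apply_site_filters",
]


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """q-th empirical quantile, nearest-rank: sorted[ceil(q*n)] (1-based)."""
    v = np.sort(np.asarray(values))
    if v.size == 0:
        raise ValueError("no data for quantile")
    if not 0 < q <= 1:
        raise ValueError("quantile must lie in (0, 1]")
    k = int(np.ceil(q * v.size))
    return float(v[k - 1])


def compute_coverage_threshold(
    matrix: GenotypeMatrix, strain: str, q: float = 0.975
) -> float:
    """Per-strain maximum-depth threshold: the q-th quantile of call DP."""
    j = matrix.strain_index(strain)
    dp = matrix.dp[:, j]
    dp = dp[dp >= 0]
    if dp.size == 0:
        raise ValueError(f"strain {strain!r} has no depth data")
    return nearest_rank_quantile(dp, q)


def apply_genotype_qc(
    matrix: GenotypeMatrix,
    min_dp: int = 10,
    max_thresholds: dict[str, float] | None = None,
    coverage_quantile: float = 0.975,
) -> GenotypeMatrix:
    """Set calls with DP < min_dp or DP > the strain threshold to missing.

    ``max_thresholds`` maps strain -> max depth; when omitted it is
    computed per strain as the ``coverage_quantile`` of that strain's DP.
    Calls with unknown DP are left untouched.
    """
    if max_thresholds is None:
        max_thresholds = {
            s: compute_coverage_threshold(matrix, s, coverage_quantile)
            for s in matrix.strains
        }
    missing_thr = [s for s in matrix.strains if s not in max_thresholds]
    if missing_thr:
        raise KeyError(f"no depth threshold for strains: {missing_thr}")
    thr = np.array([max_thresholds[s] for s in matrix.strains])
    dp = matrix.dp
    known = dp >= 0
    bad = known & ((dp < min_dp) | (dp > thr[None, :]))
    out = matrix.take_sites(np.arange(matrix.n_sites))  # copy-ish
    out.gt = np.where(bad, -1, matrix.gt).astype(np.int8)
    return out


def apply_site_filters(
    matrix: GenotypeMatrix,
    masks: MaskSet,
    maf_min: float = 0.05,
    call_rate_min: float = 0.70,
    min_dp: int = 10,
    coverage_quantile: float = 0.975,
    genotype_qc: bool = True,
    max_thresholds: dict[str, float] | None = None,
) -> tuple[GenotypeMatrix, FilterLog]:
    """Run the full site-filter cascade; returns the surviving matrix + log.

    Allele frequencies and call rates are computed over all strains present
    in the matrix (the two focal populations), missing calls excluded from
    numerator and denominator.  Per-strain depth thresholds default to the
    ``coverage_quantile`` of each strain's depth distribution in the input
    matrix (computed before any site is removed, as a genome-wide coverage
    property); pass ``max_thresholds`` to reuse thresholds across runs.
    An empty result is allowed; the log shows where sites were lost.
    """
    log = FilterLog()
    m = matrix
    if genotype_qc and max_thresholds is None:
        max_thresholds = {
            s: compute_coverage_threshold(matrix, s, coverage_quantile)
            for s in matrix.strains
        }
    arm = m.sites["arm"].to_numpy()
    pos = m.sites["pos"].to_numpy()

    keep = masks.euchromatin.contains(arm, pos)
    log.add("euchromatin", m.n_sites, int(keep.sum()))
    m = m.take_sites(keep)

    arm = m.sites["arm"].to_numpy()
    pos = m.sites["pos"].to_numpy()
    keep = ~masks.repeats.contains(arm, pos)
    log.add("repeat_mask", m.n_sites, int(keep.sum()))
    m = m.take_sites(keep)

    arm = m.sites["arm"].to_numpy()
    pos = m.sites["pos"].to_numpy()
    keep = ~masks.indel_zones.contains(arm, pos)
    log.add("indel_proximity", m.n_sites, int(keep.sum()))
    m = m.take_sites(keep)

    keep = (m.sites["is_snv"] & m.sites["is_biallelic"]).to_numpy()
    log.add("biallelic_snv", m.n_sites, int(keep.sum()))
    m = m.take_sites(keep)

    alt, total = m.allele_counts()
    minor = np.minimum(alt, total - alt)
    keep = minor > 1  # non-singleton: minor allele seen more than once
    log.add("non_singleton", m.n_sites, int(keep.sum()))
    m = m.take_sites(keep)

    if genotype_qc:
        m = apply_genotype_qc(m, min_dp=min_dp, max_thresholds=max_thresholds)
        log.add("genotype_qc", m.n_sites, m.n_sites)  # call-level stage

    keep = m.call_rate() >= call_rate_min
    log.add("call_rate", m.n_sites, int(keep.sum()))
    m = m.take_sites(keep)

    alt, total = m.allele_counts()
    with np.errstate(divide="ignore", invalid="ignore"):
        af = alt / np.where(total == 0, np.nan, total)
    maf = np.minimum(af, 1 - af)
    keep = maf >= maf_min
    log.add("pooled_maf", m.n_sites, int(keep.sum()))
    m = m.take_sites(keep)

    return m, log
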