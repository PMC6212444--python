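"""Convenience wiring of the full scan over an in-memory cohort.

Thin glue used by the analysis drivers, the tests and the acceptance
script so they all run the identical pathway: masks -> filter cascade ->
per-site theta scan -> per-arm tiers.
"""

from __future__ import annotations

import pandas as pd

from eurodiff import fst
from eurodiff.filters import apply_site_filters
from eurodiff.matrix import FilterLog, GenotypeMatrix
from eurodiff.simulate import Cohort
from eurodiff.vcfio import IntervalSet, MaskSet

__all__ = ["cohort_masks", "run_scan"]


def cohort_masks(cohort: Cohort, indel_distance: int = 5) -> MaskSet:
    """MaskSet built from a cohort's own euchromatin/repeat/indel frames."""
    return MaskSet(
        euchromatin=IntervalSet.from_frame(cohort.euchromatin),
        repeats=IntervalSet.from_frame(cohort.repeats),
        indel_zones=IntervalSet.from_frame(cohort.indels, pad=indel_distance),
    )


def run_scan(
    cohort: Cohort,
    tails: tuple[float, ...] = (0.05, 0.01, 0.005),
) -> tuple[GenotypeMatrix, FilterLog, pd.DataFrame, pd.DataFrame]:
    """Filter the cohort and scan it; returns (matrix, log, scan, thresholds).

    The scan frame carries theta, pooled MAF, inversion membership and the
    rank-based tier columns; thresholds are the per-arm critical values.
    """
    pops = cohort.config.pop_names
    matrix, log = apply_site_filters(cohort.matrix, cohort_masks(cohort))
    scan = fst.fst_scan(matrix, pops[0], pops[1], inversion=cohort.config.inversion_region)
    thresholds = fst.arm_thresholds(scan, tails=tails)
    scan = fst.assign_tiers(scan, tails=tails)
    return matrix, log, scan, thresholds
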