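"""In-memory containers for the strains x sites genotype cohort.

Genotypes are stored as alt-allele dosages (0/1/2 for diploids, 0/1 for
pseudo-haploid data, -1 for missing).  Per-call read depth (DP) and allelic
depths (AD) use -1 for "unknown".  All positions are 1-based inclusive;
converters to/from 0-based half-open BED live at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SITE_COLUMNS = ["arm", "pos", "ref", "alt", "is_snv", "is_biallelic"]


@dataclass
class GenotypeMatrix:
    """Strains x sites cohort with per-call depth information.

    Attributes
    ----------
    sites : DataFrame with columns ``arm, pos, ref, alt, is_snv,
        is_biallelic`` (positions 1-based, strictly increasing within arm).
    strains : strain identifiers, column order of the call arrays.
    populations : population label per strain, aligned with ``strains``.
    gt : (n_sites, n_strains) int8 alt-dosage matrix; -1 = missing call.
    dp : (n_sites, n_strains) int32 read depth; -1 = unknown.
    ad_ref, ad_alt : (n_sites, n_strains) int32 allelic depths; -1 = unknown.
    ploidy : 2 for diploid genotypes, 1 after pseudo-haploid sampling.
    """

    sites: pd.DataFrame
    strains: list[str]
    populations: np.ndarray
    gt: np.ndarray
    dp: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=object)
        if len(self.strains) != self.populations.shape[0]:
            raise ValueError("every strain needs a population label")
        if self.gt.shape != (len(self.sites), len(self.strains)):
            raise ValueError(
                f"gt shape {self.gt.shape} does not match "
                f"{len(self.sites)} sites x {len(self.strains)} strains"
            )
        for arm, grp in self.sites.groupby("arm", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {arm}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def pop_mask(self, label: str) -> np.ndarray:
        mask = self.populations == label
        if not mask.any():
            raise KeyError(f"no strains labelled {label!r}")
        return mask

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise KeyError(f"strain {strain!r} not in matrix") from None

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Row-subset by boolean mask or integer index, preserving order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            sites=self.sites.iloc[index].reset_index(drop=True),
            gt=self.gt[index],
            dp=self.dp[index],
            ad_ref=self.ad_ref[index],
            ad_alt=self.ad_alt[index],
        )

    def take_strains(self, keep: list[str]) -> "GenotypeMatrix":
        idx = np.array([self.strain_index(s) for s in keep])
        return replace(
            self,
            strains=list(keep),
            populations=self.populations[idx],
            gt=self.gt[:, idx],
            dp=self.dp[:, idx],
            ad_ref=self.ad_ref[:, idx],
            ad_alt=self.ad_alt[:, idx],
        )

    def allele_counts(self, pop: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele total), missing excluded."""
        gt = self.gt if pop is None else self.gt[:, self.pop_mask(pop)]
        called = gt >= 0
        alt = np.where(called, gt, 0).sum(axis=1)
        total = called.sum(axis=1) * self.ploidy
        return alt.astype(np.int64), total.astype(np.int64)

    def call_rate(self, pop: str | None = None) -> np.ndarray:
        gt = self.gt if pop is None else self.gt[:, self.pop_mask(pop)]
        return (gt >= 0).mean(axis=1)


@dataclass
class FilterLog:
    """Ordered record of (stage, sites in, sites out) for a filter cascade."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {stage!r}: {n_out} out > {n_in} in")
        self.stages.append((stage, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "sites_in", "sites_out"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        rows = ", ".join(f"{s}:{i}->{o}" for s, i, o in self.stages)
        return f"FilterLog({rows})"
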