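"""VCF and mask I/O.

VCF is 1-based inclusive; BED is 0-based half-open.  Everything internal is
1-based inclusive, with the conversion done here at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from eurodiff.matrix import GenotypeMatrix

__all__ = [
    "write_vcf",
    "load_vcf",
    "read_populations",
    "IntervalSet",
    "MaskSet",
    "load_masks",
    "EUCHROMATIN_DM5",
]

# Euchromatic arm bounds (1-based inclusive) of the D. melanogaster release-5
# assembly, from recombination-rate-calculator estimates; the default mask
# for real-coordinate data.
EUCHROMATIN_DM5: dict[str, tuple[int, int]] = {
    "2L": (530_000, 18_870_000),
    "2R": (1_870_000, 20_860_000),
    "3L": (750_000, 19_020_000),
    "3R": (2_580_000, 27_440_000),
    "X": (1_220_000, 21_210_000),
}


def write_vcf(matrix: GenotypeMatrix, path, contigs: dict[str, int] | None = None) -> None:
    """Emit a VCFv4.2 file with GT:DP:AD per call (diploid unphased)."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=eurodiff-simulate"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.strains),
    ]
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    sites = matrix.sites
    for i in range(matrix.n_sites):
        row = sites.iloc[i]
        fields = [
            str(row["arm"]),
            str(int(row["pos"])),
            ".",
            str(row["ref"]),
            str(row["alt"]),
            ".",
            "PASS",
            ".",
            "GT:DP:AD",
        ]
        for j in range(matrix.n_strains):
            g = int(matrix.gt[i, j])
            dp = int(matrix.dp[i, j])
            ar, aa = int(matrix.ad_ref[i, j]), int(matrix.ad_alt[i, j])
            dp_s = str(dp) if dp >= 0 else "."
            ad_s = f"{ar},{aa}" if ar >= 0 else "."
            fields.append(f"{gt_str[g]}:{dp_s}:{ad_s}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def load_vcf(
    path,
    populations: dict[str, str] | pd.Series | None = None,
    sample_subset: list[str] | None = None,
) -> GenotypeMatrix:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are retained but flagged ``is_biallelic=False``
    (dosage then refers to the first alt allele; genotypes carrying a
    higher allele index are stored missing).  Missing DP/AD are stored as
    -1 (unknown).  ``populations`` maps strain -> label; strains without a
    label get ``"unlabelled"``.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in samples]
        if missing:
            raise KeyError(f"requested samples absent from VCF: {missing}")
        keep = [samples.index(s) for s in sample_subset]
        samples = list(sample_subset)
    else:
        keep = list(range(len(samples)))

    rows = []
    gts, dps, adr, ada = [], [], [], []
    for lineno, var in enumerate(vcf, start=1):
        if var.REF is None or not var.ALT:
            raise ValueError(f"malformed VCF record at data line {lineno}")
        is_snv = len(var.REF) == 1 and all(len(a) == 1 for a in var.ALT)
        rows.append(
            {
                "arm": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": ",".join(var.ALT),
                "is_snv": is_snv,
                "is_biallelic": len(var.ALT) == 1,
            }
        )
        garr = np.asarray(var.genotype.array())[:, :2]
        dosage = np.where(
            (garr < 0).any(axis=1), -1, np.where((garr > 1).any(axis=1), -1, garr.clip(0).sum(axis=1))
        )
        dp = var.format("DP")
        dp = (
            np.full(len(vcf.samples), -1, dtype=np.int32)
            if dp is None
            else np.where(dp.reshape(-1) < 0, -1, dp.reshape(-1)).astype(np.int32)
        )
        ad = var.format("AD")
        if ad is None:
            ar = np.full(len(vcf.samples), -1, dtype=np.int32)
            aa = ar.copy()
        else:
            ar = np.where(ad[:, 0] < 0, -1, ad[:, 0]).astype(np.int32)
            aa = np.where(ad[:, 1] < 0, -1, ad[:, 1]).astype(np.int32) if ad.shape[1] > 1 else np.full(
                len(vcf.samples), -1, dtype=np.int32
            )
        gts.append(dosage[keep])
        dps.append(dp[keep])
        adr.append(ar[keep])
        ada.append(aa[keep])

    sites = pd.DataFrame(rows, columns=["arm", "pos", "ref", "alt", "is_snv", "is_biallelic"])
    if populations is None:
        labels = np.array(["unlabelled"] * len(samples), dtype=object)
    else:
        pmap = dict(populations) if not isinstance(populations, dict) else populations
        labels = np.array([pmap.get(s, "unlabelled") for s in samples], dtype=object)
    return GenotypeMatrix(
        sites=sites,
        strains=samples,
        populations=labels,
        gt=np.asarray(gts, dtype=np.int8),
        dp=np.asarray(dps, dtype=np.int32),
        ad_ref=np.asarray(adr, dtype=np.int32),
        ad_alt=np.asarray(ada, dtype=np.int32),
    )


def read_populations(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["strain"], df["population"]))


# ---------------------------------------------------------------------------
# interval masks


@dataclass
class IntervalSet:
    """Merged, sorted 1-based inclusive intervals per arm; O(log n) lookup."""

    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pad: int = 0) -> "IntervalSet":
        starts: dict[str, np.ndarray] = {}
        ends: dict[str, np.ndarray] = {}
        if df is None or len(df) == 0:
            return cls(starts, ends)
        for arm, grp in df.groupby("arm"):
            iv = sorted(
                (int(s) - pad, int(e) + pad) for s, e in zip(grp["start"], grp["end"])
            )
            merged = [list(iv[0])]
            for s, e in iv[1:]:
                if s <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts[arm] = np.array([m[0] for m in merged])
            ends[arm] = np.array([m[1] for m in merged])
        return cls(starts, ends)

    def contains(self, arm: np.ndarray, pos: np.ndarray) -> np.ndarray:
        arm = np.asarray(arm)
        pos = np.asarray(pos)
        out = np.zeros(pos.shape, dtype=bool)
        for a in np.unique(arm):
            if a not in self.starts:
                continue
            m = arm == a
            idx = np.searchsorted(self.starts[a], pos[m], side="right") - 1
            ok = idx >= 0
            hit = np.zeros(m.sum(), dtype=bool)
            hit[ok] = pos[m][ok] <= self.ends[a][idx[ok]]
            out[m] = hit
        return out


@dataclass
class MaskSet:
    """Euchromatin inclusion, repeat exclusion and indel-proximity exclusion."""

    euchromatin: IntervalSet
    repeats: IntervalSet
    indel_zones: IntervalSet  # indel spans padded by the proximity distance


def _read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> 1-based inclusive frame; empty file ok."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], names=["arm", "start0", "end"]
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["arm", "start", "end"])
    df["start"] = df["start0"] + 1
    return df[["arm", "start", "end"]]


def load_masks(
    euchromatin_bed, repeat_bed=None, indel_positions=None, indel_distance: int = 5
) -> MaskSet:
    """Build the mask set from BED files and an indel-span TSV.

    ``indel_positions`` is a TSV with 1-based inclusive ``arm, start, end``
    spans; a SNP within ``indel_distance`` bp of a span (distance <= 5 by
    default) is excluded downstream.
    """
    euch = _read_bed(euchromatin_bed)
    reps = _read_bed(repeat_bed) if repeat_bed is not None else None
    if indel_positions is not None:
        try:
            ind = pd.read_csv(indel_positions, sep="\t")
        except pd.errors.EmptyDataError:
            ind = None
    else:
        ind = None
    return MaskSet(
        euchromatin=IntervalSet.from_frame(euch),
        repeats=IntervalSet.from_frame(reps) if reps is not None else IntervalSet({}, {}),
        indel_zones=IntervalSet.from_frame(ind, pad=indel_distance)
        if ind is not None
        else IntervalSet({}, {}),
    )
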