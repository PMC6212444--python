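"""Functional-category annotation of SNPs and outlier-tier enrichment.

Every SNP receives exactly one category by precedence: coding (split into
synonymous / non-synonymous by codon translation) > splice site (the two
intronic bases at each intron end) > 5'/3' UTR > intron, where intronic
SNPs in positions 8-30 of introns <= 65 bp form the near-neutral
``small_intron_bg`` background and the rest are ``intron_other`` >
core promoter (1-316 bp upstream of the TSS, strand-aware) > promoter
(317-1000 bp upstream) > intergenic.  When a SNP falls in features of
multiple genes the highest-precedence category wins.

Enrichment of an outlier tier in a category versus the small-intron
background controls for pooled-MAF bin, chromosome arm and inversion
status by combining the per-stratum 2x2 tables with the
Cochran-Mantel-Haenszel test; the unstratified two-sided Fisher test is
reported alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable

__all__ = [
    "CATEGORY_PRECEDENCE",
    "load_gene_models",
    "annotate_sites",
    "enrichment_test",
]

# precedence rank -> category (lower rank wins)
CATEGORY_PRECEDENCE = [
    "coding",
    "splice_site",
    "utr5",
    "utr3",
    "small_intron_bg",
    "intron_other",
    "core_promoter",
    "promoter",
    "intergenic",
]
_RANK = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CORE_PROMOTER_BP = 316
PROMOTER_BP = 1_000
SMALL_INTRON_MAX = 65
SMALL_INTRON_WINDOW = (8, 30)  # positions from the intron 5' end, inclusive
SPLICE_BP = 2


def load_gene_models(genes_tsv, cds_fasta) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Read the gene-model TSV (with `blocks` column) and the CDS FASTA."""
    genes = pd.read_csv(genes_tsv, sep="\t")
    feat_rows = []
    for _, row in genes.iterrows():
        for order, blk in enumerate(str(row["blocks"]).split(";")):
            feat, span = blk.split(":")
            s, e = span.split("-")
            feat_rows.append(
                {
                    "gene_id": row["gene_id"],
                    "order": order,
                    "feature": feat,
                    "start": int(s),
                    "end": int(e),
                }
            )
    features = pd.DataFrame(feat_rows)
    cds: dict[str, str] = {}
    name = None
    with open(cds_fasta) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                cds[name] = ""
            elif name is not None:
                cds[name] += line
    genes = genes.drop(columns=["blocks"])
    return genes, features, cds


def _feature_intervals(genes: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Expand gene models into (arm, start, end, rank, gene_id) intervals."""
    meta = genes.set_index("gene_id")
    rows = []

    def add(gene_id, cat, s, e):
        if e < s:
            return
        rows.append(
            {
                "arm": meta.at[gene_id, "arm"],
                "start": int(s),
                "end": int(e),
                "rank": _RANK[cat],
                "gene_id": gene_id,
            }
        )

    for _, f in features.iterrows():
        g, s, e = f["gene_id"], int(f["start"]), int(f["end"])
        if f["feature"] == "cds":
            add(g, "coding", s, e)
        elif f["feature"] == "utr5":
            add(g, "utr5", s, e)
        elif f["feature"] == "utr3":
            add(g, "utr3", s, e)
        elif f["feature"] == "intron":
            length = e - s + 1
            add(g, "splice_site", s, min(s + SPLICE_BP - 1, e))
            add(g, "splice_site", max(e - SPLICE_BP + 1, s), e)
            if length <= SMALL_INTRON_MAX:
                lo, hi = SMALL_INTRON_WINDOW
                strand = meta.at[g, "strand"]
                if strand == "+":
                    add(g, "small_intron_bg", s + lo - 1, min(s + hi - 1, e))
                else:
                    add(g, "small_intron_bg", max(e - hi + 1, s), e - lo + 1)
            add(g, "intron_other", s, e)

    for gene_id, row in meta.iterrows():
        tss = int(row["tss"])
        if row["strand"] == "+":
            add(gene_id, "core_promoter", tss - CORE_PROMOTER_BP, tss - 1)
            add(gene_id, "promoter", tss - PROMOTER_BP, tss - CORE_PROMOTER_BP - 1)
        else:
            add(gene_id, "core_promoter", tss + 1, tss + CORE_PROMOTER_BP)
            add(gene_id, "promoter", tss + CORE_PROMOTER_BP + 1, tss + PROMOTER_BP)
    return pd.DataFrame(rows)


def _cds_offset_maps(
    genes: pd.DataFrame, features: pd.DataFrame
) -> dict[str, list[tuple[int, int, int]]]:
    """gene -> [(genomic start, genomic end, cds offset of block 5' end)]."""
    strand = genes.set_index("gene_id")["strand"]
    out: dict[str, list[tuple[int, int, int]]] = {}
    for gene_id, blocks in features[features["feature"] == "cds"].groupby("gene_id"):
        cum = 0
        lst = []
        for _, blk in blocks.sort_values("order").iterrows():
            lst.append((int(blk["start"]), int(blk["end"]), cum))
            cum += int(blk["end"]) - int(blk["start"]) + 1
        out[gene_id] = lst
    # strand baked into lookup below via the strand series
    out["__strand__"] = strand  # type: ignore[assignment]
    return out


def annotate_sites(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    features: pd.DataFrame,
    cds: dict[str, str],
) -> pd.DataFrame:
    """One category per SNP; returns sites index-aligned category calls.

    Columns: arm, pos, category, gene_id (empty string for intergenic).
    Coding SNPs are translated against the gene's CDS sequence; a codon
    that cannot be reconciled with the VCF REF allele yields category
    ``coding_unknown`` (kept coding, effect unresolved, counted in the
    returned frame's ``attrs['n_unresolved']``).
    """
    arm = sites["arm"].to_numpy()
    pos = sites["pos"].to_numpy().astype(np.int64)
    n = len(sites)
    best_rank = np.full(n, _RANK["intergenic"], dtype=np.int16)
    best_gene = np.array([""] * n, dtype=object)

    by_arm: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for a in np.unique(arm):
        m = np.flatnonzero(arm == a)
        order = np.argsort(pos[m], kind="mergesort")
        by_arm[a] = (pos[m][order], m[order])

    intervals = _feature_intervals(genes, features)
    for _, iv in intervals.iterrows():
        if iv["arm"] not in by_arm:
            continue
        p_sorted, idx_sorted = by_arm[iv["arm"]]
        lo = np.searchsorted(p_sorted, iv["start"], side="left")
        hi = np.searchsorted(p_sorted, iv["end"], side="right")
        if hi <= lo:
            continue
        hit = idx_sorted[lo:hi]
        better = iv["rank"] < best_rank[hit]
        best_rank[hit[better]] = iv["rank"]
        best_gene[hit[better]] = iv["gene_id"]

    category = np.array([CATEGORY_PRECEDENCE[r] for r in best_rank], dtype=object)

    # resolve coding SNPs into synonymous / non-synonymous
    offset_maps = _cds_offset_maps(genes, features)
    strand = offset_maps.pop("__strand__")
    n_unresolved = 0
    coding_idx = np.flatnonzero(best_rank == _RANK["coding"])
    ref_all = sites["ref"].to_numpy()
    alt_all = sites["alt"].to_numpy()
    for i in coding_idx:
        g = best_gene[i]
        st = strand[g]
        offset = None
        for s, e, cum in offset_maps[g]:
            if s <= pos[i] <= e:
                offset = cum + (pos[i] - s if st == "+" else e - pos[i])
                break
        if offset is None:  # pragma: no cover - defensive
            category[i] = "coding_unknown"
            n_unresolved += 1
            continue
        seq = cds[g]
        ci = offset // 3
        within = offset % 3
        codon = seq[3 * ci : 3 * ci + 3]
        ref_b = ref_all[i] if st == "+" else _COMP[ref_all[i]]
        alt_b = alt_all[i].split(",")[0]
        alt_b = alt_b if st == "+" else _COMP[alt_b]
        if len(codon) != 3 or codon[within] != ref_b:
            category[i] = "coding_unknown"
            n_unresolved += 1
            continue
        alt_codon = codon[:within] + alt_b + codon[within + 1 :]
        same = str(Seq(codon).translate()) == str(Seq(alt_codon).translate())
        category[i] = "coding_syn" if same else "coding_nonsyn"

    out = pd.DataFrame(
        {"arm": arm, "pos": pos, "category": category, "gene_id": best_gene},
        index=sites.index,
    )
    out.attrs["n_unresolved"] = n_unresolved
    return out


def enrichment_test(
    category_calls: pd.DataFrame,
    scan: pd.DataFrame,
    tier_col: str,
    n_maf_bins: int = 10,
    background: str = "small_intron_bg",
    stratify: tuple[str, ...] = ("maf_bin", "arm", "inside_inversion"),
) -> pd.DataFrame:
    """Per-category tier enrichment against the neutral background.

    ``scan`` must be index-aligned with ``category_calls`` and carry the
    boolean tier column plus ``maf``, ``arm`` and ``inside_inversion``.
    For each non-background category the per-stratum 2x2 tables
    (category vs background) x (in tier vs not) are combined with the
    Cochran-Mantel-Haenszel test; the pooled two-sided Fisher test is
    reported for comparison.  Categories with no SNP in any stratum are
    skipped.
    """
    df = category_calls[["category"]].join(
        scan[["maf", "arm", "inside_inversion", tier_col]]
    )
    df = df[df[tier_col].notna()]
    if (df["category"] == background).sum() == 0:
        raise ValueError(f"background category {background!r} is empty")
    try:
        df["maf_bin"] = pd.qcut(df["maf"], q=n_maf_bins, duplicates="drop", labels=False)
    except (ValueError, IndexError):
        df["maf_bin"] = 0
    strat_cols = [c for c in stratify if c in df.columns]
    df["_stratum"] = df[strat_cols].astype(str).agg("|".join, axis=1) if strat_cols else "all"

    bg = df[df["category"] == background]
    rows = []
    for cat, sub in df[df["category"] != background].groupby("category", sort=True):
        tables = []
        for stratum, cat_grp in sub.groupby("_stratum"):
            bg_grp = bg[bg["_stratum"] == stratum]
            t = np.array(
                [
                    [int(cat_grp[tier_col].sum()), int((~cat_grp[tier_col]).sum())],
                    [int(bg_grp[tier_col].sum()), int((~bg_grp[tier_col]).sum())],
                ]
            )
            if t.sum() > 0:
                tables.append(t)
        # strata where the category is absent but the background present
        # contribute nothing to the 2x2 comparison and are dropped
        if not tables:
            continue
        pooled = np.sum(tables, axis=0)
        fisher_or, fisher_p = stats.fisher_exact(pooled, alternative="two-sided")
        informative = [t for t in tables if t[0].sum() > 0 and t[1].sum() > 0]
        if informative and pooled[:, 0].sum() > 0 and pooled[:, 1].sum() > 0:
            st = StratifiedTable(informative)
            with np.errstate(divide="ignore", invalid="ignore"):
                or_cmh = float(st.oddsratio_pooled)
                try:
                    p_cmh = float(st.test_null_odds(correction=False).pvalue)
                except (ValueError, ZeroDivisionError):  # pragma: no cover
                    p_cmh = np.nan
        else:
            or_cmh, p_cmh = np.nan, np.nan
        rows.append(
            {
                "category": cat,
                "tier": tier_col,
                "n_category": int(len(sub)),
                "n_category_tier": int(sub[tier_col].sum()),
                "n_background": int(len(bg)),
                "n_background_tier": int(bg[tier_col].sum()),
                "or_cmh": or_cmh,
                "p_cmh": p_cmh,
                "or_fisher": float(fisher_or),
                "p_fisher": float(fisher_p),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "category",
            "tier",
            "n_category",
            "n_category_tier",
            "n_background",
            "n_background_tier",
            "or_cmh",
            "p_cmh",
            "or_fisher",
            "p_fisher",
        ],
    )
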