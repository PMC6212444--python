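"""Synthetic two-population cohort generator.

Emulates the study design the scan assumes: two samples of individually
sequenced, passively inbred isofemale lines with Balding-Nichols
allele-frequency divergence at neutral sites, a minority of planted
"selected" loci with strongly divergent frequencies, near-homozygous
genotypes, Poisson read depths with binomial allele splits, multi-arm gene
models containing small introns, one inversion region tagged by marker
SNPs, a toy GO DAG, and a T-lex-style transposable-element
presence/absence table.

Model notes
-----------
* Neutral sites: population alt frequencies are drawn independently per
  population from Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral
  frequency p (the Balding-Nichols model), whose dispersion parameter F is
  exactly the estimand of the Weir & Cockerham theta estimator.
* Selected loci model spatially antagonistic selection: the two population
  frequencies are placed symmetrically around a midpoint p-bar at
  half-distance d = sqrt(selected_F * p-bar * (1 - p-bar)), so the
  parametric among/total variance ratio d^2 / (p-bar q-bar) equals
  ``selected_F``.  (Independent Balding-Nichols draws at high F frequently
  land both populations on the same side and would not yield reliably
  detectable outliers.)
* Sites inside the inversion region get a mildly inflated F
  (``baseline_F * inversion_f_multiplier``), mimicking the elevated
  differentiation observed within cosmopolitan inversions; marker SNPs are
  in perfect association with the simulated arrangement.
* Small-intron neutral background: a configurable fraction of sites is
  placed inside positions 8-30 of introns <= 65 bp so the background
  category is populated at realistic density.

Determinism: everything is driven by one ``numpy.random.default_rng(seed)``
stream; fixed seed gives byte-identical output files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from eurodiff.matrix import GenotypeMatrix

__all__ = [
    "SimConfig",
    "Cohort",
    "simulate_site_frequencies",
    "simulate_genotypes",
    "simulate_read_depths",
    "generate_annotations",
    "generate_te_table",
    "simulate_cohort",
    "write_cohort",
]

BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
STOP_CODONS = {"TAA", "TAG", "TGA"}
TE_FAMILIES = ["roo", "jockey", "pogo", "copia", "297", "412", "F-element"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the design the pipeline targets: 26 + 16 inbred
    strains, mean coverage 28.6x, five chromosome arms named like the
    D. melanogaster euchromatin, weak genome-wide differentiation with a
    small fraction of strongly differentiated planted loci, and one
    inversion region on 2L.
    """

    n_strains_pop1: int = 26
    n_strains_pop2: int = 16
    pop_names: tuple[str, str] = ("pop1", "pop2")
    n_sites: int = 20_000
    arms: tuple[tuple[str, int], ...] = (
        ("2L", 1_200_000),
        ("2R", 1_200_000),
        ("3L", 1_200_000),
        ("3R", 1_200_000),
        ("X", 1_000_000),
    )
    euchromatin_margin: int = 50_000
    baseline_F: float = 0.05
    selected_fraction: float = 0.01
    selected_F: float = 0.6
    selected_gene_fraction: float = 0.02
    inbreeding: float = 0.95
    mean_depth: float = 28.6
    missing_rate: float = 0.03
    seed: int = 0
    n_genes: int = 500
    small_intron_gene_fraction: float = 0.35
    small_intron_site_fraction: float = 0.02
    multiallelic_fraction: float = 0.005
    n_indels: int = 300
    n_repeats: int = 40
    repeat_length: int = 2_000
    n_te: int = 100
    te_fixed_frac: float = 0.55
    te_rare_frac: float = 0.34
    te_undetermined_frac: float = 0.015
    n_te_selected: int = 2
    te_missing_rate: float = 0.05
    inversion_region: tuple[str, int, int] = ("2L", 300_000, 700_000)
    inversion_freqs: tuple[float, float] = (0.4, 0.1)
    inversion_f_multiplier: float = 1.3
    n_inversion_markers: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.baseline_F < self.selected_F < 1):
            raise ValueError("need 0 < baseline_F < selected_F < 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    def euchromatin(self) -> pd.DataFrame:
        rows = []
        for arm, length in self.arms:
            rows.append(
                {
                    "arm": arm,
                    "start": self.euchromatin_margin + 1,
                    "end": length - self.euchromatin_margin,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class Cohort:
    """A fully simulated cohort plus its ground truth."""

    config: SimConfig
    matrix: GenotypeMatrix
    genes: pd.DataFrame
    features: pd.DataFrame
    cds: dict[str, str]
    gene2go: pd.DataFrame
    obo_text: str
    te_table: pd.DataFrame
    markers: pd.DataFrame
    euchromatin: pd.DataFrame
    repeats: pd.DataFrame
    indels: pd.DataFrame
    truth_sites: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_tes: pd.DataFrame
    inversion_sample_freqs: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# elementary draws


def simulate_site_frequencies(
    p_anc: float | np.ndarray, F: float | np.ndarray, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols population frequencies around an ancestral frequency.

    Each of ``n_pops`` populations draws independently from
    Beta(p(1-F)/F, (1-p)(1-F)/F); the variance of the draws is p(1-p)F.
    Monomorphic ancestral frequencies are rejected.
    """
    p = np.asarray(p_anc, dtype=float)
    F = np.asarray(F, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("ancestral frequency must lie strictly inside (0, 1)")
    if np.any((F <= 0) | (F >= 1)):
        raise ValueError("F must lie strictly inside (0, 1)")
    scale = (1 - F) / F
    shape = np.broadcast_shapes(p.shape, F.shape)
    return rng.beta(
        np.broadcast_to(p * scale, shape), np.broadcast_to((1 - p) * scale, shape), size=(n_pops, *shape)
    )


def simulate_genotypes(
    freq: float | np.ndarray, n_strains: int, inbreeding: float, rng: np.random.Generator
) -> np.ndarray:
    """Diploid alt-dosage column(s) for inbred strains.

    With probability ``inbreeding`` a strain is homozygous (alt with
    probability ``freq``); otherwise a Hardy-Weinberg draw of two alleles.
    Returns an int8 array of shape (n_sites, n_strains).
    """
    p = np.atleast_1d(np.asarray(freq, dtype=float))
    if np.any((p < 0) | (p > 1)) or not (0 <= inbreeding <= 1):
        raise ValueError("frequencies and inbreeding must lie in [0, 1]")
    hom = rng.random((p.size, n_strains)) < inbreeding
    a1 = rng.random((p.size, n_strains)) < p[:, None]
    a2 = np.where(hom, a1, rng.random((p.size, n_strains)) < p[:, None])
    return (a1.astype(np.int8) + a2.astype(np.int8)).reshape(p.size, n_strains)


def simulate_read_depths(
    gt: np.ndarray, mean_depth: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-call (DP, AD_ref, AD_alt): Poisson total, binomial split for hets."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    gt = np.asarray(gt)
    dp = rng.poisson(mean_depth, size=gt.shape).astype(np.int32)
    alt_reads = np.zeros_like(dp)
    het = gt == 1
    alt_reads[het] = rng.binomial(dp[het], 0.5)
    alt_reads[gt == 2] = dp[gt == 2]
    ref_reads = dp - alt_reads
    return dp, ref_reads, alt_reads


# ---------------------------------------------------------------------------
# gene models, GO DAG, annotations


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG followed by random non-stop codons."""
    codons = ["ATG"]
    while len(codons) < n_codons:
        cod = "".join(BASES[rng.integers(0, 4, 3)])
        if cod not in STOP_CODONS:
            codons.append(cod)
    return "".join(codons)


def _choice_len(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def generate_annotations(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], pd.DataFrame, str]:
    """Place non-overlapping gene models and build the toy GO DAG.

    Returns (genes, features, cds, gene2go, obo_text).  ``features`` lists
    blocks in transcription order (feature in {utr5, cds, intron, utr3},
    1-based inclusive genomic coordinates).  At least
    ``small_intron_gene_fraction`` of genes carry an intron <= 65 bp so the
    neutral small-intron background is non-empty.
    """
    euch = config.euchromatin()
    arm_names = [a for a, _ in config.arms]
    lengths = {r["arm"]: r["end"] - r["start"] + 1 for _, r in euch.iterrows()}
    total = sum(lengths.values())
    per_arm = {a: max(1, round(config.n_genes * lengths[a] / total)) for a in arm_names}
    # adjust rounding to hit n_genes exactly
    while sum(per_arm.values()) > config.n_genes:
        per_arm[max(per_arm, key=per_arm.get)] -= 1
    while sum(per_arm.values()) < config.n_genes:
        per_arm[min(per_arm, key=per_arm.get)] += 1

    gene_rows, feat_rows = [], []
    cds: dict[str, str] = {}
    gid = 0
    for arm in arm_names:
        bounds = euch[euch["arm"] == arm].iloc[0]
        cursor = int(bounds["start"]) + 1_200  # room for the first promoter
        for _ in range(per_arm[arm]):
            gid += 1
            gene_id = f"SG{gid:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            small = rng.random() < config.small_intron_gene_fraction
            n_cds_exons = 2 + int(rng.random() < 0.5)
            cds_lens = [3 * _choice_len(rng, 30, 150) for _ in range(n_cds_exons)]
            intron_lens = []
            for k in range(n_cds_exons - 1):
                if small and k == 0:
                    intron_lens.append(_choice_len(rng, 55, 65))
                else:
                    intron_lens.append(_choice_len(rng, 200, 800))
            utr5 = _choice_len(rng, 80, 250)
            utr3 = _choice_len(rng, 80, 250)
            blocks = [("utr5", utr5)]
            for k, clen in enumerate(cds_lens):
                blocks.append(("cds", clen))
                if k < len(intron_lens):
                    blocks.append(("intron", intron_lens[k]))
            blocks.append(("utr3", utr3))
            span = sum(b[1] for b in blocks)
            if cursor + span > int(bounds["end"]) - 1_200:
                break  # arm full; remaining genes dropped for this arm
            tx_start, tx_end = cursor, cursor + span - 1
            # lay blocks on the genome: transcription order equals genomic
            # order on '+', reversed on '-'
            genomic = blocks if strand == "+" else blocks[::-1]
            g_cursor = tx_start
            placed = []
            for feat, length in genomic:
                placed.append((feat, g_cursor, g_cursor + length - 1))
                g_cursor += length
            if strand == "-":
                placed = placed[::-1]  # back to transcription order
            tss = tx_start if strand == "+" else tx_end
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "arm": arm,
                    "strand": strand,
                    "tss": tss,
                    "tx_start": tx_start,
                    "tx_end": tx_end,
                }
            )
            for order, (feat, s, e) in enumerate(placed):
                feat_rows.append(
                    {"gene_id": gene_id, "order": order, "feature": feat, "start": s, "end": e}
                )
            cds[gene_id] = _random_cds(sum(cds_lens) // 3, rng)
            cursor = tx_end + _choice_len(rng, 2_500, 5_000)

    if not gene_rows:
        raise ValueError("arms too short to place any gene model")
    genes = pd.DataFrame(gene_rows)
    features = pd.DataFrame(feat_rows)

    # toy GO DAG: one root, four intermediates, sixteen leaves
    intermediates = {
        "GO:0050896": "response to stimulus",
        "GO:0032502": "developmental process",
        "GO:0008152": "metabolic process",
        "GO:0002376": "immune system process",
    }
    leaves = {
        "GO:0009410": ("response to xenobiotic stimulus", ["GO:0050896"]),
        "GO:0009266": ("response to temperature stimulus", ["GO:0050896"]),
        "GO:0006950": ("response to stress", ["GO:0050896"]),
        "GO:0048066": ("pigmentation", ["GO:0032502"]),
        "GO:0007444": ("imaginal disc development", ["GO:0032502"]),
        "GO:0007297": ("ovarian follicle cell migration", ["GO:0032502"]),
        "GO:0030707": ("ovarian follicle cell development", ["GO:0032502"]),
        "GO:0006955": ("immune response", ["GO:0002376", "GO:0050896"]),
        "GO:0019731": ("antibacterial humoral response", ["GO:0002376"]),
        "GO:0008610": ("lipid biosynthetic process", ["GO:0008152"]),
        "GO:0006629": ("lipid metabolic process", ["GO:0008152"]),
        "GO:0005975": ("carbohydrate metabolic process", ["GO:0008152"]),
        "GO:0006508": ("proteolysis", ["GO:0008152"]),
        "GO:0007608": ("sensory perception of smell", ["GO:0050896"]),
        "GO:0007186": ("G protein-coupled receptor signaling", ["GO:0050896"]),
        "GO:0040003": ("chitin-based cuticle development", ["GO:0032502"]),
    }
    buf = io.StringIO()
    buf.write("format-version: 1.2\nontology: go-toy\n")
    buf.write("\n[Term]\nid: GO:0008150\nname: biological_process\nnamespace: biological_process\n")
    for tid, name in intermediates.items():
        buf.write(f"\n[Term]\nid: {tid}\nname: {name}\nnamespace: biological_process\n")
        buf.write("is_a: GO:0008150 ! biological_process\n")
    for tid, (name, parents) in leaves.items():
        buf.write(f"\n[Term]\nid: {tid}\nname: {name}\nnamespace: biological_process\n")
        for p in parents:
            buf.write(f"is_a: {p} ! parent\n")
    obo_text = buf.getvalue()

    leaf_ids = list(leaves)
    g2g_rows = []
    for gene_id in genes["gene_id"]:
        k = 1 + int(rng.integers(0, 3))
        for tid in rng.choice(leaf_ids, size=k, replace=False):
            g2g_rows.append({"gene_id": gene_id, "go_id": tid})
    gene2go = pd.DataFrame(g2g_rows).drop_duplicates().reset_index(drop=True)
    return genes, features, cds, gene2go, obo_text


def small_intron_windows(features: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Genomic spans of positions 8-30 (5' end, transcribed strand) of introns <= 65 bp."""
    strand = genes.set_index("gene_id")["strand"]
    arm = genes.set_index("gene_id")["arm"]
    rows = []
    introns = features[features["feature"] == "intron"]
    for _, it in introns.iterrows():
        length = it["end"] - it["start"] + 1
        if length > 65 or length < 30:
            continue
        if strand[it["gene_id"]] == "+":
            s, e = it["start"] + 7, it["start"] + 29
        else:
            s, e = it["end"] - 29, it["end"] - 7
        rows.append({"arm": arm[it["gene_id"]], "start": int(s), "end": int(e), "gene_id": it["gene_id"]})
    return pd.DataFrame(rows, columns=["arm", "start", "end", "gene_id"])


# ---------------------------------------------------------------------------
# TE table


def _divergent_pair(
    F: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency pairs for loci under spatially antagonistic selection.

    Midpoint ~ U(0.4, 0.6); half-distance d = sqrt(F * pbar * qbar) so the
    parametric among/total variance ratio equals F; the favored population
    is chosen at random.
    """
    pbar = rng.uniform(0.4, 0.6, n)
    d = np.sqrt(F * pbar * (1 - pbar))
    sign = rng.choice([-1.0, 1.0], n)
    p1 = np.clip(pbar + sign * d, 0.01, 0.99)
    p2 = np.clip(pbar - sign * d, 0.01, 0.99)
    return p1, p2


def generate_te_table(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """T-lex-style presence/absence table plus its ground truth.

    Calls are 'P' (present), 'A' (absent) or '-' (missing).  The table
    mixes fixed, rare, missing-heavy (undetermined) and common TEs; a few
    planted selected TEs have strongly divergent frequencies.
    """
    if config.n_te < 1:
        raise ValueError("n_te must be >= 1")
    n = config.n_te
    n_fixed = round(config.te_fixed_frac * n)
    n_rare = round(config.te_rare_frac * n)
    n_undet = round(config.te_undetermined_frac * n)
    n_sel = min(config.n_te_selected, n - n_fixed - n_rare - n_undet)
    n_common = n - n_fixed - n_rare - n_undet - n_sel
    kinds = (
        ["fixed"] * n_fixed
        + ["rare"] * n_rare
        + ["undetermined"] * n_undet
        + ["common"] * n_common
        + ["selected"] * n_sel
    )
    kinds = list(rng.permutation(kinds))

    p1 = np.empty(n)
    p2 = np.empty(n)
    for i, kind in enumerate(kinds):
        if kind == "fixed":
            p1[i] = p2[i] = 1.0
        elif kind == "rare":
            p1[i], p2[i] = rng.uniform(0.0, 0.04, 2)
        elif kind == "undetermined":
            p1[i], p2[i] = rng.uniform(0.2, 0.8, 2)
        elif kind == "common":
            f = simulate_site_frequencies(rng.uniform(0.15, 0.85), config.baseline_F, 2, rng)
            p1[i], p2[i] = float(f[0]), float(f[1])
        else:  # selected
            a, b = _divergent_pair(config.selected_F, 1, rng)
            p1[i], p2[i] = float(a[0]), float(b[0])

    strains1 = [f"{config.pop_names[0]}_s{i + 1:02d}" for i in range(config.n_strains_pop1)]
    strains2 = [f"{config.pop_names[1]}_s{i + 1:02d}" for i in range(config.n_strains_pop2)]
    arms = [a for a, _ in config.arms]
    arm_pick = rng.choice(arms, n)
    pos = rng.integers(100_000, 900_000, n)
    fams = rng.choice(TE_FAMILIES, n)

    rows = []
    truth_rows = []
    for i in range(n):
        te_id = f"TE{i + 1:04d}"
        miss_rate = 0.5 if kinds[i] == "undetermined" else config.te_missing_rate
        row = {"te_id": te_id, "family": fams[i], "arm": arm_pick[i], "pos": int(pos[i])}
        for strains, p in ((strains1, p1[i]), (strains2, p2[i])):
            for s in strains:
                if rng.random() < miss_rate:
                    row[s] = "-"
                else:
                    row[s] = "P" if rng.random() < p else "A"
        rows.append(row)
        truth_rows.append(
            {
                "te_id": te_id,
                "kind": kinds[i],
                "freq_pop1": p1[i],
                "freq_pop2": p2[i],
                "selected": kinds[i] == "selected",
            }
        )
    te_table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return te_table, truth


# ---------------------------------------------------------------------------
# whole-cohort assembly


def _sample_positions(
    rng: np.random.Generator, lo: int, hi: int, n: int, taken: set[int]
) -> list[int]:
    out: list[int] = []
    while len(out) < n:
        cand = rng.integers(lo, hi + 1, size=max(8, 2 * (n - len(out))))
        for p in cand:
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
                if len(out) == n:
                    break
    return out


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full synthetic cohort (in memory)."""
    rng = np.random.default_rng(config.seed)
    euch = config.euchromatin()
    genes, features, cds, gene2go, obo_text = generate_annotations(config, rng)

    # --- site placement -----------------------------------------------------
    arm_names = [a for a, _ in config.arms]
    lengths = {r["arm"]: r["end"] - r["start"] + 1 for _, r in euch.iterrows()}
    total_len = sum(lengths.values())
    windows = small_intron_windows(features, genes)
    n_bg = round(config.small_intron_site_fraction * config.n_sites)
    taken: dict[str, set[int]] = {a: set() for a in arm_names}
    pos_by_arm: dict[str, list[int]] = {a: [] for a in arm_names}
    if len(windows) and n_bg:
        widx = rng.integers(0, len(windows), n_bg)
        for i in widx:
            w = windows.iloc[int(i)]
            p = int(rng.integers(w["start"], w["end"] + 1))
            if p not in taken[w["arm"]]:
                taken[w["arm"]].add(p)
                pos_by_arm[w["arm"]].append(p)
    n_rest = config.n_sites - sum(len(v) for v in pos_by_arm.values())
    alloc = {a: round(n_rest * lengths[a] / total_len) for a in arm_names}
    while sum(alloc.values()) > n_rest:
        alloc[max(alloc, key=alloc.get)] -= 1
    while sum(alloc.values()) < n_rest:
        alloc[min(alloc, key=alloc.get)] += 1
    for arm in arm_names:
        b = euch[euch["arm"] == arm].iloc[0]
        pos_by_arm[arm].extend(
            _sample_positions(rng, int(b["start"]), int(b["end"]), alloc[arm], taken[arm])
        )

    sites = pd.concat(
        [
            pd.DataFrame({"arm": arm, "pos": sorted(pos_by_arm[arm])})
            for arm in arm_names
        ],
        ignore_index=True,
    )
    n_sites = len(sites)
    site_arm = sites["arm"].to_numpy()
    site_pos = sites["pos"].to_numpy()

    # --- inversion markers ---------------------------------------------------
    inv_arm, inv_start, inv_end = config.inversion_region
    marker_pos = sorted(
        _sample_positions(
            rng, inv_start, inv_end, config.n_inversion_markers, taken[inv_arm]
        )
    )
    markers = pd.DataFrame({"arm": inv_arm, "pos": marker_pos, "tag_allele": "alt"})
    msites = pd.DataFrame({"arm": inv_arm, "pos": marker_pos})
    sites = pd.concat([sites, msites], ignore_index=True)
    arm_rank = {a: i for i, a in enumerate(arm_names)}
    sites["_rank"] = sites["arm"].map(arm_rank)
    sites = (
        sites.sort_values(["_rank", "pos"], kind="mergesort")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    n_sites = len(sites)
    site_arm = sites["arm"].to_numpy()
    site_pos = sites["pos"].to_numpy()
    is_marker = np.zeros(n_sites, dtype=bool)
    mk = set(zip(markers["arm"], markers["pos"]))
    for i in range(n_sites):
        if (site_arm[i], site_pos[i]) in mk:
            is_marker[i] = True

    in_inversion = (site_arm == inv_arm) & (site_pos >= inv_start) & (site_pos <= inv_end)

    # --- selected sites ------------------------------------------------------
    n_sel = round(config.selected_fraction * n_sites)
    n_sel_genes = max(1, round(config.selected_gene_fraction * len(genes))) if n_sel else 0
    sel_gene_ids = (
        list(rng.choice(genes["gene_id"].to_numpy(), size=n_sel_genes, replace=False))
        if n_sel_genes
        else []
    )
    selected = np.zeros(n_sites, dtype=bool)
    gidx = genes.set_index("gene_id")
    for g in sel_gene_ids:
        row = gidx.loc[g]
        m = (site_arm == row["arm"]) & (site_pos >= row["tx_start"]) & (site_pos <= row["tx_end"])
        selected |= m & ~is_marker
    # fill remaining quota with intergenic sites (outside transcript+1kb spans)
    if selected.sum() < n_sel:
        in_gene_region = np.zeros(n_sites, dtype=bool)
        for _, row in genes.iterrows():
            lo = row["tx_start"] - (1_000 if row["strand"] == "+" else 0)
            hi = row["tx_end"] + (1_000 if row["strand"] == "-" else 0)
            in_gene_region |= (site_arm == row["arm"]) & (site_pos >= lo) & (site_pos <= hi)
        pool = np.flatnonzero(~in_gene_region & ~is_marker & ~in_inversion)
        extra = rng.choice(pool, size=min(len(pool), n_sel - int(selected.sum())), replace=False)
        selected[extra] = True

    # --- allele frequencies --------------------------------------------------
    p_anc = rng.uniform(0.05, 0.95, n_sites)
    F_site = np.full(n_sites, config.baseline_F)
    F_site[in_inversion] = min(config.baseline_F * config.inversion_f_multiplier, 0.95)
    freqs = simulate_site_frequencies(p_anc, F_site, 2, rng)
    p1, p2 = freqs[0].copy(), freqs[1].copy()
    sel_idx = np.flatnonzero(selected)
    s1, s2 = _divergent_pair(config.selected_F, len(sel_idx), rng)
    p1[sel_idx], p2[sel_idx] = s1, s2

    # --- genotypes -----------------------------------------------------------
    g1 = simulate_genotypes(p1, config.n_strains_pop1, config.inbreeding, rng)
    g2 = simulate_genotypes(p2, config.n_strains_pop2, config.inbreeding, rng)
    # inversion arrangement: homozygous per (inbred) strain, markers in
    # perfect association with it
    arr1 = (rng.random(config.n_strains_pop1) < config.inversion_freqs[0]).astype(np.int8)
    arr2 = (rng.random(config.n_strains_pop2) < config.inversion_freqs[1]).astype(np.int8)
    g1[is_marker] = 2 * arr1[None, :]
    g2[is_marker] = 2 * arr2[None, :]
    gt = np.concatenate([g1, g2], axis=1)

    # --- depths, missingness -------------------------------------------------
    dp, ad_ref, ad_alt = simulate_read_depths(gt, config.mean_depth, rng)
    miss = rng.random(gt.shape) < config.missing_rate
    gt = np.where(miss, -1, gt).astype(np.int8)
    dp = np.where(miss, -1, dp).astype(np.int32)
    ad_ref = np.where(miss, -1, ad_ref).astype(np.int32)
    ad_alt = np.where(miss, -1, ad_alt).astype(np.int32)

    # --- alleles -------------------------------------------------------------
    ref = BASES[rng.integers(0, 4, n_sites)].copy()
    # coding sites must carry the CDS base as REF (strand-aware)
    cds_lookup = _cds_base_lookup(genes, features, cds)
    for i in range(n_sites):
        base = cds_lookup.get((site_arm[i], int(site_pos[i])))
        if base is not None:
            ref[i] = base
    alt_off = rng.integers(1, 4, n_sites)
    base_idx = np.searchsorted(BASES, ref)
    alt = BASES[(base_idx + alt_off) % 4]
    multi = rng.random(n_sites) < config.multiallelic_fraction
    alt2 = BASES[(base_idx + ((alt_off + 1) % 3) + 1) % 4]
    alt_str = np.where(multi, np.char.add(np.char.add(alt, ","), alt2), alt)

    sites["ref"] = ref
    sites["alt"] = alt_str
    sites["is_snv"] = True
    sites["is_biallelic"] = ~multi

    strains = [f"{config.pop_names[0]}_s{i + 1:02d}" for i in range(config.n_strains_pop1)] + [
        f"{config.pop_names[1]}_s{i + 1:02d}" for i in range(config.n_strains_pop2)
    ]
    populations = np.array(
        [config.pop_names[0]] * config.n_strains_pop1 + [config.pop_names[1]] * config.n_strains_pop2,
        dtype=object,
    )
    matrix = GenotypeMatrix(
        sites=sites,
        strains=strains,
        populations=populations,
        gt=gt,
        dp=dp,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
    )

    # --- masks ---------------------------------------------------------------
    repeats = _place_repeats(config, genes, rng)
    indels = _place_indels(config, genes, selected, site_arm, site_pos, rng)

    # --- TE table ------------------------------------------------------------
    te_table, truth_tes = generate_te_table(config, rng)

    # --- truth ---------------------------------------------------------------
    truth_sites = pd.DataFrame(
        {
            "site_id": [f"{a}:{p}" for a, p in zip(site_arm, site_pos)],
            "arm": site_arm,
            "pos": site_pos,
            "p_anc": p_anc,
            "p_pop1": p1,
            "p_pop2": p2,
            "selected": selected,
            "is_marker": is_marker,
        }
    )
    contains = []
    for _, row in genes.iterrows():
        m = (
            (site_arm == row["arm"])
            & (site_pos >= row["tx_start"])
            & (site_pos <= row["tx_end"])
            & selected
        )
        contains.append(bool(m.any()))
    truth_genes = pd.DataFrame({"gene_id": genes["gene_id"], "contains_selected": contains})

    inv_freqs = {
        config.pop_names[0]: float(arr1.mean()),
        config.pop_names[1]: float(arr2.mean()),
    }
    return Cohort(
        config=config,
        matrix=matrix,
        genes=genes,
        features=features,
        cds=cds,
        gene2go=gene2go,
        obo_text=obo_text,
        te_table=te_table,
        markers=markers,
        euchromatin=euch,
        repeats=repeats,
        indels=indels,
        truth_sites=truth_sites,
        truth_genes=truth_genes,
        truth_tes=truth_tes,
        inversion_sample_freqs=inv_freqs,
    )


def _cds_base_lookup(
    genes: pd.DataFrame, features: pd.DataFrame, cds: dict[str, str]
) -> dict[tuple[str, int], str]:
    """Map genomic (arm, pos) of every CDS base to its reference nucleotide."""
    out: dict[tuple[str, int], str] = {}
    strand = genes.set_index("gene_id")["strand"]
    arm = genes.set_index("gene_id")["arm"]
    for gene_id, blocks in features[features["feature"] == "cds"].groupby("gene_id"):
        seq = cds[gene_id]
        st = strand[gene_id]
        offset = 0
        for _, blk in blocks.sort_values("order").iterrows():
            length = blk["end"] - blk["start"] + 1
            for j in range(length):
                base = seq[offset + j]
                if st == "+":
                    gpos = blk["start"] + j
                    out[(arm[gene_id], int(gpos))] = base
                else:
                    gpos = blk["end"] - j
                    out[(arm[gene_id], int(gpos))] = _COMP[base]
            offset += length
    return out


def _place_repeats(
    config: SimConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Repeat intervals in intergenic space (repeats are gene-depleted)."""
    rows = []
    euch = config.euchromatin()
    arm_names = [a for a, _ in config.arms]
    for _ in range(config.n_repeats):
        arm = str(rng.choice(arm_names))
        b = euch[euch["arm"] == arm].iloc[0]
        for _attempt in range(50):
            s = int(rng.integers(b["start"], b["end"] - config.repeat_length))
            e = s + config.repeat_length - 1
            g = genes[genes["arm"] == arm]
            if not ((g["tx_start"] - 1_000 <= e) & (g["tx_end"] + 1_000 >= s)).any():
                rows.append({"arm": arm, "start": s, "end": e})
                break
    return pd.DataFrame(rows, columns=["arm", "start", "end"]).sort_values(
        ["arm", "start"]
    ).reset_index(drop=True)


def _place_indels(
    config: SimConfig,
    genes: pd.DataFrame,
    selected: np.ndarray,
    site_arm: np.ndarray,
    site_pos: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Random short indel spans, avoiding planted selected sites (+-6 bp)."""
    rows = []
    euch = config.euchromatin()
    arm_names = [a for a, _ in config.arms]
    sel_by_arm = {
        a: np.sort(site_pos[(site_arm == a) & selected]) for a in arm_names
    }
    for _ in range(config.n_indels):
        arm = str(rng.choice(arm_names))
        b = euch[euch["arm"] == arm].iloc[0]
        for _attempt in range(50):
            s = int(rng.integers(b["start"], b["end"] - 10))
            e = s + int(rng.integers(1, 9))
            near = sel_by_arm[arm]
            i = np.searchsorted(near, s - 6)
            if i < len(near) and near[i] <= e + 6:
                continue
            rows.append({"arm": arm, "start": s, "end": e})
            break
    return pd.DataFrame(rows, columns=["arm", "start", "end"]).sort_values(
        ["arm", "start"]
    ).reset_index(drop=True)


def simulate_snp_count_bias_scores(
    seed: int,
    n_genes: int = 2_000,
    max_snps: int = 100,
    baseline_F: float = 0.05,
    n_strains_pop1: int = 26,
    n_strains_pop2: int = 16,
    inbreeding: float = 0.95,
    n_arms: int = 5,
) -> pd.DataFrame:
    """Gene max-F_ST scores with a planted SNP-count bias.

    Simulates one pool of null (Balding-Nichols) per-SNP theta values and
    assembles genes whose SNP counts vary over 1..``max_snps`` (log-uniform),
    each gene taking the maximum theta over its SNPs.  Because the maximum
    of more draws is stochastically larger, E[Z] increases with n_snps --
    the bias the 16-bin median correction is designed to remove.  Returns
    the gene frame (gene_id, arm, n_snps, max_fst) ready for
    :func:`eurodiff.genescore.z_normalize_per_arm`.
    """
    from eurodiff.fst import site_fst_wc

    rng = np.random.default_rng(seed)
    n_snps = np.exp(rng.uniform(0, np.log(max_snps), n_genes)).astype(int).clip(1, max_snps)
    total = int(n_snps.sum())
    p_anc = rng.uniform(0.05, 0.95, total)
    freqs = simulate_site_frequencies(p_anc, baseline_F, 2, rng)
    g1 = simulate_genotypes(freqs[0], n_strains_pop1, inbreeding, rng)
    g2 = simulate_genotypes(freqs[1], n_strains_pop2, inbreeding, rng)
    _, theta = site_fst_wc(g1, g2)
    theta = np.where(np.isfinite(theta), theta, 0.0)
    bounds = np.concatenate([[0], np.cumsum(n_snps)])
    max_fst = np.array([theta[bounds[i] : bounds[i + 1]].max() for i in range(n_genes)])
    return pd.DataFrame(
        {
            "gene_id": [f"BG{i + 1:05d}" for i in range(n_genes)],
            "arm": [f"arm{1 + i % n_arms}" for i in range(n_genes)],
            "n_snps": n_snps,
            "max_fst": max_fst,
        }
    )


# ---------------------------------------------------------------------------
# file emission


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write every cohort artefact to ``outdir``; returns name -> path.

    Formats: VCFv4.2 (GT:DP:AD), BED (0-based half-open) masks, indel span
    TSV, gene-model TSV with transcription-order feature blocks, CDS FASTA,
    OBO 1.2, gene2go TSV, T-lex-style TE TSV, marker TSV, population TSV
    and ground-truth TSVs.
    """
    from pathlib import Path

    from eurodiff.vcfio import write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> "Path":
        paths[name] = str(outdir / name)
        return outdir / name

    write_vcf(cohort.matrix, _p("cohort.vcf"), contigs=dict(cohort.config.arms))

    euch = cohort.euchromatin.copy()
    euch["start0"] = euch["start"] - 1
    euch[["arm", "start0", "end"]].to_csv(
        _p("euchromatin.bed"), sep="\t", header=False, index=False
    )
    rep = cohort.repeats.copy()
    if len(rep):
        rep["start0"] = rep["start"] - 1
        rep[["arm", "start0", "end"]].to_csv(
            _p("repeats.bed"), sep="\t", header=False, index=False
        )
    else:
        _p("repeats.bed").write_text("")
    cohort.indels.to_csv(_p("indels.tsv"), sep="\t", index=False)

    feats = cohort.features.sort_values(["gene_id", "order"])
    blocks = feats.groupby("gene_id").apply(
        lambda g: ";".join(f"{r.feature}:{r.start}-{r.end}" for r in g.itertuples()),
        include_groups=False,
    )
    gm = cohort.genes.copy()
    gm["blocks"] = gm["gene_id"].map(blocks)
    gm.to_csv(_p("genes.tsv"), sep="\t", index=False)

    with open(_p("cds.fasta"), "w") as fh:
        for gene_id in cohort.genes["gene_id"]:
            fh.write(f">{gene_id}\n{cohort.cds[gene_id]}\n")

    _p("go.obo").write_text(cohort.obo_text)
    cohort.gene2go.to_csv(_p("gene2go.tsv"), sep="\t", index=False)
    cohort.te_table.to_csv(_p("te_calls.tsv"), sep="\t", index=False)
    cohort.markers.to_csv(_p("inversion_markers.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {"strain": cohort.matrix.strains, "population": cohort.matrix.populations}
    ).to_csv(_p("populations.tsv"), sep="\t", index=False)
    cohort.truth_sites.to_csv(_p("truth_sites.tsv"), sep="\t", index=False)
    cohort.truth_genes.to_csv(_p("truth_genes.tsv"), sep="\t", index=False)
    cohort.truth_tes.to_csv(_p("truth_tes.tsv"), sep="\t", index=False)
    return paths
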