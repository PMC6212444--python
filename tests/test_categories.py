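"""Functional-category assignment and stratified enrichment."""

import numpy as np
import pandas as pd
import pytest

from eurodiff import categories
from eurodiff.categories import annotate_sites, enrichment_test, load_gene_models


def one_gene_models(strand="+"):
    """A single plus/minus-strand gene with a small and a large intron.

    Plus-strand layout starting at 10,000: utr5 10000-10199,
    cds 10200-10499, intron 10500-10560 (61 bp, small), cds 10561-10860,
    intron 10861-11260 (400 bp), cds 11261-11360, utr3 11361-11560.
    """
    blocks = [
        ("utr5", 10_000, 10_199),
        ("cds", 10_200, 10_499),
        ("intron", 10_500, 10_560),
        ("cds", 10_561, 10_860),
        ("intron", 10_861, 11_260),
        ("cds", 11_261, 11_360),
        ("utr3", 11_361, 11_560),
    ]
    if strand == "-":
        blocks = [(f if f in ("cds", "intron") else {"utr5": "utr3", "utr3": "utr5"}[f], s, e)
                  for f, s, e in blocks][::-1]
    genes = pd.DataFrame(
        [
            {
                "gene_id": "G1",
                "arm": "2L",
                "strand": strand,
                "tss": 10_000 if strand == "+" else 11_560,
                "tx_start": 10_000,
                "tx_end": 11_560,
            }
        ]
    )
    features = pd.DataFrame(
        [
            {"gene_id": "G1", "order": i, "feature": f, "start": s, "end": e}
            for i, (f, s, e) in enumerate(blocks)
        ]
    )
    n_codons = (300 + 300 + 100) // 3
    cds = {"G1": "ATG" + "TTT" * (n_codons - 1)}
    return genes, features, cds


def site_frame(positions, ref="T", alt="C"):
    return pd.DataFrame(
        {"arm": "2L", "pos": positions, "ref": ref, "alt": alt}
    )


class TestAnnotatePrecedence:
    def test_promoter_boundaries_plus_strand(self):
        genes, features, cds = one_gene_models("+")
        sites = site_frame([10_000 - 316, 10_000 - 317, 10_000 - 1_000, 10_000 - 1_001])
        cat = annotate_sites(sites, genes, features, cds)["category"]
        assert list(cat) == ["core_promoter", "promoter", "promoter", "intergenic"]

    def test_promoter_strand_awareness(self):
        genes, features, cds = one_gene_models("-")
        sites = site_frame([11_560 + 316, 11_560 + 317, 11_560 + 1_000, 11_560 + 1_001])
        cat = annotate_sites(sites, genes, features, cds)["category"]
        assert list(cat) == ["core_promoter", "promoter", "promoter", "intergenic"]

    def test_small_intron_offsets(self):
        genes, features, cds = one_gene_models("+")
        # small intron 10500-10560 (61 bp): offsets 8 and 30 in background,
        # 31 out; offset 8 of the 400-bp intron is not background
        sites = site_frame([10_507, 10_529, 10_530, 10_868])
        cat = annotate_sites(sites, genes, features, cds)["category"]
        assert list(cat) == ["small_intron_bg", "small_intron_bg", "intron_other", "intron_other"]

    def test_splice_sites_override_intron(self):
        genes, features, cds = one_gene_models("+")
        sites = site_frame([10_500, 10_501, 10_559, 10_560, 10_502])
        cat = annotate_sites(sites, genes, features, cds)["category"]
        assert list(cat[:4]) == ["splice_site"] * 4
        assert cat.iloc[4] != "splice_site"

    def test_utr_categories(self):
        genes, features, cds = one_gene_models("+")
        cat = annotate_sites(site_frame([10_050, 11_400]), genes, features, cds)["category"]
        assert list(cat) == ["utr5", "utr3"]

    def test_synonymous_vs_nonsynonymous(self):
        genes, features, cds = one_gene_models("+")
        # codon 2 is TTT (Phe) at 10203-10205: third position T->C is
        # synonymous (TTC = Phe); first position T->C gives CTT (Leu)
        syn = annotate_sites(site_frame([10_205], ref="T", alt="C"), genes, features, cds)
        non = annotate_sites(site_frame([10_203], ref="T", alt="C"), genes, features, cds)
        assert syn["category"].iloc[0] == "coding_syn"
        assert non["category"].iloc[0] == "coding_nonsyn"

    def test_minus_strand_codon_uses_complement(self):
        genes, features, cds = one_gene_models("-")
        # last CDS block on genome (10200-10499) is the CDS tail; the third
        # position of codon 2 lies at genomic end-4... verify a known syn site:
        # transcription runs right-to-left, CDS offset 5 (codon 2, pos 3)
        # is genomic 11360 - 5 = 11355 on the minus strand; genome REF is
        # the complement of 'T' = 'A', alt 'G' complements to 'C' -> TTC syn
        res = annotate_sites(site_frame([11_355], ref="A", alt="G"), genes, features, cds)
        assert res["category"].iloc[0] == "coding_syn"

    def test_ref_mismatch_logged_as_unknown(self):
        genes, features, cds = one_gene_models("+")
        res = annotate_sites(site_frame([10_205], ref="G", alt="C"), genes, features, cds)
        assert res["category"].iloc[0] == "coding_unknown"
        assert res.attrs["n_unresolved"] == 1

    def test_every_site_gets_exactly_one_category(self, cohort, scan):
        cat = annotate_sites(
            scan[["arm", "pos", "ref", "alt"]], cohort.genes, cohort.features, cohort.cds
        )
        assert len(cat) == len(scan)
        assert cat["category"].notna().all()
        counts = cat["category"].value_counts()
        assert counts.sum() == len(scan)
        assert counts.get("small_intron_bg", 0) > 0


class TestEnrichment:
    @staticmethod
    def _frames(cat_tier, cat_not, bg_tier, bg_not):
        cats = ["coding_nonsyn"] * (cat_tier + cat_not) + ["small_intron_bg"] * (
            bg_tier + bg_not
        )
        tier = (
            [True] * cat_tier + [False] * cat_not + [True] * bg_tier + [False] * bg_not
        )
        n = len(cats)
        calls = pd.DataFrame({"category": cats})
        scan = pd.DataFrame(
            {
                "maf": 0.2,
                "arm": "2L",
                "inside_inversion": False,
                "in_top5": tier,
            }
        )
        return calls, scan

    def test_single_stratum_fisher_enumeration(self):
        # [[3,0],[0,3]]: two-sided Fisher p = 2/20 = 0.1 (hypergeometric)
        calls, scan = self._frames(3, 0, 0, 3)
        res = enrichment_test(calls, scan, "in_top5", n_maf_bins=1)
        from scipy.stats import hypergeom

        # enumeration: N=6, K=3 in tier, n=3 category; tables as extreme: k=3 or k=0
        p_oracle = hypergeom.pmf(3, 6, 3, 3) + hypergeom.pmf(0, 6, 3, 3)
        assert p_oracle == pytest.approx(0.1)
        assert res["p_fisher"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_independence_gives_or_one_p_one(self):
        calls, scan = self._frames(10, 10, 10, 10)
        res = enrichment_test(calls, scan, "in_top5", n_maf_bins=1)
        assert res["or_fisher"].iloc[0] == pytest.approx(1.0)
        assert res["p_fisher"].iloc[0] == pytest.approx(1.0)
        assert res["or_cmh"].iloc[0] == pytest.approx(1.0)

    def test_duplicated_stratum_leaves_cmh_or_unchanged(self):
        calls, scan = self._frames(12, 6, 5, 9)
        one = enrichment_test(calls, scan, "in_top5", n_maf_bins=1)
        calls2 = pd.concat([calls, calls], ignore_index=True)
        scan2 = pd.concat([scan, scan.assign(arm="2R")], ignore_index=True)
        two = enrichment_test(calls2, scan2, "in_top5", n_maf_bins=1)
        assert two["or_cmh"].iloc[0] == pytest.approx(one["or_cmh"].iloc[0], rel=1e-12)

    def test_empty_background_rejected(self):
        calls = pd.DataFrame({"category": ["coding_syn", "intergenic"]})
        scan = pd.DataFrame(
            {"maf": [0.1, 0.2], "arm": "2L", "inside_inversion": False, "in_top5": [True, False]}
        )
        with pytest.raises(ValueError):
            enrichment_test(calls, scan, "in_top5")

    def test_category_counts_sum(self, cohort, scan):
        cat = annotate_sites(
            scan[["arm", "pos", "ref", "alt"]], cohort.genes, cohort.features, cohort.cds
        )
        res = enrichment_test(cat, scan, "in_top5")
        n_bg = (cat["category"] == "small_intron_bg").sum()
        assert (res["n_background"] == n_bg).all()
        assert (
            res["n_category"].sum() + n_bg
            == len(cat)
        )


class TestGeneModelRoundTrip:
    def test_load_gene_models_matches_cohort(self, cohort, cohort_dir):
        genes, features, cds = load_gene_models(
            cohort_dir["genes.tsv"], cohort_dir["cds.fasta"]
        )
        pd.testing.assert_frame_equal(
            genes.sort_values("gene_id").reset_index(drop=True),
            cohort.genes.sort_values("gene_id").reset_index(drop=True),
        )
        assert cds == cohort.cds
        f1 = features.sort_values(["gene_id", "order"]).reset_index(drop=True)
        f2 = cohort.features.sort_values(["gene_id", "order"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(f1[f2.columns], f2)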