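"""TE presence/absence loading, classification, F_ST and candidate calls."""

import io

import numpy as np
import pandas as pd
import pytest

from eurodiff import te
from eurodiff.fst import site_fst_wc


def te_tsv(rows, strains):
    header = ["te_id", "family", "arm", "pos"] + strains
    lines = ["\t".join(header)]
    for r in rows:
        lines.append("\t".join(str(x) for x in r))
    return io.StringIO("\n".join(lines))


STRAINS = [f"s{i}" for i in range(1, 6)]
POPS5 = {f"s{i}": ("pop1" if i <= 3 else "pop2") for i in range(1, 6)}


class TestLoad:
    def test_small_table_parses(self):
        src = te_tsv(
            [
                ["TE1", "roo", "2L", 100, "P", "A", "P", "-", "A"],
                ["TE2", "pogo", "2R", 200, "P", "P", "P", "P", "P"],
                ["TE3", "roo", "X", 300, "A", "A", "A", "A", "A"],
            ],
            STRAINS,
        )
        df = te.load_te_calls(src, strains=STRAINS)
        assert len(df) == 3
        assert df.loc[0, "s4"] == "-"

    def test_duplicate_te_id_rejected(self):
        src = te_tsv(
            [["TE1", "roo", "2L", 100] + ["P"] * 5, ["TE1", "roo", "2L", 200] + ["A"] * 5],
            STRAINS,
        )
        with pytest.raises(ValueError, match="duplicate"):
            te.load_te_calls(src)

    def test_unknown_symbol_rejected_with_coordinates(self):
        src = te_tsv([["TE1", "roo", "2L", 100, "P", "X", "P", "A", "A"]], STRAINS)
        with pytest.raises(ValueError, match="2L:100"):
            te.load_te_calls(src)

    def test_strain_mismatch_rejected(self):
        src = te_tsv([["TE1", "roo", "2L", 100, "P", "A", "P", "A", "P"]], STRAINS)
        with pytest.raises(ValueError):
            te.load_te_calls(src, strains=STRAINS + ["s99"])


class TestClassify:
    def test_paper_style_accounting(self):
        # printed classification counts: 1,632 total = 556 low + 893 fixed
        # + 22 undetermined leaves exactly 161 testable
        strains = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        pops = {s: ("pop1" if s.startswith("a") else "pop2") for s in strains}
        rows = []
        kinds = ["low"] * 556 + ["fixed"] * 893 + ["undet"] * 22 + ["test"] * 161
        for i, kind in enumerate(kinds):
            calls = {
                "low": ["A"] * 20,
                "fixed": ["P"] * 20,
                "undet": ["-"] * 8 + ["P"] * 12,
                "test": ["P"] * 5 + ["A"] * 5 + ["A"] * 10,
            }[kind]
            rows.append([f"TE{i:04d}", "roo", "2L", 1_000 + i] + calls)
        df = te.load_te_calls(te_tsv(rows, strains), strains=strains)
        cls = te.classify_tes(df, pops, "pop1", "pop2")
        counts = cls["classification"].value_counts()
        assert counts["low_freq_both"] == 556
        assert counts["fixed_both"] == 893
        assert counts["undetermined"] == 22
        assert counts["testable"] == 161
        assert counts.sum() == 1_632

    def test_low_in_one_population_only_is_testable(self):
        strains = [f"a{i}" for i in range(13)] + [f"b{i}" for i in range(10)]
        pops = {s: ("pop1" if s.startswith("a") else "pop2") for s in strains}
        # 1/13 = 7.7% in pop1, 0% in pop2 -> not low in *both*
        rows = [["TE1", "roo", "2L", 100] + ["P"] + ["A"] * 22]
        df = te.load_te_calls(te_tsv(rows, strains), strains=strains)
        cls = te.classify_tes(df, pops, "pop1", "pop2")
        assert cls.loc[0, "classification"] == "testable"

    def test_present_in_all_called_is_fixed(self):
        # one missing call of five stays under the 30% missingness rule
        strains = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        pops = {s: ("pop1" if s.startswith("a") else "pop2") for s in strains}
        rows = [["TE1", "roo", "2L", 100, "P", "P", "-", "P", "P"] + ["P"] * 5]
        df = te.load_te_calls(te_tsv(rows, strains), strains=strains)
        cls = te.classify_tes(df, pops, "pop1", "pop2")
        assert cls.loc[0, "classification"] == "fixed_both"


class TestTeFst:
    def test_fixed_difference_te(self):
        rows = [["TE1", "roo", "2L", 100, "P", "P", "P", "A", "A"]]
        df = te.load_te_calls(te_tsv(rows, STRAINS), strains=STRAINS)
        cls = te.classify_tes(df, POPS5, "pop1", "pop2")
        out = te.te_fst(df, cls, POPS5, "pop1", "pop2")
        assert out.loc[0, "fst"] == pytest.approx(1.0, abs=1e-12)

    def test_equals_snp_encoding_exactly(self):
        rng = np.random.default_rng(11)
        strains = [f"a{i}" for i in range(12)] + [f"b{i}" for i in range(9)]
        pops = {s: ("pop1" if s.startswith("a") else "pop2") for s in strains}
        rows = []
        for i in range(100):
            calls = rng.choice(["P", "A", "-"], size=21, p=[0.45, 0.45, 0.1])
            rows.append([f"TE{i:03d}", "roo", "2L", 100 + i] + list(calls))
        df = te.load_te_calls(te_tsv(rows, strains), strains=strains)
        cls = te.classify_tes(df, pops, "pop1", "pop2", maf_min=0.0, max_missing=1.0)
        out = te.te_fst(df, cls, pops, "pop1", "pop2")
        # independent encoding: present = hom-alt dosage 2, absent = 0
        code = {"P": 2, "A": 0, "-": -1}
        g1 = np.array([[code[c] for c in row[4:16]] for row in rows])
        g2 = np.array([[code[c] for c in row[16:]] for row in rows])
        _, theta = site_fst_wc(g1, g2)
        got = out["fst"].to_numpy()
        mask = out["classification"].to_numpy() == "testable"
        np.testing.assert_array_equal(got[mask], theta[mask])

    def test_population_fully_missing_reclassified(self):
        rows = [["TE1", "roo", "2L", 100, "P", "A", "P", "-", "-"]]
        df = te.load_te_calls(te_tsv(rows, STRAINS), strains=STRAINS)
        cls = te.classify_tes(df, POPS5, "pop1", "pop2", max_missing=1.0)
        out = te.te_fst(df, cls, POPS5, "pop1", "pop2")
        assert out.loc[0, "classification"] == "undetermined"
        assert np.isnan(out.loc[0, "fst"])


class TestCandidates:
    def _thresholds(self):
        return pd.DataFrame(
            [
                {"arm": "2L", "tail": 0.05, "n_sites": 1_000, "n_tier": 50, "critical_fst": 0.30},
                {"arm": "2L", "tail": 0.01, "n_sites": 1_000, "n_tier": 10, "critical_fst": 0.60},
            ]
        )

    def _scored(self, fst_vals, arm="2L"):
        return pd.DataFrame(
            {
                "te_id": [f"TE{i}" for i in range(len(fst_vals))],
                "family": "roo",
                "arm": arm,
                "pos": np.arange(len(fst_vals)) + 100,
                "freq_pop1": 0.9,
                "freq_pop2": 0.1,
                "missing_pop1": 0.0,
                "missing_pop2": 0.0,
                "classification": "testable",
                "fst": fst_vals,
            }
        )

    def test_theta_one_is_candidate_at_all_tiers(self):
        out = te.te_candidates(self._scored([1.0]), self._thresholds(), tails=(0.05, 0.01))
        assert out.loc[0, "candidate_top5"] and out.loc[0, "candidate_top1"]
        assert out.loc[0, "direction"] == "pop1"

    def test_below_critical_is_not_candidate_and_tiers_monotone(self):
        out = te.te_candidates(
            self._scored([0.1, 0.45, 0.8]), self._thresholds(), tails=(0.05, 0.01)
        )
        assert not out.loc[0, "candidate_top5"]
        assert out.loc[1, "candidate_top5"] and not out.loc[1, "candidate_top1"]
        assert (out.loc[out["candidate_top1"].fillna(False), "candidate_top5"]).all()

    def test_arm_without_threshold_skipped(self):
        out = te.te_candidates(self._scored([0.9], arm="X"), self._thresholds(), tails=(0.05,))
        assert out.loc[0, "candidate_top5"] is None

    def test_planted_tes_recovered_against_snp_thresholds(self, cohort, scan, cohort_dir):
        from eurodiff import fst as fstmod
        from eurodiff.vcfio import read_populations

        thresholds = fstmod.arm_thresholds(scan)
        pops = read_populations(cohort_dir["populations.tsv"])
        table = te.load_te_calls(cohort_dir["te_calls.tsv"], strains=cohort.matrix.strains)
        cls = te.classify_tes(table, pops, "pop1", "pop2")
        out = te.te_candidates(te.te_fst(table, cls, pops, "pop1", "pop2"), thresholds)
        truth = cohort.truth_tes.set_index("te_id")
        planted = truth[truth["selected"]].index
        flags = out.set_index("te_id").loc[planted, "candidate_top5"]
        assert flags.fillna(False).mean() >= 0.5  # both planted TEs usually recovered
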