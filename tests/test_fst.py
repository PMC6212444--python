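"""Weir & Cockerham components, outlier tiers, ANOVA and inversion tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eurodiff import fst


def brute_force_wc(gt1, gt2):
    """Scalar re-derivation of the two-population diploid components."""
    out = []
    for row1, row2 in zip(np.atleast_2d(gt1), np.atleast_2d(gt2)):
        stats_ = []
        for row in (row1, row2):
            called = [g for g in row if g >= 0]
            n = len(called)
            p = sum(called) / (2 * n) if n else float("nan")
            h = sum(1 for g in called if g == 1) / n if n else float("nan")
            stats_.append((n, p, h))
        (n1, p1, h1), (n2, p2, h2) = stats_
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - s2 / 2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2
        out.append((a, b, c))
    return np.array(out)


class TestSiteFstWC:
    def test_fixed_difference_is_one(self):
        _, theta = fst.site_fst_wc(np.full((1, 10), 2), np.zeros((1, 10), dtype=int))
        assert theta[0] == 1.0

    def test_all_heterozygous_components(self):
        # p1 = p2 = 0.5, h = 1: a = 0, b = -0.25, c = 0.5, theta = 0
        comp, theta = fst.site_fst_wc(np.ones((1, 10), dtype=int), np.ones((1, 10), dtype=int))
        assert comp.a[0] == pytest.approx(0.0, abs=1e-15)
        assert comp.b[0] == pytest.approx(-0.25, abs=1e-12)
        assert comp.c[0] == pytest.approx(0.5, abs=1e-15)
        assert theta[0] == pytest.approx(0.0, abs=1e-14)

    def test_monomorphic_site_unusable(self):
        _, theta = fst.site_fst_wc(np.zeros((1, 8), dtype=int), np.zeros((1, 6), dtype=int))
        assert np.isnan(theta[0])

    def test_fully_missing_population_unusable(self):
        _, theta = fst.site_fst_wc(np.full((1, 5), -1), np.full((1, 5), 2))
        assert np.isnan(theta[0])

    def test_symmetric_in_population_labels(self):
        rng = np.random.default_rng(0)
        g1 = rng.integers(0, 3, (200, 12))
        g2 = rng.integers(0, 3, (200, 7))
        _, t_ab = fst.site_fst_wc(g1, g2)
        _, t_ba = fst.site_fst_wc(g2, g1)
        np.testing.assert_allclose(t_ab, t_ba, rtol=0, atol=1e-14)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        g1 = rng.integers(-1, 3, (1_000, 9))
        g2 = rng.integers(-1, 3, (1_000, 14))
        ok = ((g1 >= 0).sum(1) > 0) & ((g2 >= 0).sum(1) > 0)
        g1, g2 = g1[ok], g2[ok]
        comp, _ = fst.site_fst_wc(g1, g2)
        oracle = brute_force_wc(g1, g2)
        np.testing.assert_allclose(comp.a, oracle[:, 0], rtol=0, atol=1e-12)
        np.testing.assert_allclose(comp.b, oracle[:, 1], rtol=0, atol=1e-12)
        np.testing.assert_allclose(comp.c, oracle[:, 2], rtol=0, atol=1e-12)

    @given(
        n1=st.integers(min_value=1, max_value=25),
        n2=st.integers(min_value=2, max_value=25),
    )
    @settings(deadline=None, max_examples=60)
    def test_fixed_difference_identity_property(self, n1, n2):
        _, theta = fst.site_fst_wc(
            np.full((1, n1), 2, dtype=int), np.zeros((1, n2), dtype=int)
        )
        assert abs(theta[0] - 1.0) <= 5e-16


def scan_frame(fst_values, arm="2L", start=100):
    n = len(fst_values)
    return pd.DataFrame(
        {
            "arm": arm,
            "pos": np.arange(start, start + n),
            "ref": "A",
            "alt": "T",
            "a": np.asarray(fst_values),
            "b": 0.0,
            "c": 0.0,
            "fst": np.asarray(fst_values, dtype=float),
            "usable": True,
            "maf": 0.25,
            "inside_inversion": False,
        }
    )


class TestThresholdsAndTiers:
    def test_floor_rule_counts(self):
        rng = np.random.default_rng(1)
        sc = scan_frame(rng.random(1_000))
        thr = fst.arm_thresholds(sc, tails=(0.05,))
        assert thr.iloc[0]["n_tier"] == 50
        sc2 = scan_frame(rng.random(13_140))
        thr2 = fst.arm_thresholds(sc2, tails=(0.05,))
        assert thr2.iloc[0]["n_tier"] == 657

    def test_tiers_nest_and_critical_values_increase(self, scan):
        assert (scan.loc[scan["in_top0.5"], "in_top1"]).all()
        assert (scan.loc[scan["in_top1"], "in_top5"]).all()
        thr = fst.arm_thresholds(scan)
        for _, grp in thr.groupby("arm"):
            crit = grp.sort_values("tail", ascending=False)["critical_fst"].to_numpy()
            assert (np.diff(crit) >= 0).all()

    def test_tier_assignment_is_permutation_invariant(self):
        rng = np.random.default_rng(2)
        sc = scan_frame(rng.random(400))
        shuffled = sc.sample(frac=1.0, random_state=0).reset_index(drop=True)
        t1 = fst.assign_tiers(sc).sort_values("pos")["tier"].to_numpy()
        t2 = fst.assign_tiers(shuffled).sort_values("pos")["tier"].to_numpy()
        assert (t1 == t2).all()

    def test_scan_is_pure_per_site(self, filtered):
        # theta of a site does not depend on which other sites are present
        matrix, _ = filtered
        sc = fst.fst_scan(matrix, "pop1", "pop2")
        keep = np.zeros(matrix.n_sites, dtype=bool)
        keep[::7] = True
        sc_sub = fst.fst_scan(matrix.take_sites(keep), "pop1", "pop2")
        np.testing.assert_array_equal(
            sc.loc[keep, "fst"].to_numpy(), sc_sub["fst"].to_numpy()
        )

    def test_out_of_order_sites_rejected(self, filtered):
        matrix, _ = filtered
        perm = np.random.default_rng(3).permutation(matrix.n_sites)
        with pytest.raises(ValueError):
            matrix.take_sites(perm)


class TestAnova:
    def test_identical_group_multisets_give_zero_f(self):
        sc = pd.concat(
            [scan_frame([0.1, 0.2, 0.3], arm="2L"), scan_frame([0.1, 0.2, 0.3], arm="2R")],
            ignore_index=True,
        )
        f, p = fst.arm_heterogeneity_anova(sc)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_give_tiny_p(self):
        sc = pd.concat(
            [scan_frame([0, 0, 0, 1e-9], arm="2L"), scan_frame([1, 1, 1, 1 + 1e-9], arm="2R")],
            ignore_index=True,
        )
        f, p = fst.arm_heterogeneity_anova(sc)
        assert p < 1e-10

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [rng.normal(size=int(rng.integers(3, 20))) for _ in range(k)]
            sc = pd.concat(
                [scan_frame(g, arm=f"a{i}") for i, g in enumerate(groups)],
                ignore_index=True,
            )
            f, p = fst.arm_heterogeneity_anova(sc)
            # independent oracle: explicit between/within sums of squares
            allv = np.concatenate(groups)
            grand = allv.mean()
            ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            f_oracle = (ssb / (k - 1)) / (ssw / (len(allv) - k))
            assert f == pytest.approx(f_oracle, abs=1e-10)


class TestInversion:
    def test_mann_whitney_exact_small_sample(self):
        sc = scan_frame([1, 2, 3, 4, 5, 6])
        sc.loc[:2, "inside_inversion"] = True
        res = fst.inversion_contrast(sc, ("2L", 100, 102), tails=())
        # enumeration oracle: all C(6,3) splits, two-sided
        vals = [1, 2, 3, 4, 5, 6]
        obs_u = 0
        us = []
        for combo in itertools.combinations(range(6), 3):
            inside = [vals[i] for i in combo]
            outside = [vals[i] for i in range(6) if i not in combo]
            us.append(sum(1 for a in inside for b in outside if a > b))
        p_oracle = sum(1 for u in us if min(u, 9 - u) <= min(obs_u, 9 - obs_u)) / len(us)
        assert p_oracle == pytest.approx(0.1)
        assert res["p_value"] == pytest.approx(p_oracle, abs=1e-12)
        assert res["u_statistic"] == 0

    def test_identical_groups_p_one(self):
        sc = scan_frame([0.5] * 10)
        res = fst.inversion_contrast(sc, ("2L", 100, 104), tails=())
        assert res["p_value"] == pytest.approx(1.0)

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0.05, 0.02, 400).clip(0.001)
        ps = []
        for shift in (0.0, 0.01, 0.03):
            vals = np.concatenate([base[:150] + shift, base[150:]])
            sc = scan_frame(vals)
            ps.append(fst.inversion_contrast(sc, ("2L", 100, 249), tails=())["p_value"])
        assert ps[0] > ps[1] > ps[2]

    def test_region_covering_whole_arm_rejected(self, scan):
        with pytest.raises(ValueError):
            fst.inversion_contrast(scan, ("2L", 0, 10**9))

    def test_tier_tables_count_inside_outside(self, scan, cohort):
        res = fst.inversion_contrast(scan, cohort.config.inversion_region)
        t = res["tier_tables"]["top5"]
        on_arm = scan[(scan["arm"] == "2L") & scan["usable"]]
        assert t.sum() == len(on_arm)
        assert t[0].sum() == res["n_inside"]


class TestInversionFrequency:
    def test_recovers_realized_arrangement_frequency(self, cohort, filtered):
        matrix, _ = filtered
        est = fst.inversion_frequency(matrix, cohort.markers)
        overall = est[est["arm"] == "overall"].set_index("population")["frequency"]
        # markers are in perfect association: the estimate equals the realized
        # sample arrangement frequency up to calls lost to missingness/QC
        for pop, realized in cohort.inversion_sample_freqs.items():
            assert overall[pop] == pytest.approx(realized, abs=0.05)

    def test_fixed_and_absent_markers(self):
        from tests.test_vcfio_filters import toy_matrix

        m = toy_matrix(np.full((3, 4), 2), pops=["pop1"] * 4)
        panel = pd.DataFrame({"arm": "2L", "pos": [100, 200], "tag_allele": "alt"})
        est = fst.inversion_frequency(m, panel)
        assert (est[est["arm"] == "overall"]["frequency"] == 1.0).all()
        panel_ref = panel.assign(tag_allele="ref")
        est2 = fst.inversion_frequency(m, panel_ref)
        assert (est2[est2["arm"] == "overall"]["frequency"] == 0.0).all()
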