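"""Descriptive statistics and nonparametric tests against independent oracles."""
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss

from fascicle3d import (
    ArchitectureModel,
    ValidationError,
    compare_tear_dimensions,
    describe,
    kruskal_wallis,
    mann_whitney,
    pairwise_compare,
    summarize_architecture,
)


def brute_force_exact_p(x, y):
    """Independent oracle: enumerate group labelings, U counted pairwise.

    U is computed as the number of (x_i, y_j) pairs with x_i > y_j plus half
    the ties — a different route than the rank-sum formula used by the
    implementation.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(idx):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        a, b = pooled[sel], pooled[~sel]
        gt = (a[:, None] > b[None, :]).sum()
        ties = (a[:, None] == b[None, :]).sum()
        return gt + 0.5 * ties

    u_obs = u_of(range(n1))
    us = np.array([u_of(idx) for idx in combinations(range(len(pooled)), n1)])
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def kw_direct_formula(groups):
    """Direct evaluation of the tie-corrected rank-sum formula."""
    pooled = np.concatenate(groups)
    ranks = ss.rankdata(pooled)
    N = len(pooled)
    start, acc = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)].sum()
        acc += r**2 / len(g)
        start += len(g)
    h = 12 / (N * (N + 1)) * acc - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    return h / (1 - np.sum(counts**3 - counts) / (N**3 - N))


class TestDescribe:
    def test_cadaveric_ages(self, table1):
        d = describe(table1["age_years"])
        assert round(d.mean, 1) == 82.1
        assert round(d.sd, 1) == 10.8
        assert (d.min, d.max) == (64, 95)

    def test_single_value(self):
        d = describe([5.0])
        assert d.mean == 5.0 and d.median == 5.0 and d.sd is None

    def test_even_length_median(self):
        assert describe([1, 2, 3, 4]).median == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            describe([])


class TestMannWhitney:
    B_COR = [1.88, 1.04, 1.47, 1.40]
    C_COR = [3.33, 5.0, 2.59, 2.59]
    B_SAG = [1.63, 2.08, 1.52, 1.17]
    C_SAG = [3.84, 3.00, 3.76, 3.67]

    def test_tear_diameter_p_values(self):
        """Tie-corrected normal approximation reproduces the reported p-values."""
        p_cor = mann_whitney(self.B_COR, self.C_COR).p_value
        p_sag = mann_whitney(self.B_SAG, self.C_SAG).p_value
        assert f"{p_cor:.2g}" == "0.02"
        assert round(p_cor, 3) == 0.020
        assert round(p_sag, 3) == 0.021

    def test_exact_variant_cannot_reach_the_reported_values_at_4v4(self):
        """With 4 vs 4 the smallest attainable exact two-sided p is 2/70 > 0.028,
        so p near 0.02 identifies the asymptotic method."""
        p_exact = mann_whitney(self.B_COR, self.C_COR, method="exact").p_value
        assert p_exact >= 0.028
        assert p_exact == pytest.approx(2 / 70, abs=1e-12)

    def test_identical_groups(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.z_value == 0.0 and res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 11 - n1))
            x = rng.integers(0, 6, n1).astype(float)  # integers force ties
            y = rng.integers(0, 6, n2).astype(float)
            mine = mann_whitney(x, y, method="exact").p_value
            assert mine == pytest.approx(brute_force_exact_p(x, y), abs=1e-12)

    def test_asymptotic_close_to_exact_in_rejection_region_8v8(self):
        """Where it drives decisions (exact p <= 0.05) the no-continuity
        normal approximation tracks the exact test within 0.005 for untied
        8 vs 8 data; near p = 1 the discrete exact p saturates and the two
        can differ by several hundredths."""
        rng = np.random.default_rng(123)
        n_small = 0
        for i in range(200):
            x = rng.normal(size=8)
            # alternate null and shifted draws so the tail regime is populated
            y = rng.normal(loc=1.2 if i % 2 else 0.0, size=8)
            pa = mann_whitney(x, y, method="asymptotic").p_value
            pe = mann_whitney(x, y, method="exact").p_value
            if pe <= 0.05:
                n_small += 1
                assert abs(pa - pe) < 0.005
        assert n_small >= 30  # the regime was actually exercised

    def test_asymptotic_agrees_with_scipy_no_continuity(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.integers(0, 8, rng.integers(3, 12)).astype(float)
            y = rng.integers(0, 8, rng.integers(3, 12)).astype(float)
            mine = mann_whitney(x, y)
            ref = ss.mannwhitneyu(x, y, use_continuity=False, method="asymptotic")
            assert mine.statistic == pytest.approx(float(ref.statistic), abs=1e-9)
            assert mine.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_exact_null_calibration(self):
        """Rejection rate of the exact test under the null stays at the
        attainable level (exact tests are discrete, so the attainable level
        sits below the nominal 0.05)."""
        rng = np.random.default_rng(2026)
        # continuous data -> no ties -> p depends only on U: cache per U
        cache = {}

        def exact_p(x, y):
            u = mann_whitney(x, y).statistic
            if u not in cache:
                cache[u] = mann_whitney(x, y, method="exact").p_value
            return cache[u]

        n, reps, alpha = 10, 2000, 0.05
        rejections = sum(
            exact_p(rng.normal(size=n), rng.normal(size=n)) < alpha for _ in range(reps)
        )
        # attainable level from the exact null distribution of U
        base = np.arange(1.0, 2 * n + 1)
        idx = np.array(list(combinations(range(2 * n), n)))
        us = base[idx].sum(axis=1) - n * (n + 1) / 2
        pmf_u, counts = np.unique(us, return_counts=True)
        probs = counts / counts.sum()
        p_of_u = {
            u: min(1.0, 2 * min((probs[pmf_u <= u + 1e-9]).sum(), (probs[pmf_u >= u - 1e-9]).sum()))
            for u in pmf_u
        }
        attainable = sum(pr for u, pr in zip(pmf_u, probs) if p_of_u[u] < alpha)
        se = np.sqrt(attainable * (1 - attainable) / reps)
        assert abs(rejections / reps - attainable) < 2.576 * se + 1e-12


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.p_value == pytest.approx(
            float(ss.chi2.sf(res.statistic, 2)), abs=1e-12
        )
        res_const = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert res_const.statistic == 0.0 and res_const.p_value == 1.0

    def test_separated_groups_match_direct_formula(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kw_direct_formula(groups), abs=1e-12)
        assert res.df == 2

    def test_two_group_h_equals_z_squared(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            x = rng.integers(0, 10, 7).astype(float)
            y = rng.integers(0, 10, 9).astype(float)
            if np.all(np.concatenate([x, y]) == x[0]):
                continue
            h = kruskal_wallis([x, y]).statistic
            z = mann_whitney(x, y).z_value
            assert h == pytest.approx(z**2, abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(55)
        groups = [rng.normal(size=6), rng.normal(size=8), rng.normal(size=5)]
        h0 = kruskal_wallis(groups).statistic
        for f in (np.exp, lambda v: v**3, lambda v: np.arctan(v) * 5):
            h1 = kruskal_wallis([f(g) for g in groups]).statistic
            assert h1 == pytest.approx(h0, abs=1e-9)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(13)
        groups = [rng.integers(0, 5, 8).astype(float) for _ in range(3)]
        res = kruskal_wallis(groups)
        ref = ss.kruskal(*groups)
        assert res.statistic == pytest.approx(float(ref.statistic), abs=1e-9)
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2, 3]])


class TestPairwise:
    def test_bonferroni_threshold(self):
        decisions = pairwise_compare(
            {"A": [1, 2, 3, 4], "B": [2, 3, 4, 5], "C": [9, 10, 11, 12]},
            alpha=0.05, m=3,
        )
        assert len(decisions) == 3
        for d in decisions:
            assert d.alpha_adjusted == pytest.approx(0.05 / 3)
            assert f"{d.alpha_adjusted:.4f}" == "0.0167"
            assert d.significant == (d.p_value < d.alpha_adjusted)

    def test_p_between_adjusted_and_nominal_is_not_significant(self):
        """p ~= 0.020 clears 0.05 but not the Bonferroni threshold 0.0167."""
        b, c = TestMannWhitney.B_COR, TestMannWhitney.C_COR
        (dec,) = [
            d for d in pairwise_compare({"B": b, "C": c}, alpha=0.05, m=3)
        ]
        assert 0.0167 < dec.p_value < 0.05
        assert not dec.significant

    def test_single_comparison_uses_nominal_alpha(self):
        (dec,) = pairwise_compare({"x": [1, 2, 3], "y": [4, 5, 6]}, alpha=0.05, m=1)
        assert dec.alpha_adjusted == 0.05


def _toy_measurements():
    rng = np.random.default_rng(14)
    rows = []
    for category, shift in (("A", 0.0), ("B", -1.0), ("C", -3.0)):
        for spec in range(4):
            for part in ("superficial", "middle", "deep"):
                for k in range(6):
                    rows.append({
                        "specimen_id": f"{category}{spec}",
                        "region": "anterior", "part": part, "category": category,
                        "fbl_cm": 6.5 + shift + rng.normal(0, 0.4),
                        "lat_pa_deg": 15 - 3 * shift + rng.normal(0, 2),
                        "med_pa_deg": 14 - 3 * shift + rng.normal(0, 2),
                    })
    return pd.DataFrame(rows)


class TestSummaries:
    def test_category_c_tear_medians(self, table1):
        c = table1[table1["category"] == "C"]
        assert c["coronal_cm"].median() == pytest.approx(2.96, abs=1e-12)
        assert c["sagittal_cm"].median() == pytest.approx(3.715, abs=1e-12)

    def test_single_measurement_cell(self):
        df = pd.DataFrame([{
            "specimen_id": "s", "region": "anterior", "part": "deep",
            "category": "A", "fbl_cm": 5.0, "lat_pa_deg": 10.0, "med_pa_deg": 12.0,
        }])
        out = summarize_architecture(df, min_specimens=1)
        row = out[out["part"] == "deep"].iloc[0]
        assert row["fbl_cm_median"] == row["fbl_cm_min"] == row["fbl_cm_max"] == 5.0

    def test_unlabeled_rows_rejected(self):
        df = _toy_measurements()
        df.loc[0, "part"] = None
        with pytest.raises(ValidationError):
            summarize_architecture(df)

    def test_small_cells_flagged_ineligible(self):
        df = _toy_measurements()
        df = df[~((df["category"] == "C") & (df["specimen_id"] != "C0"))]
        out = summarize_architecture(df, min_specimens=3)
        c_rows = out[out["category"] == "C"]
        assert not c_rows["tests_eligible"].any()
        assert out[out["category"] == "A"]["tests_eligible"].all()


class TestArchitectureModel:
    def test_fit_produces_summaries_and_tests(self):
        results = ArchitectureModel(_toy_measurements()).fit()
        assert {"all", "superficial", "middle", "deep"} <= set(
            results.summaries["part"].astype(str)
        )
        tests = results.tests
        omnibus = tests[tests["family"] == "category comparison"]
        # strongly separated FBL across categories: omnibus significant
        fbl = omnibus[omnibus["metric"] == "fbl_cm"].iloc[0]
        assert fbl["p_value"] < 0.001
        pair = tests[tests["family"] == "category pairwise"]
        assert set(pair["comparison"]) == {"A vs B", "A vs C", "B vs C"}
        assert np.allclose(pair["alpha_adjusted"], 0.05 / 3)

    def test_underpowered_category_excluded_with_warning(self):
        df = _toy_measurements()
        df = df[~((df["category"] == "C") & (df["specimen_id"] != "C0"))]
        with pytest.warns(UserWarning, match="excluded from tests"):
            results = ArchitectureModel(df, min_specimens=3).fit()
        tests = results.tests
        assert not tests["comparison"].str.contains("C").any()

    def test_summary_text_contains_cells_and_tests(self):
        text = ArchitectureModel(_toy_measurements()).fit().summary()
        assert "FBL (cm)" in text and "Hypothesis tests" in text

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            ArchitectureModel(_toy_measurements().iloc[:0])


def test_compare_tear_dimensions_uses_b_and_c_only(table1):
    res = compare_tear_dimensions(table1)
    assert res["coronal_cm"].n_per_group == (4, 4)
    assert res["coronal_cm"].groups_compared == ("B", "C")
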