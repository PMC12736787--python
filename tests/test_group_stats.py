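"""Statistics against enumeration and closed-form oracles."""

import itertools
import math

import numpy as np
import pytest

from probiosurf.group_stats import (
    build_gravy_records,
    compare_groups,
    mann_whitney_u,
    summarize,
    surface_profile_report,
    welch_t_test,
)
from probiosurf.surface_classifier import classify_proteome


def exact_mwu_oracle(x, y):
    """Full enumeration of C(n+m, n) group assignments (tie-free inputs)."""
    pooled = sorted(x + y)
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    dist = []
    for idx in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in idx]
        dist.append(sum(1 for xi in xs for yj in ys if xi > yj))
    total = len(dist)
    p_le = sum(d <= u_obs for d in dist) / total
    p_ge = sum(d >= u_obs for d in dist) / total
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


def welch_oracle(x, y):
    """Hand-computed Welch formula: t, Welch-Satterthwaite df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return t, df


class TestSummarize:
    def test_quartiles_linear_interpolation(self):
        s = summarize([1, 2, 3, 4, 5])
        assert (s.q1, s.median, s.q3) == (2, 3, 4)

    def test_frac_negative_strict(self):
        assert summarize([-1, 1]).frac_negative == 0.5
        assert summarize([0.0, 1.0]).frac_negative == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_median_of_normal_draws_near_theory(self):
        rng = np.random.default_rng(7)
        draws = rng.normal(-0.18, 0.3, size=10_000)
        # SE of the sample median of a normal ~ 1.2533 * sigma / sqrt(n)
        se = 1.2533 * 0.3 / np.sqrt(10_000)
        assert abs(summarize(draws).median - (-0.18)) < 3 * se

    def test_frac_negative_is_weighted_mean_over_partition(self, rng):
        a = rng.normal(-0.1, 0.3, 200)
        b = rng.normal(0.1, 0.3, 300)
        whole = summarize(np.concatenate([a, b])).frac_negative
        parts = (200 * summarize(a).frac_negative + 300 * summarize(b).frac_negative) / 500
        assert whole == pytest.approx(parts, abs=1e-12)


class TestWelch:
    def test_identical_samples_give_t0_p1(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_formula_on_fixed_vectors(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [10.0, 11.0, 12.0, 13.0]
        res = welch_t_test(x, y)
        t_ref, df_ref = welch_oracle(x, y)
        assert res["t"] == pytest.approx(t_ref, abs=1e-6)
        assert res["df"] == pytest.approx(df_ref, abs=1e-6)
        assert res["p"] < 0.001

    def test_symmetry_negates_t_preserves_p(self, rng):
        x = list(rng.normal(0, 1, 12))
        y = list(rng.normal(0.5, 2, 20))
        a, b = welch_t_test(x, y), welch_t_test(y, x)
        assert a["t"] == pytest.approx(-b["t"], abs=1e-12)
        assert a["p"] == pytest.approx(b["p"], abs=1e-12)
        assert a["df"] == pytest.approx(b["df"], abs=1e-12)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_zero_variance_equal_means_convention(self):
        res = welch_t_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res == {"t": 0.0, "df": 3.0, "p": 1.0}


class TestMannWhitney:
    def test_small_sample_exact_value(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res["U"] == 0
        assert res["p"] == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_multisets_p_near_one(self):
        assert mann_whitney_u([1, 2, 3], [1, 2, 3])["p"] >= 0.99

    def test_exact_p_matches_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 7))
            m = int(rng.integers(2, 9))
            pooled = rng.permutation(np.arange(1.0, n + m + 1))  # tie-free
            x, y = list(pooled[:n]), list(pooled[n:])
            u_ref, p_ref = exact_mwu_oracle(x, y)
            res = mann_whitney_u(x, y)
            assert res["U"] == pytest.approx(u_ref, abs=0)
            assert res["p"] == pytest.approx(p_ref, abs=1e-9)

    def test_approximation_close_to_exact_at_boundary_n(self, rng):
        """Normal approximation within 0.02 of enumeration at min(n) = 8."""
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, 25.0))
            x, y = list(pooled[:8]), list(pooled[8:])
            _, p_exact = exact_mwu_oracle(x, y)
            from scipy import stats

            p_approx = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(p_approx - p_exact) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestSurfaceProfileReport:
    def test_three_comparisons_on_synthetic_proteome(self, small_labeled_proteome):
        calls, _ = classify_proteome(small_labeled_proteome.proteome)
        records = build_gravy_records(small_labeled_proteome.proteome, calls)
        report = surface_profile_report(records)
        assert set(report) == {
            "surface_vs_proteome",
            "surface_vs_background",
            "secreted_mature_vs_full",
        }
        comp = report["surface_vs_background"]
        assert comp.summary_x.n + comp.summary_y.n == len(records)
        assert 0 < comp.welch_p <= 1 and 0 < comp.mwu_p <= 1
        # mature chains are built more hydrophilic than whole chains
        mature = report["secreted_mature_vs_full"]
        assert mature.summary_x.median < mature.summary_y.median

    def test_mature_gravy_only_for_cleaved_proteins(self, small_labeled_proteome):
        calls, _ = classify_proteome(small_labeled_proteome.proteome)
        records = build_gravy_records(small_labeled_proteome.proteome, calls)
        by_id = {c.protein_id: c for c in calls}
        for r in records:
            has_sp = by_id[r.protein_id].signal_peptide is not None
            assert (r.gravy_mature is not None) == has_sp

    def test_insufficient_group_raises_named_error(self, rng):
        from probiosurf.group_stats import GravyRecord

        records = [
            GravyRecord(protein_id=f"p{i}", gravy_full=float(g), category="none")
            for i, g in enumerate(rng.normal(-0.2, 0.2, 10))
        ]
        with pytest.raises(ValueError, match="surface"):
            surface_profile_report(records)

    def test_null_split_p_values_are_calibrated(self, rng):
        """Like-for-like splits of one distribution reject at ~ the nominal rate."""
        rejections = 0
        for _ in range(200):
            pool = rng.normal(-0.18, 0.16, size=300)
            rejections += mann_whitney_u(pool[:100], pool[100:])["p"] < 0.05
        assert 0.01 < rejections / 200 < 0.10
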