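"""Region statistics: summaries, Levene, Kruskal-Wallis, Dunn-Bonferroni.

The rank-test oracles here are brute-force implementations written straight
from the rank definitions, independent of both scipy and the package code.
"""

import numpy as np
import pandas as pd
import pytest

import pbmap
from pbmap import (summarize_regions, levene_test, kruskal_wallis, dunn_bonferroni,
                   run_group_analysis, significance_stars, load_manual_roi)


# ---------------------------------------------------------------- oracles


def _ranks(pooled):
    """Average ranks (1-based, midranks for ties), straight from the definition."""
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def brute_force_H(groups):
    """Kruskal-Wallis H with tie correction from the rank-sum definition."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = _ranks(pooled)
    idx = np.cumsum([0] + [len(g) for g in groups])
    h = 12 / (N * (N + 1)) * sum(
        len(g) * ranks[idx[i]:idx[i + 1]].mean() ** 2
        for i, g in enumerate(groups)) - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (N**3 - N)
    return h / correction


def brute_force_dunn_z(groups):
    """All pairwise Dunn z statistics from pooled midranks with tie correction."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = _ranks(pooled)
    idx = np.cumsum([0] + [len(g) for g in groups])
    means = [ranks[idx[i]:idx[i + 1]].mean() for i in range(len(groups))]
    _, counts = np.unique(pooled, return_counts=True)
    ties = (counts**3 - counts).sum()
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt((N * (N + 1) / 12 - ties / (12 * (N - 1)))
                         * (1 / len(groups[i]) + 1 / len(groups[j])))
            out.append((means[i] - means[j]) / se)
    return np.array(out)


# ---------------------------------------------------------------- summaries


@pytest.fixture(scope="module")
def lesion_summary(request):
    noisy_phantom = request.getfixturevalue("noisy_phantom")
    noisy_maps = request.getfixturevalue("noisy_maps")
    _, truth = noisy_phantom
    roi = np.zeros(truth.region_mask.shape, dtype=np.uint8)
    roi[truth.region_mask == pbmap.JUNCTION] = 1
    roi[truth.region_mask == pbmap.CORE] = 2
    regions = load_manual_roi(roi)
    return summarize_regions(noisy_maps, regions, lesion_id="L1", group="sporadic_bcc")


class TestSummarize:
    def test_twelve_rows_with_positive_counts(self, lesion_summary):
        assert len(lesion_summary) == 12
        assert (lesion_summary.n_pixels > 0).all()
        assert set(lesion_summary.region) == {"inner", "junction", "skin"}
        assert set(lesion_summary.parameter) == {"AF0", "A", "tau", "C"}

    def test_programmed_contrast_directions(self, lesion_summary):
        t = lesion_summary.set_index(["region", "parameter"])["mean"]
        assert t["inner", "tau"] < t["skin", "tau"]
        assert t["inner", "AF0"] < t["skin", "AF0"]
        assert t["inner", "A"] < t["skin", "A"]

    def test_region_means_near_true_values(self, lesion_summary, noisy_phantom):
        _, truth = noisy_phantom
        t = lesion_summary.set_index(["region", "parameter"])["mean"]
        for region, label in (("inner", pbmap.CORE), ("skin", pbmap.SKIN)):
            true_tau = truth.region_mean(label, "tau")
            assert abs(t[region, "tau"] - true_tau) / true_tau < 0.05

    def test_constant_map_gives_equal_region_means(self, noisy_phantom):
        _, truth = noisy_phantom
        shape = truth.region_mask.shape
        const = pbmap.ParameterMaps(af0=np.full(shape, 5.0), A=np.full(shape, 5.0),
                                    tau=np.full(shape, 5.0), C=np.full(shape, 5.0),
                                    error=np.zeros(shape), mask=np.ones(shape, bool))
        roi = np.zeros(shape, dtype=np.uint8)
        roi[truth.region_mask == pbmap.CORE] = 2
        roi[truth.region_mask == pbmap.JUNCTION] = 1
        table = summarize_regions(const, load_manual_roi(roi), "L", "scc")
        assert np.allclose(table["mean"], 5.0)

    def test_empty_region_omitted_with_warning(self, noisy_maps):
        roi = np.zeros(noisy_maps.shape, dtype=np.uint8)  # no core/junction at all
        with pytest.warns(UserWarning, match="empty"):
            table = summarize_regions(noisy_maps, load_manual_roi(roi), "L", "scc")
        assert set(table.region) == {"skin"}


# ---------------------------------------------------------------- levene


class TestLevene:
    def test_equal_spread_groups_give_zero(self):
        w, p = levene_test([np.array([1.0, 5.0]), np.array([11.0, 15.0])])
        assert w == 0.0 and p == 1.0

    def test_degenerate_within_group_spread_matches_deviation_F(self):
        # deviations {5,5} vs {1,1}: between-group spread, no within-group spread
        w, p = levene_test([np.array([0.0, 10.0]), np.array([4.0, 6.0])])
        assert np.isinf(w) and p == 0.0

    def test_all_zero_deviations_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            levene_test([np.array([3.0, 3.0]), np.array([8.0, 8.0])])

    def test_matches_scipy_on_generic_data(self, rng):
        from scipy import stats as sps
        groups = [rng.normal(0, s, 15) for s in (1.0, 2.0, 3.0)]
        w, p = levene_test(groups)
        w2, p2 = sps.levene(*groups, center="mean")
        assert np.isclose(w, w2) and np.isclose(p, p2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            levene_test([np.array([1.0, 2.0])])


# ---------------------------------------------------------------- kruskal


class TestKruskalWallis:
    def test_closed_form_example(self):
        h, p = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6]),
                               np.array([7, 8, 9])])
        assert np.isclose(h, 7.2)

    def test_null_split_gives_large_p(self, rng):
        sample = rng.normal(size=40)
        h, p = kruskal_wallis([sample[:20], sample[20:]])
        assert p > 0.05 or h < 4  # a random split of one sample is null

    def test_identical_observations_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis([np.array([2.0, 2.0]), np.array([2.0, 2.0])])

    @pytest.mark.parametrize("transform", [np.exp, lambda x: x**3,
                                           lambda x: np.arctan(x) * 10])
    def test_invariant_under_monotone_transform(self, rng, transform):
        groups = [rng.normal(loc, 1, 8) for loc in (0, 0.5, 1.0)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([transform(g) for g in groups])
        assert np.isclose(h1, h2)

    def test_matches_brute_force_on_small_instances(self, rng):
        """H agrees with the rank-definition oracle on all sizes with n <= 12."""
        from itertools import product
        checked = 0
        for sizes in product([2, 3, 4, 5], repeat=3):
            if sum(sizes) > 12:
                continue
            for _ in range(3):
                # integer data to generate plenty of ties
                groups = [rng.integers(0, 6, s).astype(float) for s in sizes]
                if np.ptp(np.concatenate(groups)) == 0:
                    continue
                h, _ = kruskal_wallis(groups)
                assert np.isclose(h, brute_force_H(groups)), (sizes, groups)
                checked += 1
        assert checked > 50


# ---------------------------------------------------------------- dunn


class TestDunn:
    def test_bonferroni_is_exact_clamp(self, rng):
        groups = [rng.normal(loc, 1, 10) for loc in (0, 1, 2)]
        table = dunn_bonferroni(groups)
        m = 3
        assert np.allclose(table.p_adj, np.minimum(1.0, m * table.p_raw))
        assert (table.p_adj >= table.p_raw - 1e-15).all()

    def test_identical_groups_have_near_zero_z(self):
        g = np.arange(10.0)
        table = dunn_bonferroni([g, g.copy(), g + 100])
        row = table[(table.group_a == "group0") & (table.group_b == "group1")]
        assert abs(row.z.iloc[0]) < 1e-12

    def test_well_separated_groups_all_significant(self):
        groups = [np.arange(1.0, 11), np.arange(101.0, 111), np.arange(201.0, 211)]
        table = dunn_bonferroni(groups)
        assert (table.p_adj < 0.05).all()

    def test_matches_brute_force_on_small_instances(self, rng):
        from itertools import product
        checked = 0
        for sizes in product([2, 3, 4], repeat=3):
            if sum(sizes) > 12:
                continue
            for _ in range(3):
                groups = [rng.integers(0, 5, s).astype(float) for s in sizes]
                if np.ptp(np.concatenate(groups)) == 0:
                    continue
                table = dunn_bonferroni(groups)
                assert np.allclose(table.z.to_numpy(), brute_force_dunn_z(groups))
                checked += 1
        assert checked > 30


# ---------------------------------------------------------------- cohort analysis


def _synthetic_cohort(rng, n=12, tau_inner=6.0, tau_skin=10.0):
    rows = []
    for group in ("sporadic_bcc", "nbccs_bcc"):
        for i in range(n):
            for region, tau in (("inner", tau_inner), ("junction", 8.0), ("skin", tau_skin)):
                for param, mean in (("AF0", 100.0), ("A", 60.0), ("tau", tau), ("C", 40.0)):
                    rows.append({"lesion_id": f"{group}_{i}", "group": group,
                                 "region": region, "parameter": param,
                                 "mean": mean + rng.normal(0, 0.05 * mean),
                                 "n_pixels": 500})
    return pd.DataFrame(rows)


class TestBonferroniProperties:
    from hypothesis import given, settings as hyp_settings, strategies as st

    @given(st.lists(st.lists(st.integers(0, 9), min_size=2, max_size=6),
                    min_size=2, max_size=4))
    @hyp_settings(max_examples=60, derandomize=True, deadline=None)
    def test_dunn_adjustment_order_preserving_and_clamped(self, data):
        """Dunn p_adj equals min(1, m*p_raw) and preserves the p_raw ordering."""
        groups = [np.array(g, dtype=float) for g in data]
        if np.ptp(np.concatenate(groups)) == 0:
            return
        table = dunn_bonferroni(groups)
        m = len(groups) * (len(groups) - 1) // 2
        assert np.allclose(table.p_adj, np.minimum(1.0, m * table.p_raw))
        order = np.argsort(table.p_raw.to_numpy(), kind="stable")
        assert np.all(np.diff(table.p_adj.to_numpy()[order]) >= -1e-15)


class TestGroupAnalysis:
    def test_programmed_tau_contrast_detected(self, rng):
        res = run_group_analysis(_synthetic_cohort(rng))
        row = res.pairwise_lookup("regions_within_sporadic_bcc", "tau", "inner", "skin")
        assert row.p_adj < 0.05
        assert row.stars != ""

    def test_single_lesion_table_skips_everything(self, rng):
        table = _synthetic_cohort(rng).query("lesion_id == 'sporadic_bcc_0'")
        with pytest.warns(UserWarning):
            res = run_group_analysis(table)
        assert res.omnibus.empty
        assert res.pairwise.empty

    def test_stars_ladder(self):
        assert significance_stars(0.2) == ""
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
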