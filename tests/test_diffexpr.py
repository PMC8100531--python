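"""Size factors, the exact NB test, BH adjustment, DE calls, heatmap order."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cryopirna.diffexpr import (PiRNADEModel, bh_adjust, call_de,
                                cluster_heatmap_order, fit_dispersion,
                                nb_exact_test, size_factors)


# ----------------------------------------------------------------- oracles

def nb_logpmf(x: int, mean: float, dispersion: float) -> float:
    """NB log pmf from first principles (lgamma), independent of scipy."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return (math.lgamma(x + r) - math.lgamma(r) - math.lgamma(x + 1)
            + r * math.log(p) + x * math.log(1 - p))


def oracle_nb_test(a: int, b: int, dispersion: float) -> float:
    """Direct enumeration over every split of a+b."""
    s = a + b
    if s == 0:
        return 1.0
    mu = s / 2
    probs = [math.exp(nb_logpmf(x, mu, dispersion)
                      + nb_logpmf(s - x, mu, dispersion)) for x in range(s + 1)]
    obs = probs[a]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-9)) / sum(probs))


def oracle_bh(pvals):
    """Literal step-up definition."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * m / rank_from_top)
        adj[i] = prev
    return adj


def oracle_complete_linkage_heights(rows: np.ndarray) -> list[float]:
    """O(n^3) agglomeration: merge the closest pair under max-linkage."""
    clusters = [[i] for i in range(len(rows))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(np.linalg.norm(rows[a] - rows[b])
                        for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


# ------------------------------------------------------------------- tests

class TestSizeFactors:
    def test_identical_libraries(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert size_factors(counts).tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_library_scales_proportionally(self):
        counts = pd.DataFrame({"a": [10, 20, 5, 7], "b": [20, 40, 10, 14]})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_matches_direct_median_of_ratios(self, rng):
        counts = pd.DataFrame(rng.integers(1, 500, size=(50, 2)),
                              columns=["a", "b"]).astype(float)
        sf = size_factors(counts)
        geo = np.exp(np.log(counts).mean(axis=1))
        for col in counts:
            assert sf[col] == pytest.approx(np.median(counts[col] / geo))

    def test_all_zero_features_rejected(self):
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame({"a": [0, 3], "b": [2, 0]}))


class TestNBExactTest:
    def test_most_probable_split_has_p_one(self):
        assert nb_exact_test(50, 50, 0.1) == pytest.approx(1.0)

    def test_zero_total_gives_p_one(self):
        assert nb_exact_test(0, 0, 0.1) == 1.0

    @pytest.mark.parametrize("a,b,disp", [
        (5, 40, 0.1), (0, 30, 0.05), (100, 200, 0.2),
        (1, 1, 0.1), (250, 250, 0.01), (3, 0, 0.5),
    ])
    def test_matches_enumeration_oracle(self, a, b, disp):
        assert nb_exact_test(a, b, disp) == pytest.approx(
            oracle_nb_test(a, b, disp), rel=1e-6)

    def test_random_pairs_match_oracle(self, rng):
        for _ in range(40):
            a, b = (int(x) for x in rng.integers(0, 250, size=2))
            disp = float(rng.uniform(0.01, 0.5))
            assert nb_exact_test(a, b, disp) == pytest.approx(
                oracle_nb_test(a, b, disp), rel=1e-6)

    def test_symmetric_in_counts(self):
        assert nb_exact_test(7, 91, 0.1) == pytest.approx(nb_exact_test(91, 7, 0.1))


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_equals_step_up_definition(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(oracle_bh(pvals))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_never_below_raw(self, pvals):
        assert np.all(bh_adjust(pvals) >= np.asarray(pvals) - 1e-12)


class TestCallDE:
    @pytest.mark.parametrize("padj,lfc,expected", [
        (0.009, 1.5, "up"), (0.009, 1.0, "ns"), (0.01, 1.5, "ns"),
        (0.009, -1.5, "down"), (0.009, -1.0, "ns"), (0.2, 3.0, "ns"),
    ])
    def test_strict_thresholds(self, padj, lfc, expected):
        table = pd.DataFrame({"padj": [padj], "log2fc": [lfc]})
        assert call_de(table).iloc[0] == expected


class TestModel:
    def make_counts(self, rng, n=200):
        from cryopirna.simdata import simulate_de_counts
        counts, truth = simulate_de_counts(rng, n, 20, 10)
        return counts, truth

    def test_summary_mentions_de_counts(self, rng):
        counts, _ = self.make_counts(rng)
        res = PiRNADEModel(counts).fit()
        text = res.summary()
        assert f"{len(res.up)} up" in text and f"{len(res.down)} down" in text

    def test_swapping_conditions_negates_log2fc_and_swaps_calls(self, rng):
        counts, _ = self.make_counts(rng)
        res = PiRNADEModel(counts, "fresh", "frozen").fit()
        flipped = PiRNADEModel(counts[["frozen", "fresh"]], "frozen", "fresh").fit()
        assert np.allclose(res.table["log2fc"], -flipped.table["log2fc"])
        assert set(res.up) == set(flipped.down) and set(res.down) == set(flipped.up)

    def test_planted_log2fc_recovered_within_quarter_unit(self, rng):
        from cryopirna.simdata import simulate_de_counts
        counts, truth = simulate_de_counts(rng, 300, 40, 10, log2fc=3.0)
        res = PiRNADEModel(counts).fit()
        est_up = res.table.loc[(truth == "up").to_numpy(), "log2fc"]
        assert abs(est_up.median() - 3.0) < 0.25

    def test_dispersion_trend_positive(self, rng):
        counts, _ = self.make_counts(rng)
        sf = size_factors(counts)
        model = fit_dispersion(counts / sf)
        mus = np.array([10.0, 100.0, 1000.0])
        assert np.all(model.fitted(mus) > 0)

    def test_maximum_sharing_mode_is_more_conservative(self, rng):
        counts, _ = self.make_counts(rng)
        model = PiRNADEModel(counts)
        assert model.fit(sharing_mode="maximum").n_de <= model.fit().n_de

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            PiRNADEModel(pd.DataFrame({"a": [1], "b": [2], "c": [3]}))


class TestHeatmapOrder:
    def test_identical_rows_merge_at_distance_zero(self):
        tpm = pd.DataFrame([[10.0, 20.0], [10.0, 20.0], [500.0, 1.0]])
        from scipy.cluster import hierarchy
        transformed = np.log10(tpm + 1)
        linkage = hierarchy.linkage(transformed, method="complete")
        assert linkage[0, 2] == pytest.approx(0.0)

    def test_zero_tpm_transforms_to_zero(self):
        _, transformed = cluster_heatmap_order(pd.DataFrame([[0.0, 10.0]]))
        assert transformed.iloc[0, 0] == 0.0

    def test_single_row_identity_order(self):
        order, _ = cluster_heatmap_order(pd.DataFrame([[1.0, 2.0]]))
        assert order == [0]

    def test_linkage_heights_match_naive_agglomeration(self, rng):
        tpm = pd.DataFrame(rng.uniform(0, 1000, size=(6, 2)))
        from scipy.cluster import hierarchy
        transformed = np.log10(tpm + 1).to_numpy()
        linkage = hierarchy.linkage(transformed, method="complete")
        assert sorted(linkage[:, 2]) == pytest.approx(
            oracle_complete_linkage_heights(transformed))

    def test_order_is_deterministic(self, rng):
        tpm = pd.DataFrame(rng.uniform(0, 100, size=(8, 2)))
        assert cluster_heatmap_order(tpm)[0] == cluster_heatmap_order(tpm.copy())[0]
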