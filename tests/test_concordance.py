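import numpy as np
import pandas as pd
import pytest
from scipy import stats

from forestcc.concordance import (
    agreement_composition,
    agreement_count,
    correlation_matrix,
    pearson,
    to_binary_change,
    weighted_pearson,
)
from forestcc.trajfit import LABEL_GAIN, LABEL_LOSS, LABEL_NONE


class TestToBinaryChange:
    def test_label_maps_pass_through(self):
        labels = np.array([LABEL_NONE, LABEL_LOSS, LABEL_GAIN])
        assert list(to_binary_change(labels, "loss")) == [False, True, False]
        assert list(to_binary_change(labels, "gain")) == [False, False, True]

    def test_fractional_nonzero_rule(self):
        delta = np.array([-0.3, 0.0, 0.5, np.nan])
        assert list(to_binary_change(delta, "loss", kind="fractional")) == \
            [True, False, False, False]
        assert list(to_binary_change(delta, "gain", kind="fractional")) == \
            [False, False, True, False]

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            to_binary_change(np.zeros(3), "sideways")
        with pytest.raises(ValueError):
            to_binary_change(np.zeros(3), "loss", kind="wavelet")


class TestAgreementCount:
    def test_banding_three_of_four_is_high(self):
        maps = [np.array([[1]]), np.array([[1]]), np.array([[1]]), np.array([[0]])]
        out = agreement_count(maps)
        assert out["level"][0, 0] == 3
        assert out["category"][0, 0] == 2  # high
        assert not out["full"][0, 0]

    def test_unanimous_is_high_and_full(self):
        maps = [np.ones((1, 1))] * 4
        out = agreement_count(maps)
        assert out["level"][0, 0] == 4
        assert out["category"][0, 0] == 2
        assert out["full"][0, 0]

    def test_no_flags_is_none(self):
        maps = [np.zeros((2, 2))] * 4
        out = agreement_count(maps)
        assert (out["level"] == 0).all()
        assert (out["category"] == 0).all()

    def test_one_or_two_is_low(self):
        maps = [np.array([[1, 1]]), np.array([[0, 1]]),
                np.array([[0, 0]]), np.array([[0, 0]])]
        out = agreement_count(maps)
        assert list(out["level"][0]) == [1, 2]
        assert list(out["category"][0]) == [1, 1]

    def test_level_partition_counts(self):
        rng = np.random.default_rng(0)
        maps = [rng.random((20, 20)) < 0.3 for _ in range(4)]
        out = agreement_count(maps)
        flagged_any = np.stack(maps).any(axis=0)
        assert sum((out["level"] == lv).sum() for lv in (1, 2, 3, 4)) == \
            flagged_any.sum()


class TestAgreementComposition:
    def test_dataset_within_full_agreement(self):
        m = np.ones((2, 2), dtype=bool)
        out = agreement_composition(np.full((2, 2), 4),
                                    {"a": m, "b": m, "c": m, "d": m})
        assert out.loc["a"].tolist() == [0.0, 0.0, 0.0, 100.0]

    def test_lone_dataset_all_level_one(self):
        m = np.ones((2, 2), dtype=bool)
        z = np.zeros((2, 2), dtype=bool)
        level = agreement_count([m, z, z, z])["level"]
        out = agreement_composition(level, {"a": m, "b": z, "c": z, "d": z})
        assert out.loc["a"].tolist() == [100.0, 0.0, 0.0, 0.0]
        assert out.loc["b"].isna().all()  # flags nothing

    def test_mixed_fixture_matches_hand_count(self):
        # 3x3 fixture enumerated by hand
        a = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0]], dtype=bool)
        b = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 0]], dtype=bool)
        c = np.array([[1, 0, 0], [0, 0, 0], [0, 0, 1]], dtype=bool)
        d = np.array([[0, 0, 0], [0, 0, 0], [0, 0, 1]], dtype=bool)
        level = agreement_count([a, b, c, d])["level"]
        # levels: (0,0)->3, (0,1)->1, (1,1)->2, (2,2)->2
        out = agreement_composition(level, {"a": a, "b": b, "c": c, "d": d})
        # dataset a flags three pixels at levels 3, 1, 2
        assert np.allclose(out.loc["a"], [100 / 3, 100 / 3, 100 / 3, 0.0])
        # dataset d flags one pixel at level 2
        assert np.allclose(out.loc["d"], [0.0, 100.0, 0.0, 0.0])
        assert np.isclose(out.loc["a"].sum(), 100.0)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, sig = pearson(x, 2 * x + 1)
        assert np.isclose(r, 1.0)
        assert sig

    def test_orthogonal_residual_gives_zero(self):
        x = np.arange(8.0)
        y = np.ones(8)  # start from a constant, add x, then residualise
        z = x - x.mean()
        v = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
        v = v - v.mean() - (v @ z) / (z @ z) * z  # orthogonal to x
        r, sig = pearson(x, v)
        assert abs(r) < 1e-12
        assert not sig

    def test_r30_n31_is_just_below_the_90pct_bar(self):
        # t = 0.30 sqrt(29 / (1 - 0.09)) = 1.693 < t_{0.95,29} = 1.699
        n, r_target = 31, 0.30
        x = np.arange(n, dtype=float)
        u = (x - x.mean()) / np.std(x)
        rng = np.random.default_rng(0)
        z = rng.normal(size=n)
        z = z - z.mean() - (z @ u) / (u @ u) * u
        z = z / np.std(z)
        y = r_target * u + np.sqrt(1 - r_target**2) * z
        r, sig = pearson(x, y)
        assert np.isclose(r, r_target, atol=1e-12)
        assert not sig
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert t < stats.t.ppf(0.95, n - 2)

    def test_zero_variance_flagged_not_significant(self):
        r, sig = pearson(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and not sig

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.arange(2.0), np.arange(2.0))


class TestWeightedPearson:
    def test_equal_weights_reduce_to_plain_r(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r_plain, _ = pearson(x, y)
        r_w, _ = weighted_pearson(x, y, np.full(20, 3.7))
        assert abs(r_w - r_plain) < 1e-12

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(size=15)
        w = rng.random(15) + 0.1
        r1, s1 = weighted_pearson(x, y, w)
        r2, s2 = weighted_pearson(x, y, 1000.0 * w)
        assert np.isclose(r1, r2, atol=1e-12)
        assert s1 == s2

    def test_dominant_weight_drives_r_to_two_point_relation(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([3.0, 1.0, 0.0, 2.0])
        w = np.array([1e6, 1e6, 1.0, 1.0])
        r, _ = weighted_pearson(x, y, w)
        assert r < -0.99  # the two dominant points slope downward

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_pearson(np.arange(3.0), np.arange(3.0),
                             np.array([1.0, -1.0, 1.0]))


class TestCorrelationMatrix:
    def _tables(self, vectors):
        out = {}
        for name, v in vectors.items():
            out[name] = pd.DataFrame({
                "province_id": np.arange(len(v)),
                "net_pct": v, "loss_pct": v, "gain_pct": v,
            })
        return out

    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(3)
        tables = self._tables({n: rng.normal(size=12) for n in "abcd"})
        r, sig = correlation_matrix(tables, metric="net")
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r.values, r.values.T)
        assert (sig.values == sig.values.T).all()

    def test_shared_latent_pattern_all_significant_positive(self):
        rng = np.random.default_rng(4)
        latent = rng.normal(size=20) * 5
        tables = self._tables(
            {n: latent + rng.normal(size=20) * 0.5 for n in "abcd"})
        r, sig = correlation_matrix(tables, metric="net")
        off = ~np.eye(4, dtype=bool)
        assert (r.values[off] > 0.9).all()
        assert sig.values[off].all()

    def test_net_only_dataset_excluded_except_for_net(self):
        rng = np.random.default_rng(5)
        tables = self._tables({n: rng.normal(size=10) for n in
                               ("nbr", "lc", "vcf", "gfc", "nfi")})
        r_net, _ = correlation_matrix(tables, metric="net", net_only={"nfi"})
        r_loss, _ = correlation_matrix(tables, metric="loss", net_only={"nfi"})
        assert "nfi" in r_net.index
        assert "nfi" not in r_loss.index

    def test_pairwise_province_intersection(self):
        rng = np.random.default_rng(6)
        t = self._tables({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        t["b"] = t["b"].iloc[:7]  # b misses three provinces
        r, _ = correlation_matrix(t, metric="net")
        xa = t["a"]["net_pct"].iloc[:7].to_numpy()
        xb = t["b"]["net_pct"].to_numpy()
        assert np.isclose(r.loc["a", "b"], pearson(xa, xb)[0])
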