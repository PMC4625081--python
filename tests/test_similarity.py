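"""Comparison-set construction, correlation metrics, not-comparable rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import zmapsim as z
from zmapsim.groupstats import ZStatMap
from zmapsim.thresholding import ThresholdSpec


def brute_pearson(x, y):
    """Independent sigma-formula oracle: cov / (sd_x * sd_y)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def brute_ranks(v):
    """Average ranks assigned by explicit tie-group enumeration."""
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _zmap(vol, cid="c", thr=None):
    return ZStatMap(contrast_id=cid, group_label="A",
                    volume=np.asarray(vol, dtype=float),
                    threshold_applied=thr)


class TestMetrics:
    def test_pearson_perfect_and_inverse(self):
        x = np.array([1.0, 2, 3, 5])
        assert z.pearson(x, x) == pytest.approx(1.0)
        assert z.pearson(x, -x) == pytest.approx(-1.0)

    def test_pearson_printed_example_vs_oracle(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        assert z.pearson(np.array(x, float), np.array(y, float)) == \
            pytest.approx(brute_pearson(x, y), abs=1e-12)

    def test_spearman_monotone(self):
        x = np.array([1.0, 2, 3, 10])
        assert z.spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert z.spearman(x, -x ** 3) == pytest.approx(-1.0)

    def test_spearman_ties_vs_hand_ranks(self):
        x, y = [1.0, 1.0, 2.0, 3.0], [4.0, 3.0, 2.0, 1.0]
        oracle = brute_pearson(brute_ranks(x), brute_ranks(y))
        assert z.spearman(np.array(x), np.array(y)) == \
            pytest.approx(oracle, abs=1e-10)

    def test_degenerate_inputs_not_comparable(self):
        const = np.ones(5)
        varying = np.arange(5.0)
        assert math.isnan(z.pearson(const, varying))
        assert math.isnan(z.spearman(varying, const))
        assert math.isnan(z.pearson(np.array([1.0, 2.0]),
                                    np.array([3.0, 4.0])))  # n < 3

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 50))
    def test_metrics_match_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.5 * x
        assert z.pearson(x, y) == pytest.approx(
            brute_pearson(list(x), list(y)), abs=1e-12)
        oracle_s = brute_pearson(brute_ranks(list(x)), brute_ranks(list(y)))
        assert z.spearman(x, y) == pytest.approx(oracle_s, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000),
           scale=st.floats(1e-3, 1e3),
           shift=st.floats(-10, 10))
    def test_invariance_under_positive_affine_rescale(self, seed, scale,
                                                      shift):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        for metric in (z.pearson, z.spearman):
            base = metric(x, y)
            assert metric(scale * x + shift, y) == pytest.approx(base,
                                                                 abs=1e-9)
            assert abs(base) <= 1.0


class TestComparisonSet:
    @pytest.fixture
    def mask(self):
        return z.BrainMask(np.ones((3, 3, 3), dtype=bool))

    def test_fully_empty_target_gives_empty_cca_set(self, mask, rng):
        a = _zmap(rng.normal(1, 1, (3, 3, 3)))
        b = _zmap(np.full((3, 3, 3), np.nan))
        xa, xb = z.build_comparison_set(a, b, "CCA", mask)
        assert xa.size == xb.size == 0

    def test_cca_length_equals_target_survivors(self, mask, rng):
        a = _zmap(rng.normal(5, 1, (3, 3, 3)))  # nonzero everywhere
        bvol = rng.normal(0, 1, (3, 3, 3))
        b = z.apply_threshold(_zmap(bvol), ThresholdSpec(1.0, "both"))
        k = int((np.abs(bvol) > 1.0).sum())
        xa, xb = z.build_comparison_set(a, b, "CCA", mask)
        assert xa.size == k

    def test_svi_length_is_mask_size_with_zero_imputation(self, mask, rng):
        a = _zmap(rng.normal(5, 1, (3, 3, 3)))
        b = z.apply_threshold(_zmap(rng.normal(0, 1, (3, 3, 3))),
                              ThresholdSpec(1.5, "both"))
        xa, xb = z.build_comparison_set(a, b, "SVI", mask)
        # oracle: explicit index enumeration
        n_mask = sum(
            1 for i in np.ndindex(3, 3, 3) if mask.volume[i]
        )
        assert xa.size == xb.size == n_mask
        assert np.isfinite(xb).all()
        empties = ~np.isfinite(b.volume[mask.volume])
        assert np.all(xb[empties] == 0.0)

    def test_cca_never_larger_than_svi_and_shrinks_with_t(self, mask, rng):
        a = _zmap(rng.normal(0, 2, (3, 3, 3)))
        bvol = rng.normal(0, 2, (3, 3, 3))
        prev = None
        for level in (0.0, 1.0, 2.0, 3.0):
            b = z.apply_threshold(_zmap(bvol),
                                  ThresholdSpec(level, "both"))
            n_cca = z.build_comparison_set(a, b, "CCA", mask)[0].size
            n_svi = z.build_comparison_set(a, b, "SVI", mask)[0].size
            assert n_cca <= n_svi
            if prev is not None:
                assert n_cca <= prev
            prev = n_cca


class TestCompare:
    @pytest.fixture
    def mask(self):
        return z.BrainMask(np.ones((4, 4, 4), dtype=bool))

    def test_two_voxel_overlap_not_comparable(self, mask):
        a = _zmap(np.ones((4, 4, 4)) * 2.0)
        bvol = np.full((4, 4, 4), np.nan)
        bvol[0, 0, 0] = 1.0
        bvol[0, 0, 1] = 2.0
        score = z.compare(a, _zmap(bvol), "CCA", "pearson", mask)
        assert not score.comparable
        assert score.n_voxels == 2

    def test_self_similarity_is_one(self, mask, rng):
        vol = rng.normal(3, 1, (4, 4, 4))  # nonzero on whole mask
        a = _zmap(vol, cid="q")
        b = z.apply_threshold(_zmap(vol.copy(), cid="t"),
                              ThresholdSpec(0.0, "both"))
        score = z.compare(a, b, "CCA", "pearson", mask)
        assert score.value == pytest.approx(1.0)
        assert score.n_voxels == mask.n_voxels

    def test_cca_and_svi_differ_under_partial_survival(self, mask, rng):
        """With partial survival the two strategies use different voxel
        sets; each must equal its own brute-force recomputation."""
        avol = rng.normal(0, 2, (4, 4, 4))
        bvol = rng.normal(0, 2, (4, 4, 4)) + 0.5 * avol
        a = _zmap(avol)
        b = z.apply_threshold(_zmap(bvol), ThresholdSpec(1.0, "both"))

        cca = z.compare(a, b, "CCA", "pearson", mask)
        svi = z.compare(a, b, "SVI", "pearson", mask)

        keep = np.abs(bvol) > 1.0
        oracle_cca = brute_pearson(list(avol[keep]), list(bvol[keep]))
        b_imp = np.where(keep, bvol, 0.0)
        oracle_svi = brute_pearson(list(avol.ravel()), list(b_imp.ravel()))
        assert cca.value == pytest.approx(oracle_cca, abs=1e-12)
        assert svi.value == pytest.approx(oracle_svi, abs=1e-12)
        assert cca.value != pytest.approx(svi.value, abs=1e-6)

    def test_full_survival_cca_equals_svi(self, mask, rng):
        avol = rng.normal(4, 1, (4, 4, 4))
        bvol = rng.normal(4, 1, (4, 4, 4))
        a, b = _zmap(avol), _zmap(bvol)
        for metric in ("pearson", "spearman"):
            s_cca = z.compare(a, b, "CCA", metric, mask)
            s_svi = z.compare(a, b, "SVI", metric, mask)
            assert s_cca.value == pytest.approx(s_svi.value, abs=1e-12)

    def test_positive_direction_filters_query_too(self, mask):
        """Under positive-only comparison the query's negatives and zeros
        leave the CCA set as well."""
        avol = np.ones((4, 4, 4))
        avol[0] = -1.0
        bvol = np.ones((4, 4, 4)) * 2.0
        a, b = _zmap(avol), _zmap(bvol)
        xa, _ = z.build_comparison_set(a, b, "CCA", mask,
                                       direction="positive")
        assert xa.size == mask.n_voxels - 16
        assert np.all(xa > 0)

    def test_thresholded_query_rejected(self, mask, rng):
        thr = ThresholdSpec(1.0, "both")
        a = z.apply_threshold(_zmap(rng.normal(0, 1, (4, 4, 4))), thr)
        b = _zmap(rng.normal(0, 1, (4, 4, 4)))
        with pytest.raises(ValueError, match="unthresholded"):
            z.compare(a, b, "CCA", "pearson", mask)

    def test_shape_mismatch_rejected(self, mask):
        a = _zmap(np.ones((4, 4, 4)))
        b = _zmap(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            z.compare(a, b, "CCA", "pearson", mask)
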