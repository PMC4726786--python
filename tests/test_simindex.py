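"""Pearson statistics, sparse span index construction and interval queries."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from blkit.features import FeatureMatrix, WindowGrid
from blkit.simindex import (
    Query,
    build_index,
    correlation_matrix,
    encode_runs,
    load_index,
    pearson_r,
    pvalue_matrix,
    query,
    r_pvalue,
    save_index,
    select_timescale,
)


def feature_matrix(values, duration=1.0):
    values = np.asarray(values, dtype=np.float64)
    grid = WindowGrid(
        duration=duration,
        starts=np.arange(values.shape[0]) * duration,
        samples_per_window=int(duration * 1000),
    )
    return FeatureMatrix(duration=duration, features=values, grid=grid)


def brute_force_mask(values, alpha=0.05, include_self=True):
    """Independent oracle: scipy.stats.pearsonr per pair, positive tail only."""
    w = values.shape[0]
    mask = np.zeros((w, w), dtype=bool)
    for i in range(w):
        for j in range(w):
            if i == j:
                mask[i, j] = include_self and values[i].std() > 0
                continue
            if values[i].std() == 0 or values[j].std() == 0:
                continue
            r, p = stats.pearsonr(values[i], values[j])
            mask[i, j] = r > 0 and p <= alpha
    return mask


def quad_pvalue_oracle(r, n):
    """Two-tailed p by numerical integration of the Student t density."""
    df = n - 2

    def pdf(x):
        return (
            math.gamma((df + 1) / 2)
            / (math.sqrt(df * math.pi) * math.gamma(df / 2))
            * (1 + x * x / df) ** (-(df + 1) / 2)
        )

    t = r * math.sqrt(df / (1 - r * r))
    tail, _ = integrate.quad(pdf, abs(t), math.inf)
    return 2 * tail


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        assert pearson_r(x, x) == 1.0
        assert pearson_r(x, -x) == -1.0

    def test_hand_computed_example(self):
        assert pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6, abs=1e-12)

    def test_constant_vector_yields_no_similarity_sentinel(self):
        assert np.isnan(pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.standard_normal((2, 12))
            assert pearson_r(x, y) == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)


class TestPValue:
    def test_zero_correlation_is_never_significant(self):
        for n in (3, 16, 64):
            assert r_pvalue(0.0, n) == 1.0

    def test_perfect_correlation_has_zero_pvalue(self):
        assert r_pvalue(1.0, 64) == 0.0
        assert r_pvalue(-1.0, 64) == 0.0

    @pytest.mark.parametrize(
        "r,n", [(0.5, 16), (0.3, 64), (-0.7, 10), (0.05, 200), (0.9, 5)]
    )
    def test_matches_quadrature_oracle(self, r, n):
        assert r_pvalue(r, n) == pytest.approx(quad_pvalue_oracle(r, n), abs=1e-8)

    def test_monotone_decreasing_in_magnitude(self):
        ps = [r_pvalue(r, 32) for r in np.linspace(0, 0.99, 50)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            r_pvalue(0.5, 2)

    def test_sentinel_maps_to_unity(self):
        assert r_pvalue(float("nan"), 10) == 1.0


class TestCorrelationMatrix:
    def test_matches_pairwise_calls(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal((6, 8))
        r = correlation_matrix(f)
        for i in range(6):
            for j in range(6):
                expected = 1.0 if i == j else pearson_r(f[i], f[j])
                assert r[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_rows_marked_undefined(self):
        f = np.vstack([np.ones(5), np.arange(5.0)])
        r = correlation_matrix(f)
        assert np.isnan(r[0]).all() and np.isnan(r[:, 0]).all()
        assert r[1, 1] == 1.0


class TestRunEncoding:
    def test_block_mask_compresses_to_one_run_per_block(self):
        mask = np.array([1, 1, 1, 0, 0, 1, 1, 0, 1], dtype=bool)
        p = np.arange(9, dtype=float) / 10
        runs = encode_runs(mask, p)
        assert [(r.start, r.length) for r in runs] == [(0, 3), (5, 2), (8, 1)]
        np.testing.assert_array_equal(runs[0].pvalues, [0.0, 0.1, 0.2])

    def test_alternating_mask_stores_one_run_per_singleton(self):
        """Worst case: growth is linear in the number of significant pairs."""
        mask = np.zeros(100, dtype=bool)
        mask[::2] = True
        runs = encode_runs(mask, np.zeros(100))
        assert len(runs) == 50 and all(r.length == 1 for r in runs)

    def test_empty_mask_encodes_to_no_runs(self):
        assert encode_runs(np.zeros(10, dtype=bool), np.zeros(10)) == []


class TestBuildIndex:
    def test_identical_windows_store_every_pair_as_one_run(self):
        f = np.tile(np.array([1.0, 2.0, 5.0, 3.0]), (6, 1))
        idx = build_index({1.0: feature_matrix(f)})
        for row in idx.rows[1.0]:
            assert len(row) == 1
            assert row[0].start == 0 and row[0].length == 6
            assert np.all(row[0].pvalues == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("w", [12, 30])
    def test_densified_index_equals_brute_force_mask(self, seed, w):
        rng = np.random.default_rng(seed)
        # correlated structure so a mix of significant and not
        base = rng.standard_normal(10)
        f = base + 0.8 * rng.standard_normal((w, 10))
        idx = build_index({1.0: feature_matrix(f)})
        np.testing.assert_array_equal(idx.densify(1.0), brute_force_mask(f))

    def test_no_stored_pair_has_nonpositive_correlation(self):
        rng = np.random.default_rng(7)
        f = rng.standard_normal((20, 8))
        f[10:] = -f[:10]  # force strong negative pairs
        idx = build_index({1.0: feature_matrix(f)})
        mask = idx.densify(1.0)
        r = correlation_matrix(f)
        assert np.all(r[mask] > 0)

    def test_shrinking_alpha_never_adds_entries(self):
        rng = np.random.default_rng(8)
        f = rng.standard_normal((30, 6))
        loose = build_index({1.0: feature_matrix(f)}, alpha=0.05).densify(1.0)
        tight = build_index({1.0: feature_matrix(f)}, alpha=0.01).densify(1.0)
        assert np.all(loose[tight])  # tight is a subset of loose

    def test_index_is_symmetric_as_unordered_pairs(self):
        rng = np.random.default_rng(9)
        f = rng.standard_normal((25, 8))
        mask = build_index({1.0: feature_matrix(f)}).densify(1.0)
        np.testing.assert_array_equal(mask, mask.T)

    def test_self_pair_optional(self):
        rng = np.random.default_rng(10)
        f = rng.standard_normal((8, 8))
        with_self = build_index({1.0: feature_matrix(f)}).densify(1.0)
        without = build_index({1.0: feature_matrix(f)}, include_self=False).densify(1.0)
        assert np.all(np.diag(with_self))
        assert not np.any(np.diag(without))

    def test_degenerate_features_skipped_with_warning(self):
        f = np.zeros((1, 8))
        with pytest.warns(UserWarning, match="degenerate"):
            idx = build_index({1.0: feature_matrix(f)})
        assert idx.rows == {}

    def test_pvalue_matrix_matches_scalar_path(self):
        rng = np.random.default_rng(11)
        f = rng.standard_normal((10, 16))
        r = correlation_matrix(f)
        p = pvalue_matrix(r, 16)
        for i in range(10):
            for j in range(10):
                assert p[i, j] == pytest.approx(r_pvalue(r[i, j], 16), abs=1e-14)


class TestTimescaleSelection:
    DEFAULTS = [0.5, 1.0, 1.5, 5.0]

    @pytest.mark.parametrize(
        "length,expected",
        [(0.6, 0.5), (1.5, 1.5), (0.3, 0.5), (1.0, 1.0), (4.9, 1.5), (60.0, 5.0)],
    )
    def test_largest_duration_not_exceeding_query(self, length, expected):
        assert select_timescale(length, self.DEFAULTS) == expected


class TestQuery:
    def build(self, f, duration=1.0, **kw):
        return build_index({duration: feature_matrix(f, duration)}, **kw)

    def test_run_decodes_to_consecutive_windows_with_pvalues(self):
        f = np.tile(np.array([1.0, 2.0, 5.0, 3.0]), (10, 1))
        f[7:10] *= 2.3  # still perfectly correlated
        idx = self.build(f)
        res = query(idx, Query(start=2.0, length=1.0))
        assert res.duration == 1.0 and res.query_window == 2
        assert [(h[0], h[1]) for h in res.hits] == [(float(i), float(i + 1)) for i in range(10)]

    def test_window_without_partners_returns_empty_hits(self):
        rng = np.random.default_rng(12)
        f = rng.standard_normal((10, 64))
        idx = self.build(f, alpha=1e-12, include_self=False)
        res = query(idx, Query(start=0.0, length=1.0))
        assert res.hits == []

    def test_query_beyond_recording_warns_and_returns_empty(self):
        rng = np.random.default_rng(13)
        idx = self.build(rng.standard_normal((5, 8)))
        with pytest.warns(UserWarning, match="beyond"):
            res = query(idx, Query(start=100.0, length=1.0))
        assert res.hits == []

    def test_synthetic_condition_query_is_condition_dominated(self, default_session):
        """Querying a condition-A window retrieves mostly condition-A windows."""
        from blkit.features import SpectralConfig, extract_features

        series, truth, _ = default_session
        feats = extract_features(series, SpectralConfig(durations=(1.5,)))
        idx = build_index(feats, include_self=False)
        labels = truth.window_labels(feats[1.5].grid)
        a_windows = [i for i, lab in enumerate(labels) if lab == "A"]
        hits_labels = []
        for i in a_windows:
            res = query(idx, Query(start=i * 1.5 + 0.1, length=1.5))
            hits_labels += [labels[int(h[0] / 1.5)] for h in res.hits]
        assert hits_labels
        precision = sum(lab == "A" for lab in hits_labels) / len(hits_labels)
        assert precision > 0.5


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(14)
        feats = {
            d: feature_matrix(rng.standard_normal((12, 8)), d) for d in (0.5, 1.0)
        }
        idx = build_index(feats)
        idx.source_sha256 = "abc123"
        path = tmp_path / "file.idx.h5"
        save_index(idx, path)
        loaded = load_index(path)
        assert loaded.alpha == idx.alpha
        assert loaded.include_self == idx.include_self
        assert loaded.source_sha256 == "abc123"
        for d in feats:
            np.testing.assert_array_equal(loaded.densify(d), idx.densify(d))
            np.testing.assert_allclose(loaded.r_matrices[d], idx.r_matrices[d])
            for row_a, row_b in zip(loaded.rows[d], idx.rows[d]):
                for ra, rb in zip(row_a, row_b):
                    assert ra.start == rb.start
                    np.testing.assert_array_equal(ra.pvalues, rb.pvalues)
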