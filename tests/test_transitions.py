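"""Correlation maps, Fisher z, FDR masking, Ward clustering, concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tbimine import transitions


def _frame(arr, prefix):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr, index=[f"p{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestCorrelationMatrix:
    def test_identical_columns_correlate_one(self, rng):
        x = (rng.random((100, 1)) < 0.4).astype(int)
        r, und = transitions.correlation_matrix(_frame(x, "a"), _frame(x, "b"))
        assert r.iloc[0, 0] == pytest.approx(1.0)
        assert not und.iloc[0, 0]

    def test_complementary_columns_correlate_minus_one(self, rng):
        x = (rng.random((100, 1)) < 0.4).astype(int)
        r, _ = transitions.correlation_matrix(_frame(x, "a"), _frame(1 - x, "b"))
        assert r.iloc[0, 0] == pytest.approx(-1.0)

    def test_phi_closed_form_from_2x2_counts(self):
        # n11=40, n10=10, n01=10, n00=40 -> phi = (1600-100)/2500 = 0.60
        a = np.r_[np.ones(50), np.zeros(50)]
        b = np.r_[np.ones(40), np.zeros(10), np.ones(10), np.zeros(40)]
        r, _ = transitions.correlation_matrix(_frame(a[:, None], "a"), _frame(b[:, None], "b"))
        assert r.iloc[0, 0] == pytest.approx(0.60)

    def test_random_tables_match_contingency_formula(self, rng):
        for _ in range(20):
            x = (rng.random(200) < rng.uniform(0.2, 0.8)).astype(int)
            y = (rng.random(200) < rng.uniform(0.2, 0.8)).astype(int)
            if x.std() == 0 or y.std() == 0:
                continue
            n11 = int(((x == 1) & (y == 1)).sum())
            n10 = int(((x == 1) & (y == 0)).sum())
            n01 = int(((x == 0) & (y == 1)).sum())
            n00 = int(((x == 0) & (y == 0)).sum())
            phi = (n11 * n00 - n10 * n01) / np.sqrt(
                (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
            )
            r, _ = transitions.correlation_matrix(
                _frame(x[:, None], "a"), _frame(y[:, None], "b")
            )
            assert r.iloc[0, 0] == pytest.approx(phi)

    def test_constant_column_flagged_undefined(self, rng):
        x = (rng.random((50, 1)) < 0.5).astype(int)
        const = np.ones((50, 1), dtype=int)
        r, und = transitions.correlation_matrix(_frame(x, "a"), _frame(const, "b"))
        assert bool(und.iloc[0, 0])

    def test_patient_axis_mismatch_rejected(self, rng):
        a = _frame((rng.random((20, 1)) < 0.5).astype(int), "a")
        b = _frame((rng.random((21, 1)) < 0.5).astype(int), "b")
        with pytest.raises(ValueError, match="patients"):
            transitions.correlation_matrix(a, b)


class TestFisher:
    def test_zero_correlation(self):
        z, p = transitions.fisher_significance(0.0, 100)
        assert (z, p) == (0.0, 1.0)

    def test_atanh_half(self):
        z, _ = transitions.fisher_significance(0.5, 100)
        assert z == pytest.approx(0.54931, abs=1e-5)

    def test_odd_symmetry(self):
        for r in (0.1, 0.3, 0.7):
            zp, _ = transitions.fisher_significance(r, 50)
            zn, _ = transitions.fisher_significance(-r, 50)
            assert zp == pytest.approx(-zn)

    def test_degenerate_unit_correlation(self):
        z, p = transitions.fisher_significance(1.0, 100)
        assert np.isinf(z) and p == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n > 3"):
            transitions.fisher_significance(0.5, 3)

    def test_normal_and_t_routes_agree_within_band(self):
        """Sanity band: z-based and t-based p-values track each other.

        At moderate significance the two routes agree to within 10%
        relative; deep in the tails relative differences between the two
        approximations blow up, so those cases are compared on the log
        scale instead.
        """
        for n in (100, 500, 1000):
            for r in (0.05, 0.1, 0.3, 0.5):
                _, p_z = transitions.fisher_significance(r, n)
                t = r * np.sqrt((n - 2) / (1 - r**2))
                p_t = 2 * stats.t.sf(abs(t), df=n - 2)
                if p_t >= 1e-4:
                    assert abs(p_z - p_t) / p_t < 0.10
                else:
                    assert abs(np.log(p_z) - np.log(p_t)) / abs(np.log(p_t)) < 0.10


class TestFdrMask:
    def _map(self, r, p):
        r = pd.DataFrame(np.atleast_2d(r))
        p = pd.DataFrame(np.atleast_2d(p))
        return r, p

    def test_all_tiny_p_unmasked(self):
        r, p = self._map([[0.5, -0.3]], [[1e-12, 1e-12]])
        masked, q = transitions.fdr_mask(r, p)
        pd.testing.assert_frame_equal(masked, r)

    def test_all_large_p_fully_masked(self):
        r, p = self._map([[0.5, -0.3]], [[0.5, 0.5]])
        masked, _ = transitions.fdr_mask(r, p)
        assert (masked.to_numpy() == 0).all()

    def test_masking_idempotent_and_bounded(self, rng):
        r = pd.DataFrame(rng.uniform(-1, 1, size=(5, 4)))
        p = pd.DataFrame(rng.uniform(0, 1, size=(5, 4)))
        m1, q1 = transitions.fdr_mask(r, p)
        m2, _ = transitions.fdr_mask(m1, p)
        pd.testing.assert_frame_equal(m1, m2)
        vals = m1.to_numpy()
        assert np.all((vals == 0) | ((vals >= -1) & (vals <= 1)))

    def test_masked_value_zero_whenever_q_above_alpha(self, rng):
        r = pd.DataFrame(rng.uniform(-1, 1, size=(6, 6)))
        p = pd.DataFrame(rng.uniform(0, 1, size=(6, 6)))
        masked, q = transitions.fdr_mask(r, p, alpha=0.05)
        above = q.to_numpy() > 0.05
        assert (masked.to_numpy()[above] == 0).all()

    def test_undefined_cells_excluded_from_family(self):
        r, p = self._map([[0.5, np.nan]], [[1e-12, 1.0]])
        und = pd.DataFrame([[False, True]])
        masked, q = transitions.fdr_mask(r, p, undefined=und)
        assert masked.iloc[0, 1] == 0
        assert np.isnan(q.iloc[0, 1])


def brute_force_ward(dist: np.ndarray):
    """O(n^3) Ward agglomeration via the Lance-Williams update.

    Returns the sorted merge heights; independent of scipy's implementation.
    """
    n = dist.shape[0]
    d2 = dist.astype(float) ** 2
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}

    def get(i, j):
        return d[(min(i, j), max(i, j))]

    heights = []
    next_id = n
    while len(active) > 1:
        best = min(
            ((get(i, j), i, j) for i in active for j in active if i < j),
            key=lambda t: t[0],
        )
        h, i, j = best
        heights.append(h)
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dk2 = (
                (ni + nk) * get(i, k) ** 2
                + (nj + nk) * get(j, k) ** 2
                - nk * h**2
            ) / (ni + nj + nk)
            d[(min(k, next_id), max(k, next_id))] = np.sqrt(dk2)
        sizes[next_id] = ni + nj
        active = [a for a in active if a not in (i, j)] + [next_id]
        next_id += 1
    return np.array(heights)


class TestWardCluster:
    def test_identical_profiles_merge_at_height_zero(self):
        mat = pd.DataFrame(
            [[0.5, -0.2, 0.1], [0.5, -0.2, 0.1], [-0.4, 0.8, 0.0]],
            index=["a", "b", "c"],
        )
        res = transitions.ward_cluster(mat, "rows")
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_planted_pairs_merge_before_cross_pairs(self, rng):
        base1 = rng.normal(size=6)
        base2 = rng.normal(size=6) + 5
        mat = pd.DataFrame(
            [base1 + rng.normal(scale=0.01, size=6) for _ in range(2)]
            + [base2 + rng.normal(scale=0.01, size=6) for _ in range(2)],
            index=["a1", "a2", "b1", "b2"],
        )
        res = transitions.ward_cluster(mat, "rows")
        two = res.flat_clusters(2)
        assert two["a1"] == two["a2"] and two["b1"] == two["b2"]
        assert two["a1"] != two["b1"]

    def test_deterministic_across_runs(self, rng):
        mat = pd.DataFrame(rng.normal(size=(6, 5)))
        a = transitions.ward_cluster(mat, "rows")
        b = transitions.ward_cluster(mat, "rows")
        np.testing.assert_array_equal(a.linkage_matrix, b.linkage_matrix)
        assert a.leaf_order == b.leaf_order

    @pytest.mark.parametrize("n_items", [2, 3, 4, 5, 6, 7, 8])
    def test_matches_brute_force_reference(self, n_items, rng):
        from scipy.spatial.distance import squareform

        profiles = rng.normal(size=(n_items, 6))
        mat = pd.DataFrame(profiles, index=[f"i{k}" for k in range(n_items)])
        res = transitions.ward_cluster(mat, "rows")
        dist = squareform(transitions._profile_distance(profiles))
        ref_heights = brute_force_ward(dist)
        np.testing.assert_allclose(res.linkage_matrix[:, 2], ref_heights, atol=1e-10)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            transitions.ward_cluster(pd.DataFrame([[1.0, 2.0]]), "rows")


class TestGroupedMap:
    def test_absent_category_dropped_with_warning(self, rng):
        n = 120
        pre = pd.DataFrame(
            {"P1": (rng.random(n) < 0.3).astype(int)},
            index=[f"c{i}" for i in range(n)],
        )
        labels = pd.DataFrame(
            {
                "severity": ["mild"] * n,  # other categories absent
                "falls": (rng.random(n) < 0.5).astype(int),
                "MVC": np.zeros(n, dtype=int),
            },
            index=pre.index,
        )
        with pytest.warns(UserWarning, match="absent"):
            tm = transitions.grouped_transition_map(pre, labels)
        assert "severity:severe" not in tm.masked.columns
        assert "cause:MVC" not in tm.masked.columns
        assert "cause:falls" in tm.masked.columns

    def test_independent_label_masked_to_zero(self, rng):
        n = 400
        pre = pd.DataFrame(
            {"P1": (rng.random(n) < 0.3).astype(int)}, index=range(n)
        )
        labels = pd.DataFrame(
            {"severity": rng.choice(["mild", "severe"], size=n),
             "falls": (rng.random(n) < 0.4).astype(int)},
            index=range(n),
        )
        tm = transitions.grouped_transition_map(pre, labels)
        assert (tm.masked.to_numpy() == 0).all()


class TestRenderAndCompare:
    def _toy_map(self, rng, seed_shift=0):
        n = 300
        g = np.random.default_rng(77 + seed_shift)
        shared = (g.random(n) < 0.4).astype(int)
        pre = pd.DataFrame(
            {"P1": shared, "P2": (g.random(n) < 0.3).astype(int)}, index=range(n)
        )
        ev = pd.DataFrame(
            {"E1": np.where(g.random(n) < 0.8, shared, 1 - shared),
             "E2": (g.random(n) < 0.3).astype(int)}, index=range(n)
        )
        return transitions.transition_map(pre, ev)

    def test_tsv_roundtrips_bit_exactly(self, tmp_path, rng):
        tm = self._toy_map(rng)
        transitions.render_heatmap(tm, tmp_path / "h.png", tmp_path / "h.tsv")
        back = pd.read_csv(tmp_path / "h.tsv", sep="\t", index_col=0)
        ordered = tm.ordered_masked()
        assert list(back.index) == list(ordered.index)
        assert list(back.columns) == list(ordered.columns)
        np.testing.assert_array_equal(back.to_numpy(), ordered.to_numpy())
        assert (tmp_path / "h.png").exists()

    def test_identical_maps_fully_concordant(self, rng):
        tm = self._toy_map(rng)
        out = transitions.compare_splits({"a": tm, "b": tm})
        row = out.iloc[0]
        assert row["sign_agreement"] == 1.0
        assert row["jaccard_significant"] == 1.0
        assert row["cluster_ari"] == 1.0

    def test_axis_mismatch_rejected(self, rng):
        tm = self._toy_map(rng)
        other = self._toy_map(rng)
        other.masked.columns = ["X1", "X2"]
        with pytest.raises(ValueError, match="axes"):
            transitions.compare_splits({"a": tm, "b": other})
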