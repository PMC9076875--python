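"""Diversity indices against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from multidiv import CommunityTable, css_normalize, multidiversity, shannon
from multidiv.diversity import (
    BetaResult,
    DegenerateNormalizationError,
    EmptyCommunityError,
    RarefactionDepthError,
    bray_curtis,
    multi_betadiversity,
    rarefied_shannon,
    shannon_per_plot,
)


def brute_shannon(x):
    x = np.asarray(x, dtype=float)
    p = x[x > 0] / x.sum()
    return -sum(pi * np.log(pi) for pi in p)


class TestShannon:
    def test_single_taxon_is_zero(self):
        assert shannon([5, 0, 0]) == 0.0

    def test_uniform_community(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4), abs=1e-14)

    def test_matches_direct_formula(self):
        assert shannon([4, 2, 1]) == pytest.approx(brute_shannon([4, 2, 1]), abs=1e-14)

    def test_random_vectors_match_brute_force(self, rng):
        for _ in range(100):
            x = rng.uniform(0, 10, rng.integers(2, 30))
            assert shannon(x) == pytest.approx(brute_shannon(x), abs=1e-12)

    def test_scale_invariance(self, rng):
        x = rng.uniform(0.1, 5, 12)
        assert shannon(x) == pytest.approx(shannon(100 * x), abs=1e-12)

    def test_all_zero_raises(self):
        with pytest.raises(EmptyCommunityError):
            shannon([0, 0, 0])


class TestRarefiedShannon:
    def _table(self, rows, group="bacteria"):
        df = pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))])
        return CommunityTable(df, group, "count")

    def test_full_depth_equals_unrarefied(self):
        t = self._table([[5, 3, 2], [4, 4, 2]])
        out = rarefied_shannon(t, depth=10, n_iter=5, seed=0)
        exact = shannon_per_plot(t)
        assert np.allclose(out, exact)

    def test_identical_plots_agree_within_mc_error(self):
        t = self._table([[40, 30, 20], [40, 30, 20]])
        out = rarefied_shannon(t, depth=30, n_iter=2000, seed=1)
        assert abs(out.iloc[0] - out.iloc[1]) < 0.02

    def test_matches_exact_hypergeometric_expectation(self):
        # 2-taxon plot [8, 2], depth 5: enumerate all subsample compositions
        t = self._table([[8, 2]])
        n_iter = 100_000
        out = rarefied_shannon(t, depth=5, n_iter=n_iter, seed=2)
        ks = np.arange(3, 6)  # taxon-1 draws possible given only 2 of taxon 2
        probs = hypergeom.pmf(ks, 10, 8, 5)
        hs = np.array([brute_shannon([k, 5 - k]) for k in ks])
        expect = float(probs @ hs)
        var = float(probs @ (hs - expect) ** 2)
        se = np.sqrt(var / n_iter)
        assert abs(out.iloc[0] - expect) < 3 * se + 1e-12

    def test_depth_error_lists_offenders(self):
        t = self._table([[5, 5], [2, 1]])
        with pytest.raises(RarefactionDepthError, match="p1"):
            rarefied_shannon(t, depth=8, n_iter=3, seed=0)

    def test_seeded_reproducibility(self):
        t = self._table([[30, 20, 10], [15, 25, 20]])
        a = rarefied_shannon(t, depth=20, n_iter=50, seed=3)
        b = rarefied_shannon(t, depth=20, n_iter=50, seed=3)
        assert a.equals(b)


class TestCssNormalize:
    def test_scalar_multiple_rows_identical(self, toy_table):
        df = pd.DataFrame([[1, 2, 3, 4], [3, 6, 9, 12]], index=["a", "b"])
        out = css_normalize(CommunityTable(df, "fungi", "count"))
        assert np.allclose(out.abundance[0], out.abundance[1])

    def test_hand_computed_at_median_quantile(self, toy_table):
        # per plot: q = median of positive counts, s = sum of counts <= q,
        # rescale by median(s).  p1: q=2.5, s=3; p2: q=5, s=6; p3: q=10, s=20.
        out = css_normalize(toy_table, quantile=0.5)
        s = np.array([3.0, 6.0, 20.0])
        expect = toy_table.abundance / s[:, None] * np.median(s)
        assert np.allclose(out.abundance, expect)
        assert out.semantics == "normalized"

    def test_preserves_within_plot_rank_order(self, rng):
        counts = rng.integers(0, 50, (6, 10))
        counts[:, 0] += 1  # no all-zero plots
        t = CommunityTable(
            pd.DataFrame(counts, index=[f"p{i}" for i in range(6)]),
            "bacteria",
            "count",
        )
        out = css_normalize(t)
        for raw, norm in zip(t.abundance, out.abundance):
            assert np.array_equal(np.argsort(raw, kind="stable"),
                                  np.argsort(norm, kind="stable"))

    def test_single_taxon_falls_back_with_warning(self):
        df = pd.DataFrame([[5], [10]], index=["a", "b"], columns=["t"])
        with pytest.warns(RuntimeWarning, match="total-sum"):
            out = css_normalize(CommunityTable(df, "fungi", "count"))
        assert np.allclose(out.abundance[0], out.abundance[1])


class TestMultidiversity:
    def _div(self, arr, groups=None):
        arr = np.asarray(arr, dtype=float)
        cols = groups or [f"g{i}" for i in range(arr.shape[1])]
        return pd.DataFrame(arr, columns=cols,
                            index=[f"p{i}" for i in range(arr.shape[0])])

    def test_extreme_plots_hit_bounds(self, rng):
        arr = rng.uniform(1, 2, (8, 5))
        arr[0] = 5.0   # best in every group
        arr[1] = 0.1   # worst in every group
        md = multidiversity(self._div(arr)).md
        assert md.iloc[0] == 1.0
        assert md.iloc[1] == 0.0

    def test_hand_ranked_example(self):
        # group ranks: g1 = [1,2,3,4]; g2 = [2.5,2.5,4,1] (tie -> average)
        div = self._div([[1, 2], [2, 2], [3, 3], [4, 1]])
        out = multidiversity(div)
        assert np.allclose(out.mean_ranks, [1.75, 2.25, 3.5, 2.5])
        assert np.allclose(out.md, [0.0, 0.5 / 1.75, 1.0, 0.75 / 1.75])

    def test_monotone_transform_invariance_exp(self, rng):
        arr = rng.uniform(0, 3, (12, 5))
        base = multidiversity(self._div(arr)).md
        arr2 = arr.copy()
        arr2[:, 2] = np.exp(arr2[:, 2])
        assert np.allclose(base, multidiversity(self._div(arr2)).md)

    @given(st.integers(0, 4), st.sampled_from(["exp", "cube", "affine"]))
    def test_monotone_transform_invariance_property(self, col, kind):
        rng = np.random.default_rng(99)
        arr = rng.uniform(0, 3, (10, 5))
        base = multidiversity(self._div(arr)).md
        f = {"exp": np.exp, "cube": lambda v: v**3, "affine": lambda v: 2 * v + 7}[kind]
        arr2 = arr.copy()
        arr2[:, col] = f(arr2[:, col])
        assert np.allclose(base, multidiversity(self._div(arr2)).md)

    def test_missing_group_requires_flag(self):
        div = self._div([[1, 2], [2, np.nan], [3, 1]])
        with pytest.raises(EmptyCommunityError):
            multidiversity(div)
        out = multidiversity(div, allow_missing=True)
        assert np.isfinite(out.md).all()

    def test_constant_mean_ranks_degenerate(self):
        div = self._div([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(DegenerateNormalizationError):
            multidiversity(div)


class TestBrayCurtis:
    def _table(self, rows):
        return CommunityTable(
            pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))]),
            "vascular_plants",
            "cover",
        )

    def test_bounds(self):
        d = bray_curtis(self._table([[1, 2, 0], [1, 2, 0], [0, 0, 9]]))
        # identical rows -> 0; disjoint support -> 1
        assert d[0] == pytest.approx(0.0, abs=1e-15)
        assert d[1] == pytest.approx(1.0, abs=1e-15)

    def test_formula_oracle(self):
        d = bray_curtis(self._table([[6, 2, 0], [2, 2, 4]]))
        assert d[0] == pytest.approx((4 + 0 + 4) / (8 + 4 + 4), abs=1e-14)

    def test_metric_axioms_random(self, rng):
        from scipy.spatial.distance import squareform

        rows = rng.uniform(0, 5, (7, 9))
        m = squareform(bray_curtis(self._table(rows)))
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)
        assert ((m >= 0) & (m <= 1)).all()

    def test_all_zero_pair_undefined(self):
        with pytest.raises(EmptyCommunityError):
            bray_curtis(self._table([[0, 0], [0, 0], [1, 2]]))


class TestMultiBetadiversity:
    def _tables(self, rows_by_group):
        out = []
        for g, rows in rows_by_group.items():
            out.append(
                CommunityTable(
                    pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))]),
                    g,
                    "cover",
                )
            )
        return out

    def test_identical_groups_give_zero(self):
        rows = [[1, 2], [1, 2], [1, 2]]
        groups = {g: rows for g in ("vascular_plants", "bryophytes", "invertebrates")}
        beta = multi_betadiversity(self._tables(groups))
        assert np.allclose(beta.mbd, 0.0)

    def test_mbd_is_mean_of_group_values(self, rng):
        groups = {
            g: rng.uniform(0, 4, (4, 6))
            for g in ("vascular_plants", "bryophytes", "invertebrates", "fungi",
                      "bacteria")
        }
        beta = multi_betadiversity(self._tables(groups))
        stack = np.vstack([beta.per_group[g] for g in beta.per_group])
        assert np.allclose(beta.mbd, stack.mean(axis=0))

    def test_misaligned_tables_raise(self):
        t1 = self._tables({"vascular_plants": [[1, 2], [3, 4]]})[0]
        t2 = CommunityTable(
            pd.DataFrame([[1, 2]], index=["only"]), "bryophytes", "cover"
        )
        with pytest.raises(Exception, match="missing"):
            multi_betadiversity([t1, t2])

    def test_stage_summary_and_symmetry(self, rng):
        groups = {
            g: rng.uniform(0, 4, (6, 5))
            for g in ("vascular_plants", "bryophytes")
        }
        beta = multi_betadiversity(self._tables(groups))
        sq = beta.mbd_square().to_numpy()
        assert np.allclose(sq, sq.T)
        assert np.allclose(np.diag(sq), 0.0)
        summ = beta.stage_summary([True, True, True, False, False, False])
        assert set(summ["stage"]) == {"early", "late"}
        mb = summ[summ.group == "multi_betadiversity"]
        assert (mb["n_pairs"] == 3).all()
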