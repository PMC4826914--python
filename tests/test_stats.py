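"""Rank statistics, expression breadth, and the group-comparison machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import mann_whitney_exact_two_sided

from netsel.stats import (
    add_breadth,
    breadth_selection_trend,
    collapse_by_max,
    compare_groups,
    expression_breadth,
    mann_whitney,
    partial_spearman,
    spearman,
)


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_near_one(self):
        _, p = mann_whitney([1, 2, 3, 4] * 5, [1, 2, 3, 4] * 5)
        assert p > 0.9

    def test_approximation_close_to_enumeration(self, rng):
        # 9 vs 9 tie-free data takes the asymptotic path; enumeration over
        # all C(18, 9) labelings is the ground truth.
        a = rng.normal(size=9)
        b = rng.normal(loc=0.8, size=9)
        _, p_approx = mann_whitney(a, b)
        p_exact = mann_whitney_exact_two_sided(a.tolist(), b.tolist())
        assert p_approx == pytest.approx(p_exact, abs=0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariance_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=6), r.normal(size=9)
        _, p1 = mann_whitney(a, b)
        _, p2 = mann_whitney(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        rho, _ = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariance_under_separate_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=12), r.normal(size=12)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)


class TestPartialSpearman:
    def test_independent_control_leaves_rho_unchanged(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        rho_m, _ = spearman(x, y)
        rho_p, _ = partial_spearman(x, y, z)
        assert rho_p == pytest.approx(rho_m, abs=0.02)

    def test_common_cause_partials_out(self, rng):
        n = 2000
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = z + rng.normal(size=n)
        rho_p, p = partial_spearman(x, y, z)
        assert abs(rho_p) < 2 / np.sqrt(n) * 2

    def test_constant_control_rejected(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError):
            partial_spearman(x, x, np.ones(10))

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        n = 200
        z = rng.normal(size=n)
        x = 0.4 * z + rng.normal(size=n)
        y = -0.3 * z + 0.2 * x + rng.normal(size=n)
        rho, p = partial_spearman(x, y, z)
        ref = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z", method="spearman"
        )
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)


class TestBreadth:
    def test_all_present(self):
        assert expression_breadth([4] * 16) == 16

    def test_all_below_threshold(self):
        assert expression_breadth([2] * 16) == 0

    def test_rule_boundary(self):
        counts = [4, 3, 3] + [0] * 13
        assert expression_breadth(counts) == 3

    def test_count_above_replicates_rejected(self):
        with pytest.raises(ValueError):
            expression_breadth([5] + [0] * 15)

    def test_add_breadth_column(self):
        df = pd.DataFrame({f"tissue_{i:02d}": [4, 0] for i in range(1, 17)})
        out = add_breadth(df)
        assert out["breadth"].tolist() == [16, 0]


class TestCollapseByMax:
    def test_keeps_max_reference_row_per_gene(self):
        df = pd.DataFrame(
            {"gene": ["g1", "g1", "g2"], "probe": ["a", "b", "c"], "abundance": [5.0, 9.0, 1.0]}
        )
        out = collapse_by_max(df, "gene", "abundance")
        assert set(out["probe"]) == {"b", "c"}


class TestTrendAndComparison:
    def _table(self, breadth, selected, tested=None):
        n = len(breadth)
        return pd.DataFrame(
            {
                "breadth": breadth,
                "selected": selected,
                "tested": tested if tested is not None else [True] * n,
                "degree": np.arange(n),
            }
        )

    def test_tied_fractions_reported_as_zero(self):
        t = self._table([0] * 4 + [1] * 4 + [2] * 4, [True, False] * 6)
        rho, p = breadth_selection_trend(t)
        assert rho == 0.0 and p == 1.0

    def test_increasing_fractions_give_rho_one(self):
        t = self._table(
            [0] * 4 + [1] * 4 + [2] * 4,
            [False] * 4 + [True, False, False, False] + [True, True, False, False],
        )
        rho, _ = breadth_selection_trend(t)
        assert rho == pytest.approx(1.0)

    def test_too_few_bins_rejected(self):
        t = self._table([0] * 4 + [1] * 4, [True, False] * 4)
        with pytest.raises(ValueError):
            breadth_selection_trend(t)

    def test_compare_groups_consistency(self):
        t = self._table([0] * 10, [True] * 5 + [False] * 5)
        t["degree"] = [10, 11, 12, 13, 14, 1, 2, 3, 4, 5]
        res = compare_groups(t, "degree")
        assert res.mean_selected > res.mean_other
        assert res.p_value == pytest.approx(mann_whitney(t.degree[:5], t.degree[5:])[1])

    def test_untested_genes_excluded(self):
        t = self._table([0] * 6, [True] * 3 + [False] * 3, tested=[True] * 4 + [False] * 2)
        res = compare_groups(t, "degree")
        assert res.n_selected + res.n_other == 4

    def test_empty_group_skipped_with_error(self):
        t = self._table([0] * 4, [False] * 4)
        with pytest.raises(ValueError, match="skipped"):
            compare_groups(t, "degree")

    def test_null_rejection_rate_calibrated(self, rng):
        """Same-distribution groups: rejection at 0.05 within [0.01, 0.10]."""
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(size=60)
            b = rng.normal(size=60)
            _, p = mann_whitney(a, b)
            rejections += p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.10
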