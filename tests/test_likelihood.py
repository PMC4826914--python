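"""Pruning likelihood against exhaustive enumeration and closed forms."""

import numpy as np
import pytest
from oracles import (
    encode_column,
    enumeration_balanced4_loglik,
    enumeration_star_loglik,
)

from netsel import trees
from netsel.codon_model import discretize_beta, m8_class_set
from netsel.codons import CODON_INDEX, CODONS
from netsel.likelihood import (
    OmegaGrid,
    PatternAlignment,
    mixture_loglik,
    site_log_likelihood,
)
from netsel.msa import Alignment


class TestAgainstEnumeration:
    def test_star_tree_matches_exhaustive_sum(self, star3, rng):
        pi = rng.dirichlet(np.ones(61))
        cs = m8_class_set(2.0, 3.0, 0.85, 3.0, 4)
        rho = cs.scale_factor(2.0, pi)
        for _ in range(5):
            col = rng.integers(0, 61, size=3)
            ours = site_log_likelihood(
                [CODONS[c] for c in col], star3, cs, 2.0, pi, rate_scale=rho
            )
            oracle = enumeration_star_loglik([0.2, 0.1, 0.3], col, 2.0, pi, cs, rho)
            assert ours == pytest.approx(oracle, rel=1e-10, abs=1e-10)

    def test_balanced_tree_with_missing_data(self, rng):
        tree = trees.from_newick("((a:0.15,b:0.25):0.1,(c:0.05,d:0.3):0.2);")
        pi = rng.dirichlet(np.ones(61))
        cs = discretize_beta(1.5, 3.0, 3)
        rho = cs.scale_factor(1.7, pi)
        col = {"a": "ATG", "b": "---", "c": "ATA", "d": "CTG"}
        ours = site_log_likelihood(col, tree, cs, 1.7, pi, rate_scale=rho)
        states = encode_column([col[t] for t in ("a", "b", "c", "d")])
        oracle = enumeration_balanced4_loglik(
            (0.15, 0.25, 0.05, 0.3, 0.1, 0.2), states, 1.7, pi, cs, rho
        )
        assert ours == pytest.approx(oracle, rel=1e-10, abs=1e-10)


class TestZeroBranchClosedForms:
    def test_identical_column_gives_stationary_probability(self, equal_pi):
        tree = trees.from_newick("(a:0,b:0,c:0);")
        cs = discretize_beta(2.0, 2.0, 4)
        ll = site_log_likelihood({"a": "ATG", "b": "ATG", "c": "ATG"}, tree, cs, 2.0, equal_pi)
        assert ll == pytest.approx(np.log(equal_pi[CODON_INDEX["ATG"]]), abs=1e-12)

    def test_conflicting_column_is_an_error(self, equal_pi):
        tree = trees.from_newick("(a:0,b:0,c:0);")
        cs = discretize_beta(2.0, 2.0, 4)
        with pytest.raises(ValueError):
            site_log_likelihood({"a": "ATG", "b": "TTT", "c": "ATG"}, tree, cs, 2.0, equal_pi)

    def test_alignment_loglik_is_sum_of_stationary_logs(self, equal_pi):
        tree = trees.from_newick("(a:0,b:0,c:0);")
        cs = discretize_beta(2.0, 2.0, 4)
        seq = "ATGAAACCC"
        aln = Alignment(ids=["a", "b", "c"], seqs=[seq] * 3)
        pat = PatternAlignment.from_alignment(aln, tree)
        ll = mixture_loglik(tree, cs, 2.0, equal_pi, pat)
        expected = sum(
            np.log(equal_pi[CODON_INDEX[seq[i : i + 3]]]) for i in range(0, 9, 3)
        )
        assert ll == pytest.approx(expected, abs=1e-10)


class TestDivergenceSummaries:
    def test_tip_path_lengths(self):
        tree = trees.from_newick("((a:0.1,b:0.2):0.3,c:0.4);")
        d = trees.tip_path_lengths(tree)
        order = {t: i for i, t in enumerate(tree.tip_labels)}
        assert d[order["a"], order["b"]] == pytest.approx(0.3)
        assert d[order["a"], order["c"]] == pytest.approx(0.8)
        assert d[order["b"], order["c"]] == pytest.approx(0.9)

    def test_observed_diff_counts_pairwise_mismatches(self):
        from netsel.likelihood import observed_mean_pairwise_diff

        aln = Alignment(ids=["a", "b"], seqs=["ATGAAA", "ATGCCC"])
        tree = trees.from_newick("(a:0.1,b:0.1);")
        pat = PatternAlignment.from_alignment(aln, tree)
        assert observed_mean_pairwise_diff(pat) == pytest.approx(0.5)

    def test_predicted_diff_matches_simulation(self, five_taxon_tree, equal_pi):
        """Closed-form expected pairwise divergence agrees with a large
        simulated alignment under the same regime."""
        from netsel.likelihood import observed_mean_pairwise_diff, predicted_mean_pairwise_diff
        from netsel.synthetic import simulate_gene_family

        cs = discretize_beta(2.0, 5.0, 10)
        rho = cs.scale_factor(2.0, equal_pi)
        pred = predicted_mean_pairwise_diff(five_taxon_tree, 2.0, equal_pi, cs, rho)
        aln, _ = simulate_gene_family(
            five_taxon_tree, 4000, "M7", {"p": 2.0, "q": 5.0}, 31, kappa=2.0, pi=equal_pi
        )
        obs = observed_mean_pairwise_diff(PatternAlignment.from_alignment(aln, five_taxon_tree))
        assert obs == pytest.approx(pred, abs=0.02)

    def test_regimes_are_separable_by_divergence(self, five_taxon_tree, equal_pi):
        """The two generator regimes predict clearly different pairwise
        divergences, the basis for per-gene rate-scale matching."""
        from netsel.likelihood import predicted_mean_pairwise_diff

        cs7 = discretize_beta(2.0, 5.0, 10)
        cs8 = m8_class_set(2.0, 5.0, 0.8, 4.0, 10)
        d7 = predicted_mean_pairwise_diff(
            five_taxon_tree, 2.0, equal_pi, cs7, cs7.scale_factor(2.0, equal_pi)
        )
        d8 = predicted_mean_pairwise_diff(
            five_taxon_tree, 2.0, equal_pi, cs8, cs8.scale_factor(2.0, equal_pi)
        )
        # both regimes have identical expected substitutions per codon, but
        # the spike regime concentrates change on fewer, saturating sites,
        # so its observed per-codon divergence is distinctly lower
        assert d7 - d8 > 0.05


class TestOmegaGrid:
    def test_grid_curves_match_direct_evaluation_at_grid_points(self, five_taxon_tree, equal_pi, rng):
        from netsel.likelihood import class_pattern_logliks

        grid = OmegaGrid(five_taxon_tree, 2.0, equal_pi, rate_scale=1.0)
        states = rng.integers(0, 61, size=(5, 20))
        pat = PatternAlignment.from_states(states)
        curves = grid.site_curves(pat)
        direct = class_pattern_logliks(
            five_taxon_tree, 2.0, equal_pi, grid.grid[[0, 10, -1]], pat, time_scale=1.0
        )
        # float32 curves against float64 direct evaluation
        assert np.allclose(curves[[0, 10, -1]], direct, rtol=5e-5, atol=5e-4)

    def test_interpolation_error_is_small_between_grid_points(self, five_taxon_tree, equal_pi, rng):
        from netsel.likelihood import class_pattern_logliks

        grid = OmegaGrid(five_taxon_tree, 2.0, equal_pi, rate_scale=1.0)
        states = rng.integers(0, 61, size=(5, 30))
        pat = PatternAlignment.from_states(states)
        curves = grid.site_curves(pat)
        probe = np.array([0.23, 0.57, 2.3])
        interp = grid.interp_class_logliks(curves, probe)
        direct = class_pattern_logliks(five_taxon_tree, 2.0, equal_pi, probe, pat, time_scale=1.0)
        assert np.abs(interp - direct).max() < 0.01  # per-site log units

    def test_mixture_loglik_consistent_with_direct_mixture(self, five_taxon_tree, equal_pi, rng):
        cs = m8_class_set(2.0, 5.0, 0.9, 2.5, 10)
        rho = cs.scale_factor(2.0, equal_pi)
        grid = OmegaGrid(five_taxon_tree, 2.0, equal_pi, rate_scale=rho)
        states = rng.integers(0, 61, size=(5, 40))
        pat = PatternAlignment.from_states(states)
        via_grid = grid.mixture_loglik(grid.site_curves(pat), pat.weights, cs)
        direct = mixture_loglik(five_taxon_tree, cs, 2.0, equal_pi, pat, rate_scale=rho)
        # agreement at the interpolation level (PCHIP: <~1e-3 per site)
        assert via_grid == pytest.approx(direct, abs=0.005 * pat.n_sites)
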