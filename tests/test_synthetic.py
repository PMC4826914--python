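"""The synthetic-study generator: sequences, artifacts, networks, covariates."""

import networkx as nx
import numpy as np
import pytest
from scipy.stats import spearmanr

from netsel import trees
from netsel.align_filter import singleton_window_mask
from netsel.codons import STOP_CODONS, translate_cds
from netsel.msa import Alignment
from netsel.synthetic import (
    EffectSpec,
    ErrorSpec,
    NetworkSpec,
    assign_covariates_and_selection,
    inject_annotation_errors,
    simulate_gene_family,
    simulate_network,
)


class TestGeneFamilySimulation:
    def test_zero_branch_lengths_give_identical_sequences(self):
        tree = trees.from_newick("(a:0,b:0,c:0);")
        aln, _ = simulate_gene_family(tree, 30, "M7", {"p": 2, "q": 5}, 0)
        assert len(set(aln.seqs)) == 1

    def test_m7_site_omegas_never_exceed_one(self, five_taxon_tree):
        _, lab = simulate_gene_family(five_taxon_tree, 10000, "M7", {"p": 2, "q": 5}, 1)
        assert lab.site_omegas.max() <= 1.0
        assert not lab.spike_sites.any()

    def test_m8_spike_fraction_binomial(self, five_taxon_tree):
        n = 10000
        _, lab = simulate_gene_family(
            five_taxon_tree, n, "M8", {"p": 2, "q": 5, "p0": 0.8, "omega_s": 4.0}, 2
        )
        frac = lab.spike_sites.mean()
        sd = np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) < 3 * sd

    def test_alignments_gapless_stop_free_and_sized(self, five_taxon_tree):
        aln, _ = simulate_gene_family(five_taxon_tree, 77, "M7", {"p": 2, "q": 5}, 3)
        assert aln.length == 3 * 77
        for seq in aln.seqs:
            assert "-" not in seq
            assert not any(seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq), 3))
            assert len(translate_cds(seq)) == 77

    def test_seed_fixes_every_byte(self, five_taxon_tree):
        a1, _ = simulate_gene_family(five_taxon_tree, 50, "M8", {"p": 2, "q": 5, "p0": 0.9, "omega_s": 3.0}, 42)
        a2, _ = simulate_gene_family(five_taxon_tree, 50, "M8", {"p": 2, "q": 5, "p0": 0.9, "omega_s": 3.0}, 42)
        assert a1.seqs == a2.seqs

    def test_divergence_scales_with_branch_length(self):
        short = trees.default_tree(5, 0.2)
        long = trees.default_tree(5, 4.0)
        pid = {}
        for name, tree in (("short", short), ("long", long)):
            aln, _ = simulate_gene_family(tree, 800, "M7", {"p": 2, "q": 5}, 9)
            a, b = aln.seqs[0], aln.seqs[-1]
            pid[name] = np.mean([x == y for x, y in zip(a, b)])
        assert pid["short"] > 0.9 > pid["long"]

    def test_invalid_inputs_rejected(self, five_taxon_tree):
        with pytest.raises(ValueError):
            simulate_gene_family(five_taxon_tree, 0, "M7", {"p": 2, "q": 5}, 0)
        with pytest.raises(ValueError):
            simulate_gene_family(five_taxon_tree, 10, "M9", {"p": 2, "q": 5}, 0)


class TestCohort:
    def test_null_fraction_controls_regime_mix(self):
        from netsel.synthetic import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(n_genes=200, n_codons=6, null_fraction=0.7, seed=5)
        regimes = [lab.regime for _, _, lab in simulate_cohort(cfg)]
        frac_m7 = regimes.count("M7") / len(regimes)
        assert abs(frac_m7 - 0.7) < 3 * np.sqrt(0.7 * 0.3 / 200)


class TestErrorInjection:
    def test_zero_windows_identity(self, five_taxon_tree):
        aln, lab = simulate_gene_family(five_taxon_tree, 40, "M7", {"p": 2, "q": 5}, 4)
        out, _ = inject_annotation_errors(aln, ErrorSpec(n_windows=0), 5, lab)
        assert out.seqs == aln.seqs

    def test_window_is_singleton_rich(self, five_taxon_tree):
        aln, lab = simulate_gene_family(five_taxon_tree, 60, "M7", {"p": 2, "q": 5}, 6)
        out, lab = inject_annotation_errors(aln, ErrorSpec(1, 15), 7, lab)
        prots = [translate_cds(s) for s in out.seqs]
        ti = out.ids.index(lab.error_taxon)
        singles = 0
        for col in lab.error_columns:
            aa = prots[ti][col - 1]
            if all(prots[i][col - 1] != aa for i in range(len(prots)) if i != ti):
                singles += 1
        assert singles >= 10

    def test_injected_columns_are_masked_by_the_window_filter(self, five_taxon_tree):
        aln, lab = simulate_gene_family(five_taxon_tree, 80, "M7", {"p": 2, "q": 5}, 8)
        out, lab = inject_annotation_errors(aln, ErrorSpec(1, 15), 9, lab)
        prot = Alignment(ids=list(out.ids), seqs=[translate_cds(s) for s in out.seqs])
        mask = singleton_window_mask(prot)
        assert lab.error_columns <= mask.union()

    def test_window_longer_than_alignment_rejected(self, five_taxon_tree):
        aln, lab = simulate_gene_family(five_taxon_tree, 10, "M7", {"p": 2, "q": 5}, 10)
        with pytest.raises(ValueError):
            inject_annotation_errors(aln, ErrorSpec(1, 15), 11, lab)


class TestNetwork:
    def test_edge_count_closed_form(self):
        for n, m in ((100, 2), (50, 3)):
            g = simulate_network(NetworkSpec(n_nodes=n, m=m), 0)
            assert g.number_of_edges() == m * (n - m) + m * (m - 1) // 2

    def test_simple_connected_graph(self):
        g = simulate_network(NetworkSpec(n_nodes=120, m=2), 1)
        assert nx.is_connected(g)
        assert all(u != v for u, v in g.edges)
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()

    def test_edge_attributes_present(self):
        g = simulate_network(NetworkSpec(n_nodes=30, m=2), 2)
        for _, _, d in g.edges(data=True):
            assert d["interaction_type"] in {"physical", "genetic"}
            assert d["evidence"] in {"LTP", "HTP"}
            assert 0 <= d["score"] <= 1000

    def test_m_bounds_enforced(self):
        with pytest.raises(ValueError):
            NetworkSpec(n_nodes=5, m=5)


@pytest.fixture(scope="module")
def big_net():
    return simulate_network(NetworkSpec(n_nodes=5000, m=3), 3)


class TestCovariates:

    def test_no_effect_means_no_degree_association(self, big_net):
        df = assign_covariates_and_selection(big_net, EffectSpec(beta1=0.0), 4)
        sel = df[df.selected_true].degree_true
        other = df[~df.selected_true].degree_true
        se = np.sqrt(sel.var() / len(sel) + other.var() / len(other))
        assert abs(sel.mean() - other.mean()) < 3 * se

    def test_negative_effect_selects_low_degree(self, big_net):
        df = assign_covariates_and_selection(big_net, EffectSpec(beta1=-1.0), 5)
        assert df[df.selected_true].degree_true.mean() < df[~df.selected_true].degree_true.mean()

    def test_positive_effect_selects_high_degree(self, big_net):
        df = assign_covariates_and_selection(big_net, EffectSpec(beta1=1.0), 6)
        assert df[df.selected_true].degree_true.mean() > df[~df.selected_true].degree_true.mean()

    def test_copula_hits_target_rank_correlation(self, big_net):
        df = assign_covariates_and_selection(big_net, EffectSpec(beta1=0.0), 7)
        rho = spearmanr(df.mrna_abundance, df.degree_true).statistic
        assert rho == pytest.approx(0.4, abs=0.05)

    def test_tissue_counts_in_range(self, big_net):
        df = assign_covariates_and_selection(big_net, EffectSpec(beta1=0.0), 8)
        tissue_cols = [c for c in df.columns if c.startswith("tissue_")]
        assert len(tissue_cols) == 16
        assert df[tissue_cols].to_numpy().min() >= 0
        assert df[tissue_cols].to_numpy().max() <= 4

    def test_extreme_rank_correlation_rejected(self):
        with pytest.raises(ValueError):
            EffectSpec(rho={"mrna_abundance": 1.0})
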