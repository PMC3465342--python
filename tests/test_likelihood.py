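import itertools

import numpy as np
import pytest

from phyloframe.io_formats import CharacterMatrix
from phyloframe.likelihood import (clock_lrt, fit_model, jc_distance,
                                   log_likelihood, ml_pairwise_distance,
                                   ml_search, model_select, nj_tree,
                                   optimize_branch_lengths, per_gene_rates,
                                   site_log_likelihoods)
from phyloframe.models import SubstitutionModel
from phyloframe.supermatrix import ry_recode
from phyloframe.syndata import (SimulationScenario, simulate_chronogram,
                                simulate_partition)
from phyloframe.trees import Phylotree, all_unrooted_topologies, robinson_foulds


def brute_force_lnl(tree, model, matrix):
    """Sum over all internal-state assignments and rate categories — the
    independent oracle for the pruning algorithm."""
    rates, w = model.category_rates()
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    k = model.n_states
    pi = np.array(model.base_frequencies)
    lnL = 0.0
    for site in range(matrix.n_sites):
        tot = 0.0
        for ci, r in enumerate(rates):
            P = {id(n): model.transition_matrices(
                np.array([(n.length or 0.0) * r]))[0] for n in nodes}
            s = 0.0
            for assign in itertools.product(range(k), repeat=len(internals)):
                amap = dict(zip([id(n) for n in internals], assign))
                pr = pi[amap[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    ps = amap[id(n.parent)]
                    if n.is_leaf:
                        ch = matrix.sequence(n.label)[site]
                        pr *= (1.0 if ch in "?-"
                               else P[id(n)][ps, model.states.index(ch)])
                    else:
                        pr *= P[id(n)][ps, amap[id(n)]]
                s += pr
            tot += w[ci] * s
        lnL += np.log(tot)
    return lnL


GTR_GI = SubstitutionModel.gtr(exchangeabilities=(1, 2, 1, 1, 3, 1),
                               base_frequencies=(0.1, 0.2, 0.3, 0.4),
                               gamma_shape=0.5, p_inv=0.2)


class TestPruning:
    def test_matches_brute_force_with_missing_data(self, quartet_tree,
                                                   quartet_matrix):
        lp = log_likelihood(quartet_tree, GTR_GI, quartet_matrix)
        lb = brute_force_lnl(quartet_tree, GTR_GI, quartet_matrix)
        assert lp == pytest.approx(lb, abs=1e-10)

    def test_matches_brute_force_five_taxa(self):
        t = Phylotree.from_newick(
            "((a:0.1,b:0.2):0.15,(c:0.3,(d:0.05,e:0.4):0.1):0.2);").unroot()
        m = CharacterMatrix(list("abcde"), ["ACG", "AAG", "CAG", "CCG", "TTG"])
        model = SubstitutionModel.hky(3.0, (0.3, 0.2, 0.2, 0.3), gamma_shape=0.7)
        assert log_likelihood(t, model, m) == pytest.approx(
            brute_force_lnl(t, model, m), abs=1e-10)

    def test_rooting_invariance(self, quartet_tree, quartet_matrix):
        base = log_likelihood(quartet_tree, GTR_GI, quartet_matrix)
        for leaf in quartet_tree.leaves():
            t2 = quartet_tree.reroot_on_edge(leaf)
            assert log_likelihood(t2, GTR_GI, quartet_matrix) == pytest.approx(
                base, abs=1e-9)

    def test_site_rows_sum_to_total(self, quartet_tree, quartet_matrix):
        row = site_log_likelihoods(quartet_tree, GTR_GI, quartet_matrix)
        assert row.sum() == pytest.approx(
            log_likelihood(quartet_tree, GTR_GI, quartet_matrix), abs=1e-8)

    def test_single_taxon_rejected(self):
        m = CharacterMatrix(["a"], ["ACGT"])
        t = Phylotree.from_newick("(a:1);")
        with pytest.raises(ValueError):
            site_log_likelihoods(t, GTR_GI, m)

    def test_negative_branch_rejected(self, quartet_matrix):
        t = Phylotree.from_newick("((a:0.1,b:0.2):0.1,(c:0.3,d:0.1):0.1);")
        t.leaves()[0].length = -0.5
        with pytest.raises(ValueError):
            log_likelihood(t, GTR_GI, quartet_matrix)

    def test_gamma_limit_is_rate_homogeneous(self, quartet_tree,
                                             quartet_matrix):
        flat = SubstitutionModel.gtr(exchangeabilities=(1, 2, 1, 1, 3, 1))
        gam = flat.with_rates(gamma_shape=1e6)
        assert log_likelihood(quartet_tree, gam, quartet_matrix) == \
            pytest.approx(log_likelihood(quartet_tree, flat, quartet_matrix),
                          abs=1e-6)

    def test_binary_model_relabeling_symmetry(self):
        m = CharacterMatrix(["a", "b", "c", "d"],
                            ["RYRY", "RRYY", "YYRR", "YRYR"], alphabet="RY")
        swapped = CharacterMatrix(["a", "b", "c", "d"],
                                  ["YRYR", "YYRR", "RRYY", "RYRY"],
                                  alphabet="RY")
        t = Phylotree.from_newick("((a:0.2,b:0.1):0.1,(c:0.3,d:0.2):0.1);")
        m1 = SubstitutionModel.binary(freq_r=0.3)
        m2 = SubstitutionModel.binary(freq_r=0.7)
        assert log_likelihood(t, m1, m) == pytest.approx(
            log_likelihood(t, m2, swapped), abs=1e-9)


class TestDistances:
    def test_jc_closed_form(self):
        s1 = "A" * 1000
        s2 = "A" * 800 + "C" * 200
        d = ml_pairwise_distance(s1, s2, SubstitutionModel.jc())
        assert d == pytest.approx(jc_distance(0.2), abs=1e-6)

    def test_jc_formula_values(self):
        assert jc_distance(0.0) == 0.0
        assert jc_distance(0.2) == pytest.approx(-0.75 * np.log(1 - 0.8 * 0.2 / 0.6))
        assert np.isinf(jc_distance(0.8))


class TestBranchLengths:
    def test_zero_variation_collapses(self):
        m = CharacterMatrix(list("abcd"), ["ACGT"] * 4)
        t = Phylotree.from_newick("((a:0.3,b:0.3):0.3,(c:0.3,d:0.3):0.3);").unroot()
        opt = optimize_branch_lengths(t, SubstitutionModel.jc(), m)
        for n in opt.postorder():
            if n.parent is not None:
                assert n.length < 1e-6

    def test_lengths_recovered(self, six_taxon_chronogram):
        gm = simulate_partition(six_taxon_chronogram,
                                SubstitutionModel.jc(), 20000, seed=60)
        truth = six_taxon_chronogram.to_ultrametric_lengths()
        for n in truth.postorder():
            if n.parent is not None:
                n.length *= 0.01
        opt = optimize_branch_lengths(truth, SubstitutionModel.jc(), gm)
        for nt, no in zip(truth.postorder(), opt.postorder()):
            if nt.parent is not None and nt.length > 0.02:
                assert no.length == pytest.approx(nt.length, rel=0.15)

    def test_lnl_never_decreases(self, six_taxon_jc_data):
        t = nj_tree(six_taxon_jc_data)
        l0 = log_likelihood(t, SubstitutionModel.jc(), six_taxon_jc_data)
        opt = optimize_branch_lengths(t, SubstitutionModel.jc(),
                                      six_taxon_jc_data)
        assert opt.root.annotations["lnl"] >= l0 - 1e-9


class TestSearchAndSelection:
    def test_recovery_and_ascent(self, six_taxon_chronogram,
                                 six_taxon_jc_data):
        start = nj_tree(six_taxon_jc_data)
        l_start = log_likelihood(start, SubstitutionModel.jc(),
                                 six_taxon_jc_data)
        best = ml_search(six_taxon_jc_data, SubstitutionModel.jc(),
                         n_starts=1, seed=1)
        assert best.root.annotations["lnl"] >= l_start
        assert robinson_foulds(best, six_taxon_chronogram.tree) == 0

    def test_matches_exhaustive_at_five_taxa(self):
        sc = SimulationScenario(n_taxa=5, clock="strict", base_rate=0.02,
                                root_age=10, seed=70)
        ch = simulate_chronogram(sc)
        m = simulate_partition(ch, SubstitutionModel.jc(), 400, seed=71)
        best = ml_search(m, SubstitutionModel.jc(), n_starts=2, seed=2)
        lnls = {}
        for t in all_unrooted_topologies(m.taxa):
            opt = optimize_branch_lengths(t, SubstitutionModel.jc(), m,
                                          tol=1e-5, max_sweeps=10)
            lnls[frozenset(t.bipartitions())] = opt.root.annotations["lnl"]
        assert best.root.annotations["lnl"] == pytest.approx(
            max(lnls.values()), abs=0.05)

    def test_model_select_jc_on_jc_data(self, six_taxon_jc_data):
        m = model_select(six_taxon_jc_data, "BIC")
        assert m.name.startswith("JC")

    def test_nested_models_never_fit_worse(self, six_taxon_jc_data):
        tree = nj_tree(six_taxon_jc_data)
        _m1, l_hky, _ = fit_model(six_taxon_jc_data, "HKY", (), tree)
        _m2, l_gtr, _ = fit_model(six_taxon_jc_data, "GTR", (), tree)
        assert l_gtr >= l_hky - 0.05

    def test_degenerate_matrix_returns_jc(self):
        m = CharacterMatrix(list("abcd"), ["AAAA"] * 4)
        with pytest.warns(UserWarning):
            sel = model_select(m, "BIC")
        assert sel.name == "JC"


class TestClock:
    def test_statistic_nonnegative_and_null_accepts(self, six_taxon_chronogram,
                                                    six_taxon_jc_data):
        stat, df, p = clock_lrt(six_taxon_jc_data, six_taxon_chronogram.tree)
        assert stat >= 0
        assert df == 4
        assert p > 0.01  # clock data should not be strongly rejected

    def test_rate_heterogeneity_rejected(self):
        sc = SimulationScenario(n_taxa=6, clock="autocorrelated", sigma2=0.3,
                                base_rate=0.01, root_age=10, seed=14)
        ch = simulate_chronogram(sc)
        m = simulate_partition(ch, SubstitutionModel.jc(), 5000, seed=15)
        stat, df, p = clock_lrt(m, ch.tree)
        assert p < 0.05


class TestGeneRates:
    def test_two_to_one_ratio_recovered(self, six_taxon_chronogram):
        g1 = simulate_partition(six_taxon_chronogram, SubstitutionModel.jc(),
                                4000, 1.0, seed=16)
        g2 = simulate_partition(six_taxon_chronogram, SubstitutionModel.jc(),
                                4000, 2.0, seed=17)
        rates = per_gene_rates({"g1": g1, "g2": g2}, nj_tree(g1))
        assert rates["g2"] / rates["g1"] == pytest.approx(2.0, rel=0.1)
        assert np.mean(list(rates.values())) == pytest.approx(1.0)

    def test_identical_genes_rate_one(self, six_taxon_jc_data):
        rates = per_gene_rates({"a": six_taxon_jc_data,
                                "b": six_taxon_jc_data},
                               nj_tree(six_taxon_jc_data))
        assert rates["a"] == pytest.approx(1.0)
        assert rates["b"] == pytest.approx(1.0)

    def test_invariant_to_reference_rescaling(self, six_taxon_jc_data):
        ref = nj_tree(six_taxon_jc_data)
        ref2 = ref.copy()
        for n in ref2.postorder():
            if n.parent is not None:
                n.length = (n.length or 0) * 7.5
        r1 = per_gene_rates({"a": six_taxon_jc_data}, ref)
        r2 = per_gene_rates({"a": six_taxon_jc_data}, ref2)
        assert r1["a"] == pytest.approx(r2["a"])


class TestBootstrapML:
    def test_strong_signal_supports_and_range(self, six_taxon_chronogram,
                                              six_taxon_jc_data):
        from phyloframe.likelihood import bootstrap_ml
        support = bootstrap_ml(six_taxon_jc_data, SubstitutionModel.jc(),
                               n_reps=5, seed=3)
        assert all(0 <= v <= 100 for v in support.values())
        for split in six_taxon_chronogram.tree.bipartitions():
            assert support.get(split, 0.0) >= 80.0
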