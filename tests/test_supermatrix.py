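import itertools

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from phyloframe.io_formats import CharacterMatrix, PartitionEntry, PartitionMap
from phyloframe.models import SubstitutionModel
from phyloframe.supermatrix import (chi2_homogeneity, concatenate,
                                    indel_filter, p_distance_matrix,
                                    pairwise_align_score, progressive_align,
                                    ry_recode, stability_filter, sweep_align)
from phyloframe.syndata import (SimulationScenario, simulate_chronogram,
                                simulate_partition)


def nw_affine_oracle(s1, s2, gap_open, gap_extend, match=1.0, mismatch=-1.0):
    """Exhaustive Gotoh DP (plain dict implementation) for the optimal
    global affine-gap score; independent of the package's vectorized code."""
    n, m = len(s1), len(s2)
    NEG = float("-inf")
    M = {(0, 0): 0.0}
    X, Y = {}, {}
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            sub = NEG
            if i > 0 and j > 0:
                s = match if s1[i - 1] == s2[j - 1] else mismatch
                sub = max(M.get((i - 1, j - 1), NEG), X.get((i - 1, j - 1), NEG),
                          Y.get((i - 1, j - 1), NEG)) + s
            M[(i, j)] = sub
            x = NEG
            if i > 0:
                x = max(M.get((i - 1, j), NEG) - gap_open - gap_extend,
                        X.get((i - 1, j), NEG) - gap_extend)
            X[(i, j)] = x
            y = NEG
            if j > 0:
                y = max(M.get((i, j - 1), NEG) - gap_open - gap_extend,
                        Y.get((i, j - 1), NEG) - gap_extend)
            Y[(i, j)] = y
    return max(M[(n, m)], X[(n, m)], Y[(n, m)])


class TestAlignment:
    def test_identical_sequences_gapless(self):
        m = progressive_align({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        assert m.sequences == ["ACGT"] * 3

    def test_single_deletion_recovered(self):
        m = progressive_align({"a": "ACGTACGT", "b": "ACGACGT"}, 3, 1)
        assert m.sequence("a") == "ACGTACGT"
        assert m.sequence("b").count("-") == 1
        # the placement is optimal under the scoring scheme
        score = pairwise_align_score("ACGTACGT", "ACGACGT", 3, 1)
        assert score == nw_affine_oracle("ACGTACGT", "ACGACGT", 3, 1)

    def test_pairwise_scores_match_dp_oracle(self, rng):
        for _ in range(20):
            s1 = "".join(rng.choice(list("ACGT"), rng.integers(5, 30)))
            s2 = "".join(rng.choice(list("ACGT"), rng.integers(5, 30)))
            go, ge = float(rng.integers(2, 8)), float(rng.integers(1, 4))
            assert pairwise_align_score(s1, s2, go, ge) == pytest.approx(
                nw_affine_oracle(s1, s2, go, ge))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_align({"a": "", "b": "ACGT"})


class TestStability:
    def test_identical_sweep_keeps_all(self):
        seqs = {"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"}
        alns = sweep_align(seqs, grid=[(3, 1), (9, 3), (15, 5)])
        mask = stability_filter(alns)
        assert mask.keep.all()
        assert len(mask.keep) == alns[0].n_sites

    def test_shifted_gap_drops_affected_columns(self):
        # hand-built 3-taxon toy: one sweep member places the gap one
        # column to the right; the moved columns lose their homology sets
        a1 = CharacterMatrix(["x", "y", "z"], ["ACGTA", "AC-TA", "ACGTA"])
        a2 = CharacterMatrix(["x", "y", "z"], ["ACGTA", "ACT-A", "ACGTA"])
        mask = stability_filter([a1, a2])
        # columns 0,1,4 assert identical homology pairs in both; 2,3 differ
        assert list(mask.keep) == [True, True, False, False, True]

    def test_order_invariance(self):
        seqs = {"a": "ACGTTTACGT", "b": "ACGACGT", "c": "ACGTTACG"}
        alns = sweep_align(seqs)
        m1 = stability_filter(alns)
        m2 = stability_filter([alns[0]] + alns[:0:-1])
        assert np.array_equal(m1.keep, m2.keep)

    def test_different_taxa_rejected(self):
        a1 = CharacterMatrix(["x", "y"], ["AC", "AC"])
        a2 = CharacterMatrix(["x", "z"], ["AC", "AC"])
        with pytest.raises(ValueError):
            stability_filter([a1, a2])


class TestIndelFilter:
    def test_run_of_three_removed_run_of_two_kept(self):
        m = CharacterMatrix(["x", "y"], ["AC---GTA--C", "ACGTACGTACC"])
        out = indel_filter(m, max_gap_len=2)
        assert out.sequence("x") == "ACGTA--C"
        assert out.n_sites == 8

    def test_gapless_unchanged(self):
        m = CharacterMatrix(["x", "y"], ["ACGT", "AGGT"])
        assert indel_filter(m).sequences == m.sequences

    def test_idempotent(self, rng):
        seqs = ["".join(rng.choice(list("ACGT-"), 60)) for _ in range(4)]
        m = CharacterMatrix([f"t{i}" for i in range(4)], seqs)
        once = indel_filter(m)
        twice = indel_filter(once)
        assert once.sequences == twice.sequences

    def test_partitions_reindexed(self):
        pm = PartitionMap([PartitionEntry("g1", 0, 6), PartitionEntry("g2", 6, 11)])
        m = CharacterMatrix(["x", "y"], ["AC---GGTACG", "ACGTACGTACG"],
                            partitions=pm)
        out = indel_filter(m, 2)
        assert out.partitions.total_sites == out.n_sites
        assert [e.name for e in out.partitions] == ["g1", "g2"]


class TestConcatenate:
    def test_basic_two_genes(self):
        g = {"g1": CharacterMatrix(["a", "b"], ["ACG", "ACG"]),
             "g2": CharacterMatrix(["a", "b"], ["TTTT", "CCCC"])}
        mat, pmap = concatenate(g)
        assert mat.n_sites == 7
        assert len(pmap) == 2

    def test_trna_merge_partition_counts(self):
        # 52 genes with the 22 tRNAs merged -> 31 partitions; adding the two
        # cytochrome genes gives 33
        genes = {f"trna{i:02d}": CharacterMatrix(["a", "b"], ["AC", "GT"])
                 for i in range(22)}
        for i in range(30):
            genes[f"gene{i:02d}"] = CharacterMatrix(["a", "b"], ["ACG", "GTA"])
        assert len(genes) == 52
        _mat, pmap = concatenate(
            genes, merge_groups={"trna_concat": list(genes)[:22]})
        assert len(pmap) == 31
        genes["cytb"] = CharacterMatrix(["a", "b"], ["AAAA", "TTTT"])
        genes["co1"] = CharacterMatrix(["a", "b"], ["GGGG", "CCCC"])
        _mat, pmap = concatenate(
            genes, merge_groups={"trna_concat": list(genes)[:22]})
        assert len(pmap) == 33

    def test_missing_taxon_block_filled(self):
        g = {"g1": CharacterMatrix(["a", "b"], ["ACG", "ACG"]),
             "g2": CharacterMatrix(["a"], ["TTTT"])}
        mat, pmap = concatenate(g)
        assert mat.sequence("b") == "ACG????"
        # non-missing cell count conserved
        total_in = 6 + 4
        assert (~mat.missing_mask()).sum() == total_in

    def test_duplicate_gene_in_two_groups_rejected(self):
        g = {"g1": CharacterMatrix(["a"], ["AC"]),
             "g2": CharacterMatrix(["a"], ["AC"])}
        with pytest.raises(ValueError):
            concatenate(g, merge_groups={"x": ["g1"], "y": ["g1"]})


class TestRYRecode:
    def test_definitional_mapping(self):
        m = CharacterMatrix(["x"], ["ACGTRYN-?"], alphabet="DNA")
        assert ry_recode(m).sequence("x") == "RYRYRY???"

    def test_transitions_invisible(self):
        m = CharacterMatrix(["x", "y"], ["ACGT", "GTAC"])  # all transitions
        r = ry_recode(m)
        assert r.sequence("x") == r.sequence("y")
        assert p_distance_matrix(r)[0, 1] == 0.0

    def test_commutes_with_subsetting(self):
        from phyloframe.io_formats import subset_matrix
        m = CharacterMatrix(["a", "b", "c"], ["ACGT", "AGGT", "TTTT"])
        a = ry_recode(subset_matrix(m, ["a", "c"]))
        b = subset_matrix(ry_recode(m), ["a", "c"])
        assert a.sequences == b.sequences

    def test_non_dna_rejected(self):
        m = CharacterMatrix(["x"], ["RY"], alphabet="RY")
        with pytest.raises(Exception):
            ry_recode(m)

    def test_recoding_hides_transition_composition_bias(self):
        """Composition bias confined to transitions (A<->G exchange) rejects
        under NT coding but not after RY recoding."""
        rng = np.random.default_rng(5)
        # two taxa, same purine/pyrimidine totals, opposite A/G usage
        s1 = "".join(rng.choice(list("AACCTT"), 600))
        s2 = "".join(rng.choice(list("GGCCTT"), 600))
        m = CharacterMatrix(["x", "y"], [s1, s2])
        assert chi2_homogeneity(m).rejects()
        assert not chi2_homogeneity(ry_recode(m)).rejects()


class TestChi2:
    def test_identical_composition(self):
        m = CharacterMatrix(["x", "y"], ["ACGT" * 10, "TGCA" * 10])
        r = chi2_homogeneity(m)
        assert r.statistic == pytest.approx(0.0, abs=1e-9)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_independent_contingency(self):
        m = CharacterMatrix(["x", "y"], ["A" * 60 + "C" * 40, "T" * 30 + "C" * 70])
        r = chi2_homogeneity(m)
        table = np.array([[60, 40, 0], [0, 70, 30]])  # A, C, T counts
        stat, p, df, _ = chi2_contingency(table, correction=False)
        assert r.statistic == pytest.approx(stat)
        assert r.p_value == pytest.approx(p)
        assert r.df == df

    def test_empty_taxon_rejected(self):
        m = CharacterMatrix(["x", "y"], ["ACGT", "????"])
        with pytest.raises(ValueError):
            chi2_homogeneity(m)

    def test_type_one_error_calibrated(self):
        """Stationary data rejects at roughly the nominal 5% rate.

        A star tree with long branches makes the taxon compositions
        effectively independent multinomial draws, the regime where the
        contingency chi-square null calibration applies (trees with shallow
        cherries make the test conservative because compositions are
        phylogenetically correlated).
        """
        from phyloframe.trees import Phylotree
        star = Phylotree.from_newick(
            "(T1:50,T2:50,T3:50,T4:50,T5:50,T6:50);", rooted=True)
        sc = SimulationScenario(n_taxa=6, fixed_tree=star, root_age=50,
                                base_rate=0.05, clock="strict", seed=30)
        ch = simulate_chronogram(sc)
        rej = 0
        n_rep = 300
        for rep in range(n_rep):
            m = simulate_partition(ch, SubstitutionModel.gtr(
                base_frequencies=(0.3, 0.2, 0.2, 0.3)), 400, seed=1000 + rep)
            rej += chi2_homogeneity(m).rejects(0.05)
        rate = rej / n_rep
        band = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= band + 0.01


class TestPDistance:
    def test_examples(self):
        m = CharacterMatrix(["x", "y"], ["AAAA", "AATT"])
        assert p_distance_matrix(m)[0, 1] == 0.5
        m2 = CharacterMatrix(["x", "y"], ["ACGT", "ACGT"])
        assert p_distance_matrix(m2)[0, 1] == 0.0

    def test_matches_brute_force(self, rng):
        seqs = ["".join(rng.choice(list("ACGT?"), 40)) for _ in range(5)]
        m = CharacterMatrix([f"t{i}" for i in range(5)], seqs)
        D = p_distance_matrix(m)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                num = den = 0
                for a, b in zip(seqs[i], seqs[j]):
                    if a in "?-" or b in "?-":
                        continue
                    den += 1
                    num += a != b
                assert D[i, j] == pytest.approx(num / den)

    def test_zero_shared_sites_flagged(self):
        m = CharacterMatrix(["x", "y"], ["AC??", "??GT"])
        with pytest.warns(UserWarning):
            D = p_distance_matrix(m)
        assert np.isnan(D[0, 1])
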