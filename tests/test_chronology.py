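import itertools

import numpy as np
import pytest

from phyloframe.chronology import (Chronogram, RateEstimate, bootstrap_age_ci,
                                   clock_fit, cv_lambda, divergence_rate,
                                   fossil_cv, pl_fit)
from phyloframe.io_formats import CalibrationConstraint
from phyloframe.models import SubstitutionModel
from phyloframe.syndata import (SimulationScenario, simulate_chronogram,
                                simulate_partition)
from phyloframe.trees import Phylotree


def subs_tree(chrono, rate=None):
    """Branch lengths in substitutions/site from a dated tree."""
    t = chrono.tree.copy()
    for n in t.postorder():
        if n.parent is not None:
            r = rate if rate is not None else n.annotations["rate"]
            n.length = (n.parent.annotations["age"]
                        - n.annotations["age"]) * r
    return t


@pytest.fixture(scope="module")
def clock_truth():
    sc = SimulationScenario(n_taxa=10, clock="strict", base_rate=0.002,
                            root_age=50.0, seed=41)
    return simulate_chronogram(sc)


@pytest.fixture(scope="module")
def root_calibration(clock_truth):
    return [CalibrationConstraint("root", tuple(clock_truth.tree.taxa),
                                  "crown", "fixed", 50.0)]


class TestPLFit:
    def test_clock_data_recovered_exactly(self, clock_truth, root_calibration):
        """Noise-free clock branch lengths are penalty-free and
        likelihood-optimal at the truth for any smoothing value."""
        tree = subs_tree(clock_truth, 0.002)
        for lam in (0.1, 1.0, 100.0):
            fit = pl_fit(tree, 10000, root_calibration, lam, n_restarts=2,
                         seed=1)
            truth = clock_truth.ages()
            for clade, age in fit.ages().items():
                assert age == pytest.approx(truth[clade], abs=0.05)
            rates = [n.annotations["rate"] for n in fit.tree.postorder()
                     if "rate" in n.annotations]
            assert np.allclose(rates, 0.002, rtol=0.05)

    def test_three_taxon_grid_search_oracle(self):
        """Hand-set 3-taxon problem: the PL optimum matches a brute-force
        grid search over (inner age, rates tied to clock)."""
        nwk = "((A:0.02,B:0.02):0.03,C:0.05);"
        tree = Phylotree.from_newick(nwk)
        cal = [CalibrationConstraint("root", ("A", "B", "C"), "crown",
                                     "fixed", 10.0)]
        n_sites = 1000
        lam = 1e7  # effectively a clock: one shared rate
        fit = pl_fit(tree, n_sites, cal, lam, n_restarts=3, seed=2)
        # brute force: shared rate r and inner age a on fine grids
        obs = {"A": 0.02 * n_sites, "B": 0.02 * n_sites,
               "AB": 0.03 * n_sites, "C": 0.05 * n_sites}

        def loglik(r, a):
            mus = {"A": r * a * n_sites, "B": r * a * n_sites,
                   "AB": r * (10 - a) * n_sites, "C": r * 10 * n_sites}
            return sum(obs[k] * np.log(mus[k]) - mus[k] for k in obs)

        grid_r = np.linspace(0.001, 0.01, 800)
        grid_a = np.linspace(0.5, 9.5, 800)
        vals = [(loglik(r, a), r, a) for r in grid_r for a in grid_a]
        _best, r_star, a_star = max(vals)
        inner = fit.tree.mrca(["A", "B"])
        assert inner.annotations["age"] == pytest.approx(a_star, abs=0.02)
        assert inner.annotations["rate"] == pytest.approx(r_star, rel=0.01)

    def test_lambda_infinity_equals_clock_fit(self, clock_truth,
                                              root_calibration):
        sc = SimulationScenario(n_taxa=10, clock="autocorrelated",
                                sigma2=0.05, base_rate=0.002, root_age=50.0,
                                seed=42)
        truth = simulate_chronogram(sc)
        tree = subs_tree(truth)
        cal = [CalibrationConstraint("root", tuple(tree.taxa), "crown",
                                     "fixed", 50.0)]
        big = pl_fit(tree, 10000, cal, 1e8, n_restarts=3, seed=3)
        clk = clock_fit(tree, 10000, cal, n_restarts=3, seed=4)
        for clade, age in clk.ages().items():
            # 1e-4 of the root age: the numeric-gradient resolution of two
            # independent optimizations of the same objective
            assert big.ages()[clade] == pytest.approx(age, abs=1e-4 * 50.0)

    def test_age_monotonicity_invariant(self, clock_truth, root_calibration):
        tree = subs_tree(clock_truth, 0.002)
        fit = pl_fit(tree, 5000, root_calibration, 10.0, n_restarts=2, seed=5)
        fit.check_ages()  # raises on violation

    def test_min_constraint_respected(self, clock_truth, root_calibration):
        tree = subs_tree(clock_truth, 0.002)
        ages = clock_truth.ages()
        clade = next(k for k in ages if 2 <= len(k) <= 5)
        push = CalibrationConstraint("push", tuple(sorted(clade)), "crown",
                                     "min", ages[clade] * 1.4)
        fit = pl_fit(tree, 5000, root_calibration + [push], 1.0,
                     n_restarts=2, seed=6)
        assert fit.ages()[clade] >= ages[clade] * 1.4 - 1e-6

    def test_calibration_scaling_linearity(self, clock_truth):
        """With one fixed calibration and clock data, estimated ages scale
        linearly with the calibration age (identifiability check)."""
        tree = subs_tree(clock_truth, 0.002)
        taxa = tuple(clock_truth.tree.taxa)
        f50 = pl_fit(tree, 5000,
                     [CalibrationConstraint("r", taxa, "crown", "fixed", 50)],
                     1.0, n_restarts=2, seed=7)
        f100 = pl_fit(tree, 5000,
                      [CalibrationConstraint("r", taxa, "crown", "fixed", 100)],
                      1.0, n_restarts=2, seed=7)
        for clade, age in f50.ages().items():
            if age > 1:
                assert f100.ages()[clade] == pytest.approx(2 * age, rel=0.02)

    def test_requires_fixed_anchor(self, clock_truth):
        tree = subs_tree(clock_truth, 0.002)
        cal = [CalibrationConstraint("m", tuple(tree.taxa), "crown", "min", 5)]
        with pytest.raises(ValueError, match="fixed"):
            pl_fit(tree, 5000, cal, 1.0)

    def test_zero_length_terminal_rejected(self, clock_truth,
                                           root_calibration):
        tree = subs_tree(clock_truth, 0.002)
        tree.leaves()[0].length = 0.0
        with pytest.raises(ValueError, match="terminal"):
            pl_fit(tree, 5000, root_calibration, 1.0)

    def test_infeasible_constraints_rejected(self, clock_truth):
        tree = subs_tree(clock_truth, 0.002)
        taxa = tuple(clock_truth.tree.taxa)
        ages = clock_truth.ages()
        clade = next(k for k in ages if 2 <= len(k) <= 5)
        cal = [CalibrationConstraint("root", taxa, "crown", "fixed", 50),
               CalibrationConstraint("bad", tuple(sorted(clade)), "crown",
                                     "min", 60.0)]
        with pytest.raises(ValueError, match="[Ii]nfeasible"):
            pl_fit(tree, 5000, cal, 1.0)


class TestCrossValidation:
    def test_scores_nonnegative_and_curve_shape(self, clock_truth,
                                                root_calibration):
        tree = subs_tree(clock_truth, 0.002)
        best, curve = cv_lambda(tree, 5000, root_calibration,
                                [0.1, 10.0, 1000.0], n_restarts=1, seed=1)
        assert all(s >= 0 for _l, s in curve)
        scores = dict(curve)
        # clock data: heavy smoothing must not hurt prediction
        assert scores[1000.0] <= scores[0.1] * 1.1 + 1e-9

    def test_single_value_grid_warns(self, clock_truth, root_calibration):
        tree = subs_tree(clock_truth, 0.002)
        with pytest.warns(UserWarning):
            best, curve = cv_lambda(tree, 5000, root_calibration, [1.0],
                                    n_restarts=1, seed=2)
        assert best == 1.0


class TestFossilCV:
    def _cals(self, truth):
        ages = truth.ages()
        taxa = tuple(truth.tree.taxa)
        cals = [CalibrationConstraint("root", taxa, "crown", "fixed", 50.0)]
        clades = sorted((k for k in ages if 2 <= len(k) < len(taxa)), key=len)
        for i, k in enumerate(clades[:3]):
            cals.append(CalibrationConstraint(
                f"f{i}", tuple(sorted(k)), "crown", "min",
                max(ages[k] * 0.7, 0.05)))
        return cals, ages, clades

    def test_consistent_fossils_unflagged(self, clock_truth):
        tree = subs_tree(clock_truth, 0.002)
        cals, _ages, _clades = self._cals(clock_truth)
        rows = fossil_cv(tree, 5000, cals, lam=10.0, seed=1)
        flagged = [r["fossil"] for r in rows if r.get("violated")]
        assert flagged == []
        total = sum(r.get("sq_deviation", 0.0) for r in rows)
        assert rows[-1]["total_sq_deviation"] == pytest.approx(total)

    def test_inflated_fossil_flagged(self, clock_truth):
        tree = subs_tree(clock_truth, 0.002)
        cals, ages, clades = self._cals(clock_truth)
        bad_age = min(ages[clades[0]] * 2.5, 45.0)
        bad = CalibrationConstraint("bad", tuple(sorted(clades[0])), "crown",
                                    "min", bad_age)
        rows = fossil_cv(tree, 5000, cals + [bad], lam=10.0, seed=2)
        flagged = [r["fossil"] for r in rows if r.get("violated")]
        assert flagged == ["bad"]

    def test_needs_two_calibrations(self, clock_truth, root_calibration):
        tree = subs_tree(clock_truth, 0.002)
        with pytest.raises(ValueError):
            fossil_cv(tree, 5000, root_calibration)


class TestBootstrapCI:
    def test_intervals_cover_point_estimate(self, clock_truth,
                                            root_calibration):
        gm = simulate_partition(clock_truth, SubstitutionModel.jc(), 1500,
                                seed=52)
        tree = subs_tree(clock_truth, 0.002)
        ci = bootstrap_age_ci(gm, tree, SubstitutionModel.jc(),
                              root_calibration, lam=10.0, n_boot=12, seed=3)
        fit = pl_fit(tree, 1500, root_calibration, 10.0, n_restarts=2, seed=4)
        covered = 0
        checked = 0
        for clade, (lo, hi) in ci.items():
            assert lo <= hi
            if len(clade) > 1 and clade in fit.ages():
                checked += 1
                covered += lo - 1.0 <= fit.ages()[clade] <= hi + 1.0
        assert checked > 0 and covered >= 0.7 * checked


class TestDivergenceRate:
    def test_arithmetic_definition(self, clock_truth):
        """Corrected distance 0.0062 at a 2-MY-old node gives 0.31 %/MY."""
        taxa = clock_truth.tree.taxa[:2]
        pair = clock_truth.tree.mrca(taxa)
        from phyloframe.trees import Node
        root = Node()
        root.annotations["age"] = 2.0
        for t in taxa:
            lf = root.add_child(Node(t))
            lf.annotations["age"] = 0.0
        mini = Chronogram(Phylotree(root))
        D = np.array([[0.0, 0.0062], [0.0062, 0.0]])
        est = divergence_rate(D, list(taxa), mini, taxa)
        assert est.rate == pytest.approx(0.31)

    def test_zero_distance_zero_rate(self, clock_truth):
        taxa = list(clock_truth.tree.taxa)
        D = np.zeros((len(taxa), len(taxa)))
        est = divergence_rate(D, taxa, clock_truth, taxa)
        assert est.rate == 0.0

    def test_per_lineage_flag_halves(self, clock_truth):
        taxa = list(clock_truth.tree.taxa)
        rng = np.random.default_rng(1)
        D = np.abs(rng.normal(0.05, 0.01, (len(taxa), len(taxa))))
        D = (D + D.T) / 2
        a = divergence_rate(D, taxa, clock_truth, taxa)
        b = divergence_rate(D, taxa, clock_truth, taxa, per_lineage=True)
        assert b.rate == pytest.approx(a.rate / 2)

    def test_ci_must_contain_rate(self):
        with pytest.raises(ValueError):
            RateEstimate("x", "g", 1.0, (1.5, 2.0))
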