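"""Penalized-likelihood divergence dating with fossil calibration.

Node ages are estimated on a fixed topology with ML branch lengths by
maximizing a continuous-Poisson substitution likelihood minus lambda times a
roughness penalty on rate changes between adjacent branches (Sanderson's
penalized likelihood).  The smoothing parameter is chosen by
leave-one-terminal-out cross-validation; fossil calibrations enter as fixed
or minimum node ages; confidence intervals come from branch-length
bootstrap profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .io_formats import CalibrationConstraint, CharacterMatrix
from .trees import Node, Phylotree, leaf_set

__all__ = [
    "Chronogram", "RateEstimate", "pl_fit", "cv_lambda", "fossil_cv",
    "bootstrap_age_ci", "divergence_rate", "default_lambda_grid", "clock_fit",
]


@dataclass
class Chronogram:
    """A dated tree: node ages in MY and per-branch absolute rates.

    Ages live in ``node.annotations['age']`` (tips 0), the rate of the
    branch subtending a node in ``node.annotations['rate']``
    (substitutions/site/MY).
    """

    tree: Phylotree
    smoothing: float = 0.0
    calibrations: list[CalibrationConstraint] = field(default_factory=list)

    def __post_init__(self):
        for n in self.tree.postorder():
            if "age" not in n.annotations:
                raise ValueError("every node needs an 'age' annotation")
        self.check_ages()

    def check_ages(self) -> None:
        for n in self.tree.postorder():
            for c in n.children:
                if c.annotations["age"] > n.annotations["age"] + 1e-9:
                    raise ValueError("child age exceeds parent age")

    @property
    def root_age(self) -> float:
        return self.tree.root.annotations["age"]

    def ages(self) -> dict[frozenset, float]:
        """Node ages keyed by the clade (leaf set) below each node."""
        return {frozenset(leaf_set(n)): n.annotations["age"]
                for n in self.tree.postorder()}

    def age_of_mrca(self, taxa) -> float:
        return self.tree.mrca(taxa).annotations["age"]

    def branch_durations(self) -> dict[Node, float]:
        return {n: n.parent.annotations["age"] - n.annotations["age"]
                for n in self.tree.postorder() if n.parent is not None}

    def to_ultrametric_lengths(self) -> Phylotree:
        """Copy with branch lengths set to time durations (MY)."""
        t = self.tree.copy()
        for n in t.postorder():
            if n.parent is not None:
                n.length = n.parent.annotations["age"] - n.annotations["age"]
        return t


@dataclass(frozen=True)
class RateEstimate:
    """A %/MY divergence-rate estimate with a 95% CI."""
    clade: str
    gene: str
    rate: float          # percent divergence per MY (pairwise convention)
    ci: tuple[float, float]
    n_pairs: int = 0

    def __post_init__(self):
        if not (self.ci[0] <= self.rate <= self.ci[1]):
            raise ValueError("rate must lie inside its CI")


# ============================================================== PL machinery

def _calibration_node(tree: Phylotree, c: CalibrationConstraint) -> Node:
    """Node a calibration applies to: the MRCA for a crown calibration, the
    MRCA's parent for a stem calibration."""
    m = tree.mrca(c.mrca_taxa)
    if c.attachment == "stem":
        if m.parent is None:
            return m  # stem of the whole ingroup: the root itself
        return m.parent
    if m.is_leaf:
        raise ValueError(f"calibration {c.name}: crown node is a tip")
    return m


class _PLProblem:
    """Penalized-likelihood dating on a fixed rooted topology.

    Node ages are parameterized as root age times nested proportions
    (sigmoid-transformed), which keeps every child younger than its parent
    by construction; static lower bounds propagate fixed/minimum
    calibrations so the feasible region is respected during optimization.
    Branch rates are log-parameterized.
    """

    def __init__(self, tree: Phylotree, n_sites: int,
                 calibrations: list[CalibrationConstraint], lam: float):
        self.tree = tree.copy()
        if not self.tree.rooted and len(self.tree.root.children) > 2:
            raise ValueError("penalized likelihood needs a rooted tree")
        self.n_sites = n_sites
        self.lam = lam
        self.calibrations = list(calibrations)
        self.nodes = list(self.tree.preorder())           # root first
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = np.array([self.index[id(n.parent)] if n.parent is not None
                                else -1 for n in self.nodes])
        self.is_leaf = np.array([n.is_leaf for n in self.nodes])
        self.obs = np.array([(n.length or 0.0) * n_sites if n.parent is not None
                             else 0.0 for n in self.nodes])
        for n in self.nodes:
            if n.is_leaf and n.parent is not None and (n.length or 0.0) == 0.0:
                raise ValueError(
                    f"zero-length terminal branch at {n.label}: prune such "
                    f"tips before dating")
        # attach calibrations
        self.fixed = {}
        self.minage = {}
        for c in self.calibrations:
            i = self.index[id(_calibration_node(self.tree, c))]
            if c.kind == "fixed":
                if i in self.fixed and abs(self.fixed[i] - c.age) > 1e-9:
                    raise ValueError(f"conflicting fixed ages at node {i}")
                self.fixed[i] = c.age
            else:
                self.minage[i] = max(self.minage.get(i, 0.0), c.age)
        if not self.fixed:
            raise ValueError("at least one fixed calibration is required to "
                             "anchor absolute ages")
        # static lower bounds, computed leaf->root
        self.lb = np.zeros(len(self.nodes))
        for i in range(len(self.nodes) - 1, -1, -1):
            lo = max(self.fixed.get(i, 0.0), self.minage.get(i, 0.0))
            for j, p in enumerate(self.parent):
                if p == i:
                    lo = max(lo, self.lb[j])
            self.lb[i] = lo
        for i, a in self.fixed.items():
            if a < self.lb[i] - 1e-9:
                raise ValueError("infeasible calibrations: a fixed age lies "
                                 "below a minimum age in its subtree")
        # free internal (non-root, non-fixed) nodes get a proportion param
        self.free_internal = [i for i in range(1, len(self.nodes))
                              if not self.is_leaf[i] and i not in self.fixed]
        self.root_free = 0 not in self.fixed
        self.branch_ix = np.where(self.parent >= 0)[0]
        self.n_age_params = len(self.free_internal) + int(self.root_free)
        self.n_params = self.n_age_params + len(self.branch_ix)
        # under a reversible model only the SUM of the two root-adjacent
        # branch lengths is identifiable (the ML split is arbitrary), so
        # their substitution counts are pooled into one Poisson observation
        root_kids = np.where(self.parent == 0)[0]
        self.basal_pair = tuple(root_kids) if len(root_kids) == 2 else ()

    # ---------------------------------------------------------------- ages
    def ages_from(self, x: np.ndarray) -> np.ndarray:
        ages = np.zeros(len(self.nodes))
        k = 0
        if self.root_free:
            ages[0] = self.lb[0] + np.exp(np.clip(x[0], -30, 30))
            k = 1
        else:
            ages[0] = self.fixed[0]
        free_pos = {i: k + j for j, i in enumerate(self.free_internal)}
        for i in range(1, len(self.nodes)):
            if self.is_leaf[i]:
                continue
            if i in self.fixed:
                ages[i] = self.fixed[i]
                continue
            q = 1.0 / (1.0 + np.exp(-np.clip(x[free_pos[i]], -30, 30)))
            pa = ages[self.parent[i]]
            ages[i] = self.lb[i] + (pa - self.lb[i]) * q
        return ages

    def rates_from(self, x: np.ndarray) -> np.ndarray:
        return np.exp(np.clip(x[self.n_age_params:], -30, 10))

    # ----------------------------------------------------------- objective
    def neg_objective(self, x: np.ndarray) -> float:
        ages = self.ages_from(x)
        rates = self.rates_from(x)
        t = ages[self.parent[self.branch_ix]] - ages[self.branch_ix]
        t = np.maximum(t, 1e-8)
        mu = rates * t * self.n_sites
        obs = self.obs[self.branch_ix]
        if self.basal_pair:
            pos = {j: k for k, j in enumerate(self.branch_ix)}
            a, b = (pos[j] for j in self.basal_pair)
            mu_pool = mu[a] + mu[b]
            obs_pool = obs[a] + obs[b]
            keep = np.ones(len(mu), dtype=bool)
            keep[[a, b]] = False
            loglik = float(obs[keep] @ np.log(mu[keep]) - mu[keep].sum()
                           + obs_pool * np.log(mu_pool) - mu_pool)
        else:
            loglik = float(obs @ np.log(mu) - mu.sum())
        # roughness: squared rate differences on parent-child branch pairs,
        # plus the variance of the root-adjacent rates; rates are scaled by
        # their mean so the penalty (and lambda) is dimensionless and the
        # lambda -> infinity limit is the strict clock at any rate scale
        rate_of = np.full(len(self.nodes), np.nan)
        rate_of[self.branch_ix] = rates / max(rates.mean(), 1e-300)
        pen = 0.0
        root_rates = []
        for j in self.branch_ix:
            p = self.parent[j]
            if p == 0:
                root_rates.append(rate_of[j])
            else:
                pen += (rate_of[p] - rate_of[j]) ** 2
        rr = np.asarray(root_rates)
        if len(rr) > 1:
            pen += rr.var()
        return -(loglik - self.lam * pen)

    def _molecular_depths(self) -> np.ndarray:
        """Mean node-to-tip path length (subs/site) below each node."""
        depth = np.zeros(len(self.nodes))
        count = np.zeros(len(self.nodes))
        for i in range(len(self.nodes) - 1, 0, -1):
            n = self.nodes[i]
            if n.is_leaf:
                count[i] = 1
            p = self.parent[i]
            depth[p] += depth[i] + count[i] * self.obs[i] / self.n_sites
            count[p] += count[i]
        with np.errstate(invalid="ignore"):
            return np.where(count > 0, depth / np.maximum(count, 1), 0.0)

    def initial(self, rng, jitter: float = 0.0) -> np.ndarray:
        """Start from clock-scaled ages implied by the branch lengths.

        Node ages are initialized proportional to mean molecular depth,
        scaled so the anchoring fixed calibration holds; rates start at the
        implied clock rate.  A generic start (all proportions 0.5) leaves
        deeply nested sigmoids nearly saturated and stalls the optimizer.
        """
        x = np.zeros(self.n_params)
        anchor_i, anchor_age = next(iter(self.fixed.items()))
        d = self._molecular_depths()
        scale = anchor_age / max(d[anchor_i], 1e-12)
        ages0 = np.maximum(d * scale, 0.0)
        ages0[0] = max(ages0[0], self.lb[0] + 1e-3)
        # clamp into the feasible band top-down, then convert to parameters
        for i in range(1, len(self.nodes)):
            if self.is_leaf[i]:
                ages0[i] = 0.0
                continue
            if i in self.fixed:
                ages0[i] = self.fixed[i]
                continue
            hi = ages0[self.parent[i]]
            lo = self.lb[i]
            ages0[i] = float(np.clip(ages0[i], lo + 0.02 * max(hi - lo, 1e-6),
                                     hi - 0.02 * max(hi - lo, 1e-6)))
        k = 0
        if self.root_free:
            x[0] = np.log(max(ages0[0] - self.lb[0], 1e-6))
            k = 1
        for j, i in enumerate(self.free_internal):
            pa = ages0[self.parent[i]] if self.parent[i] not in self.fixed \
                else self.fixed[self.parent[i]]
            lo = self.lb[i]
            q = np.clip((ages0[i] - lo) / max(pa - lo, 1e-9), 0.02, 0.98)
            x[k + j] = np.log(q / (1 - q))
        r0 = max(1.0 / max(scale, 1e-12), 1e-10)
        x[self.n_age_params:] = np.log(r0)
        if jitter > 0:
            x += rng.normal(0.0, jitter, size=len(x))
        return x

    def solve_clock(self, n_restarts: int = 3, seed: int = 0) -> np.ndarray:
        """Single-rate (strict clock) solution, also used as a warm start."""
        nap, nb = self.n_age_params, len(self.branch_ix)

        def neg(z):
            return self.neg_objective(
                np.concatenate([z[:nap], np.full(nb, z[-1])]))

        rng = np.random.default_rng(seed)
        best_z, best_f = None, np.inf
        for r in range(n_restarts):
            x0 = self.initial(rng, jitter=0.0 if r == 0 else 0.8)
            z0 = np.concatenate([x0[:nap], [x0[-1]]])
            res = minimize(neg, z0, method="L-BFGS-B",
                           options={"maxiter": 5000, "ftol": 1e-16,
                                    "gtol": 1e-12})
            if res.fun < best_f:
                best_z, best_f = res.x, float(res.fun)
        return np.concatenate([best_z[:nap], np.full(nb, best_z[-1])])

    def solve(self, n_restarts: int = 5, seed: int = 0) -> tuple[np.ndarray, float]:
        """Clock warm start, then full rate-per-branch optimization with
        jittered restarts."""
        rng = np.random.default_rng(seed)
        x_clock = self.solve_clock(n_restarts=min(n_restarts, 3), seed=seed)
        best_x, best_f = x_clock, self.neg_objective(x_clock)
        for r in range(n_restarts):
            x0 = x_clock if r == 0 else \
                x_clock + rng.normal(0.0, 0.3, size=len(x_clock))
            res = minimize(self.neg_objective, x0, method="L-BFGS-B",
                           options={"maxiter": 5000, "ftol": 1e-16,
                                    "gtol": 1e-12})
            if res.fun < best_f:
                best_x, best_f = res.x, float(res.fun)
        return best_x, best_f

    def chronogram(self, x: np.ndarray) -> Chronogram:
        ages = self.ages_from(x)
        rates = self.rates_from(x)
        rate_of = {}
        for k, j in enumerate(self.branch_ix):
            rate_of[j] = rates[k]
        t = self.tree
        for i, n in enumerate(self.nodes):
            n.annotations["age"] = float(ages[i])
            if i in rate_of:
                n.annotations["rate"] = float(rate_of[i])
        return Chronogram(t, smoothing=self.lam, calibrations=self.calibrations)


def pl_fit(tree: Phylotree, n_sites: int,
           calibrations: list[CalibrationConstraint], lam: float = 1.0,
           n_restarts: int = 5, seed: int = 0) -> Chronogram:
    """Penalized-likelihood dating (Sanderson) of a tree with ML branch
    lengths.

    Maximizes a continuous-Poisson likelihood of the observed branch
    substitutions (branch length x n_sites) over node ages and per-branch
    rates, minus ``lam`` times a roughness penalty on rate changes between
    adjacent branches; calibrations pin (fixed) or bound (min) node ages.
    """
    if lam < 0:
        raise ValueError("smoothing parameter must be >= 0")
    prob = _PLProblem(tree, n_sites, calibrations, lam)
    x, _f = prob.solve(n_restarts=n_restarts, seed=seed)
    chrono = prob.chronogram(x)
    chrono.check_ages()
    return chrono


def clock_fit(tree: Phylotree, n_sites: int,
              calibrations: list[CalibrationConstraint],
              n_restarts: int = 5, seed: int = 0) -> Chronogram:
    """Single-rate (strict clock) Poisson fit: the lam -> infinity limit of
    penalized likelihood."""
    prob = _PLProblem(tree, n_sites, calibrations, 0.0)
    x = prob.solve_clock(n_restarts=n_restarts, seed=seed)
    return prob.chronogram(x)


# ======================================================== cross-validation

def default_lambda_grid(n: int = 21, lo: float = 0.1, hi: float = 10000.0
                        ) -> np.ndarray:
    """The standard smoothing sweep: ``n`` log-spaced values in [lo, hi]."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def cv_lambda(tree: Phylotree, n_sites: int,
              calibrations: list[CalibrationConstraint],
              lambda_grid=None, n_restarts: int = 2, seed: int = 0
              ) -> tuple[float, list[tuple[float, float]]]:
    """Leave-one-terminal-out cross-validation of the smoothing parameter.

    Each terminal branch is pruned in turn; the dating model fitted on the
    remainder predicts the pruned branch's expected substitutions (parent
    rate x terminal duration); the chi-square-type prediction error
    sum((obs - pred)^2 / max(pred, 1)) is accumulated per lambda and the
    minimizer returned with the full score curve."""
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    if np.any(grid <= 0):
        raise ValueError("lambda grid values must be > 0")
    if len(grid) == 1:
        warnings.warn("single-value lambda grid: nothing to cross-validate")
    leaves = [lf for lf in tree.leaves()]
    curve = []
    for li, lam in enumerate(grid):
        score = 0.0
        for lf in leaves:
            pruned = tree.prune_taxa([lf.label])
            if pruned.n_leaves < 3:
                continue
            try:
                fit = pl_fit(pruned, n_sites, _usable(calibrations, pruned),
                             lam, n_restarts=n_restarts,
                             seed=seed + 31 * li)
            except ValueError:
                continue
            obs = (lf.length or 0.0) * n_sites
            # predict with the sibling-side parent rate and the fitted age
            # of the node the tip attached to
            attach = _attachment_age_and_rate(fit, tree, lf)
            if attach is None:
                continue
            age, rate = attach
            pred = max(rate * age * n_sites, 1e-8)
            score += (obs - pred) ** 2 / max(pred, 1.0)
        curve.append((float(lam), float(score)))
    best = min(curve, key=lambda t: t[1])[0]
    return best, curve


def _usable(calibrations, pruned_tree):
    """Restrict calibrations to the taxa of a pruned tree (a calibration
    keeps pointing at the same node as long as enough taxa survive)."""
    taxa = set(pruned_tree.taxa)
    out = []
    for c in calibrations:
        kept = tuple(t for t in c.mrca_taxa if t in taxa)
        need = 2 if c.attachment == "crown" else 1
        if len(kept) >= need:
            out.append(CalibrationConstraint(c.name, kept, c.attachment,
                                             c.kind, c.age))
    if not any(c.kind == "fixed" for c in out):
        raise ValueError("pruning removed the anchoring calibration")
    return out


def _attachment_age_and_rate(fit: Chronogram, full_tree: Phylotree, leaf
                             ) -> tuple[float, float] | None:
    """Age and local rate of the node where ``leaf`` attached, located in
    the pruned fit by the leaf's sister group."""
    sibs = set()
    p = leaf.parent
    if p is None:
        return None
    for c in p.children:
        if c is not leaf:
            sibs |= set(leaf_set(c))
    sibs &= set(fit.tree.taxa)
    if not sibs:
        return None
    if len(sibs) == 1:
        node = fit.tree.find_leaf(next(iter(sibs)))
    else:
        node = fit.tree.mrca(sibs)
    # the tip attached somewhere on the reduced edge above this node; use
    # the edge midpoint as the attachment age and the edge's fitted rate
    age_child = node.annotations["age"]
    age_parent = (node.parent.annotations["age"] if node.parent is not None
                  else fit.root_age)
    rate = node.annotations.get("rate")
    if rate is None:  # attached at the root: average the root-adjacent rates
        rates = [c.annotations["rate"] for c in fit.tree.root.children
                 if "rate" in c.annotations]
        rate = float(np.mean(rates))
    return float((age_child + age_parent) / 2.0), float(rate)


def fossil_cv(tree: Phylotree, n_sites: int,
              calibrations: list[CalibrationConstraint], lam: float = 1.0,
              n_restarts: int = 2, seed: int = 0) -> list[dict]:
    """Fossil cross-validation: refit without each calibration in turn and
    compare the freed node's inferred age with the fossil's age.

    Returns one row per removable fossil: inferred age, deviation
    (inferred - fossil), squared deviation, and a violation flag for
    minimum-age fossils whose constraint the remaining evidence breaks."""
    if len(calibrations) < 2:
        raise ValueError("fossil cross-validation needs >= 2 calibrations")
    rows = []
    for c in calibrations:
        rest = [d for d in calibrations if d is not c]
        if not any(d.kind == "fixed" for d in rest):
            rows.append({"fossil": c.name, "skipped": True,
                         "reason": "removal leaves no fixed anchor"})
            continue
        try:
            fit = pl_fit(tree, n_sites, rest, lam, n_restarts=n_restarts,
                         seed=seed)
        except ValueError as err:
            rows.append({"fossil": c.name, "skipped": True,
                         "reason": str(err)})
            continue
        node = _calibration_node(fit.tree, c)
        inferred = float(node.annotations["age"])
        dev = inferred - c.age
        # 5% / 0.2 MY slack absorbs optimizer noise in the refits
        slack = max(0.05 * c.age, 0.2)
        violated = (c.kind == "min" and inferred < c.age - slack) or \
                   (c.kind == "fixed" and abs(dev) > 0.25 * c.age)
        rows.append({"fossil": c.name, "skipped": False, "age": c.age,
                     "inferred": inferred, "deviation": dev,
                     "sq_deviation": dev * dev, "violated": bool(violated)})
    total = sum(r.get("sq_deviation", 0.0) for r in rows)
    for r in rows:
        r["total_sq_deviation"] = total
    return rows


# ================================================================ bootstrap

def bootstrap_age_ci(matrix: CharacterMatrix, topology: Phylotree, model,
                     calibrations: list[CalibrationConstraint],
                     lam: float = 1.0, n_boot: int = 100, seed: int = 0,
                     n_restarts: int = 2) -> dict[frozenset, tuple[float, float]]:
    """Bootstrap profiles of node ages.

    Columns are resampled (within partitions when a partition map exists),
    branch lengths re-optimized by ML on the fixed topology, the dating
    model refitted, and per-node 95 percent percentile intervals returned
    keyed by clade."""
    from .likelihood import optimize_branch_lengths
    if n_boot < 2:
        raise ValueError("need n_boot >= 2")
    rng = np.random.default_rng(seed)
    ages: dict[frozenset, list[float]] = {}
    done = 0
    while done < n_boot:
        cols = _stratified_columns(matrix, rng)
        rep = matrix.select_columns(cols)
        if rep.missing_mask().all():
            continue
        nvar = False
        for i in range(1, rep.n_taxa):
            if (rep.data[i] != rep.data[0]).any():
                nvar = True
                break
        if not nvar:
            warnings.warn("bootstrap replicate with no variable sites skipped")
            done += 1
            continue
        bl = optimize_branch_lengths(topology, model, rep, tol=1e-4,
                                     max_sweeps=3)
        rooted = bl if bl.rooted else _root_for_dating(bl, calibrations)
        fit = pl_fit(rooted, rep.n_sites, calibrations, lam,
                     n_restarts=n_restarts, seed=int(rng.integers(2**31)))
        for clade, age in fit.ages().items():
            ages.setdefault(clade, []).append(age)
        done += 1
    return {c: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for c, v in ages.items() if len(v) >= 2}


def _stratified_columns(matrix: CharacterMatrix, rng) -> np.ndarray:
    if matrix.partitions is None:
        return rng.integers(matrix.n_sites, size=matrix.n_sites)
    cols = []
    for e in matrix.partitions:
        cols.append(rng.integers(e.start, e.end, size=e.end - e.start))
    return np.concatenate(cols)


def _root_for_dating(tree: Phylotree, calibrations) -> Phylotree:
    """Root an unrooted ML tree on the edge above the anchoring clade."""
    fixed = [c for c in calibrations if c.kind == "fixed"]
    taxa = set(fixed[0].mrca_taxa) if fixed else set(tree.taxa[:1])
    for n in tree.postorder():
        if n.parent is not None and set(leaf_set(n)) == taxa:
            return tree.reroot_on_edge(n)
    m = tree.mrca(taxa)
    if m.parent is None:
        m = tree.root.children[0]
    return tree.reroot_on_edge(m)


# ============================================================ rate per MY

def divergence_rate(distances: np.ndarray, taxa: list[str],
                    chronogram: Chronogram, clade_taxa, gene: str = "",
                    age_ci: dict[frozenset, tuple[float, float]] | None = None,
                    distance_se: np.ndarray | None = None,
                    per_lineage: bool = False) -> RateEstimate:
    """Percent sequence divergence per MY within a clade.

    For every taxon pair in the clade with a dated MRCA, the model-corrected
    pairwise distance (in percent) is divided by the MRCA age (pairwise
    convention; ``per_lineage`` halves it).  Because pair rates share tree
    paths and are strongly correlated, the CI comes from a taxon-level
    bootstrap (resampling clade members, not pairs), widened by the
    distance-estimation error (``distance_se``, treated as fully shared
    across pairs — conservative) and by calibration age uncertainty when
    supplied, both via the delta rule."""
    clade_taxa = [t for t in clade_taxa]
    ix = {t: i for i, t in enumerate(taxa)}
    pair_rho: dict[tuple[int, int], float] = {}
    var_extra = []
    for i in range(len(clade_taxa)):
        for j in range(i + 1, len(clade_taxa)):
            a, b = clade_taxa[i], clade_taxa[j]
            try:
                node = chronogram.tree.mrca([a, b])
            except KeyError:
                continue
            age = node.annotations["age"]
            if age <= 0:
                continue
            d = distances[ix[a], ix[b]]
            if not np.isfinite(d):
                continue
            rho = 100.0 * d / age
            if per_lineage:
                rho /= 2.0
            pair_rho[(i, j)] = rho
            if distance_se is not None:
                se_d = distance_se[ix[a], ix[b]]
                if np.isfinite(se_d):
                    scale = (100.0 / age) * (0.5 if per_lineage else 1.0)
                    var_extra.append((scale * se_d) ** 2)
            if age_ci:
                key = frozenset(leaf_set(node))
                if key in age_ci:
                    lo, hi = age_ci[key]
                    sd_t = (hi - lo) / 3.92
                    var_extra.append((rho / age) ** 2 * sd_t ** 2)
    if not pair_rho:
        raise ValueError("no datable pairs in the clade")
    rate = float(np.mean(list(pair_rho.values())))
    rng = np.random.default_rng(0)
    boots = []
    m = len(clade_taxa)
    for _ in range(400):
        pick = rng.integers(m, size=m)
        vals = [pair_rho[(min(a, b), max(a, b))]
                for a in pick for b in pick
                if a != b and (min(a, b), max(a, b)) in pair_rho]
        if vals:
            boots.append(np.mean(vals))
    if len(boots) > 10:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = rate
    if var_extra:
        pad = 1.96 * np.sqrt(np.mean(var_extra))
        lo, hi = lo - pad, hi + pad
    ci = (float(max(min(lo, rate), 0.0)), float(max(hi, rate)))
    return RateEstimate(clade=",".join(sorted(clade_taxa)[:3]) + "...",
                        gene=gene, rate=rate, ci=ci, n_pairs=len(pair_rho))
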