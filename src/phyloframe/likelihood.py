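"""Maximum-likelihood phylogenetics on time-reversible models.

Felsenstein pruning with discrete-gamma + invariant-sites rate mixtures,
coordinate-wise branch-length optimization, NNI/SPR hill-climbing tree
search, model selection over a JC..GTR ladder, the molecular-clock
likelihood-ratio test, and distance-regression per-gene relative rates.

Site patterns are compressed before pruning; per-site log-likelihoods are
expanded back to site order for the topology tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import chi2
from skbio import DistanceMatrix
from skbio.tree import nj

from .io_formats import CharacterMatrix
from .models import SubstitutionModel
from .parsimony import _neighbor_move, _postorder_nodes
from .supermatrix import p_distance_matrix
from .trees import Node, Phylotree, random_topology

__all__ = [
    "site_log_likelihoods", "log_likelihood", "optimize_branch_lengths",
    "ml_search", "bootstrap_ml", "model_select", "clock_lrt", "per_gene_rates",
    "nj_tree", "ml_pairwise_distance", "jc_distance", "MODEL_LADDER",
]

MIN_BL, MAX_BL = 1e-9, 20.0


# ================================================================ patterns

def _pattern_partials(matrix: CharacterMatrix):
    """Compress columns to unique patterns.

    Returns (leaf_partials (n_taxa, n_patterns, k), counts, inverse)."""
    cached = getattr(matrix, "_pattern_cache", None)
    if cached is not None:
        return cached
    enc = matrix.encoded()  # bitmasks, 0 = unobserved
    k = 4 if matrix.alphabet == "DNA" else 2
    uniq, inv, counts = np.unique(enc.T, axis=0, return_inverse=True,
                                  return_counts=True)
    bits = (uniq[:, :, None] >> np.arange(k)) & 1  # (npat, ntaxa, k)
    part = bits.astype(float)
    missing = uniq == 0
    part[missing] = 1.0
    out = np.ascontiguousarray(part.transpose(1, 0, 2)), counts, inv
    matrix._pattern_cache = out
    return out


def _collect_branches(tree: Phylotree):
    nodes = [n for n in tree.postorder()]
    lengths = np.array([n.length if n.parent is not None else 0.0
                        for n in nodes], float)
    if np.any(lengths < 0):
        raise ValueError("negative branch length")
    return nodes, lengths


def _pattern_lnl(tree: Phylotree, model: SubstitutionModel, leaf_part,
                 taxon_index) -> np.ndarray:
    """Per-pattern log-likelihood via scaled pruning."""
    nodes, lengths = _collect_branches(tree)
    rates, cat_w = model.category_rates()
    pi = np.asarray(model.base_frequencies)
    npat = leaf_part.shape[1]
    per_cat = np.empty((len(rates), npat))
    node_ix = {id(n): i for i, n in enumerate(nodes)}
    for ci, r in enumerate(rates):
        P = model.transition_matrices(lengths * r)  # (n_nodes, k, k)
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(npat)
        for n in nodes:
            if n.is_leaf:
                partial[id(n)] = leaf_part[taxon_index[n.label]]
            else:
                acc = None
                for c in n.children:
                    cp = partial.pop(id(c))
                    contrib = cp @ P[node_ix[id(c)]].T
                    acc = contrib if acc is None else acc * contrib
                m = acc.max(axis=1)
                m = np.where(m > 0, m, 1.0)
                logscale += np.log(m)
                partial[id(n)] = acc / m[:, None]
        lik = partial[id(nodes[-1])] @ pi
        per_cat[ci] = np.log(np.maximum(lik, 1e-300)) + logscale
    return logsumexp(per_cat, axis=0, b=cat_w[:, None])


def site_log_likelihoods(tree: Phylotree, model: SubstitutionModel,
                         matrix: CharacterMatrix) -> np.ndarray:
    """Per-site log-likelihoods (one row of a site-likelihood table)."""
    if matrix.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    leaf_part, _counts, inv = _pattern_partials(matrix)
    idx = {t: i for i, t in enumerate(matrix.taxa)}
    lnl = _pattern_lnl(tree, model, leaf_part, idx)
    return lnl[inv]


def log_likelihood(tree: Phylotree, model: SubstitutionModel,
                   matrix: CharacterMatrix) -> float:
    leaf_part, counts, _inv = _pattern_partials(matrix)
    idx = {t: i for i, t in enumerate(matrix.taxa)}
    return float(_pattern_lnl(tree, model, leaf_part, idx) @ counts)


# ======================================================== branch lengths

def optimize_branch_lengths(tree: Phylotree, model: SubstitutionModel,
                            matrix: CharacterMatrix, tol: float = 1e-6,
                            max_sweeps: int = 20) -> Phylotree:
    """Coordinate-wise (Brent) optimization of each branch length, iterated
    to convergence of the total log-likelihood."""
    t = tree.copy()
    for n in t.postorder():
        # lengths may arrive unset or in time units; a near-saturated start
        # leaves the coordinate descent in a flat region, so restart small
        if n.parent is not None and (n.length is None or n.length > 2.0):
            n.length = 0.1
    leaf_part, counts, _inv = _pattern_partials(matrix)
    idx = {ta: i for i, ta in enumerate(matrix.taxa)}

    def total(tr):
        return float(_pattern_lnl(tr, model, leaf_part, idx) @ counts)

    prev = total(t)
    converged = False
    for _sweep in range(max_sweeps):
        for n in t.postorder():
            if n.parent is None:
                continue

            def neg(x, node=n):
                node.length = x
                return -total(t)

            res = minimize_scalar(neg, bounds=(MIN_BL, MAX_BL),
                                  method="bounded",
                                  options={"xatol": 1e-8})
            n.length = float(res.x)
        cur = total(t)
        if cur < prev - 1e-9:  # ascent property: should never decrease
            warnings.warn("branch-length optimization decreased lnL")
        if abs(cur - prev) < tol:
            converged = True
            prev = cur
            break
        prev = cur
    if not converged:
        t.root.annotations["bl_converged"] = False
    t.root.annotations["lnl"] = prev
    return t


# ================================================================== search

def nj_tree(matrix: CharacterMatrix, model: SubstitutionModel | None = None
            ) -> Phylotree:
    """Neighbor-joining starting tree from pairwise distances (ML distances
    under ``model`` if given, else p-distances); negative NJ branch lengths
    are clipped to zero."""
    if model is None:
        D = p_distance_matrix(matrix)
    else:
        n = matrix.n_taxa
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = ml_pairwise_distance(
                    matrix.sequences[i], matrix.sequences[j], model)
    D = np.nan_to_num(D, nan=np.nanmax(D[np.isfinite(D)]) if np.isfinite(D).any() else 1.0)
    sk = nj(DistanceMatrix((D + D.T) / 2, ids=matrix.taxa))

    def convert(sn) -> Node:
        n = Node(label=sn.name if not sn.children else None,
                 length=max(sn.length or 0.0, 0.0))
        for c in sn.children:
            n.add_child(convert(c))
        return n

    t = Phylotree(convert(sk.root()), rooted=False)
    t.root.length = None
    if len(t.root.children) == 2:
        t.unroot()
    return t


def ml_search(matrix: CharacterMatrix, model: SubstitutionModel,
              n_starts: int = 1, seed: int = 0, max_rounds: int = 20
              ) -> Phylotree:
    """Hill-climbing ML tree search (NNI/SPR moves with branch-length
    re-optimization), best of ``n_starts`` starting trees (NJ first, then
    random-addition starts)."""
    if matrix.n_taxa < 4:
        raise ValueError("ML search requires at least 4 taxa")
    rng = np.random.default_rng(seed)
    best_tree, best_lnl = None, -np.inf
    for s in range(n_starts):
        start = nj_tree(matrix) if s == 0 else random_topology(matrix.taxa, rng)
        cur = optimize_branch_lengths(start, model, matrix)
        cur_lnl = cur.root.annotations["lnl"]
        for _round in range(max_rounds):
            improved = False
            n = len(_postorder_nodes(cur))
            for i in range(n):
                for j in range(n):
                    cand = _neighbor_move(cur, i, j)
                    if cand is None:
                        continue
                    cand = optimize_branch_lengths(cand, model, matrix,
                                                   tol=1e-3, max_sweeps=1)
                    if cand.root.annotations["lnl"] > cur_lnl + 1e-6:
                        cur, cur_lnl = cand, cand.root.annotations["lnl"]
                        improved = True
            if not improved:
                break
        cur = optimize_branch_lengths(cur, model, matrix)
        cur_lnl = cur.root.annotations["lnl"]
        if cur_lnl > best_lnl:
            best_tree, best_lnl = cur, cur_lnl
    best_tree.root.annotations["lnl"] = best_lnl
    return best_tree


# ========================================================= model selection

def bootstrap_ml(matrix: CharacterMatrix, model: SubstitutionModel,
                 n_reps: int = 100, seed: int = 0, n_starts: int = 1
                 ) -> dict[frozenset, float]:
    """Nonparametric ML bootstrap: resample columns (within partitions when
    a partition map exists, preserving gene composition), re-search, and
    report split frequencies in percent."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        if matrix.partitions is not None:
            cols = np.concatenate([
                rng.integers(e.start, e.end, size=e.end - e.start)
                for e in matrix.partitions])
        else:
            cols = rng.integers(matrix.n_sites, size=matrix.n_sites)
        rep = matrix.select_columns(cols)
        t = ml_search(rep, model, n_starts=n_starts,
                      seed=int(rng.integers(2 ** 31)))
        for b in t.bipartitions():
            counts[b] = counts.get(b, 0) + 1
    return {b: 100.0 * c / n_reps for b, c in counts.items()}


#: (name, uses_freqs, n_exchange_params, builder(params, freqs) -> model)
MODEL_LADDER = ["JC", "K80", "HKY", "TIM", "GTR"]
RATE_VARIANTS = [(), ("G",), ("I",), ("G", "I")]


def _build_model(name: str, x: np.ndarray, freqs, variant) -> SubstitutionModel:
    """Assemble a model from the unconstrained parameter vector ``x``."""
    i = 0
    if name == "JC":
        exch, fr = (1.0,) * 6, (0.25,) * 4
    elif name == "K80":
        kappa = np.exp(x[i]); i += 1
        exch, fr = (1, kappa, 1, 1, kappa, 1), (0.25,) * 4
    elif name == "HKY":
        kappa = np.exp(x[i]); i += 1
        exch, fr = (1, kappa, 1, 1, kappa, 1), freqs
    elif name == "TIM":
        a, b, d = np.exp(x[i]), np.exp(x[i + 1]), np.exp(x[i + 2]); i += 3
        exch, fr = (a, b, 1, 1, d, a), freqs
    elif name == "GTR":
        r = np.exp(x[i:i + 5]); i += 5
        exch, fr = (*r, 1.0), freqs
    else:
        raise ValueError(name)
    gamma = float(np.exp(np.clip(x[i], -7, 9))) if "G" in variant else None
    if "G" in variant:
        i += 1
    pinv = 1 / (1 + np.exp(-x[i])) * 0.9 if "I" in variant else None
    return SubstitutionModel(name="+".join([name, *variant]),
                             exchangeabilities=tuple(np.asarray(exch, float)),
                             base_frequencies=tuple(fr),
                             gamma_shape=gamma, p_inv=pinv)


def _n_free_params(name: str, variant) -> int:
    base = {"JC": 0, "K80": 1, "HKY": 4, "TIM": 6, "GTR": 8}[name]
    return base + ("G" in variant) + ("I" in variant)


def _x0(name: str, variant) -> np.ndarray:
    n = {"JC": 0, "K80": 1, "HKY": 1, "TIM": 3, "GTR": 5}[name]
    x = [np.log(2.0)] * n if name in ("K80", "HKY") else [0.0] * n
    if "G" in variant:
        x.append(np.log(0.5))
    if "I" in variant:
        x.append(0.0)
    return np.asarray(x, float)


def _nested_parent(name: str, variant) -> tuple | None:
    i = MODEL_LADDER.index(name) if name in MODEL_LADDER else 0
    return (MODEL_LADDER[i - 1], variant) if i > 0 else None


def _warm_x0(name: str, variant, xs: dict) -> np.ndarray | None:
    """Start a fit from the fitted parameters of a nested submodel."""
    n_exch = {"JC": 0, "K80": 1, "HKY": 1, "TIM": 3, "GTR": 5}

    def exch_part(key):
        return xs[key][:n_exch[key[0]]]

    def rate_part(key):
        return xs[key][n_exch[key[0]]:]

    # exchangeability block from the previous ladder rung (same variant)
    parent = _nested_parent(name, variant)
    if parent is not None and parent in xs:
        pe = exch_part(parent)
        if name == "HKY":
            exch = pe  # same kappa layout as K80
        elif name == "TIM":
            lk = pe[0] if len(pe) else np.log(2.0)
            exch = np.array([0.0, lk, lk])
        elif name == "GTR":
            la, lb, ld = (pe if len(pe) == 3 else (0.0, np.log(2.0), np.log(2.0)))
            exch = np.array([-la, lb - la, -la, -la, ld - la])
        else:
            exch = np.zeros(n_exch[name])
        rates = rate_part(parent)
        return np.concatenate([exch, rates])
    # rate block from the same rung with a smaller variant
    if variant == ("G", "I") and (name, ("G",)) in xs:
        return np.concatenate([xs[(name, ("G",))], [0.0]])
    if variant in (("G",), ("I",)) and (name, ()) in xs:
        extra = [np.log(0.5)] if variant == ("G",) else [0.0]
        return np.concatenate([xs[(name, ())], extra])
    return None


def empirical_frequencies(matrix: CharacterMatrix) -> tuple:
    counts = np.array([(matrix.data == b).sum() for b in (b"A", b"C", b"G", b"T")],
                      float)
    counts = np.maximum(counts, 1.0)
    return tuple(counts / counts.sum())


def fit_model(matrix: CharacterMatrix, name: str, variant=(),
              tree: Phylotree | None = None, optimize_bl: bool = True,
              x0: np.ndarray | None = None
              ) -> tuple[SubstitutionModel, float, np.ndarray]:
    """Optimize one model's free parameters (empirical base frequencies) on
    a fixed topology; with ``optimize_bl`` the branch lengths are
    re-optimized under the fitted model as well.

    Returns (model, lnL, fitted parameter vector)."""
    freqs = empirical_frequencies(matrix)
    if tree is None:
        tree = nj_tree(matrix)
    if x0 is None:
        x0 = _x0(name, variant)
    t = tree
    if optimize_bl:
        t = optimize_branch_lengths(tree, _build_model(name, x0, freqs, variant),
                                    matrix, tol=1e-4, max_sweeps=3)

    def neg(x):
        try:
            m = _build_model(name, x, freqs, variant)
        except (ValueError, OverflowError):
            return 1e12
        return -log_likelihood(t, m, matrix)

    if len(x0):
        if len(x0) >= 3:  # gradient-based is far more reliable in >2 dims
            res = minimize(neg, x0, method="L-BFGS-B",
                           options={"maxiter": 500, "ftol": 1e-10})
        else:
            res = minimize(neg, x0, method="Nelder-Mead",
                           options={"xatol": 1e-3, "fatol": 1e-5,
                                    "maxiter": 300 * max(len(x0), 1)})
        x = res.x
    else:
        x = np.asarray(x0, float)
    model = _build_model(name, x, freqs, variant)
    lnl = -neg(x)
    if optimize_bl:
        t = optimize_branch_lengths(t, model, matrix, tol=1e-4, max_sweeps=3)
        lnl = float(t.root.annotations["lnl"])
    return model, lnl, x


def model_select(matrix: CharacterMatrix, criterion: str = "BIC",
                 ladder=None, variants=None) -> SubstitutionModel:
    """Pick a substitution model on a fixed NJ topology.

    The ladder is JC/K80/HKY/TIM/GTR crossed with {-, +G, +I, +G+I}
    (20 models); the winner minimizes AIC or BIC, or is chosen by
    hierarchical LRTs up the nested chain."""
    ladder = MODEL_LADDER if ladder is None else ladder
    variants = RATE_VARIANTS if variants is None else variants
    obs = np.where(matrix.missing_mask(), b"", matrix.data)
    n_var = sum(len(set(obs[:, c].tobytes().replace(b"\x00", b""))) > 1
                for c in range(matrix.n_sites))
    if n_var == 0:
        warnings.warn("no variable sites; returning JC")
        return SubstitutionModel.jc()
    tree = nj_tree(matrix)
    # branch lengths optimized once under a flexible model, then held fixed
    # across the ladder (the usual fast model-selection protocol)
    base = SubstitutionModel.hky(kappa=2.0,
                                 base_frequencies=empirical_frequencies(matrix),
                                 gamma_shape=0.5)
    tree = optimize_branch_lengths(tree, base, matrix, tol=1e-4, max_sweeps=3)
    fits = {}
    xs: dict[tuple, np.ndarray] = {}
    for variant in variants:
        for name in ladder:
            x0 = _warm_x0(name, variant, xs)
            model, lnl, x = fit_model(matrix, name, variant, tree,
                                      optimize_bl=False, x0=x0)
            # warm-started refit if a nested submodel scored higher
            sub = _nested_parent(name, variant)
            if sub in fits and lnl < fits[sub][1] - 1e-6:
                m2, l2, x2 = fit_model(matrix, name, variant, tree,
                                       optimize_bl=False)
                if l2 > lnl:
                    model, lnl, x = m2, l2, x2
            xs[(name, variant)] = x
            k = _n_free_params(name, variant)
            fits[(name, variant)] = (model, lnl, k)
    n = matrix.n_sites
    if criterion.upper() == "AIC":
        key = min(fits, key=lambda key: -2 * fits[key][1] + 2 * fits[key][2])
    elif criterion.upper() == "BIC":
        key = min(fits, key=lambda key: -2 * fits[key][1] + np.log(n) * fits[key][2])
    elif criterion.lower() == "hlrt":
        key = _hlrt(fits, ladder, variants)
    else:
        raise ValueError(f"unknown criterion {criterion}")
    return fits[key][0]


def _hlrt(fits, ladder, variants, alpha: float = 0.01):
    """Hierarchical LRTs: walk up the exchangeability ladder, then add +G,
    then +I, keeping each addition only if it significantly improves fit."""
    cur = (ladder[0], ())
    for name in ladder[1:]:
        cand = (name, cur[1])
        if cand not in fits:
            continue
        stat = 2 * (fits[cand][1] - fits[cur][1])
        df = fits[cand][2] - fits[cur][2]
        if df > 0 and chi2.sf(max(stat, 0), df) < alpha:
            cur = cand
    for add in ("G", "I"):
        variant = tuple(sorted(set(cur[1]) | {add}))
        cand = (cur[0], variant)
        if cand not in fits:
            continue
        stat = 2 * (fits[cand][1] - fits[cur][1])
        if chi2.sf(max(stat, 0), 1) < alpha:
            cur = cand
    return cur


# =============================================================== clock LRT

def _clock_lnl(tree: Phylotree, model: SubstitutionModel,
               matrix: CharacterMatrix) -> float:
    """ML under a strict clock: node heights parameterized as root height
    times nested proportions (monotonic by construction)."""
    t = tree.copy()
    if len(t.root.children) > 2:
        # root arbitrarily on the first child branch for the clock fit
        t = t.reroot_on_edge(t.root.children[0])
    internals = [n for n in t.postorder() if not n.is_leaf]
    leaf_part, counts, _ = _pattern_partials(matrix)
    idx = {ta: i for i, ta in enumerate(matrix.taxa)}

    def set_heights(x):
        root_h = np.exp(x[0])
        props = 1 / (1 + np.exp(-x[1:]))
        heights = {}
        k = 1
        for n in t.preorder():
            if n.is_leaf:
                heights[id(n)] = 0.0
            elif n is t.root:
                heights[id(n)] = root_h
            else:
                heights[id(n)] = props[k - 1] * heights[id(n.parent)]
                k += 1
        for n in t.postorder():
            if n.parent is not None:
                n.length = max(heights[id(n.parent)] - heights[id(n)], MIN_BL)

    def neg(x):
        set_heights(x)
        return -float(_pattern_lnl(t, model, leaf_part, idx) @ counts)

    x0 = np.concatenate([[np.log(0.3)], np.zeros(len(internals) - 1)])
    best = None
    for scale in (0.1, 0.3, 1.0):
        x0[0] = np.log(scale)
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-5, "fatol": 1e-7})
        res = minimize(neg, res.x, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return -float(best.fun)


def clock_lrt(matrix: CharacterMatrix, tree: Phylotree,
              model: SubstitutionModel | None = None
              ) -> tuple[float, int, float]:
    """Likelihood-ratio test of a strict molecular clock on a fixed topology.

    Returns (statistic, df, p) with df = n_taxa - 2."""
    model = model or SubstitutionModel.jc()
    t0 = tree.copy()
    for n in t0.postorder():  # lengths may arrive in time units; restart small
        if n.parent is not None and (n.length is None or n.length > 2.0):
            n.length = 0.1
    free = optimize_branch_lengths(t0, model, matrix)
    lnl_free = free.root.annotations["lnl"]
    lnl_clock = _clock_lnl(tree, model, matrix)
    stat = 2.0 * (lnl_free - lnl_clock)
    if stat < -1e-3:
        raise RuntimeError("clock fit exceeded unconstrained fit: "
                           "optimization failure")
    stat = max(stat, 0.0)
    df = matrix.n_taxa - 2
    return stat, df, float(chi2.sf(stat, df))


# ============================================================ distances

def jc_distance(p: float, k: int = 4) -> float:
    """Jukes-Cantor-corrected distance from an observed mismatch fraction."""
    a = (k - 1) / k
    if p >= a:
        return np.inf
    return -a * np.log(1 - p / a)


def ml_pairwise_distance(seq1: str, seq2: str, model: SubstitutionModel,
                         max_d: float = 20.0, with_se: bool = False):
    """ML distance between two sequences under a fixed model.

    With ``with_se`` also returns the curvature (observed-information)
    standard error of the distance."""
    m = CharacterMatrix(["a", "b"], [seq1, seq2],
                        alphabet="DNA" if model.n_states == 4 else "RY")
    leaf_part, counts, _ = _pattern_partials(m)
    idx = {"a": 0, "b": 1}
    root = Node()
    root.add_child(Node("a", 0.0))
    b = Node("b", 0.1)
    root.add_child(b)
    t = Phylotree(root)

    def neg(d):
        b.length = d
        return -float(_pattern_lnl(t, model, leaf_part, idx) @ counts)

    res = minimize_scalar(neg, bounds=(MIN_BL, max_d), method="bounded",
                          options={"xatol": 1e-10})
    d_hat = float(res.x)
    if not with_se:
        return d_hat
    h = max(1e-4, d_hat * 1e-3)
    curv = (neg(d_hat + h) - 2 * neg(d_hat) + neg(max(d_hat - h, MIN_BL))) / h ** 2
    se = 1.0 / np.sqrt(curv) if curv > 0 else np.inf
    return d_hat, float(se)


def per_gene_rates(gene_matrices: dict[str, CharacterMatrix],
                   reference_tree: Phylotree,
                   model: SubstitutionModel | None = None,
                   min_taxa: int = 4) -> dict[str, float]:
    """Relative evolutionary rate of each gene by distance regression.

    Per gene, pairwise ML distances are regressed (least squares through
    the origin) on the patristic distances of a shared reference tree;
    fitted slopes are normalized to mean 1."""
    model = model or SubstitutionModel.jc()
    ref_d = _patristic(reference_tree)
    rates = {}
    for name, m in gene_matrices.items():
        obs = ~m.missing_mask()
        present = [t for i, t in enumerate(m.taxa) if obs[i].any()]
        if len(present) < min_taxa:
            raise ValueError(f"gene {name} has fewer than {min_taxa} taxa")
        num = den = 0.0
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                a, b = present[i], present[j]
                if (a, b) not in ref_d and (b, a) not in ref_d:
                    continue
                ia, ib = m.taxa.index(a), m.taxa.index(b)
                both = obs[ia] & obs[ib]
                if both.sum() < 10:
                    continue
                sub = m.select_columns(both)
                d = ml_pairwise_distance(sub.sequence(a), sub.sequence(b), model)
                r = ref_d.get((a, b), ref_d.get((b, a)))
                if np.isfinite(d) and r > 0:
                    num += d * r
                    den += r * r
        rates[name] = num / den if den > 0 else np.nan
    vals = np.array([v for v in rates.values() if np.isfinite(v)])
    mean = vals.mean() if len(vals) else 1.0
    return {k: v / mean for k, v in rates.items()}


def _patristic(tree: Phylotree) -> dict[tuple[str, str], float]:
    leaves = tree.leaves()
    depth = {}
    for n in tree.preorder():
        depth[id(n)] = (0.0 if n.parent is None
                        else depth[id(n.parent)] + (n.length or 0.0))
    anc = {}
    for lf in leaves:
        path = set()
        a = lf
        while a is not None:
            path.add(id(a))
            a = a.parent
        anc[lf.label] = (path, lf)
    out = {}
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            a, b = leaves[i], leaves[j]
            pa = anc[a.label][0]
            n = b
            while id(n) not in pa:
                n = n.parent
            out[(a.label, b.label)] = (depth[id(a)] + depth[id(b)]
                                       - 2 * depth[id(n)])
    return out
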