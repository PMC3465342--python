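"""Fitch parsimony: scoring, heuristic search, bootstrap, strict consensus,
Bremer and compartment-partitioned Bremer supports, and Templeton tests.

Character states are bitmask-encoded so the Fitch downpass vectorizes over
sites; '?' and '-' carry no states and contribute no steps.  The heuristic
search is random-order stepwise addition followed by SPR hill-climbing,
pooling all equally parsimonious trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import wilcoxon

from .io_formats import CharacterMatrix
from .trees import (Node, Phylotree, attach_on_edge, detach, leaf_set,
                    random_topology)

__all__ = [
    "fitch_score", "site_fitch_steps", "mp_search", "ParsimonyResult",
    "bootstrap_mp", "bremer_support", "partitioned_bremer", "BremerRecord",
    "templeton_test", "strict_consensus",
]


# ================================================================ encoding

def parsimony_encoding(matrix: CharacterMatrix) -> np.ndarray:
    """(n_taxa, n_sites) uint32 bitmasks; 0 = unobserved."""
    if matrix.alphabet in ("DNA", "RY"):
        return matrix.encoded().astype(np.uint32)
    # multistate digits
    enc = np.zeros(matrix.shape, dtype=np.uint32)
    for d in range(10):
        enc[matrix.data == str(d).encode()] = 1 << d
    return enc


# ================================================================= scoring

def _site_steps(tree: Phylotree, enc: np.ndarray, taxon_index: dict[str, int]
                ) -> np.ndarray:
    """Fitch downpass step counts per site (vectorized over sites)."""
    n_sites = enc.shape[1]
    steps = np.zeros(n_sites, dtype=np.int64)
    states: dict[int, np.ndarray] = {}
    for n in tree.postorder():
        if n.is_leaf:
            if n.label not in taxon_index:
                raise KeyError(f"leaf {n.label} has no sequence")
            states[id(n)] = enc[taxon_index[n.label]]
        else:
            acc = None
            for c in n.children:
                s = states.pop(id(c))
                if acc is None:
                    acc = s
                    continue
                inter = acc & s
                union = acc | s
                change = (inter == 0) & (acc != 0) & (s != 0)
                steps += change
                acc = np.where(inter != 0, inter, union)
            states[id(n)] = acc
    return steps


def site_fitch_steps(tree: Phylotree, matrix: CharacterMatrix) -> np.ndarray:
    enc = parsimony_encoding(matrix)
    idx = {t: i for i, t in enumerate(matrix.taxa)}
    return _site_steps(tree, enc, idx)


def fitch_score(tree: Phylotree, matrix: CharacterMatrix,
                weights: np.ndarray | None = None) -> int:
    """Minimum number of state changes over all sites (Fitch parsimony)."""
    steps = site_fitch_steps(tree, matrix)
    if weights is None:
        return int(steps.sum())
    return int((steps * weights).sum())


# ================================================================== search

@dataclass
class ParsimonyResult:
    best_score: int
    best_trees: list[Phylotree]
    consensus: Phylotree
    searches: int


def _tree_key(tree: Phylotree) -> frozenset:
    return frozenset(tree.bipartitions())


def _postorder_nodes(tree: Phylotree) -> list[Node]:
    return list(tree.postorder())


def _neighbor_move(tree: Phylotree, i: int, j: int) -> Phylotree | None:
    """SPR move: prune postorder node i, regraft on edge above node j."""
    t = tree.copy()
    nodes = _postorder_nodes(t)
    p, target = nodes[i], nodes[j]
    if p.parent is None or target.parent is None or p is target:
        return None
    # target must not lie inside the pruned subtree, nor be p's parent edge
    a = target
    while a is not None:
        if a is p:
            return None
        a = a.parent
    if target is p.parent:
        return None
    want = frozenset(leaf_set(target))
    detach(t, p)
    # relocate the target edge by leaf set (detach may restructure the tree)
    target = next((n for n in t.postorder()
                   if n is not t.root and frozenset(leaf_set(n)) == want),
                  None)
    if target is None:
        return None
    attach_on_edge(t, target, p)
    if len(t.root.children) < 3 and t.n_leaves > 3:
        t.unroot()
    return t


def _hill_climb(tree: Phylotree, score_fn, collect: dict, max_trees: int
                ) -> tuple[Phylotree, float]:
    current, cur_score = tree, score_fn(tree)
    improved = True
    while improved:
        improved = False
        n = len(_postorder_nodes(current))
        for i in range(n):
            for j in range(n):
                t2 = _neighbor_move(current, i, j)
                if t2 is None:
                    continue
                s2 = score_fn(t2)
                if s2 < cur_score:
                    current, cur_score = t2, s2
                    improved = True
                elif s2 == cur_score and len(collect) < max_trees:
                    collect.setdefault(_tree_key(t2), t2)
        collect.setdefault(_tree_key(current), current)
    return current, cur_score


def _stepwise_addition(taxa: list[str], score_fn_builder, rng) -> Phylotree:
    order = list(taxa)
    rng.shuffle(order)
    root = Node()
    for t in order[:3]:
        root.add_child(Node(t))
    tree = Phylotree(root, rooted=False)
    for lab in order[3:]:
        score_fn = score_fn_builder(order[:len(tree.taxa) + 1])
        best, best_t = None, None
        nodes = _postorder_nodes(tree)
        for k, e in enumerate(nodes):
            if e.parent is None:
                continue
            t2 = tree.copy()
            e2 = _postorder_nodes(t2)[k]
            attach_on_edge(t2, e2, Node(lab))
            s = score_fn(t2)
            if best is None or s < best:
                best, best_t = s, t2
        tree = best_t
    return tree


def mp_search(matrix: CharacterMatrix, n_starts: int = 10, seed: int = 0,
              max_trees: int = 1000,
              forbidden_clade: frozenset | None = None) -> ParsimonyResult:
    """Heuristic MP search: random-order stepwise addition then SPR
    hill-climbing, pooling all equally best trees across replicates.

    ``forbidden_clade`` turns the search into a reverse-constraint search
    (trees containing that split are rejected), as used for Bremer support.
    """
    if matrix.n_taxa < 4:
        raise ValueError("MP search requires at least 4 taxa")
    rng = np.random.default_rng(seed)
    enc_full = parsimony_encoding(matrix)
    idx = {t: i for i, t in enumerate(matrix.taxa)}

    def full_score(tree: Phylotree) -> float:
        s = float(_site_steps(tree, enc_full, idx).sum())
        if forbidden_clade is not None and tree.has_clade(forbidden_clade):
            return np.inf
        return s

    def builder(_present):
        return full_score

    pool: dict[frozenset, Phylotree] = {}
    best_overall = np.inf
    for _ in range(n_starts):
        start = _stepwise_addition(matrix.taxa, builder, rng)
        if forbidden_clade is not None and not np.isfinite(full_score(start)):
            start = random_topology(matrix.taxa, rng)
            for _try in range(50):
                if np.isfinite(full_score(start)):
                    break
                start = random_topology(matrix.taxa, rng)
        collect: dict[frozenset, Phylotree] = {}
        t, s = _hill_climb(start, full_score, collect, max_trees)
        if s < best_overall:
            best_overall = s
            pool = {}
        if s == best_overall:
            for k, cand in collect.items():
                if full_score(cand) == best_overall and len(pool) < max_trees:
                    pool.setdefault(k, cand)
            pool.setdefault(_tree_key(t), t)
    best_trees = list(pool.values())
    cons = strict_consensus(best_trees)
    return ParsimonyResult(int(best_overall), best_trees, cons, n_starts)


# =============================================================== consensus

def strict_consensus(trees: list[Phylotree]) -> Phylotree:
    """Collapse edges of the first tree whose split is absent from any other."""
    if not trees:
        raise ValueError("no trees")
    common = set.intersection(*(set(t.bipartitions()) for t in trees))
    base = trees[0].copy()
    all_taxa = frozenset(base.taxa)
    ref = min(all_taxa)
    changed = True
    while changed:
        changed = False
        for n in list(base.postorder()):
            if n.is_leaf or n.parent is None:
                continue
            side = frozenset(leaf_set(n))
            if ref in side:
                side = all_taxa - side
            if 2 <= len(side) <= len(all_taxa) - 2 and side not in common:
                parent = n.parent
                parent.children.remove(n)
                for c in n.children:
                    parent.children.append(c)
                    c.parent = parent
                changed = True
    return base


def majority_consensus(trees: list[Phylotree], threshold: float = 0.5
                       ) -> tuple[Phylotree, dict[frozenset, float]]:
    """Majority-rule consensus with split frequencies (used by bootstrap
    and Bayesian summaries)."""
    counts: dict[frozenset, int] = {}
    for t in trees:
        for b in t.bipartitions():
            counts[b] = counts.get(b, 0) + 1
    n = len(trees)
    freqs = {b: c / n for b, c in counts.items()}
    keep = sorted([b for b, f in freqs.items() if f > threshold],
                  key=lambda b: (-freqs[b], sorted(b)))
    taxa = sorted(trees[0].taxa)
    root = Node()
    for t in taxa:
        root.add_child(Node(t))
    cons = Phylotree(root, rooted=False)
    all_taxa = frozenset(taxa)
    for split in keep:
        _insert_split(cons, split, all_taxa)
    return cons, freqs


def _insert_split(tree: Phylotree, split: frozenset, all_taxa: frozenset) -> None:
    """Group the children spanning ``split`` under a new node (if compatible)."""
    for n in tree.postorder():
        if n.is_leaf:
            continue
        kids_in = [c for c in n.children if frozenset(leaf_set(c)) <= split]
        covered = frozenset().union(*(frozenset(leaf_set(c)) for c in kids_in)) \
            if kids_in else frozenset()
        if covered == split and len(kids_in) < len(n.children):
            new = Node()
            for c in kids_in:
                n.children.remove(c)
                new.add_child(c)
            n.add_child(new)
            return


# =============================================================== bootstrap

def bootstrap_mp(matrix: CharacterMatrix, n_reps: int = 100, seed: int = 0,
                 n_starts: int = 2) -> dict[frozenset, float]:
    """Nonparametric bootstrap: resample columns with replacement, re-search,
    and report split frequencies (%) across replicate strict consensus trees."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(matrix.n_sites, size=matrix.n_sites)
        rep = matrix.select_columns(cols)
        res = mp_search(rep, n_starts=n_starts, seed=int(rng.integers(2**31)))
        for b in res.consensus.bipartitions():
            counts[b] = counts.get(b, 0) + 1
    return {b: 100.0 * c / n_reps for b, c in counts.items()}


# ================================================================== Bremer

@dataclass
class BremerRecord:
    clade: frozenset
    total: int
    by_compartment: dict[str, int]


def bremer_support(matrix: CharacterMatrix, clade, result: ParsimonyResult,
                   n_starts: int = 10, seed: int = 0) -> int:
    """Decay index: extra steps needed in the best tree lacking the clade."""
    clade = frozenset(clade)
    unknown = clade - set(matrix.taxa)
    if unknown:
        raise ValueError(f"clade taxa not in matrix: {sorted(unknown)}")
    anti = mp_search(matrix, n_starts=n_starts, seed=seed,
                     forbidden_clade=clade)
    return int(anti.best_score - result.best_score)


def partitioned_bremer(matrix: CharacterMatrix, clade,
                       result: ParsimonyResult, n_starts: int = 10,
                       seed: int = 0) -> BremerRecord:
    """Decompose Bremer support by genome compartment.

    For the best unconstrained tree and the best tree lacking the clade,
    per-compartment step differences are computed from per-site Fitch steps
    on the same tree pair, so the components sum to the total.  A negative
    component means that compartment favors the clade's absence.
    """
    if matrix.partitions is None:
        raise ValueError("matrix needs a partition map")
    clade = frozenset(clade)
    anti = mp_search(matrix, n_starts=n_starts, seed=seed,
                     forbidden_clade=clade)
    best_t = result.best_trees[0]
    anti_t = anti.best_trees[0]
    s_best = site_fitch_steps(best_t, matrix)
    s_anti = site_fitch_steps(anti_t, matrix)
    by_comp = {}
    for comp in matrix.partitions.compartments:
        m = matrix.partitions.by_compartment(comp)
        if site_informative_count(matrix, m) == 0:
            warnings.warn(f"compartment {comp} has no parsimony-informative sites")
        by_comp[comp] = int((s_anti[m] - s_best[m]).sum())
    total = int(s_anti.sum() - s_best.sum())
    return BremerRecord(clade, total, by_comp)


def site_informative_count(matrix: CharacterMatrix, mask: np.ndarray) -> int:
    """Number of parsimony-informative sites under the mask."""
    sub = matrix.data[:, mask]
    n_inf = 0
    for c in range(sub.shape[1]):
        col = sub[:, c]
        col = col[(col != b"?") & (col != b"-")]
        if col.size == 0:
            continue
        _vals, cnts = np.unique(col, return_counts=True)
        if (cnts >= 2).sum() >= 2:
            n_inf += 1
    return n_inf


# ================================================================ Templeton

def templeton_test(tree_a: Phylotree, tree_b: Phylotree,
                   matrix: CharacterMatrix) -> float:
    """Wilcoxon signed-rank test on per-site parsimony step differences
    between two trees (two-sided); p = 1 when the trees imply identical
    step vectors."""
    if set(tree_a.taxa) != set(tree_b.taxa):
        raise ValueError("trees are over different taxa")
    da = site_fitch_steps(tree_a, matrix)
    db = site_fitch_steps(tree_b, matrix)
    diff = (da - db).astype(float)
    nz = diff[diff != 0]
    if nz.size == 0:
        return 1.0
    method = "exact" if nz.size <= 25 else "approx"
    res = wilcoxon(nz, alternative="two-sided", method=method,
                   correction=(method == "approx"))
    return float(res.pvalue)
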