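"""Bayesian phylogenetic MCMC and posterior summaries.

A single-chain Metropolis-Hastings sampler over topology (NNI proposals,
which have a constant, symmetric neighborhood on binary unrooted trees),
branch lengths (multiplier proposals, Exp(10) prior) and rate-heterogeneity
parameters (gamma shape, proportion of invariant sites).  Partitions share
the topology and branch lengths but keep their own substitution models.
Convergence is assessed by split-frequency agreement between independent
runs.  Posterior summaries: majority-rule consensus with clade posterior
probabilities, and the posterior distribution of the root (outgroup
attachment) over the branches of an ingroup reference topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import CharacterMatrix
from .likelihood import _pattern_lnl, _pattern_partials
from .models import SubstitutionModel
from .parsimony import majority_consensus
from .trees import Node, Phylotree, leaf_set, random_topology

__all__ = [
    "mcmc_run", "PosteriorSample", "consensus_posterior",
    "root_posterior_map", "RootPosteriorMap", "split_frequency_deviation",
]

BL_PRIOR_RATE = 10.0     # exponential prior on branch lengths
ALPHA_PRIOR_RATE = 1.0   # exponential prior on the gamma shape


@dataclass
class PosteriorSample:
    """MCMC output: sampled trees, parameters, and the lnL trace."""
    trees: list[Phylotree]
    params: list[dict]
    lnl: np.ndarray
    generations: np.ndarray
    run_ids: np.ndarray
    acceptance_rate: float = np.nan

    def __len__(self):
        return len(self.trees)

    def post_burnin(self, burnin_fraction: float = 0.25) -> "PosteriorSample":
        keep = []
        for run in np.unique(self.run_ids):
            ix = np.where(self.run_ids == run)[0]
            keep.extend(ix[int(np.ceil(burnin_fraction * len(ix))):])
        keep = np.asarray(sorted(keep))
        return PosteriorSample([self.trees[i] for i in keep],
                               [self.params[i] for i in keep],
                               self.lnl[keep], self.generations[keep],
                               self.run_ids[keep], self.acceptance_rate)

    def stationarity_burnin(self) -> int:
        """First sample index whose window mean lnL is within one SD of the
        final quarter of the trace (a simple stationarity heuristic)."""
        lnl = self.lnl
        tail = lnl[3 * len(lnl) // 4:]
        mu, sd = tail.mean(), max(tail.std(), 1e-12)
        w = max(len(lnl) // 20, 1)
        for i in range(0, len(lnl) - w):
            if abs(lnl[i:i + w].mean() - mu) <= sd:
                return i
        return 3 * len(lnl) // 4


def _nni_move(tree: Phylotree, rng) -> Phylotree | None:
    """Random nearest-neighbor interchange (symmetric proposal)."""
    t = tree.copy()
    internal_edges = [n for n in t.postorder()
                      if n.parent is not None and not n.is_leaf]
    if not internal_edges:
        return None
    v = internal_edges[rng.integers(len(internal_edges))]
    u = v.parent
    a_side = [c for c in u.children if c is not v]
    b_side = list(v.children)
    a = a_side[rng.integers(len(a_side))]
    b = b_side[rng.integers(len(b_side))]
    ia, ib = u.children.index(a), v.children.index(b)
    u.children[ia], v.children[ib] = b, a
    a.parent, b.parent = v, u
    return t


def mcmc_run(matrix: CharacterMatrix,
             partition_models: dict[str, SubstitutionModel] | SubstitutionModel,
             n_gen: int = 10000, sample_every: int = 100, n_runs: int = 1,
             seed: int = 0, prior_only: bool = False,
             tune_window: int = 200) -> PosteriorSample:
    """Metropolis-Hastings over topology, branch lengths, and per-partition
    rate-heterogeneity parameters; ``n_runs`` independent chains from random
    starting trees are concatenated (distinguished by ``run_ids``)."""
    if n_gen < sample_every:
        raise ValueError("n_gen must be >= sample_every")
    if matrix.partitions is not None and isinstance(partition_models, dict):
        models = {e.name: partition_models[e.name] for e in matrix.partitions}
        tables = []
        for e in matrix.partitions:
            sub = matrix.select_columns(slice(e.start, e.end))
            part, counts, _ = _pattern_partials(sub)
            tables.append((e.name, sub.taxa, part, counts))
    else:
        model = (partition_models if isinstance(partition_models, SubstitutionModel)
                 else next(iter(partition_models.values())))
        models = {"all": model}
        part, counts, _ = _pattern_partials(matrix)
        tables = [("all", matrix.taxa, part, counts)]
    idx = {t: i for i, t in enumerate(matrix.taxa)}

    trees, params_out, lnls, gens, runs = [], [], [], [], []
    n_acc = n_prop = 0
    for run in range(n_runs):
        rng = np.random.default_rng(seed + 1000003 * run)
        tree = random_topology(matrix.taxa, rng)
        for n in tree.postorder():
            if n.parent is not None:
                n.length = float(rng.exponential(1 / BL_PRIOR_RATE))
        state = {name: {"gamma_shape": m.gamma_shape, "p_inv": m.p_inv}
                 for name, m in models.items()}

        def lnlike(tr, st):
            if prior_only:
                return 0.0
            tot = 0.0
            for name, _taxa, part, counts in tables:
                m = models[name].with_rates(**st[name])
                tot += float(_pattern_lnl(tr, m, part, idx) @ counts)
            return tot

        def lnprior(tr, st):
            lp = 0.0
            for n in tr.postorder():
                if n.parent is not None:
                    lp += np.log(BL_PRIOR_RATE) - BL_PRIOR_RATE * n.length
            for s in st.values():
                if s["gamma_shape"] is not None:
                    lp += -ALPHA_PRIOR_RATE * s["gamma_shape"]
            return lp

        cur_like = lnlike(tree, state)
        cur_prior = lnprior(tree, state)
        window_acc = 0
        for gen in range(1, n_gen + 1):
            u = rng.random()
            hastings = 0.0
            new_tree, new_state = tree, state
            if u < 0.4 and matrix.n_taxa >= 4:  # topology: NNI
                cand = _nni_move(tree, rng)
                if cand is None:
                    continue
                new_tree = cand
            elif u < 0.8:  # branch-length multiplier
                new_tree = tree.copy()
                branches = [n for n in new_tree.postorder() if n.parent is not None]
                b = branches[rng.integers(len(branches))]
                factor = np.exp(0.5 * (rng.random() - 0.5))
                b.length = b.length * factor
                hastings = np.log(factor)
            else:  # model-parameter slide
                name = list(models)[rng.integers(len(models))]
                s = {k: dict(v) for k, v in state.items()}
                if s[name]["gamma_shape"] is not None and rng.random() < 0.5:
                    f = np.exp(0.6 * (rng.random() - 0.5))
                    s[name]["gamma_shape"] *= f
                    hastings = np.log(f)
                elif s[name]["p_inv"] is not None:
                    p = s[name]["p_inv"] + 0.1 * (rng.random() - 0.5)
                    s[name]["p_inv"] = float(np.clip(abs(p), 0.0, 0.95))
                else:
                    continue
                new_state = s
            new_like = lnlike(new_tree, new_state)
            new_prior = lnprior(new_tree, new_state)
            log_r = (new_like + new_prior) - (cur_like + cur_prior) + hastings
            n_prop += 1
            if np.log(rng.random() + 1e-300) < log_r:
                tree, state = new_tree, new_state
                cur_like, cur_prior = new_like, new_prior
                n_acc += 1
                window_acc += 1
            if gen % tune_window == 0:
                if window_acc == 0:
                    warnings.warn(f"zero acceptance in generations "
                                  f"{gen - tune_window}-{gen}; proposals may "
                                  f"need tuning")
                window_acc = 0
            if gen % sample_every == 0:
                trees.append(tree.copy())
                params_out.append({k: dict(v) for k, v in state.items()})
                lnls.append(cur_like + cur_prior if prior_only else cur_like)
                gens.append(gen)
                runs.append(run)
    return PosteriorSample(trees, params_out, np.asarray(lnls, float),
                           np.asarray(gens), np.asarray(runs),
                           acceptance_rate=n_acc / max(n_prop, 1))


# ================================================================ summaries

def consensus_posterior(sample: PosteriorSample, burnin_fraction: float = 0.25
                        ) -> tuple[Phylotree, dict[frozenset, float]]:
    """Majority-rule consensus of post-burn-in trees; split frequencies are
    the clade posterior probabilities; consensus branch lengths are means
    over the trees containing each clade."""
    post = sample.post_burnin(burnin_fraction)
    if len(post) == 0:
        raise ValueError("no post-burn-in samples")
    cons, freqs = majority_consensus(post.trees)
    # annotate PP and mean branch lengths
    all_taxa = frozenset(cons.taxa)
    ref = min(all_taxa)
    sums: dict = {}
    for t in post.trees:
        for n in t.postorder():
            if n.parent is None:
                continue
            side = frozenset(leaf_set(n))
            if ref in side and len(side) > 1:
                side = all_taxa - side
            key = side
            s, c = sums.get(key, (0.0, 0))
            sums[key] = (s + (n.length or 0.0), c + 1)
    for n in cons.postorder():
        if n.parent is None:
            continue
        side = frozenset(leaf_set(n))
        if ref in side and len(side) > 1:
            side = all_taxa - side
        if side in sums:
            s, c = sums[side]
            n.length = s / c
        if not n.is_leaf:
            n.annotations["posterior"] = freqs.get(side, 1.0)
    return cons, freqs


@dataclass
class RootPosteriorMap:
    """Posterior probability of the outgroup attaching to each branch of an
    ingroup reference topology, keyed by the ingroup split of the branch."""
    probabilities: dict[frozenset, float]
    n_trees: int
    n_nonmonophyletic: int = 0
    group_probabilities: dict[str, float] = field(default_factory=dict)


def _attachment_split(tree: Phylotree, outgroup: set, ingroup: frozenset
                      ) -> frozenset:
    """Ingroup split of the branch where the outgroup (or its MRCA clade)
    attaches.  Canonical form: the side lacking the smallest ingroup taxon."""
    ref_leaf = sorted(ingroup)[0]
    t = tree.reroot_on_edge(tree.find_leaf(ref_leaf))
    m = t.mrca(outgroup)
    below = frozenset(leaf_set(m))
    side = frozenset(below - outgroup) if below != outgroup else frozenset()
    if below == outgroup:
        # attachment edge joins m's parent's remaining subtree
        p = m.parent
        rest = [c for c in p.children if c is not m]
        side = frozenset().union(*(frozenset(leaf_set(c)) for c in rest)) \
            if rest else frozenset()
        side = frozenset(side - outgroup)
    if ref_leaf in side:
        side = ingroup - side
    return side


def root_posterior_map(sample: PosteriorSample | list[Phylotree],
                       outgroup_taxa, ingroup_reference: Phylotree,
                       burnin_fraction: float = 0.25,
                       clade_groups: dict[str, set] | None = None
                       ) -> RootPosteriorMap:
    """Map the posterior distribution of the root over the branches of the
    ingroup reference topology.

    For each post-burn-in tree the outgroup is located and the ingroup
    branch it attaches to is recorded; trees where the outgroup is not
    monophyletic are counted at their MRCA's attachment and tallied."""
    if isinstance(sample, PosteriorSample):
        trees = sample.post_burnin(burnin_fraction).trees
    else:
        trees = list(sample)
    og = set(outgroup_taxa)
    ingroup = frozenset(ingroup_reference.taxa)
    counts: dict[frozenset, int] = {}
    nonmono = 0
    for t in trees:
        missing = og - set(t.taxa)
        if missing:
            raise ValueError(f"outgroup taxa absent from a sampled tree: "
                             f"{sorted(missing)}")
        if not t.has_clade(og):
            nonmono += 1
        split = _attachment_split(t, og, ingroup)
        counts[split] = counts.get(split, 0) + 1
    n = len(trees)
    probs = {k: v / n for k, v in counts.items()}
    group_probs = {}
    if clade_groups:
        for gname, gtaxa in clade_groups.items():
            gtaxa = frozenset(gtaxa)
            tot = 0.0
            for split, p in probs.items():
                side = split if split <= gtaxa else ingroup - split
                if side <= gtaxa:
                    tot += p
            group_probs[gname] = tot
    if nonmono:
        warnings.warn(f"outgroup non-monophyletic in {nonmono}/{n} sampled "
                      f"trees; counted at the MRCA attachment")
    return RootPosteriorMap(probs, n, nonmono, group_probs)


def split_frequency_deviation(sample: PosteriorSample,
                              burnin_fraction: float = 0.25) -> float:
    """Average absolute split-frequency difference between runs (the
    standard two-run convergence diagnostic)."""
    post = sample.post_burnin(burnin_fraction)
    run_ids = np.unique(post.run_ids)
    if len(run_ids) < 2:
        raise ValueError("need at least two runs")
    freqs = []
    for run in run_ids:
        trees = [t for t, r in zip(post.trees, post.run_ids) if r == run]
        counts: dict[frozenset, int] = {}
        for t in trees:
            for b in t.bipartitions():
                counts[b] = counts.get(b, 0) + 1
        freqs.append({b: c / len(trees) for b, c in counts.items()})
    all_splits = set().union(*(set(f) for f in freqs))
    devs = []
    for b in all_splits:
        vals = [f.get(b, 0.0) for f in freqs]
        devs.append(max(vals) - min(vals))
    return float(np.mean(devs)) if devs else 0.0
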