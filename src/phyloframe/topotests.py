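"""Constrained-topology enumeration and likelihood-based topology tests.

Stable clades are collapsed to group labels; all (2k-5)!! unrooted backbone
topologies over the k labels are enumerated, resolved against the data by
freezing each group's subtree from the unconstrained ML tree, and compared
with the Shimodaira-Hasegawa (SH) test and the approximately unbiased (AU)
test, both driven by RELL resampling of per-site log-likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .io_formats import CharacterMatrix
from .likelihood import optimize_branch_lengths, site_log_likelihoods
from .models import SubstitutionModel
from .trees import Node, Phylotree, all_unrooted_topologies, leaf_set

__all__ = [
    "enumerate_topologies", "TopologySet", "constrained_ml", "sh_test",
    "au_test", "topology_test_report", "TestReport", "DEFAULT_AU_SCALES",
]

DEFAULT_AU_SCALES = tuple(np.round(np.linspace(0.5, 1.4, 10), 2))


@dataclass
class TopologySet:
    """Named backbone topologies over group labels, rooted on the outgroup."""
    topologies: list[Phylotree]
    labels: list[str]
    outgroup: str
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.names:
            self.names = [f"t{i + 1}" for i in range(len(self.topologies))]

    def __len__(self):
        return len(self.topologies)

    def __iter__(self):
        return iter(zip(self.names, self.topologies))


def enumerate_topologies(group_labels: list[str], outgroup_label: str
                         ) -> TopologySet:
    """All distinct unrooted binary topologies over the labels (one of which
    is the outgroup), each returned rooted on the outgroup.

    For k labels there are (2k-5)!! topologies: 3 for k=4, 15 for k=5.
    """
    labels = list(group_labels)
    if outgroup_label not in labels:
        labels = labels + [outgroup_label]
    k = len(labels)
    if not (3 <= k <= 8):
        raise ValueError(f"need between 3 and 8 labels, got {k}")
    seen: set[frozenset] = set()
    out = []
    for t in all_unrooted_topologies(labels):
        key = frozenset(t.bipartitions())
        if key in seen:
            continue
        seen.add(key)
        out.append(t.root_with_outgroup([outgroup_label]))
    return TopologySet(out, labels, outgroup_label)


# ============================================================ constrained ML

def _induced_subtree(tree: Phylotree, taxa: set) -> Node:
    sub = tree.prune_taxa(set(tree.taxa) - set(taxa))
    return sub.root


def constrained_ml(matrix: CharacterMatrix, model: SubstitutionModel,
                   constraint: Phylotree, groups: dict[str, str],
                   ml_tree: Phylotree) -> tuple[Phylotree, np.ndarray]:
    """Resolve a backbone constraint into a full tree and fit it.

    Every matrix taxon must belong to exactly one group label of the
    constraint; group subtrees are frozen from the unconstrained ML tree,
    the backbone is forced to the constraint, and branch lengths are
    re-optimized.  Returns the fitted tree and its per-site lnL row.
    """
    unassigned = set(matrix.taxa) - set(groups)
    if unassigned:
        raise ValueError(f"taxa not assigned to any group: {sorted(unassigned)}")
    members: dict[str, set] = {}
    for taxon, g in groups.items():
        members.setdefault(g, set()).add(taxon)
    missing = set(constraint.taxa) - set(members)
    if missing:
        raise ValueError(f"constraint groups without members: {sorted(missing)}")

    def expand(n: Node) -> Node:
        if n.is_leaf:
            taxa = members[n.label]
            if len(taxa) == 1:
                return Node(next(iter(taxa)), 0.05)
            sub = _induced_subtree(ml_tree, taxa)
            sub.length = 0.05
            return sub
        m = Node(length=0.05 if n.parent is not None else None)
        for c in n.children:
            m.add_child(expand(c))
        return m

    full = Phylotree(expand(constraint.root), rooted=False)
    if len(full.root.children) == 2:
        full.unroot()
    fitted = optimize_branch_lengths(full, model, matrix, tol=1e-4,
                                     max_sweeps=6)
    row = site_log_likelihoods(fitted, model, matrix)
    return fitted, row


# ================================================================= SH test

def _rell_totals(table: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """(n_trees, n_boot) totals from resampled site columns."""
    return table[:, idx].sum(axis=1) if idx.ndim == 1 else \
        np.stack([table[:, b].sum(axis=1) for b in idx], axis=1)


def sh_test(site_lnl_table: np.ndarray, n_boot: int = 1000, seed: int = 0
            ) -> np.ndarray:
    """Shimodaira-Hasegawa test over a set of candidate topologies.

    RELL bootstrap of per-site log-likelihoods with a centered-maxima null;
    returns one p-value per topology (the ML topology gets p = 1)."""
    table = np.asarray(site_lnl_table, float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("need a (n_trees >= 2, n_sites) table")
    if n_boot < 100:
        warnings.warn("SH test with fewer than 100 RELL replicates")
    rng = np.random.default_rng(seed)
    n_trees, n_sites = table.shape
    totals = table.sum(axis=1)
    delta_obs = totals.max() - totals
    boot = np.empty((n_trees, n_boot))
    for b in range(n_boot):
        idx = rng.integers(n_sites, size=n_sites)
        boot[:, b] = table[:, idx].sum(axis=1)
    centered = boot - boot.mean(axis=1, keepdims=True)
    null_max = centered.max(axis=0)  # (n_boot,)
    p = ((null_max[None, :] - centered) >= delta_obs[:, None]).mean(axis=1)
    return p


# ================================================================= AU test

def au_test(site_lnl_table: np.ndarray, scale_factors=DEFAULT_AU_SCALES,
            n_boot: int = 1000, seed: int = 0) -> np.ndarray:
    """Approximately unbiased test via multiscale RELL bootstrap.

    For each scale r the sites are resampled at size round(r*n) and the
    bootstrap proportion BP(r) of each topology being the maximum is
    recorded; signed distance d and curvature c are fitted by weighted
    least squares to Phi^-1(1 - BP(r)) = d*sqrt(r) + c/sqrt(r), giving
    p = 1 - Phi(d - c).  Scales where BP is degenerate (0 or 1) are
    dropped; if fewer than 3 informative scales remain for a topology the
    naive BP at scale 1 is returned with a warning.
    """
    table = np.asarray(site_lnl_table, float)
    n_trees, n_sites = table.shape
    if n_trees == 1:
        return np.ones(1)
    rng = np.random.default_rng(seed)
    scales = np.asarray(scale_factors, float)
    bp = np.zeros((n_trees, len(scales)))
    for si, r in enumerate(scales):
        m = max(int(round(r * n_sites)), 1)
        wins = np.zeros(n_trees)
        for _ in range(n_boot):
            idx = rng.integers(n_sites, size=m)
            tot = table[:, idx].sum(axis=1)
            wins += tot >= tot.max() - 1e-12  # ties credit every maximum
        bp[:, si] = wins / n_boot
    # naive BP at the scale closest to 1 (fallback and single-scale limit)
    near1 = int(np.argmin(np.abs(scales - 1.0)))
    p = np.empty(n_trees)
    for i in range(n_trees):
        ok = (bp[i] > 0) & (bp[i] < 1)
        if ok.sum() < 3:
            if len(scales) > 1:
                warnings.warn(
                    f"topology {i}: degenerate BP at all scales; "
                    f"falling back to naive bootstrap proportion")
            p[i] = np.clip(bp[i, near1], 0.0, 1.0)
            continue
        r = scales[ok]
        z = norm.ppf(1 - bp[i, ok])
        X = np.stack([np.sqrt(r), 1 / np.sqrt(r)], axis=1)
        # binomial delta-rule weights
        var = bp[i, ok] * (1 - bp[i, ok]) / (n_boot * norm.pdf(z) ** 2)
        W = 1 / var
        beta, *_ = np.linalg.lstsq(X * np.sqrt(W)[:, None],
                                   z * np.sqrt(W), rcond=None)
        d, c = beta
        p[i] = float(norm.sf(d - c))
    return p


# ================================================================== report

@dataclass
class TestReport:
    names: list[str]
    lnl: np.ndarray
    au_p: np.ndarray
    sh_p: np.ndarray
    alpha: float = 0.05

    def significant(self) -> list[str]:
        """Topologies rejected by the AU test at level alpha."""
        return [n for n, p in zip(self.names, self.au_p) if p < self.alpha]

    def to_rows(self) -> list[dict]:
        return [{"topology": n, "lnL": float(l), "AU": float(a), "SH": float(s)}
                for n, l, a, s in zip(self.names, self.lnl, self.au_p, self.sh_p)]


def topology_test_report(names: list[str], site_lnl_table: np.ndarray,
                         n_boot: int = 1000, seed: int = 0,
                         alpha: float = 0.05) -> TestReport:
    table = np.asarray(site_lnl_table, float)
    return TestReport(names, table.sum(axis=1),
                      au_test(table, n_boot=n_boot, seed=seed),
                      sh_test(table, n_boot=n_boot, seed=seed + 1),
                      alpha)
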