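"""Supermatrix assembly: progressive alignment with a gap-parameter sweep,
alignment-stability filtering, long-indel exclusion, concatenation with
partition bookkeeping, RY recoding, and compositional-bias diagnostics.

The stability filter follows the sweep-and-compare idea: align the same
sequences under a grid of gap penalties and keep only columns whose homology
statement (which residue of which taxon sits in the column) is identical in
every sweep alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency
from skbio import DistanceMatrix
from skbio.tree import nj

from .io_formats import (AlphabetError, CharacterMatrix, PartitionEntry,
                         PartitionMap)

__all__ = [
    "progressive_align", "pairwise_align_score", "sweep_align",
    "stability_filter", "StabilityMask",
    "indel_filter", "concatenate", "ry_recode", "chi2_homogeneity",
    "CompositionReport", "p_distance_matrix", "DEFAULT_SWEEP_GRID",
]

# gap-penalty sweep grid: 3x3 subset of the open 3-15 / extend 3-7 ranges
DEFAULT_SWEEP_GRID = [(go, ge) for go in (3, 9, 15) for ge in (3, 5, 7)]

_DNA_IDX = {b: i for i, b in enumerate("ACGT")}


# ========================================================== pairwise/profile

def _profile_counts(profile: np.ndarray) -> np.ndarray:
    """(L, 4) residue counts per column of a byte profile (gaps excluded)."""
    counts = np.zeros((profile.shape[1], 4))
    for b, i in _DNA_IDX.items():
        counts[:, i] = (profile == b.encode()).sum(axis=0)
    return counts


def _align_profiles(A: np.ndarray, B: np.ndarray, gap_open: float,
                    gap_extend: float, match: float, mismatch: float
                    ) -> np.ndarray:
    """Gotoh affine-gap global alignment of two byte profiles; returns the
    merged profile (rows of A then rows of B, '-' filled)."""
    ca, cb = _profile_counts(A), _profile_counts(B)
    S = np.full((4, 4), mismatch)
    np.fill_diagonal(S, match)
    na = max(ca.sum(axis=1).max(), 1)
    nb = max(cb.sum(axis=1).max(), 1)
    pair = (ca @ S @ cb.T) / (na * nb)  # (LA, LB) mean-of-pairs column score
    LA, LB = pair.shape
    NEG = -1e30
    M = np.full((LA + 1, LB + 1), NEG)
    X = np.full((LA + 1, LB + 1), NEG)  # gap in B (consume A)
    Y = np.full((LA + 1, LB + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    X[1:, 0] = -gap_open - gap_extend * np.arange(1, LA + 1)
    Y[0, 1:] = -gap_open - gap_extend * np.arange(1, LB + 1)
    ptrM = np.zeros((LA + 1, LB + 1), dtype=np.int8)
    ptrX = np.zeros((LA + 1, LB + 1), dtype=np.int8)
    ptrY = np.zeros((LA + 1, LB + 1), dtype=np.int8)
    for i in range(1, LA + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        # X: gap in B, move down
        openx = prevM - gap_open - gap_extend
        extx = prevX - gap_extend
        X[i] = np.where(openx >= extx, openx, extx)
        ptrX[i] = np.where(openx >= extx, 0, 1)
        rowM = M[i]
        rowY = Y[i]
        rowPM = ptrM[i]
        rowPY = ptrY[i]
        sc = pair[i - 1]
        for j in range(1, LB + 1):
            # M: diagonal from best of three
            best, arg = prevM[j - 1], 0
            if prevX[j - 1] > best:
                best, arg = prevX[j - 1], 1
            if prevY[j - 1] > best:
                best, arg = prevY[j - 1], 2
            rowM[j] = best + sc[j - 1]
            rowPM[j] = arg
            # Y: gap in A, move right
            openy = rowM[j - 1] - gap_open - gap_extend
            exty = rowY[j - 1] - gap_extend
            if openy >= exty:
                rowY[j], rowPY[j] = openy, 0
            else:
                rowY[j], rowPY[j] = exty, 2
    # traceback
    i, j = LA, LB
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ops = []  # 0=match, 1=down(gap in B), 2=right(gap in A)
    while i > 0 or j > 0:
        if i == 0:
            ops.append(2); j -= 1; continue
        if j == 0:
            ops.append(1); i -= 1; continue
        if state == 0:
            ops.append(0)
            state = ptrM[i, j]
            i -= 1; j -= 1
        elif state == 1:
            ops.append(1)
            state = 0 if ptrX[i, j] == 0 else 1
            i -= 1
        else:
            ops.append(2)
            state = 0 if ptrY[i, j] == 0 else 2
            j -= 1
    ops.reverse()
    L = len(ops)
    out = np.full((A.shape[0] + B.shape[0], L), b"-", dtype="S1")
    ia = ja = 0
    for col, op in enumerate(ops):
        if op in (0, 1):
            out[:A.shape[0], col] = A[:, ia]
            ia += 1
        if op in (0, 2):
            out[A.shape[0]:, col] = B[:, ja]
            ja += 1
    return out


def pairwise_align_score(s1: str, s2: str, gap_open: float = 5.0,
                         gap_extend: float = 1.0, match: float = 1.0,
                         mismatch: float = -1.0) -> float:
    """Optimal affine-gap global alignment score of two sequences."""
    A = np.frombuffer(s1.upper().encode(), dtype="S1")[None, :]
    B = np.frombuffer(s2.upper().encode(), dtype="S1")[None, :]
    merged = _align_profiles(A, B, gap_open, gap_extend, match, mismatch)
    return _score_pair(merged[0], merged[1], gap_open, gap_extend, match, mismatch)


def _score_pair(r1, r2, gap_open, gap_extend, match, mismatch) -> float:
    score, in_gap = 0.0, False
    for a, b in zip(r1, r2):
        if a == b"-" or b == b"-":
            score += -(gap_extend if in_gap else gap_open + gap_extend)
            in_gap = True
        else:
            score += match if a == b else mismatch
            in_gap = False
    return score


def progressive_align(seqs: dict[str, str] | list[tuple[str, str]],
                      gap_open: float = 5.0, gap_extend: float = 1.0,
                      match: float = 1.0, mismatch: float = -1.0
                      ) -> CharacterMatrix:
    """Progressive multiple alignment: pairwise affine-gap distances →
    neighbor-joining guide tree → profile-profile merges.  Deterministic;
    guide-tree ties broken by taxon-label order."""
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    names = [t for t, _ in items]
    raw = {t: s.upper().replace("-", "") for t, s in items}
    if any(len(s) == 0 for s in raw.values()):
        raise ValueError("empty sequence")
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    if len(names) == 2:
        A = np.frombuffer(raw[names[0]].encode(), dtype="S1")[None, :]
        B = np.frombuffer(raw[names[1]].encode(), dtype="S1")[None, :]
        merged = _align_profiles(A, B, gap_open, gap_extend, match, mismatch)
        return _matrix_from_profile(names, merged)
    # guide distances: p-distance on pairwise alignments
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            A = np.frombuffer(raw[names[i]].encode(), dtype="S1")[None, :]
            B = np.frombuffer(raw[names[j]].encode(), dtype="S1")[None, :]
            m = _align_profiles(A, B, gap_open, gap_extend, match, mismatch)
            both = (m[0] != b"-") & (m[1] != b"-")
            D[i, j] = D[j, i] = (
                (m[0][both] != m[1][both]).mean() if both.any() else 1.0)
    guide = nj(DistanceMatrix(D, ids=names))
    # merge following the guide tree's postorder
    profiles = {t: np.frombuffer(raw[t].encode(), dtype="S1")[None, :]
                for t in names}
    orders = {t: [t] for t in names}

    def merge(node):
        kids = list(node.children)
        if not kids:
            return node.name
        done = [merge(c) for c in kids]
        done.sort()  # deterministic tie-break by label order
        acc = done[0]
        for other in done[1:]:
            merged = _align_profiles(profiles[acc], profiles[other],
                                     gap_open, gap_extend, match, mismatch)
            key = acc + "|" + other
            profiles[key] = merged
            orders[key] = orders[acc] + orders[other]
            acc = key
        return acc

    top = merge(guide.root())
    prof, order = profiles[top], orders[top]
    # restore input taxon order
    idx = [order.index(t) for t in names]
    return _matrix_from_profile(names, prof[idx])


def _matrix_from_profile(names, profile) -> CharacterMatrix:
    seqs = [profile[i].tobytes().decode() for i in range(profile.shape[0])]
    return CharacterMatrix(names, seqs, alphabet="DNA")


def sweep_align(seqs, grid=None, **scores) -> list[CharacterMatrix]:
    """Align the same sequences under every (gap_open, gap_extend) of the grid."""
    grid = DEFAULT_SWEEP_GRID if grid is None else grid
    return [progressive_align(seqs, go, ge, **scores) for go, ge in grid]


# ============================================================== stability

@dataclass
class StabilityMask:
    """Per-column keep/drop decisions for the reference sweep alignment."""
    keep: np.ndarray                 # bool, len = reference alignment length
    agreement: np.ndarray            # number of sweep alignments agreeing

    def apply(self, matrix: CharacterMatrix) -> CharacterMatrix:
        return matrix.select_columns(self.keep)


def _homology_columns(matrix: CharacterMatrix) -> list[frozenset]:
    """Per column, the set of (taxon, residue_index) pairs it asserts."""
    res_idx = np.cumsum(matrix.data != b"-", axis=1) - 1
    cols = []
    for c in range(matrix.n_sites):
        cols.append(frozenset(
            (i, int(res_idx[i, c])) for i in range(matrix.n_taxa)
            if matrix.data[i, c] != b"-"))
    return cols


def stability_filter(sweep_alignments: list[CharacterMatrix],
                     min_agreement: float = 1.0) -> StabilityMask:
    """Keep reference columns whose homology set recurs in a fraction
    ``min_agreement`` of the sweep alignments (default: all of them)."""
    if len(sweep_alignments) < 2:
        raise ValueError("need at least 2 sweep alignments")
    taxa0 = sweep_alignments[0].taxa
    for a in sweep_alignments[1:]:
        if a.taxa != taxa0:
            raise ValueError("sweep alignments cover different taxon sets")
    ref_cols = _homology_columns(sweep_alignments[0])
    others = [set(_homology_columns(a)) for a in sweep_alignments[1:]]
    agreement = np.array(
        [1 + sum(col in o for o in others) for col in ref_cols])
    need = int(np.ceil(min_agreement * len(sweep_alignments)))
    return StabilityMask(keep=agreement >= need, agreement=agreement)


# ============================================================ indel filter

def indel_filter(matrix: CharacterMatrix, max_gap_len: int = 2
                 ) -> CharacterMatrix:
    """Remove columns lying in any maximal gap run longer than
    ``max_gap_len`` in any taxon (long indels excluded from analysis)."""
    drop = np.zeros(matrix.n_sites, dtype=bool)
    gaps = matrix.data == b"-"
    for i in range(matrix.n_taxa):
        run = 0
        for c in range(matrix.n_sites):
            if gaps[i, c]:
                run += 1
            else:
                if run > max_gap_len:
                    drop[c - run:c] = True
                run = 0
        if run > max_gap_len:
            drop[matrix.n_sites - run:] = True
    if drop.all():
        warnings.warn("indel filter removed every column")
    return matrix.select_columns(~drop)


# ============================================================ concatenation

def concatenate(gene_matrices: dict[str, CharacterMatrix],
                compartments: dict[str, str] | None = None,
                merge_groups: dict[str, list[str]] | None = None
                ) -> tuple[CharacterMatrix, PartitionMap]:
    """Column-wise concatenation over the taxon union.

    Missing gene-by-taxon blocks are filled with '?'.  Genes listed in a
    merge group are pooled into a single named partition (e.g. 22 tRNAs
    concatenated into one block).
    """
    if len(set(gene_matrices)) != len(gene_matrices):
        raise ValueError("duplicate gene names")
    compartments = compartments or {}
    merge_groups = merge_groups or {}
    merged_of = {}
    for group, members in merge_groups.items():
        for g in members:
            if g in merged_of:
                raise ValueError(f"gene {g} appears in two merge groups")
            merged_of[g] = group
    # partition order: first appearance order of (merge-group or gene)
    order: list[tuple[str, list[str]]] = []
    seen = {}
    for g in gene_matrices:
        key = merged_of.get(g, g)
        if key not in seen:
            seen[key] = []
            order.append((key, seen[key]))
        seen[key].append(g)
    taxa: list[str] = []
    for m in gene_matrices.values():
        for t in m.taxa:
            if t not in taxa:
                taxa.append(t)
    entries, pieces, pos = [], {t: [] for t in taxa}, 0
    for part_name, members in order:
        width = sum(gene_matrices[g].n_sites for g in members)
        comp = compartments.get(members[0], "nuclear")
        entries.append(PartitionEntry(part_name, pos, pos + width, comp))
        pos += width
        for g in members:
            m = gene_matrices[g]
            blank = "?" * m.n_sites
            for t in taxa:
                pieces[t].append(m.sequence(t) if t in m.taxa else blank)
    pmap = PartitionMap(entries)
    seqs = ["".join(pieces[t]) for t in taxa]
    alph = next(iter(gene_matrices.values())).alphabet
    return CharacterMatrix(taxa, seqs, alph, pmap), pmap


# ================================================================ recoding

_RY_MAP = {"A": "R", "G": "R", "R": "R", "C": "Y", "T": "Y", "Y": "Y"}


def ry_recode(matrix: CharacterMatrix) -> CharacterMatrix:
    """Collapse DNA to purine/pyrimidine states.  A,G,R → R; C,T,Y → Y;
    every other ambiguity code, '?' and '-' become '?'."""
    if matrix.alphabet != "DNA":
        raise AlphabetError("RY recoding requires a DNA matrix")
    lut = np.full(256, ord("?"), dtype=np.uint8)
    for src, dst in _RY_MAP.items():
        lut[ord(src)] = ord(dst)
    rec = lut[matrix.data.view(np.uint8)]
    seqs = [rec[i].tobytes().decode() for i in range(matrix.n_taxa)]
    return CharacterMatrix(matrix.taxa, seqs, "RY", matrix.partitions)


# ============================================================= diagnostics

@dataclass
class CompositionReport:
    """Taxon-by-state composition and a chi-square homogeneity test."""
    taxa: list[str]
    states: str
    frequencies: np.ndarray   # (n_taxa, n_states), rows sum to 1
    counts: np.ndarray
    statistic: float
    df: int
    p_value: float

    def rejects(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def chi2_homogeneity(matrix: CharacterMatrix, columns=None) -> CompositionReport:
    """Chi-square test of base-composition homogeneity across taxa
    (missing and gap cells excluded from the counts)."""
    data = matrix.data if columns is None else matrix.data[:, columns]
    states = "ACGT" if matrix.alphabet == "DNA" else "RY"
    counts = np.zeros((matrix.n_taxa, len(states)))
    for k, st in enumerate(states):
        counts[:, k] = (data == st.encode()).sum(axis=1)
    rows = counts.sum(axis=1)
    if (rows == 0).any():
        bad = [matrix.taxa[i] for i in np.where(rows == 0)[0]]
        raise ValueError(f"taxa with no observed characters: {bad}")
    freqs = counts / rows[:, None]
    nz = counts.sum(axis=0) > 0
    table = counts[:, nz]
    if table.shape[1] < 2 or np.allclose(freqs, freqs[0]):
        stat, p, df = 0.0, 1.0, (matrix.n_taxa - 1) * (len(states) - 1)
    else:
        stat, p, df, _ = chi2_contingency(table, correction=False)
    return CompositionReport(matrix.taxa, states, freqs, counts,
                             float(stat), int(df), float(p))


def composition_by_partition(matrix: CharacterMatrix) -> dict[str, CompositionReport]:
    """Per-partition homogeneity reports (taxa lacking a gene are dropped
    from that gene's table)."""
    if matrix.partitions is None:
        raise ValueError("matrix has no partition map")
    out = {}
    for e in matrix.partitions:
        sub = matrix.data[:, e.start:e.end]
        present = ~((sub == b"?") | (sub == b"-")).all(axis=1)
        taxa = [t for t, keep in zip(matrix.taxa, present) if keep]
        if len(taxa) < 2:
            continue
        seqs = [sub[i].tobytes().decode()
                for i in np.where(present)[0]]
        out[e.name] = chi2_homogeneity(
            CharacterMatrix(taxa, seqs, matrix.alphabet))
    return out


def p_distance_matrix(matrix: CharacterMatrix) -> np.ndarray:
    """Pairwise proportion of differing sites over pairwise-complete sites.

    Pairs sharing no observed site get NaN (flagged undefined)."""
    obs = ~matrix.missing_mask()
    n = matrix.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            m = int(both.sum())
            if m == 0:
                D[i, j] = D[j, i] = np.nan
                warnings.warn(
                    f"no shared sites between {matrix.taxa[i]} and {matrix.taxa[j]}")
            else:
                diff = (matrix.data[i, both] != matrix.data[j, both]).mean()
                D[i, j] = D[j, i] = float(diff)
    return D
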