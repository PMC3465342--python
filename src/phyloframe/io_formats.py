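"""Readers and writers for alignments, trees, partition and calibration files.

The shared data model consumed by every analysis stage:

* :class:`CharacterMatrix` — taxa × sites, DNA / RY / multistate alphabet.
* :class:`PartitionMap` — named, disjoint site ranges tagged by genome
  compartment (mito / nuclear / morphology) and codon position.
* :class:`CalibrationConstraint` — fossil calibration (stem or crown,
  fixed or minimum age in MY).

Coordinates are 0-based half-open internally; files use the 1-based
inclusive convention of PHYLIP/NEXUS/RAxML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

from .trees import Phylotree

DNA_CHARS = set("ACGTRYSWKMBDHVN")
RY_CHARS = set("RY")
MISSING = "?"
GAP = "-"

# bitmask encoding: A=1, C=2, G=4, T=8; ambiguity codes are unions;
# '?' and '-' carry no state information (full mask for likelihood,
# empty observation for parsimony/composition).
DNA_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15, "?": 15, "-": 15,
}
RY_BITS = {"R": 1, "Y": 2, "?": 3, "-": 3}


class AlignmentLengthError(ValueError):
    pass


class LabelError(ValueError):
    pass


class AlphabetError(ValueError):
    pass


@dataclass(frozen=True)
class PartitionEntry:
    name: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    compartment: str = "nuclear"  # mito | nuclear | morphology
    codon_position: int | None = None

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PartitionMap:
    entries: list[PartitionEntry]

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("partition names must be unique")
        prev = 0
        for e in sorted(self.entries, key=lambda e: e.start):
            if e.start != prev:
                raise ValueError("partition ranges must be disjoint and tile the matrix")
            if e.end <= e.start:
                raise ValueError(f"empty partition {e.name}")
            prev = e.end
        self.total_sites = prev

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def __getitem__(self, name: str) -> PartitionEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def columns(self, name: str) -> slice:
        e = self[name]
        return slice(e.start, e.end)

    def by_compartment(self, compartment: str) -> np.ndarray:
        """Boolean site mask for one genome compartment."""
        mask = np.zeros(self.total_sites, dtype=bool)
        for e in self.entries:
            if e.compartment == compartment:
                mask[e.start:e.end] = True
        return mask

    @property
    def compartments(self) -> list[str]:
        seen = []
        for e in self.entries:
            if e.compartment not in seen:
                seen.append(e.compartment)
        return seen


class CharacterMatrix:
    """Aligned taxa × sites character data.

    Rows are stored as a byte matrix for vectorized column work; '?' is
    fully missing, '-' (alignment gap) is likewise treated as unobserved
    throughout (long indels are excluded rather than scored).
    """

    def __init__(self, taxa: list[str], sequences: list[str],
                 alphabet: str = "DNA", partitions: PartitionMap | None = None):
        if len(taxa) != len(sequences):
            raise LabelError("taxa and sequences differ in count")
        if len(set(taxa)) != len(taxa):
            dup = sorted({t for t in taxa if taxa.count(t) > 1})
            raise LabelError(f"duplicate taxon labels: {dup}")
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise AlignmentLengthError(f"ragged alignment, row lengths {sorted(lengths)}")
        self.taxa = list(taxa)
        self.alphabet = alphabet
        seqs = [s.upper() for s in sequences]
        allowed = self._allowed_chars(alphabet)
        for t, s in zip(taxa, seqs):
            bad = set(s) - allowed
            if bad:
                raise AlphabetError(f"taxon {t}: characters {sorted(bad)} not in {alphabet} alphabet")
        self.data = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(
            len(taxa), -1) if seqs and seqs[0] else np.empty((len(taxa), 0), dtype="S1")
        if partitions is not None and partitions.total_sites != self.n_sites:
            raise ValueError("partition map does not tile the matrix")
        self.partitions = partitions

    @staticmethod
    def _allowed_chars(alphabet: str) -> set:
        if alphabet == "DNA":
            return DNA_CHARS | {MISSING, GAP}
        if alphabet == "RY":
            return RY_CHARS | {MISSING, GAP}
        if alphabet == "MULTISTATE":
            return set("0123456789") | {MISSING, GAP}
        raise ValueError(f"unknown alphabet {alphabet}")

    # ------------------------------------------------------------ properties
    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sequence(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return self.data[i].tobytes().decode()

    @property
    def sequences(self) -> list[str]:
        return [self.data[i].tobytes().decode() for i in range(self.n_taxa)]

    def missing_mask(self) -> np.ndarray:
        """True where a cell is '?' or '-' (unobserved)."""
        return (self.data == b"?") | (self.data == b"-")

    def completeness(self) -> float:
        """Fraction of observed (non-missing, non-gap) cells."""
        if self.data.size == 0:
            return 0.0
        return 1.0 - self.missing_mask().mean()

    def encoded(self) -> np.ndarray:
        """uint8 state-set encoding (bitmask) for DNA/RY; 0 = unobserved."""
        if self.alphabet == "DNA":
            table = DNA_BITS
        elif self.alphabet == "RY":
            table = RY_BITS
        else:
            raise AlphabetError("encoded() supports DNA and RY alphabets")
        lut = np.zeros(256, dtype=np.uint8)
        for ch, bits in table.items():
            lut[ord(ch)] = bits
        enc = lut[self.data.view(np.uint8)]
        enc[self.missing_mask()] = 0
        return enc

    def select_columns(self, mask_or_index) -> "CharacterMatrix":
        """New matrix restricted to the given columns; partitions re-indexed."""
        cols = np.arange(self.n_sites)[mask_or_index]
        new = self.data[:, cols]
        parts = None
        if self.partitions is not None:
            keep = np.zeros(self.n_sites, dtype=bool)
            keep[cols] = True
            entries, pos = [], 0
            for e in self.partitions:
                n = int(keep[e.start:e.end].sum())
                if n > 0:
                    entries.append(PartitionEntry(e.name, pos, pos + n,
                                                  e.compartment, e.codon_position))
                    pos += n
            parts = PartitionMap(entries) if entries else None
        seqs = [new[i].tobytes().decode() for i in range(new.shape[0])]
        return CharacterMatrix(self.taxa, seqs, self.alphabet, parts)

    def __repr__(self) -> str:
        return (f"CharacterMatrix({self.n_taxa} taxa × {self.n_sites} sites, "
                f"{self.alphabet}, completeness={self.completeness():.3f})")


@dataclass(frozen=True)
class CalibrationConstraint:
    """A fossil calibration attached to a node of the dated tree."""
    name: str
    mrca_taxa: tuple[str, ...]
    attachment: str  # stem | crown
    kind: str        # fixed | min
    age: float       # MY

    def __post_init__(self):
        if self.attachment not in ("stem", "crown"):
            raise ValueError(f"attachment must be stem or crown, got {self.attachment}")
        if self.kind not in ("fixed", "min"):
            raise ValueError(f"kind must be fixed or min, got {self.kind}")
        if self.age <= 0:
            raise ValueError(f"calibration age must be > 0, got {self.age}")
        lo = 2 if self.attachment == "crown" else 1
        if len(self.mrca_taxa) < lo:
            raise ValueError(f"{self.attachment} calibration needs ≥{lo} taxa")


# ========================================================================= IO

_FORMATS = {"FASTA": "fasta", "PHYLIP": "phylip-relaxed", "NEXUS": "nexus"}


def read_alignment(path, format: str = "FASTA", alphabet: str = "DNA") -> CharacterMatrix:
    """Read an aligned matrix (FASTA, relaxed sequential PHYLIP, or NEXUS)."""
    fmt = _FORMATS[format.upper()]
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise AlignmentLengthError(f"no sequences in {path}")
        taxa = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
    else:
        aln = AlignIO.read(path, fmt)
        taxa = [r.id for r in aln]
        seqs = [str(r.seq) for r in aln]
    return CharacterMatrix(taxa, seqs, alphabet=alphabet)


def write_alignment(matrix: CharacterMatrix, path, format: str = "FASTA") -> None:
    fmt = _FORMATS[format.upper()]
    records = [SeqRecord(Seq(s), id=t, description="")
               for t, s in zip(matrix.taxa, matrix.sequences)]
    if fmt == "fasta":
        SeqIO.write(records, path, "fasta-2line")
    else:
        aln = MultipleSeqAlignment(records)
        if fmt == "nexus":
            for r in aln:
                r.annotations["molecule_type"] = "DNA"
        AlignIO.write(aln, path, fmt)


def read_tree(path_or_str) -> Phylotree:
    """Read a Newick tree from a path or a literal Newick string."""
    s = str(path_or_str)
    if not s.lstrip().startswith("("):
        with open(path_or_str) as fh:
            s = fh.read()
    return Phylotree.from_newick(s)


def write_tree(tree: Phylotree, path, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(**kwargs) + "\n")


def read_partitions(path) -> PartitionMap:
    """RAxML-style partition lines extended with a compartment tag:

        mito, DNA, cytb = 1-1141
        nuclear, DNA, rag1_pos3 = 1142-2000\\3

    An optional ``\\k`` suffix records codon position k.
    """
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            head, rng = line.split("=")
            fields = [f.strip() for f in head.split(",")]
            if len(fields) == 3:
                compartment, _datatype, name = fields
            elif len(fields) == 2:
                compartment, name = fields
            else:
                raise ValueError(f"cannot parse partition line: {line}")
            rng = rng.strip()
            codon = None
            if "\\" in rng:
                rng, codon_s = rng.split("\\")
                codon = int(codon_s)
            lo, hi = rng.strip().split("-")
            entries.append(PartitionEntry(name, int(lo) - 1, int(hi),
                                          compartment, codon))
    return PartitionMap(entries)


def write_partitions(pmap: PartitionMap, path) -> None:
    with open(path, "w") as fh:
        for e in pmap:
            rng = f"{e.start + 1}-{e.end}"
            if e.codon_position is not None:
                rng += f"\\{e.codon_position}"
            fh.write(f"{e.compartment}, DNA, {e.name} = {rng}\n")


def read_calibrations(path, tree_taxa: set | None = None) -> list[CalibrationConstraint]:
    """Tab-separated calibrations: name, comma-joined taxa, stem|crown,
    fixed|min, age (MY).  Lines starting with '#' are comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, taxa_s, attachment, kind, age_s = line.split("\t")
            taxa = tuple(t.strip() for t in taxa_s.split(","))
            if tree_taxa is not None:
                unknown = set(taxa) - set(tree_taxa)
                if unknown:
                    raise LabelError(f"calibration {name}: unknown taxa {sorted(unknown)}")
            out.append(CalibrationConstraint(name, taxa, attachment.strip(),
                                             kind.strip(), float(age_s)))
    _check_calibration_conflicts(out)
    return out


def _check_calibration_conflicts(constraints: list[CalibrationConstraint]) -> None:
    by_node: dict[tuple, list[CalibrationConstraint]] = {}
    for c in constraints:
        by_node.setdefault((frozenset(c.mrca_taxa), c.attachment), []).append(c)
    for key, group in by_node.items():
        fixed = [c for c in group if c.kind == "fixed"]
        mins = [c for c in group if c.kind == "min"]
        if fixed and mins and any(m.age > min(f.age for f in fixed) for m in mins):
            raise ValueError(
                f"conflicting calibrations on node {sorted(key[0])}: "
                f"min age exceeds fixed age")
        if len(fixed) > 1 and len({c.age for c in fixed}) > 1:
            raise ValueError(f"multiple different fixed ages on node {sorted(key[0])}")


def subset_matrix(matrix: CharacterMatrix, taxa: list[str]) -> CharacterMatrix:
    """Restrict a matrix to a taxon subset; columns and partitions unchanged.

    Partitions left with no observed data are reported via a warning.
    """
    unknown = set(taxa) - set(matrix.taxa)
    if unknown:
        raise LabelError(f"unknown taxa: {sorted(unknown)}")
    if len(taxa) < 2:
        raise ValueError("matrix requires at least 2 taxa")
    idx = [matrix.taxa.index(t) for t in taxa]
    seqs = [matrix.data[i].tobytes().decode() for i in idx]
    out = CharacterMatrix(list(taxa), seqs, matrix.alphabet, matrix.partitions)
    if matrix.partitions is not None:
        miss = out.missing_mask()
        empty = [e.name for e in matrix.partitions
                 if miss[:, e.start:e.end].all()]
        if empty:
            warnings.warn(f"partitions entirely missing after subsetting: {empty}")
    return out
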