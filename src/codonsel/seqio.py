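"""Sequence and tree I/O plus protein-guided codon back-translation.

Alignments are held in :class:`CodonAlignment`; species trees with a
foreground/background branch labelling in :class:`SpeciesTree` (a thin layer
over :mod:`dendropy`). All coordinates in the package are 1-based: codon i
occupies nucleotides 3i-2..3i.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

from . import genetics

__all__ = [
    "CodonAlignment",
    "SpeciesTree",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "backtranslate",
    "BacktranslationError",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping.

    Sequences are upper-cased; duplicate identifiers and empty records are
    errors. The identifier is the header token before the first whitespace.
    """
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    handle = io.StringIO(path) if isinstance(path, str) and path.startswith(">") else open(path)
    with handle:
        for line in handle:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    _store_record(seqs, name, chunks)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ValueError("FASTA record with empty identifier")
                chunks = []
            else:
                if name is None:
                    raise ValueError("sequence data before first FASTA header")
                chunks.append(line)
        if name is not None:
            _store_record(seqs, name, chunks)
    if not seqs:
        raise ValueError("no FASTA records found")
    return seqs


def _store_record(seqs: dict[str, str], name: str, chunks: list[str]) -> None:
    if name in seqs:
        raise ValueError(f"duplicate FASTA identifier: {name!r}")
    seq = "".join(chunks).upper()
    if not seq:
        raise ValueError(f"empty FASTA record: {name!r}")
    seqs[name] = seq


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    """Write sequences as FASTA with fixed line wrapping (byte-reproducible)."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

_ALLOWED = set("ACGTN-")


@dataclass
class CodonAlignment:
    """An in-frame aligned set of coding sequences.

    taxa hold the ordered identifiers, sequences the aligned DNA strings
    (equal length, multiple of 3, alphabet A/C/G/T/N/-).
    """

    taxa: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.taxa) != set(self.sequences):
            raise ValueError("taxa and sequence keys disagree")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        (self._length,) = lengths
        if self._length % 3 != 0:
            raise ValueError(f"alignment length {self._length} is not a multiple of 3")
        for t, s in self.sequences.items():
            bad = set(s) - _ALLOWED
            if bad:
                raise ValueError(f"illegal characters {sorted(bad)} in sequence {t!r}")

    @property
    def length(self) -> int:
        """Alignment length in nucleotides."""
        return self._length

    @property
    def n_codons(self) -> int:
        return self._length // 3

    def codon(self, taxon: str, position: int) -> str:
        """Codon at 1-based codon position."""
        if not 1 <= position <= self.n_codons:
            raise IndexError(f"codon position {position} outside [1, {self.n_codons}]")
        i = 3 * (position - 1)
        return self.sequences[taxon][i : i + 3]

    def to_protein(self) -> dict[str, str]:
        """Translate every sequence; '-' for all-gap codons, 'X' for ambiguity."""
        return {t: genetics.translate(self.sequences[t]) for t in self.taxa}

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        seqs = read_fasta(path)
        return cls(list(seqs), seqs)

    def write(self, path) -> None:
        write_fasta({t: self.sequences[t] for t in self.taxa}, path)


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

class SpeciesTree:
    """Rooted tree with branch lengths and a foreground branch labelling.

    Branch lengths are expected substitutions per codon site. A branch is
    foreground iff every tip descendant of its child node is in the
    designated foreground taxon set, which also flags the terminal branches
    of foreground tips; this labels a non-monophyletic foreground group
    branch by branch without touching the paths connecting it.
    """

    def __init__(self, tree: dendropy.Tree, foreground_taxa: set[str] | None = None):
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels in tree")
        self.taxa = labels
        self.foreground_taxa: frozenset[str] = frozenset()
        if foreground_taxa:
            self.tag_foreground(foreground_taxa)

    @classmethod
    def from_newick(cls, source, foreground_taxa=None) -> "SpeciesTree":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            data = Path(source).read_text()
        else:
            data = str(source)
        tree = dendropy.Tree.get(
            data=data, schema="newick", rooting="default-rooted",
            preserve_underscores=True,
        )
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                edge.length = 0.0
            if edge.length is not None and edge.length < 0:
                raise ValueError(
                    f"negative branch length on branch above "
                    f"{_node_name(edge.head_node)!r}"
                )
        return cls(tree, foreground_taxa)

    def tag_foreground(self, taxa) -> "SpeciesTree":
        """Flag foreground branches from a foreground taxon set (in place)."""
        taxa = frozenset(taxa)
        unknown = taxa - set(self.taxa)
        if unknown:
            raise ValueError(f"foreground taxa not in tree: {sorted(unknown)}")
        self.foreground_taxa = taxa
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node.tip_set = frozenset({node.taxon.label})
            else:
                node.tip_set = frozenset().union(*(c.tip_set for c in node.child_nodes()))
            node.is_foreground = bool(taxa) and node.tip_set <= taxa
        return self

    def foreground_branch_count(self) -> int:
        return sum(
            1
            for n in self.tree.preorder_node_iter()
            if n is not self.tree.seed_node and getattr(n, "is_foreground", False)
        )

    def n_tips(self) -> int:
        return len(self.taxa)

    def write_newick(self, path) -> None:
        Path(path).write_text(
            self.tree.as_string(schema="newick", suppress_rooting=True)
        )


def read_newick(path, foreground_taxa=None) -> SpeciesTree:
    return SpeciesTree.from_newick(path, foreground_taxa)


def _node_name(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or "<internal>"


# ---------------------------------------------------------------------------
# Back-translation (protein-guided codon alignment)
# ---------------------------------------------------------------------------

class BacktranslationError(ValueError):
    pass


def backtranslate(protein_alignment: dict[str, str], cds_by_taxon: dict[str, str]) -> CodonAlignment:
    """Thread unaligned CDS onto a protein alignment, column by column.

    Each amino-acid column maps to the codon that encoded it; protein gaps
    map to '---'. A single trailing stop codon on the CDS is trimmed;
    internal stops and translation mismatches are fatal, naming the taxon
    and the 1-based residue at fault.
    """
    missing = set(protein_alignment) - set(cds_by_taxon)
    if missing:
        raise BacktranslationError(f"no CDS for taxa: {sorted(missing)}")
    out: dict[str, str] = {}
    for taxon, prot in protein_alignment.items():
        cds = cds_by_taxon[taxon].upper()
        if len(cds) % 3 != 0:
            raise BacktranslationError(
                f"CDS length {len(cds)} for {taxon!r} is not a multiple of 3"
            )
        if len(cds) >= 3 and cds[-3:] in genetics.STOP_CODONS:
            cds = cds[:-3]
        ungapped = prot.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise BacktranslationError(
                f"{taxon!r}: CDS encodes {len(cds) // 3} residues but the "
                f"ungapped protein has {len(ungapped)}"
            )
        codons = []
        k = 0  # 0-based index into ungapped protein / codon list
        for col, aa in enumerate(prot, start=1):
            if aa == "-":
                codons.append("---")
                continue
            codon = cds[3 * k : 3 * k + 3]
            trans = genetics.translate_codon(codon)
            if trans == "*":
                raise BacktranslationError(
                    f"{taxon!r}: internal stop codon {codon} at residue {k + 1}"
                )
            if aa.upper() != trans and not (aa.upper() == "X" or trans == "X"):
                raise BacktranslationError(
                    f"{taxon!r}: codon {codon} translates to {trans}, protein "
                    f"has {aa.upper()} at residue {k + 1} (column {col})"
                )
            codons.append(codon)
            k += 1
        out[taxon] = "".join(codons)
    return CodonAlignment(list(protein_alignment), out)
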