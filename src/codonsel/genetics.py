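"""Standard genetic code tables and amino-acid property classes.

The codon state space used throughout the package is the 61 sense codons of
the standard genetic code, indexed lexicographically (AAA=0 ... TTT=60 with
the three stop codons removed). Stop codons are excluded from every rate
matrix and simulation, matching the convention of codon-model software such
as codeml.
"""

from __future__ import annotations

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)

#: the 61 sense codons in lexicographic order
CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in STOP_CODONS
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

#: amino acid encoded by each sense codon, parallel to CODONS
CODON_AA: tuple[str, ...] = tuple(_standard.forward_table[c] for c in CODONS)

N_CODONS = len(CODONS)  # 61

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(n1: str, n2: str) -> bool:
    """True if n1->n2 is a purine<->purine or pyrimidine<->pyrimidine change."""
    return (n1 in _PURINES and n2 in _PURINES) or (
        n1 in _PYRIMIDINES and n2 in _PYRIMIDINES
    )


def translate_codon(codon: str) -> str:
    """Translate one codon; 'X' for anything containing N or a gap, '*' for stops."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    if codon == "---":
        return "-"
    if codon in CODON_INDEX:
        return CODON_AA[CODON_INDEX[codon]]
    return "X"


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string codon by codon."""
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3))


#: deterministic codon choice per amino acid (first sense codon in
#: lexicographic order) used when a specific residue must be written back
#: into a nucleotide alignment
CANONICAL_CODON: dict[str, str] = {}
for _c, _a in zip(CODONS, CODON_AA):
    CANONICAL_CODON.setdefault(_a, _c)


# ---------------------------------------------------------------------------
# Amino-acid property classes
# ---------------------------------------------------------------------------
# Four side-chain classes: hydrophobic, polar-uncharged (described as
# "hydrophilic" against a hydrophobic partner and "neutral" against a charged
# one), basic, acidic. Glycine is grouped with the hydrophobics, histidine
# with the basics.

HYDROPHOBIC = "hydrophobic"
POLAR = "polar"  # uncharged hydrophilic / neutral
BASIC = "basic"
ACIDIC = "acidic"

AA_PROPERTY_CLASS: dict[str, str] = {
    **{aa: HYDROPHOBIC for aa in "GAVLIPFMW"},
    **{aa: POLAR for aa in "STCYNQ"},
    **{aa: BASIC for aa in "KRH"},
    **{aa: ACIDIC for aa in "DE"},
}

_CHARGED = {BASIC, ACIDIC}


def property_class(aa: str) -> str:
    """Side-chain property class of a standard amino-acid letter."""
    aa = aa.upper()
    try:
        return AA_PROPERTY_CLASS[aa]
    except KeyError:
        raise ValueError(f"unknown amino acid letter: {aa!r}") from None


def property_label(cls: str, other: str) -> str:
    """Human-readable class name, phrased relative to the other side of a change.

    The polar-uncharged class reads as "hydrophilic" when contrasted with a
    hydrophobicity change and as "neutral" when contrasted with a charge
    change, which is how such substitutions are conventionally described.
    """
    if cls == POLAR:
        return "neutral" if other in _CHARGED else "hydrophilic"
    return cls
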