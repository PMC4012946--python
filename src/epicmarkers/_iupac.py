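"""IUPAC nucleotide ambiguity tables shared across the package."""

from __future__ import annotations

from Bio.Seq import Seq

GAP = "-"

#: code -> set of unambiguous bases it denotes
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

UNAMBIGUOUS = frozenset("ACGT")

#: two-fold ambiguity codes — the signature of a heterozygous site in a
#: diploid Sanger trace (both alleles visible as a double peak)
TWOFOLD = frozenset("RYSWKM")


def base_set(code: str) -> frozenset[str]:
    """Expand one IUPAC code to its set of unambiguous bases."""
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC nucleotide code: {code!r}") from None


def set_code(bases: frozenset[str] | set[str]) -> str:
    """Minimal IUPAC code covering a set of unambiguous bases."""
    try:
        return SET_TO_CODE[frozenset(bases)]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(bases)!r}") from None


def revcomp(seq: str) -> str:
    """Reverse complement, ambiguity codes included (R<->Y etc.)."""
    return str(Seq(seq).reverse_complement())


def count_ambiguous(seq: str) -> int:
    """Number of residues outside {A,C,G,T}, case-insensitive."""
    return sum(1 for ch in seq.upper() if ch not in UNAMBIGUOUS)
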