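"""Small nucleotide/peptide sequence helpers shared across modules."""

from __future__ import annotations

from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide sequence (standard code, '*' for stops).

    Trailing bases that do not fill a codon are ignored.
    """
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def codons(seq: str) -> list[str]:
    usable = len(seq) - len(seq) % 3
    return [seq[i : i + 3] for i in range(0, usable, 3)]


def is_intact_orf(cds: str) -> bool:
    """ATG start, terminal stop, no internal stop, length divisible by 3."""
    if len(cds) % 3 != 0 or len(cds) < 6:
        return False
    cdn = codons(cds)
    if cdn[0] != "ATG" or cdn[-1] not in STOP_CODONS:
        return False
    return not any(c in STOP_CODONS for c in cdn[1:-1])


def internal_stop_positions(cds: str) -> list[int]:
    """Codon indices (0-based) of internal stops; terminal codon excluded."""
    cdn = codons(cds)
    return [i for i, c in enumerate(cdn[:-1]) if c in STOP_CODONS]
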