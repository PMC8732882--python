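"""Vertebrate mitochondrial genetic code.

The vertebrate mitochondrial code (NCBI translation table 2) differs from
the standard code in four codons: AGA and AGG are stops rather than
arginine, ATA codes methionine, and TGA codes tryptophan.  Mitochondrial
protein-coding genes may initiate at any ATN codon and may end on an
incomplete stop (a trailing T or TA completed to UAA by polyadenylation
of the mRNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

_VERT_MITO = CodonTable.unambiguous_dna_by_id[2]

#: Start codons of the form A-T-N accepted for mitochondrial PCGs.
ATN_STARTS = frozenset({"ATA", "ATC", "ATG", "ATT"})

_BASES = "TCAG"

_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


def _full_codon_map() -> dict[str, str]:
    table = {}
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                codon = b1 + b2 + b3
                if codon in _VERT_MITO.stop_codons:
                    table[codon] = "*"
                else:
                    table[codon] = _VERT_MITO.forward_table[codon]
    return table


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table with start/stop sets.

    The default instance is the vertebrate mitochondrial code; ``codon_map``
    maps all 64 DNA codons to one-letter amino acids with ``*`` for stops.
    """

    id: str = "vertebrate_mitochondrial"
    start_codons: frozenset[str] = ATN_STARTS
    stop_codons: frozenset[str] = frozenset(_VERT_MITO.stop_codons)
    codon_map: dict[str, str] = field(default_factory=_full_codon_map)

    def translate(self, codon: str) -> str:
        codon = codon.upper().replace("U", "T")
        if len(codon) != 3 or any(b not in "ACGT" for b in codon):
            raise ValueError(f"not a DNA codon: {codon!r}")
        return self.codon_map[codon]

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == "*"

    def amino_acid_3letter(self, codon: str) -> str:
        aa = self.translate(codon)
        if aa == "*":
            raise ValueError(f"{codon} is a stop codon")
        return _THREE_LETTER[aa]

    def synonymous_families(self) -> dict[str, list[str]]:
        """Map each amino acid (one-letter) to its list of sense codons."""
        fams: dict[str, list[str]] = {}
        for codon, aa in sorted(self.codon_map.items()):
            if aa == "*":
                continue
            fams.setdefault(aa, []).append(codon)
        return fams


VERTEBRATE_MITO = GeneticCode()
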