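"""Annotated rearrangement records (AIRR-style rows)."""

from __future__ import annotations

from dataclasses import dataclass, field

from .germline import translate

#: one fixed codon per amino acid, for deterministic reverse translation
_PREFERRED_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "AGA", "S": "AGC", "T": "ACT", "V": "GTG",
    "W": "TGG", "Y": "TAT",
}


def reverse_translate(aa: str) -> str:
    """Deterministic reverse translation: one fixed codon per residue."""
    return "".join(_PREFERRED_CODON[r] for r in aa)


@dataclass
class ChainRecord:
    """One annotated heavy- or light-chain rearrangement.

    ``v_call``/``d_call``/``j_call`` are ordered lists of tied best allele
    names (lexicographic within a tie).  The junction runs from the conserved
    V cysteine codon through the conserved J W/F codon inclusive; ``cdr3_aa``
    is the junction translation minus those two anchors.  ``mutation_rate``
    is V-region germline mismatches over aligned germline length, the
    junction excluded on both counts.
    """

    sequence_id: str
    v_call: list[str]
    d_call: list[str]
    j_call: list[str]
    junction: str = ""
    junction_aa: str = ""
    cdr3_aa: str = ""
    productive: bool = False
    patient_id: str = ""
    cell_id: str = ""
    locus: str = ""
    v_mutation_count: int = 0
    v_germline_aligned_length: int = 0
    cdr3_shm: int | None = None
    isotype: str | None = None
    region_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)
    extras: dict[str, str] = field(default_factory=dict)

    @property
    def mutation_rate(self) -> float | None:
        if self.v_germline_aligned_length == 0:
            return None
        return self.v_mutation_count / self.v_germline_aligned_length

    @property
    def has_junction(self) -> bool:
        return bool(self.junction)

    def junction_consistent(self) -> bool:
        """True unless junction_aa contradicts the junction translation."""
        if not self.junction or len(self.junction) % 3 != 0:
            return True
        return self.junction_aa == translate(self.junction)
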