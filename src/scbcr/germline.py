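"""Germline immunoglobulin segment handling.

Immunoglobulin variable domains are assembled from germline V, (D,) and J
gene segments.  This module parses IMGT-style allele names (``IGHV1-18*04``),
loads germline segment libraries from FASTA plus a sidecar anchor table, and
exposes an indexed :class:`GermlineDatabase` used by the annotator and the
simulator.

Anchor conventions
------------------
Every V segment carries the position of the conserved second-cysteine codon
(the 5' boundary of the junction); every J segment carries the position of
the conserved [W|F]-G-x-G motif (whose first codon is the 3' junction
boundary).  Anchor positions travel in a sidecar TSV rather than being
re-derived from gapped IMGT numbering.  All coordinates are 0-based,
half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

LOCI = ("IGH", "IGK", "IGL")
SEGMENT_TYPES = ("V", "D", "J")

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(nt: str) -> str:
    """Translate a nucleotide string with the standard genetic code.

    Trailing partial codons are ignored; stop codons become ``*``.
    ``translate("")`` is ``""``.
    """
    nt = nt.upper()
    return "".join(
        _CODON_TABLE.get(nt[i : i + 3], "X") for i in range(0, len(nt) - len(nt) % 3, 3)
    )


class AlleleNameError(ValueError):
    """Raised for strings that do not parse as IMGT-style allele names."""


@dataclass(frozen=True)
class AlleleName:
    """Parsed IMGT-style allele name.

    ``IGHV1-18*04`` -> locus ``IGH``, segment_type ``V``, family ``IGHV1``,
    gene ``IGHV1-18``, allele ``"04"``.  The allele component may be absent.
    """

    locus: str
    segment_type: str
    family: str
    gene: str
    allele: str | None

    def __str__(self) -> str:
        return format_allele_name(self)


_ALLELE_RE = re.compile(
    r"^(?P<locus>IG[HKL])(?P<type>[VDJ])"
    r"(?P<famnum>\d+)"
    r"(?P<genetail>(?:[-/][\w.]+)*)"
    r"(?:\*(?P<allele>\d+))?$"
)


def parse_allele_name(name: str) -> AlleleName:
    """Parse an IMGT-style allele name into its components.

    Raises :class:`AlleleNameError` if the string does not start with
    ``IG[HKL][VDJ]`` or otherwise fails the nomenclature pattern.
    """
    if not name:
        raise AlleleNameError("empty allele name")
    m = _ALLELE_RE.match(name)
    if m is None:
        raise AlleleNameError(f"not an IMGT-style allele name: {name!r}")
    locus = m.group("locus")
    segment_type = m.group("type")
    family = f"{locus}{segment_type}{m.group('famnum')}"
    gene = family + m.group("genetail")
    return AlleleName(
        locus=locus,
        segment_type=segment_type,
        family=family,
        gene=gene,
        allele=m.group("allele"),
    )


def format_allele_name(name: AlleleName) -> str:
    """Inverse of :func:`parse_allele_name`."""
    if name.allele is None:
        return name.gene
    return f"{name.gene}*{name.allele}"


@dataclass
class GermlineSegment:
    """One germline V, D or J allele with its sequence and anchors.

    ``cys_codon_start`` (V only) is the 0-based start of the conserved
    second-cysteine codon; ``j_motif_start`` (J only) the start of the
    [W|F]-G-x-G motif.  ``reading_frame_offset`` is ``j_motif_start mod 3``
    for J segments.  Optional CDR1/CDR2 spans support simplified framework /
    CDR region reporting on annotated queries.
    """

    allele_id: str
    locus: str
    segment_type: str
    sequence: str
    cys_codon_start: int | None = None
    j_motif_start: int | None = None
    reading_frame_offset: int | None = None
    cdr1_span: tuple[int, int] | None = None
    cdr2_span: tuple[int, int] | None = None
    name: AlleleName = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.name = parse_allele_name(self.allele_id)
        self.validate()

    def validate(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.allele_id}: empty sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(
                f"{self.allele_id}: non-ACGT characters {sorted(bad)} in sequence"
            )
        if self.locus not in LOCI:
            raise ValueError(f"{self.allele_id}: bad locus {self.locus}")
        if self.segment_type not in SEGMENT_TYPES:
            raise ValueError(f"{self.allele_id}: bad segment type {self.segment_type}")
        if self.segment_type == "V":
            if self.cys_codon_start is None:
                raise ValueError(f"{self.allele_id}: V segment missing cys_codon_start")
            codon = self.sequence[self.cys_codon_start : self.cys_codon_start + 3]
            if translate(codon) != "C":
                raise ValueError(
                    f"{self.allele_id}: codon at cys_codon_start translates to "
                    f"{translate(codon)!r}, expected 'C'"
                )
        if self.segment_type == "J":
            if self.j_motif_start is None:
                raise ValueError(f"{self.allele_id}: J segment missing j_motif_start")
            codon = self.sequence[self.j_motif_start : self.j_motif_start + 3]
            if translate(codon) not in ("W", "F"):
                raise ValueError(
                    f"{self.allele_id}: motif codon translates to "
                    f"{translate(codon)!r}, expected W or F"
                )
            if self.reading_frame_offset is None:
                self.reading_frame_offset = self.j_motif_start % 3

    @property
    def v_tail_length(self) -> int:
        """Germline nucleotides 3' of the conserved cysteine codon (V only)."""
        if self.segment_type != "V" or self.cys_codon_start is None:
            raise ValueError("v_tail_length is defined for anchored V segments only")
        return len(self.sequence) - (self.cys_codon_start + 3)


def read_anchor_table(path: str | Path) -> dict[str, dict[str, int]]:
    """Read the sidecar anchor TSV: one row per allele, integer columns.

    Recognised columns: ``cys_codon_start``, ``j_motif_start``,
    ``reading_frame_offset``, ``cdr1_start``, ``cdr1_end``, ``cdr2_start``,
    ``cdr2_end``.  Empty cells mean "not applicable".
    """
    anchors: dict[str, dict[str, int]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            allele_id = row.pop("allele_id")
            anchors[allele_id] = {k: int(v) for k, v in row.items() if v != ""}
    return anchors


def read_germline_fasta(
    path: str | Path, anchor_table: dict[str, dict[str, int]] | str | Path
) -> list[GermlineSegment]:
    """Load germline segments from FASTA with anchors from a sidecar table.

    FASTA headers are allele names.  Records whose required anchors are
    missing or inconsistent are rejected with a logged reason; duplicate
    allele ids and non-ACGT characters raise.
    """
    if not isinstance(anchor_table, dict):
        anchor_table = read_anchor_table(anchor_table)
    segments: list[GermlineSegment] = []
    seen: set[str] = set()
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        allele_id = rec.id
        if allele_id in seen:
            raise ValueError(f"duplicate allele_id {allele_id!r} in {path}")
        seen.add(allele_id)
        seq = str(rec.seq).upper()
        if set(seq) - set("ACGT"):
            raise ValueError(f"record {allele_id!r}: non-ACGT character in sequence")
        try:
            name = parse_allele_name(allele_id)
        except AlleleNameError as exc:
            logger.warning("rejecting %s: %s", allele_id, exc)
            continue
        a = anchor_table.get(allele_id, {})
        cdr1 = (
            (a["cdr1_start"], a["cdr1_end"]) if "cdr1_start" in a and "cdr1_end" in a else None
        )
        cdr2 = (
            (a["cdr2_start"], a["cdr2_end"]) if "cdr2_start" in a and "cdr2_end" in a else None
        )
        try:
            segments.append(
                GermlineSegment(
                    allele_id=allele_id,
                    locus=name.locus,
                    segment_type=name.segment_type,
                    sequence=seq,
                    cys_codon_start=a.get("cys_codon_start"),
                    j_motif_start=a.get("j_motif_start"),
                    reading_frame_offset=a.get("reading_frame_offset"),
                    cdr1_span=cdr1,
                    cdr2_span=cdr2,
                )
            )
        except ValueError as exc:
            logger.warning("rejecting %s: %s", allele_id, exc)
    if n_records == 0:
        logger.warning("germline FASTA %s contains no records", path)
    return segments


class GermlineDatabase:
    """Germline segments indexed by locus and segment type."""

    def __init__(self, segments: Iterable[GermlineSegment]):
        self.segments: dict[str, GermlineSegment] = {}
        self._by_locus_type: dict[tuple[str, str], list[GermlineSegment]] = {}
        for seg in segments:
            if seg.allele_id in self.segments:
                raise ValueError(f"duplicate allele_id {seg.allele_id!r}")
            self.segments[seg.allele_id] = seg
            self._by_locus_type.setdefault((seg.locus, seg.segment_type), []).append(seg)

    def __len__(self) -> int:
        return len(self.segments)

    def __getitem__(self, allele_id: str) -> GermlineSegment:
        return self.segments[allele_id]

    def __contains__(self, allele_id: str) -> bool:
        return allele_id in self.segments

    def select(self, locus: str | None = None, segment_type: str | None = None) -> list[GermlineSegment]:
        out = []
        for (loc, st), segs in sorted(self._by_locus_type.items()):
            if locus is not None and loc != locus:
                continue
            if segment_type is not None and st != segment_type:
                continue
            out.extend(segs)
        return sorted(out, key=lambda s: s.allele_id)

    def loci(self) -> list[str]:
        return sorted({loc for loc, _ in self._by_locus_type})


def default_germline_paths() -> tuple[Path, Path]:
    """Paths of the bundled synthetic toy germline FASTA and anchor table."""
    data = resources.files("scbcr") / "data"
    return (
        Path(str(data / "synthetic_germline.fasta")),
        Path(str(data / "synthetic_germline_anchors.tsv")),
    )


def load_default_germline() -> GermlineDatabase:
    """Load the bundled synthetic toy germline set.

    The bundled set is synthetic: IMGT-style allele names over sequences
    generated once with a fixed RNG, with the anchor structure (conserved
    Cys, [W|F]-G-x-G motif) of real immunoglobulin segments.  It exists to
    exercise the pipeline end-to-end, not to annotate real reads.
    """
    fasta, anchors = default_germline_paths()
    return GermlineDatabase(read_germline_fasta(fasta, anchors))
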