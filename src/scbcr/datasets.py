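"""Worked-example data: the published shared-clonotype table of a
12-patient anti-NMDAR encephalitis CSF single-cell BCR cohort.

The study behind this table reported four clonotypes shared across
patients, three of which carry the recurrent heavy-chain clone
IGHV1-18*04 / IGHJ3*02 with CDR3 ``ARVGSKYGFETFDI`` (length 14, the modal
heavy CDR3 length in that cohort).  Each table row is expanded here into
one complete cell (one heavy + one light chain) per listed patient,
13 cells in total, carrying the printed V/D/J allele calls and CDR3 amino
acids.  Junction nucleotides are back-translated deterministically so the
records are internally consistent; they are examples of *annotated* output,
not raw reads.
"""

from __future__ import annotations

from .cells import Cell, assemble_cells
from .records import ChainRecord, reverse_translate

#: (patients, heavy (v, d-list, j, cdr3, cdr3_shm), light (v, j-list, cdr3, cdr3_shm))
_SHARED_CLONOTYPE_ROWS = [
    (
        ["PA21", "PA22", "PA23", "PA25", "PA29"],
        ("IGHV1-18*04", ["IGHD1-26*01", "IGHD2-2*03", "IGHD2-8*01"], "IGHJ3*02",
         "ARVGSKYGFETFDI", 0),
        (["IGLV1-44*01"], ["IGLJ3*02"], "AAWDDSLNGPV", 0),
    ),
    (
        ["PA21", "PA22", "PA23"],
        ("IGHV1-18*04", ["IGHD1-26*01", "IGHD2-2*03", "IGHD2-8*01"], "IGHJ3*02",
         "ARVGSKYGFETFDI", 0),
        (["IGLV1-40*01", "IGLV1-40*02"], ["IGLJ3*02"], "QSYDRSLSGYWV", 1),
    ),
    (
        ["PA8", "PA22", "PA30"],
        ("IGHV1-18*04", ["IGHD1-26*01", "IGHD2-2*03", "IGHD2-8*01"], "IGHJ3*02",
         "ARVGSKYGFETFDI", 0),
        (["IGLV1-44*01"], ["IGLJ2*01", "IGLJ3*01"], "AAWDDSLTGVV", 2),
    ),
    (
        ["PA11", "PA31"],
        ("IGHV4-39*01", ["IGHD6-6*01"], "IGHJ4*02", "ARRSSGVRIAARRPFDC", 0),
        (["IGLV2-11*01"], ["IGLJ3*02"], "SSYVRAWV", 1),
    ),
]

#: the recurrent heavy-chain CDR3 of the cohort (modal length, 14 residues)
COMMON_CLONE_CDR3 = "ARVGSKYGFETFDI"


def _junction(cdr3: str, terminal: str) -> tuple[str, str]:
    aa = "C" + cdr3 + terminal
    return reverse_translate(aa), aa


def shared_clonotype_example_records() -> list[ChainRecord]:
    """The 13 paired-chain cells of the shared-clonotype table, as records."""
    records: list[ChainRecord] = []
    for row_idx, (patients, heavy, light) in enumerate(_SHARED_CLONOTYPE_ROWS, start=1):
        hv, hd, hj, hcdr3, hshm = heavy
        lv, lj, lcdr3, lshm = light
        for patient in patients:
            cell_id = f"{patient}_row{row_idx}"
            h_nt, h_aa = _junction(hcdr3, "W")
            l_nt, l_aa = _junction(lcdr3, "F")
            records.append(
                ChainRecord(
                    sequence_id=f"{cell_id}_IGH",
                    v_call=[hv], d_call=list(hd), j_call=[hj],
                    junction=h_nt, junction_aa=h_aa, cdr3_aa=hcdr3,
                    productive=True, patient_id=patient, cell_id=cell_id,
                    locus="IGH", v_mutation_count=0,
                    v_germline_aligned_length=141, cdr3_shm=hshm,
                )
            )
            records.append(
                ChainRecord(
                    sequence_id=f"{cell_id}_IGL",
                    v_call=list(lv), d_call=[], j_call=list(lj),
                    junction=l_nt, junction_aa=l_aa, cdr3_aa=lcdr3,
                    productive=True, patient_id=patient, cell_id=cell_id,
                    locus="IGL", v_mutation_count=0,
                    v_germline_aligned_length=141, cdr3_shm=lshm,
                )
            )
    return records


def shared_clonotype_example_cells() -> list[Cell]:
    """The same worked example assembled into 13 complete cells."""
    return assemble_cells(shared_clonotype_example_records())
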