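"""Cell assembly and completeness classification.

A cell bundles the heavy (IGH) and light (IGK/IGL) chain records sharing one
(patient_id, cell_id).  A cell is *complete* when both chain classes are
present and at most one of them is duplicated — i.e. one heavy with one or
more lights, or one light with one or more heavies.  Cells with two or more
chains of both classes at once (likely doublets), or with only one chain
class, are *incomplete*: their paired antibody cannot be determined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import ChainRecord

COMPLETE = "complete"
INCOMPLETE = "incomplete"


@dataclass
class Cell:
    cell_id: str
    patient_id: str
    heavy_chains: list[ChainRecord] = field(default_factory=list)
    light_chains: list[ChainRecord] = field(default_factory=list)
    completeness: str = INCOMPLETE

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_chains)

    @property
    def n_light(self) -> int:
        return len(self.light_chains)


def classify_cell_completeness(cell: Cell) -> str:
    """Apply the completeness rule to a cell's chain cardinalities."""
    nh, nl = cell.n_heavy, cell.n_light
    if nh >= 1 and nl >= 1 and (nh == 1 or nl == 1):
        return COMPLETE
    return INCOMPLETE


def assemble_cells(records: list[ChainRecord]) -> list[Cell]:
    """Group records into cells by (patient_id, cell_id) and classify them.

    Records sharing a cell_id but carrying different patient_ids indicate a
    corrupted input and raise.  Chains partition by locus class: IGH is
    heavy; IGK and IGL are light.
    """
    by_cell: dict[tuple[str, str], Cell] = {}
    patient_of: dict[str, str] = {}
    for rec in records:
        if rec.cell_id in patient_of and patient_of[rec.cell_id] != rec.patient_id:
            raise ValueError(
                f"cell_id {rec.cell_id!r} appears under patients "
                f"{patient_of[rec.cell_id]!r} and {rec.patient_id!r}"
            )
        patient_of[rec.cell_id] = rec.patient_id
        key = (rec.patient_id, rec.cell_id)
        cell = by_cell.setdefault(key, Cell(cell_id=rec.cell_id, patient_id=rec.patient_id))
        if rec.locus == "IGH":
            cell.heavy_chains.append(rec)
        else:
            cell.light_chains.append(rec)
    cells = [by_cell[k] for k in sorted(by_cell)]
    for cell in cells:
        cell.completeness = classify_cell_completeness(cell)
    return cells
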