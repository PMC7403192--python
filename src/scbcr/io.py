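"""Readers and writers for rearrangement and clonotype tables.

The on-disk rearrangement format follows the AIRR Rearrangement convention:
tab-separated UTF-8 with a header row, multi-allele calls joined by commas,
``productive`` serialised as ``T``/``F``.  Clonotype tables come in two
dialects: ``airr`` (junction_aa / cdr3_aa columns) and ``mixcr-like``
(MiXCR clone-export style, CDR3 printed with the conserved anchor residues
included).  All CDR3 strings are normalised at read time to the internal
convention: junction = conserved C through conserved W/F inclusive, CDR3 =
junction minus those two anchors.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from .germline import translate
from .records import ChainRecord

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "sequence_id",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
)

#: serialisation order for the defined fields
_FIELD_COLUMNS = (
    "sequence_id",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "cdr3_aa",
    "productive",
    "patient_id",
    "cell_id",
    "locus",
    "v_mutation_count",
    "v_germline_aligned_length",
    "cdr3_shm",
    "isotype",
)


def _join_calls(calls: list[str]) -> str:
    return ",".join(calls)


def _split_calls(value: str) -> list[str]:
    if not value or pd.isna(value):
        return []
    return [c.strip() for c in str(value).split(",") if c.strip()]


def write_rearrangement_tsv(records: Iterable[ChainRecord], path: str | Path) -> None:
    """Write records as AIRR-style TSV; unknown ``extras`` columns appended."""
    rows = []
    extra_cols: list[str] = []
    for rec in records:
        row = {
            "sequence_id": rec.sequence_id,
            "v_call": _join_calls(rec.v_call),
            "d_call": _join_calls(rec.d_call),
            "j_call": _join_calls(rec.j_call),
            "junction": rec.junction,
            "junction_aa": rec.junction_aa,
            "cdr3_aa": rec.cdr3_aa,
            "productive": "T" if rec.productive else "F",
            "patient_id": rec.patient_id,
            "cell_id": rec.cell_id,
            "locus": rec.locus,
            "v_mutation_count": rec.v_mutation_count,
            "v_germline_aligned_length": rec.v_germline_aligned_length,
            "cdr3_shm": "" if rec.cdr3_shm is None else rec.cdr3_shm,
            "isotype": rec.isotype or "",
        }
        for k, v in rec.extras.items():
            row[k] = v
            if k not in extra_cols:
                extra_cols.append(k)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_FIELD_COLUMNS) + extra_cols)
    df.to_csv(path, sep="\t", index=False)


def read_rearrangement_tsv(path: str | Path) -> list[ChainRecord]:
    """Read an AIRR-style rearrangement TSV into :class:`ChainRecord` rows.

    Raises ``ValueError`` naming the first missing mandatory column.  Rows
    whose ``junction_aa`` contradicts the translation of ``junction`` are
    kept but flagged with ``extras['junction_inconsistent'] = 'T'`` and a
    logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")
    records = []
    known = set(_FIELD_COLUMNS)
    for _, row in df.iterrows():
        rec = ChainRecord(
            sequence_id=row["sequence_id"],
            v_call=_split_calls(row["v_call"]),
            d_call=_split_calls(row["d_call"]),
            j_call=_split_calls(row["j_call"]),
            junction=row["junction"],
            junction_aa=row["junction_aa"],
            cdr3_aa=row.get("cdr3_aa", ""),
            productive=row["productive"] in ("T", "TRUE", "True", "true", "1"),
            patient_id=row.get("patient_id", ""),
            cell_id=row.get("cell_id", ""),
            locus=row.get("locus", ""),
            v_mutation_count=int(row.get("v_mutation_count") or 0),
            v_germline_aligned_length=int(row.get("v_germline_aligned_length") or 0),
            cdr3_shm=int(row["cdr3_shm"]) if row.get("cdr3_shm", "") != "" else None,
            isotype=row.get("isotype") or None,
            extras={k: row[k] for k in df.columns if k not in known},
        )
        if not rec.junction_consistent():
            rec.extras["junction_inconsistent"] = "T"
            logger.warning(
                "record %s: junction_aa %r != translation of junction %r",
                rec.sequence_id, rec.junction_aa, translate(rec.junction),
            )
        records.append(rec)
    return records


class ClonotypeRow(NamedTuple):
    """One clone-table row normalised to the internal CDR3 convention."""

    v_call: str
    j_call: str
    cdr3_aa: str
    count: int


def normalize_cdr3(cdr3: str, dialect: str) -> str:
    """Normalise a CDR3 string from a table dialect to the internal form.

    ``mixcr-like`` tables print the junction (anchors included,
    ``CARDNWGPDYW``); the anchors are stripped.  ``airr`` CDR3 columns are
    already anchor-free.  Normalisation of an already-normalised string is a
    no-op.
    """
    if dialect == "mixcr-like":
        if len(cdr3) >= 4 and cdr3[0] == "C" and cdr3[-1] in "WF":
            return cdr3[1:-1]
        return cdr3
    if dialect in ("airr", "internal"):
        return cdr3
    raise ValueError(f"unknown dialect: {dialect!r}")


_MIXCR_COLUMN_ALIASES = {
    "v_call": ("bestVGene", "bestVHit", "allVHitsWithScore", "v_call"),
    "j_call": ("bestJGene", "bestJHit", "allJHitsWithScore", "j_call"),
    "cdr3_aa": ("aaSeqCDR3", "cdr3_aa"),
    "count": ("cloneCount", "count"),
}


def read_clonotype_table(path: str | Path, dialect: str) -> list[ClonotypeRow]:
    """Read a clone table in the ``airr`` or ``mixcr-like`` dialect.

    AIRR tables use ``v_call``/``j_call`` and either ``cdr3_aa`` or
    ``junction_aa`` (anchors stripped from the latter); mixcr-like tables
    use MiXCR clone-export column names and anchor-inclusive CDR3 strings.
    Counts default to 1 where absent.
    """
    if dialect not in ("airr", "mixcr-like"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows: list[ClonotypeRow] = []
    if dialect == "airr":
        for _, row in df.iterrows():
            if "cdr3_aa" in df.columns and row["cdr3_aa"]:
                cdr3 = row["cdr3_aa"]
            elif "junction_aa" in df.columns and row["junction_aa"]:
                cdr3 = row["junction_aa"][1:-1]
            else:
                continue
            count = int(float(row.get("duplicate_count") or row.get("count") or 1))
            rows.append(ClonotypeRow(row["v_call"], row["j_call"], cdr3, max(count, 1)))
    else:
        cols = {}
        for field_name, aliases in _MIXCR_COLUMN_ALIASES.items():
            for alias in aliases:
                if alias in df.columns:
                    cols[field_name] = alias
                    break
        for required in ("v_call", "j_call", "cdr3_aa"):
            if required not in cols:
                raise ValueError(f"mixcr-like table lacks a column for {required}")
        for _, row in df.iterrows():
            cdr3 = normalize_cdr3(row[cols["cdr3_aa"]], "mixcr-like")
            count = int(float(row[cols["count"]])) if "count" in cols else 1
            rows.append(
                ClonotypeRow(row[cols["v_call"]], row[cols["j_call"]], cdr3, max(count, 1))
            )
    return rows
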