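"""Clone clustering, cross-patient common clones, shared paired clonotypes,
and CDR3 search.

Definitions (the amino-acid clustering model):

* **Clone** — heavy- or light-chain records whose V calls and J calls match
  (at allele or gene level) and whose junction translates to identical
  amino acids.  A *common clone* recurs in two or more patients.
* **Clonotype** — a paired heavy+light identity over complete cells: same
  heavy V and J, same light V and J, and identical CDR3 amino acids on both
  chains.  A *shared clonotype* spans two or more patients.

Records with tied multi-allele calls match when their call sets intersect
at the chosen level; because intersection is not transitive, clustering is
the transitive closure of the pairwise matching relation (union-find).
The D segment is not part of any key: D assignment is frequently ambiguous
(multi-D listings) and the clone definition names only V, J and the
junction amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .cells import COMPLETE, Cell
from .germline import parse_allele_name
from .io import ClonotypeRow
from .records import ChainRecord

import logging

logger = logging.getLogger(__name__)

MATCH_LEVELS = ("allele", "gene")


def call_labels(calls: Sequence[str], level: str = "allele") -> frozenset[str]:
    """Reduce a (possibly tied) call list to labels at the matching level."""
    if level == "allele":
        return frozenset(calls)
    if level == "gene":
        return frozenset(parse_allele_name(c).gene for c in calls)
    raise ValueError(f"unknown match level: {level!r}")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


@dataclass
class Clone:
    """An equivalence class of chain records under the clone definition."""

    locus: str
    v_alleles: frozenset[str]
    j_alleles: frozenset[str]
    junction_aa: str
    members: list[ChainRecord] = field(default_factory=list)

    @property
    def cdr3_aa(self) -> str:
        return self.junction_aa[1:-1] if len(self.junction_aa) >= 2 else ""

    @property
    def patients(self) -> frozenset[str]:
        return frozenset(r.patient_id for r in self.members)

    def patient_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.members:
            counts[r.patient_id] = counts.get(r.patient_id, 0) + 1
        return counts

    def key(self) -> tuple:
        return (self.locus, tuple(sorted(self.v_alleles)), tuple(sorted(self.j_alleles)),
                self.junction_aa)

    def key_str(self) -> str:
        return "{}|{}|{}|{}".format(
            self.locus, "/".join(sorted(self.v_alleles)),
            "/".join(sorted(self.j_alleles)), self.cdr3_aa,
        )


def cluster_clones(records: Iterable[ChainRecord], level: str = "allele") -> list[Clone]:
    """Partition productive, junction-bearing records into clones.

    Two records co-cluster iff they share the locus, their V call sets
    intersect at ``level``, their J call sets intersect, and their junction
    amino-acid translations are identical; the partition is the transitive
    closure of this relation.  Records lacking a junction or calls are
    excluded with a logged reason.
    """
    usable: list[ChainRecord] = []
    for rec in records:
        if not rec.junction_aa or not rec.v_call or not rec.j_call:
            logger.info("cluster_clones: excluding %s (missing junction or calls)",
                        rec.sequence_id)
            continue
        usable.append(rec)

    groups: dict[tuple[str, str], list[int]] = {}
    for i, rec in enumerate(usable):
        groups.setdefault((rec.locus, rec.junction_aa), []).append(i)

    uf = _UnionFind(len(usable))
    for indices in groups.values():
        v_sets = {i: call_labels(usable[i].v_call, level) for i in indices}
        j_sets = {i: call_labels(usable[i].j_call, level) for i in indices}
        for a_pos, i in enumerate(indices):
            for j in indices[a_pos + 1 :]:
                if v_sets[i] & v_sets[j] and j_sets[i] & j_sets[j]:
                    uf.union(i, j)

    clusters: dict[int, list[ChainRecord]] = {}
    for i, rec in enumerate(usable):
        clusters.setdefault(uf.find(i), []).append(rec)

    clones = []
    for members in clusters.values():
        v_union = frozenset().union(*(call_labels(m.v_call, level) for m in members))
        j_union = frozenset().union(*(call_labels(m.j_call, level) for m in members))
        clones.append(
            Clone(
                locus=members[0].locus,
                v_alleles=v_union,
                j_alleles=j_union,
                junction_aa=members[0].junction_aa,
                members=sorted(members, key=lambda r: r.sequence_id),
            )
        )
    clones.sort(key=lambda c: c.key())
    return clones


def find_common_clones(clones: Iterable[Clone], min_patients: int = 2) -> pd.DataFrame:
    """Clones spanning >= min_patients patients, as an occurrence table.

    One row per common clone with its per-patient member counts (the
    patients-by-clones heat-map matrix), sorted by patient span descending
    then clone key.
    """
    common = [c for c in clones if len(c.patients) >= min_patients]
    common.sort(key=lambda c: (-len(c.patients), c.key()))
    patients = sorted({p for c in common for p in c.patients})
    rows = []
    for c in common:
        counts = c.patient_counts()
        row = {
            "clone_key": c.key_str(),
            "locus": c.locus,
            "v_call": "/".join(sorted(c.v_alleles)),
            "j_call": "/".join(sorted(c.j_alleles)),
            "cdr3_aa": c.cdr3_aa,
            "n_patients": len(c.patients),
            "n_members": len(c.members),
        }
        for p in patients:
            row[p] = counts.get(p, 0)
        rows.append(row)
    columns = ["clone_key", "locus", "v_call", "j_call", "cdr3_aa",
               "n_patients", "n_members"] + patients
    return pd.DataFrame(rows, columns=columns)


@dataclass
class Clonotype:
    """A paired heavy+light identity class over complete cells."""

    heavy_v: frozenset[str]
    heavy_j: frozenset[str]
    heavy_cdr3_aa: str
    light_v: frozenset[str]
    light_j: frozenset[str]
    light_cdr3_aa: str
    heavy_d: frozenset[str] = frozenset()
    cells: list[Cell] = field(default_factory=list)

    @property
    def patients(self) -> frozenset[str]:
        return frozenset(c.patient_id for c in self.cells)

    def key(self) -> tuple:
        return (
            tuple(sorted(self.heavy_v)), tuple(sorted(self.heavy_j)), self.heavy_cdr3_aa,
            tuple(sorted(self.light_v)), tuple(sorted(self.light_j)), self.light_cdr3_aa,
        )


def find_shared_clonotypes(
    cells: Iterable[Cell], min_patients: int = 2, level: str = "allele"
) -> list[Clonotype]:
    """Group complete cells into clonotypes and keep cross-patient ones.

    Complete cells with a duplicated chain class contribute every
    heavy-by-light pairing as a candidate, but each cell counts at most once
    per clonotype group.  Matching is the transitive closure of: heavy V and
    J call sets intersect at ``level``, light V and J call sets intersect,
    and heavy and light CDR3 amino acids are identical.
    """
    pairings: list[tuple[Cell, ChainRecord, ChainRecord]] = []
    for cell in cells:
        if cell.completeness != COMPLETE:
            continue
        for h in cell.heavy_chains:
            for l in cell.light_chains:
                if h.cdr3_aa and l.cdr3_aa and h.v_call and h.j_call and l.v_call and l.j_call:
                    pairings.append((cell, h, l))

    groups: dict[tuple[str, str], list[int]] = {}
    for i, (_, h, l) in enumerate(pairings):
        groups.setdefault((h.cdr3_aa, l.cdr3_aa), []).append(i)

    uf = _UnionFind(len(pairings))
    for indices in groups.values():
        labels = {
            i: (
                call_labels(pairings[i][1].v_call, level),
                call_labels(pairings[i][1].j_call, level),
                call_labels(pairings[i][2].v_call, level),
                call_labels(pairings[i][2].j_call, level),
            )
            for i in indices
        }
        for a_pos, i in enumerate(indices):
            for j in indices[a_pos + 1 :]:
                if all(labels[i][k] & labels[j][k] for k in range(4)):
                    uf.union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(pairings)):
        clusters.setdefault(uf.find(i), []).append(i)

    clonotypes = []
    for indices in clusters.values():
        seen_cells: dict[tuple[str, str], Cell] = {}
        hv: set[str] = set()
        hj: set[str] = set()
        hd: set[str] = set()
        lv: set[str] = set()
        lj: set[str] = set()
        for i in indices:
            cell, h, l = pairings[i]
            seen_cells[(cell.patient_id, cell.cell_id)] = cell
            hv |= call_labels(h.v_call, level)
            hj |= call_labels(h.j_call, level)
            hd |= call_labels(h.d_call, level) if h.d_call else set()
            lv |= call_labels(l.v_call, level)
            lj |= call_labels(l.j_call, level)
        cell0, h0, l0 = pairings[indices[0]]
        ct = Clonotype(
            heavy_v=frozenset(hv), heavy_j=frozenset(hj), heavy_cdr3_aa=h0.cdr3_aa,
            light_v=frozenset(lv), light_j=frozenset(lj), light_cdr3_aa=l0.cdr3_aa,
            heavy_d=frozenset(hd),
            cells=[seen_cells[k] for k in sorted(seen_cells)],
        )
        if len(ct.patients) >= min_patients:
            clonotypes.append(ct)
    clonotypes.sort(key=lambda c: (-len(c.patients), c.key()))
    return clonotypes


def clonotype_table(clonotypes: Iterable[Clonotype]) -> pd.DataFrame:
    """Shared-clonotype report: patient list, heavy V/D/J + CDR3, light V/J + CDR3."""
    rows = []
    for ct in clonotypes:
        rows.append(
            {
                "patients": " ".join(sorted(ct.patients)),
                "n_patients": len(ct.patients),
                "n_cells": len(ct.cells),
                "heavy_v": "/".join(sorted(ct.heavy_v)),
                "heavy_d": "/".join(sorted(ct.heavy_d)),
                "heavy_j": "/".join(sorted(ct.heavy_j)),
                "heavy_cdr3_aa": ct.heavy_cdr3_aa,
                "light_v": "/".join(sorted(ct.light_v)),
                "light_j": "/".join(sorted(ct.light_j)),
                "light_cdr3_aa": ct.light_cdr3_aa,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patients", "n_patients", "n_cells", "heavy_v", "heavy_d", "heavy_j",
                 "heavy_cdr3_aa", "light_v", "light_j", "light_cdr3_aa"],
    )


def search_cdr3(
    target_cdr3_aa: str,
    repertoire: Iterable[ChainRecord | ClonotypeRow],
    max_mismatch: int = 0,
) -> list[dict]:
    """Find repertoire entries within Hamming distance of a target CDR3.

    Lengths must match exactly (no indels); an empty hit list means the
    target was not found.  The target must already be in the internal
    (anchor-free) convention.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    hits = []
    for entry in repertoire:
        cdr3 = entry.cdr3_aa
        if len(cdr3) != len(target_cdr3_aa):
            continue
        dist = sum(a != b for a, b in zip(cdr3, target_cdr3_aa))
        if dist <= max_mismatch:
            ident = entry.sequence_id if isinstance(entry, ChainRecord) else \
                f"{entry.v_call}|{entry.j_call}|{entry.cdr3_aa}"
            hits.append({"id": ident, "cdr3_aa": cdr3, "mismatches": dist})
    return hits


def overlap_counts(
    cohort_a: Iterable[Clone] | set, cohort_b: Iterable[Clone] | set,
    level: str | None = None,
) -> dict[str, int]:
    """Venn counts {A_only, B_only, shared} between two clone sets.

    Inputs are :class:`Clone` lists (keys derived at ``level``, default
    allele) or pre-built key sets; clone lists require a single consistent
    level for both sides.
    """
    def keys(cohort) -> set:
        items = list(cohort)
        if items and isinstance(items[0], Clone):
            lv = level or "allele"
            return {
                (c.locus, call_labels(sorted(c.v_alleles), lv),
                 call_labels(sorted(c.j_alleles), lv), c.junction_aa)
                for c in items
            }
        if level is not None and items and not isinstance(items[0], Clone):
            raise ValueError("level applies to Clone inputs only; got raw keys")
        return set(items)

    a, b = keys(cohort_a), keys(cohort_b)
    shared = a & b
    return {"A_only": len(a - shared), "B_only": len(b - shared), "shared": len(shared)}
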