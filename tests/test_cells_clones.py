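"""Cell completeness, clone clustering, shared clonotypes, CDR3 search."""

import itertools

import numpy as np
import pytest

import scbcr
from scbcr.cells import COMPLETE, INCOMPLETE, Cell
from scbcr.clones import call_labels
from scbcr.datasets import (
    COMMON_CLONE_CDR3,
    shared_clonotype_example_cells,
    shared_clonotype_example_records,
)
from scbcr.io import ClonotypeRow
from scbcr.records import ChainRecord


def _chain(locus="IGH", **kw):
    defaults = dict(
        sequence_id="s", v_call=["IGHV1-18*04"], d_call=[], j_call=["IGHJ3*02"],
        junction="TGTGCGAGATGG", junction_aa="CARW", cdr3_aa="AR",
        productive=True, patient_id="PA01", cell_id="c1", locus=locus,
    )
    defaults.update(kw)
    return ChainRecord(**defaults)


class TestCompleteness:
    @pytest.mark.parametrize(
        "n_heavy, n_light, expected",
        [
            (1, 1, COMPLETE),
            (1, 2, COMPLETE),   # one heavy, several lights
            (2, 1, COMPLETE),   # one light, several heavies
            (2, 2, INCOMPLETE),  # doublet: both classes duplicated
            (1, 0, INCOMPLETE),  # heavy only
            (0, 1, INCOMPLETE),  # light only
            (0, 0, INCOMPLETE),
            (3, 1, COMPLETE),
            (2, 3, INCOMPLETE),
        ],
    )
    def test_cardinality_rules(self, n_heavy, n_light, expected):
        cell = Cell(
            cell_id="c", patient_id="p",
            heavy_chains=[_chain() for _ in range(n_heavy)],
            light_chains=[_chain(locus="IGL") for _ in range(n_light)],
        )
        assert scbcr.classify_cell_completeness(cell) == expected

    def test_counts_partition_all_cells(self, db):
        cfg = scbcr.SimulationConfig(
            n_patients=3, cells_per_patient=20, incomplete_fraction=0.3, seed=19
        )
        cohort = scbcr.simulate_cohort(cfg, db)
        records = [
            ChainRecord(
                sequence_id=ch.sequence_id, v_call=[ch.truth.v_allele], d_call=[],
                j_call=[ch.truth.j_allele], junction_aa=ch.truth.junction_aa,
                cdr3_aa=ch.truth.junction_aa[1:-1], productive=True,
                patient_id=cell.patient_id, cell_id=cell.cell_id,
                locus=ch.truth.locus,
            )
            for cell in cohort.cells for ch in cell.chains
        ]
        cells = scbcr.assemble_cells(records)
        n_complete = sum(c.completeness == COMPLETE for c in cells)
        n_incomplete = sum(c.completeness == INCOMPLETE for c in cells)
        assert n_complete + n_incomplete == len(cells)
        truth_by_cell = {c.cell_id: c.completeness_truth for c in cohort.cells}
        for cell in cells:
            assert cell.completeness == truth_by_cell[cell.cell_id]


class TestAssembleCells:
    def test_one_cell_per_patient_cell_pair(self):
        records = [
            _chain(sequence_id="h", cell_id="c1"),
            _chain(sequence_id="l", cell_id="c1", locus="IGL"),
        ]
        cells = scbcr.assemble_cells(records)
        assert len(cells) == 1
        assert cells[0].n_heavy == 1 and cells[0].n_light == 1
        assert cells[0].completeness == COMPLETE

    def test_conflicting_patient_for_same_cell_raises(self):
        records = [
            _chain(cell_id="c1", patient_id="PA01"),
            _chain(cell_id="c1", patient_id="PA02", locus="IGL"),
        ]
        with pytest.raises(ValueError, match="c1"):
            scbcr.assemble_cells(records)

    def test_empty_input_gives_empty_list(self):
        assert scbcr.assemble_cells([]) == []

    def test_worked_example_yields_13_cells(self):
        cells = shared_clonotype_example_cells()
        assert len(cells) == 13
        assert all(c.completeness == COMPLETE for c in cells)


def brute_force_clone_partition(records, level="allele"):
    """Transitive closure of pairwise clone matching, by repeated merging."""
    def match(a, b):
        return (
            a.locus == b.locus
            and a.junction_aa == b.junction_aa
            and call_labels(a.v_call, level) & call_labels(b.v_call, level)
            and call_labels(a.j_call, level) & call_labels(b.j_call, level)
        )

    groups = [{i} for i in range(len(records))]
    changed = True
    while changed:
        changed = False
        for gi, gj in itertools.combinations(range(len(groups)), 2):
            if groups[gi] and groups[gj] and any(
                match(records[i], records[j])
                for i in groups[gi] for j in groups[gj]
            ):
                groups[gi] |= groups[gj]
                groups[gj] = set()
                changed = True
                break
    return sorted(frozenset(g) for g in groups if g)


class TestClusterClones:
    def test_cross_patient_records_with_same_key_cocluster(self):
        a = _chain(sequence_id="a", patient_id="PA01",
                   junction_aa="CARVGSKYGFETFDIW", cdr3_aa="ARVGSKYGFETFDI")
        b = _chain(sequence_id="b", patient_id="PA02", cell_id="c2",
                   junction_aa="CARVGSKYGFETFDIW", cdr3_aa="ARVGSKYGFETFDI")
        clones = scbcr.cluster_clones([a, b])
        assert len(clones) == 1
        assert clones[0].patients == {"PA01", "PA02"}

    def test_single_residue_difference_separates_clones(self):
        a = _chain(sequence_id="a", junction_aa="CARVGSKYGFETFDIW")
        b = _chain(sequence_id="b", junction_aa="CARVGSKYGFETFDVW")
        assert len(scbcr.cluster_clones([a, b])) == 2

    def test_partition_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(33)
        v_pool = ["IGHV1-18*01", "IGHV1-18*04", "IGHV3-23*01", "IGHV4-39*01"]
        j_pool = ["IGHJ3*02", "IGHJ4*02"]
        junction_pool = ["CARAW", "CARCW", "CARDW"]
        records = []
        for i in range(50):
            v_calls = list(rng.choice(v_pool, size=int(rng.integers(1, 3)),
                                      replace=False))
            records.append(_chain(
                sequence_id=f"r{i}", v_call=v_calls,
                j_call=[str(rng.choice(j_pool))],
                junction_aa=str(rng.choice(junction_pool)),
                patient_id=f"PA{rng.integers(1, 4)}", cell_id=f"c{i}",
            ))
        clones = scbcr.cluster_clones(records)
        got = {
            frozenset(records.index(m) for m in c.members) for c in clones
        }
        assert got == set(brute_force_clone_partition(records))

    def test_partition_covers_every_usable_record_once(self):
        records = shared_clonotype_example_records()
        heavy = [r for r in records if r.locus == "IGH"]
        clones = scbcr.cluster_clones(heavy)
        member_ids = [m.sequence_id for c in clones for m in c.members]
        assert sorted(member_ids) == sorted(r.sequence_id for r in heavy)

    def test_record_without_junction_excluded(self):
        a = _chain(sequence_id="a")
        b = _chain(sequence_id="b", junction_aa="", cdr3_aa="")
        clones = scbcr.cluster_clones([a, b])
        assert [m.sequence_id for c in clones for m in c.members] == ["a"]

    def test_gene_level_collapses_alleles(self):
        a = _chain(sequence_id="a", v_call=["IGHV1-18*01"])
        b = _chain(sequence_id="b", v_call=["IGHV1-18*04"])
        assert len(scbcr.cluster_clones([a, b], level="allele")) == 2
        assert len(scbcr.cluster_clones([a, b], level="gene")) == 1


class TestCommonClones:
    def test_worked_example_common_clone_spans_seven_patients(self):
        heavy = [r for r in shared_clonotype_example_records() if r.locus == "IGH"]
        table = scbcr.find_common_clones(scbcr.cluster_clones(heavy))
        top = table.iloc[0]
        assert top["cdr3_aa"] == COMMON_CLONE_CDR3
        assert top["n_patients"] == 7
        spanning = {p for p in ("PA8", "PA21", "PA22", "PA23", "PA25", "PA29", "PA30")}
        assert {p for p in spanning if top[p] > 0} == spanning

    def test_all_unique_junctions_give_empty_table(self):
        records = [
            _chain(sequence_id=f"r{i}", junction_aa=f"CAR{aa}W", cell_id=f"c{i}")
            for i, aa in enumerate("ACDEFG")
        ]
        table = scbcr.find_common_clones(scbcr.cluster_clones(records))
        assert len(table) == 0

    def test_planted_clone_detected_in_exactly_planted_patients(self, db):
        from scbcr.simulate import planted_junction_nt
        clone = scbcr.PlantedClone(
            clone_id="x", heavy_v="IGHV1-18*04", heavy_j="IGHJ3*02",
            heavy_junction_nt=planted_junction_nt("ARVGSKYGFETFDI", db["IGHJ3*02"]),
            light_v="IGLV1-44*01", light_j="IGLJ3*02",
            light_junction_nt=planted_junction_nt("AAWDDSLNGPV", db["IGLJ3*02"]),
            patient_ids=["PA02", "PA05", "PA09"], cells_each=1,
        )
        cfg = scbcr.SimulationConfig(
            n_patients=12, cells_per_patient=4, shm_rate=0.0,
            incomplete_fraction=0.0, planted_clones=[clone], seed=77,
        )
        cohort = scbcr.simulate_cohort(cfg, db)
        records = [
            scbcr.annotate_sequence(
                ch.sequence, db, sequence_id=ch.sequence_id,
                patient_id=cell.patient_id, cell_id=cell.cell_id,
            )
            for cell in cohort.cells for ch in cell.chains
        ]
        heavy = [r for r in records if r and r.locus == "IGH" and r.productive]
        table = scbcr.find_common_clones(scbcr.cluster_clones(heavy))
        hit = table[table["cdr3_aa"] == "ARVGSKYGFETFDI"]
        assert len(hit) == 1
        present = {p for p in ("PA02", "PA05", "PA09") if hit.iloc[0][p] > 0}
        assert present == {"PA02", "PA05", "PA09"}


class TestSharedClonotypes:
    def test_worked_example_finds_four_shared_clonotypes(self):
        cts = scbcr.find_shared_clonotypes(shared_clonotype_example_cells())
        assert len(cts) == 4
        assert sum(ct.heavy_cdr3_aa == COMMON_CLONE_CDR3 for ct in cts) == 3

    def test_light_cdr3_difference_separates_clonotypes(self):
        cts = scbcr.find_shared_clonotypes(shared_clonotype_example_cells())
        light_cdr3s = {ct.light_cdr3_aa for ct in cts
                       if ct.heavy_cdr3_aa == COMMON_CLONE_CDR3}
        assert {"AAWDDSLNGPV", "QSYDRSLSGYWV", "AAWDDSLTGVV"} == light_cdr3s

    def test_result_invariant_under_input_permutation(self):
        cells = shared_clonotype_example_cells()
        keys = [ct.key() for ct in scbcr.find_shared_clonotypes(cells)]
        rng = np.random.default_rng(4)
        for _ in range(3):
            perm = list(cells)
            rng.shuffle(perm)
            assert [ct.key() for ct in scbcr.find_shared_clonotypes(perm)] == keys

    def test_incomplete_cells_do_not_contribute(self):
        cells = shared_clonotype_example_cells()
        # duplicating both chains of every cell makes them all incomplete
        for cell in cells:
            cell.heavy_chains = cell.heavy_chains * 2
            cell.light_chains = cell.light_chains * 2
            cell.completeness = scbcr.classify_cell_completeness(cell)
        assert scbcr.find_shared_clonotypes(cells) == []

    def test_cell_with_two_lights_counted_once_per_group(self):
        cells = shared_clonotype_example_cells()
        # give one member cell of clonotype row 1 a second light chain copy
        target = next(c for c in cells if c.cell_id == "PA21_row1")
        dup = shared_clonotype_example_records()
        extra = next(r for r in dup if r.sequence_id == "PA21_row1_IGL")
        extra.sequence_id = "PA21_row1_IGL_b"
        target.light_chains.append(extra)
        target.completeness = scbcr.classify_cell_completeness(target)
        assert target.completeness == COMPLETE
        cts = scbcr.find_shared_clonotypes(cells)
        row1 = next(ct for ct in cts if ct.light_cdr3_aa == "AAWDDSLNGPV")
        assert sum(1 for c in row1.cells if c.cell_id == "PA21_row1") == 1


class TestSearchCdr3:
    def _table(self):
        return [
            ClonotypeRow("IGHV4-59", "IGHJ4", "ARDNWGPDY", 3),
            ClonotypeRow("IGHV1-2", "IGHJ6", "ARGGNNWNYRSWFDP", 1),
            ClonotypeRow("IGHV1-18", "IGHJ3", "ARVGSKYGFETFDV", 1),  # Hamming 1
        ]

    def test_absent_target_returns_no_hits(self):
        assert scbcr.search_cdr3("ARVGSKYGFETFDI", self._table()[:2]) == []

    def test_verbatim_target_found(self):
        table = self._table() + [ClonotypeRow("IGHV1-18*04", "IGHJ3*02",
                                              "ARVGSKYGFETFDI", 2)]
        hits = scbcr.search_cdr3("ARVGSKYGFETFDI", table)
        assert len(hits) == 1 and hits[0]["mismatches"] == 0

    def test_hamming_neighbourhood_matches_exhaustive_scan(self):
        rng = np.random.default_rng(9)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        target = "ARVGSKYGFETFDI"
        table = []
        for i in range(200):
            s = list(target)
            n_mut = int(rng.integers(0, 4))
            for pos in rng.choice(len(s), size=n_mut, replace=False):
                s[pos] = str(rng.choice(alphabet))
            table.append(ClonotypeRow("V", "J", "".join(s), 1))
        hits = scbcr.search_cdr3(target, table, max_mismatch=1)
        expected = [
            row for row in table
            if sum(a != b for a, b in zip(row.cdr3_aa, target)) <= 1
        ]
        assert len(hits) == len(expected)
        assert all(h["mismatches"] <= 1 for h in hits)

    def test_negative_max_mismatch_raises(self):
        with pytest.raises(ValueError):
            scbcr.search_cdr3("AR", [], max_mismatch=-1)


class TestOverlapCounts:
    def test_disjoint_and_identical_sets(self):
        a = {("IGH", "V1", "J1", f"CAR{i}W") for i in range(44)}
        b = {("IGH", "V2", "J2", f"CGT{i}W") for i in range(10)}
        assert scbcr.overlap_counts(a, b) == {"A_only": 44, "B_only": 10, "shared": 0}
        assert scbcr.overlap_counts(a, a) == {"A_only": 0, "B_only": 0, "shared": 44}

    def test_random_sets_match_set_algebra(self):
        rng = np.random.default_rng(2)
        universe = [("IGH", "V", "J", f"C{i}W") for i in range(30)]
        a = {universe[i] for i in rng.choice(30, size=15, replace=False)}
        b = {universe[i] for i in rng.choice(30, size=12, replace=False)}
        out = scbcr.overlap_counts(a, b)
        assert out["shared"] == len(a & b)
        assert out["A_only"] + out["shared"] == len(a)
        assert out["B_only"] + out["shared"] == len(b)

    def test_clone_inputs_keyed_at_requested_level(self):
        a = _chain(sequence_id="a", v_call=["IGHV1-18*01"])
        b = _chain(sequence_id="b", v_call=["IGHV1-18*04"])
        ca = scbcr.cluster_clones([a])
        cb = scbcr.cluster_clones([b])
        assert scbcr.overlap_counts(ca, cb, level="gene")["shared"] == 1
        assert scbcr.overlap_counts(ca, cb, level="allele")["shared"] == 0
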