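"""V(D)J recombination simulator with ground truth.

Generates multi-patient, paired heavy+light single-cell BCR cohorts with the
statistical structure the downstream analysis assumes: skewed V/D/J usage,
exonucleolytic junctional trimming, untemplated N insertion, low per-site
somatic hypermutation (SHM), planted cross-patient convergent clones, and a
configurable fraction of incomplete cells (missing or supernumerary chains).

The generative model is deliberately minimal: uniform-random N nucleotides,
uniform trimming lengths on [0, trim_max], independent per-site point
substitutions, no indels or gene conversion.  Productivity is enforced by
construction (the junction reading frame is forced consistent with the V
frame, and stop-bearing junctions are resampled), with a switch to emit a
stated fraction of frameshifted, non-productive chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .germline import GermlineDatabase, GermlineSegment, translate
from .records import reverse_translate

_NT = np.array(list("ACGT"))
_MAX_RESAMPLE = 200


@dataclass
class PlantedClone:
    """A convergent (cross-patient) paired-chain clone to plant in the cohort."""

    clone_id: str
    heavy_v: str
    heavy_j: str
    heavy_junction_nt: str
    light_v: str
    light_j: str
    light_junction_nt: str
    patient_ids: list[str]
    cells_each: int = 1


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults mirror a small CSF-derived single-cell cohort: 12 patients,
    tens of cells each, strongly skewed segment usage, hypomutated
    repertoires (per-site SHM rate 0.005), lambda light chains outnumbering
    kappa, and a fifth of cells incomplete.
    """

    n_patients: int = 12
    cells_per_patient: int | list[int] = 20
    v_usage: dict[str, dict[str, float]] | None = None
    d_usage: dict[str, float] | None = None
    j_usage: dict[str, dict[str, float]] | None = None
    trim_max: int = 4
    n_insert_max: int = 6
    shm_rate: float = 0.005
    lambda_fraction: float = 0.7
    incomplete_fraction: float = 0.2
    productive_fraction: float = 1.0
    planted_clones: list[PlantedClone] = field(default_factory=list)
    seed: int = 0

    def patient_ids(self) -> list[str]:
        return [f"PA{i + 1:02d}" for i in range(self.n_patients)]

    def cells_for(self, patient_index: int) -> int:
        if isinstance(self.cells_per_patient, int):
            return self.cells_per_patient
        return self.cells_per_patient[patient_index]

    def validate(self, db: GermlineDatabase) -> list[str]:
        """Return a list of findings; empty means runnable."""
        findings = []
        if self.n_patients < 1:
            findings.append("n_patients: must be >= 1")
        if not 0 <= self.shm_rate <= 0.2:
            findings.append("shm_rate: must be in [0, 0.2]")
        for name, usage in (("v_usage", self.v_usage), ("j_usage", self.j_usage)):
            if usage is None:
                continue
            for locus, vec in usage.items():
                total = sum(vec.values())
                if abs(total - 1.0) > 1e-9:
                    findings.append(f"{name}[{locus}]: probabilities sum to {total}, not 1")
                for allele in vec:
                    if allele not in db:
                        findings.append(f"{name}[{locus}]: unknown allele {allele}")
        if self.d_usage is not None:
            total = sum(self.d_usage.values())
            if abs(total - 1.0) > 1e-9:
                findings.append(f"d_usage: probabilities sum to {total}, not 1")
        patients = set(self.patient_ids())
        for clone in self.planted_clones:
            for allele in (clone.heavy_v, clone.heavy_j, clone.light_v, clone.light_j):
                if allele not in db:
                    findings.append(f"planted clone {clone.clone_id}: unknown allele {allele}")
            if not set(clone.patient_ids) <= patients:
                findings.append(
                    f"planted clone {clone.clone_id}: patient_ids outside cohort"
                )
            for junc in (clone.heavy_junction_nt, clone.light_junction_nt):
                if len(junc) % 3 != 0:
                    findings.append(
                        f"planted clone {clone.clone_id}: junction length not a multiple of 3"
                    )
                elif "*" in translate(junc):
                    findings.append(
                        f"planted clone {clone.clone_id}: junction contains a stop codon"
                    )
        return findings


def skewed_usage(alleles: list[str], decay: float = 0.5) -> dict[str, float]:
    """Geometric usage vector over alleles (first dominates), normalised."""
    weights = np.array([decay**i for i in range(len(alleles))])
    weights /= weights.sum()
    return dict(zip(sorted(alleles), weights))


def default_usage(db: GermlineDatabase) -> tuple[dict, dict, dict]:
    """Skewed default V/D/J usage over the database's alleles."""
    v_usage = {
        locus: skewed_usage([s.allele_id for s in db.select(locus=locus, segment_type="V")])
        for locus in db.loci()
    }
    d_alleles = [s.allele_id for s in db.select(locus="IGH", segment_type="D")]
    d_usage = skewed_usage(d_alleles) if d_alleles else {}
    j_usage = {
        locus: skewed_usage([s.allele_id for s in db.select(locus=locus, segment_type="J")])
        for locus in db.loci()
    }
    return v_usage, d_usage, j_usage


@dataclass
class ChainTruth:
    """Ground truth for one simulated chain."""

    sequence_id: str
    patient_id: str
    cell_id: str
    locus: str
    v_allele: str
    d_allele: str
    j_allele: str
    junction_start: int
    junction_end: int
    junction_nt: str
    junction_aa: str
    shm_positions: list[int]
    planted_clone_id: str
    productive: bool


@dataclass
class SimulatedChain:
    sequence_id: str
    sequence: str
    truth: ChainTruth


@dataclass
class SimulatedCell:
    cell_id: str
    patient_id: str
    chains: list[SimulatedChain]
    completeness_truth: str  # "complete" | "incomplete"
    planted_clone_id: str = ""


@dataclass
class CohortTruth:
    """All ground truth for a simulated cohort."""

    cells: list[SimulatedCell]

    def chain_frame(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            for chain in cell.chains:
                t = asdict(chain.truth)
                t["shm_positions"] = ",".join(map(str, chain.truth.shm_positions))
                t["cell_completeness"] = cell.completeness_truth
                rows.append(t)
        return pd.DataFrame(rows)

    def planted_members(self) -> dict[str, dict[str, set[str]]]:
        """clone_id -> patient_id -> member cell ids."""
        out: dict[str, dict[str, set[str]]] = {}
        for cell in self.cells:
            if cell.planted_clone_id:
                out.setdefault(cell.planted_clone_id, {}).setdefault(
                    cell.patient_id, set()
                ).add(cell.cell_id)
        return out


def apply_shm(
    sequence_nt: str,
    shm_rate: float,
    rng: np.random.Generator,
    protect: tuple[int, int] | None = None,
) -> tuple[str, list[int]]:
    """Independent per-site point substitution at rate ``shm_rate``.

    Each mutated site is substituted to a uniformly chosen *different* base.
    ``protect`` optionally shields a half-open span (used to preserve planted
    junction identity).  Positions are returned sorted.
    """
    if not 0 <= shm_rate <= 0.2:
        raise ValueError("shm_rate must be in [0, 0.2]")
    if shm_rate == 0 or not sequence_nt:
        return sequence_nt, []
    hits = rng.random(len(sequence_nt)) < shm_rate
    if protect is not None:
        hits[protect[0] : protect[1]] = False
    positions = np.flatnonzero(hits)
    seq = list(sequence_nt)
    for pos in positions:
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[rng.integers(3)]
    return "".join(seq), positions.tolist()


def _draw(usage: dict[str, float], rng: np.random.Generator) -> str:
    labels = sorted(usage)
    probs = np.array([usage[k] for k in labels])
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def simulate_rearrangement(
    config: SimulationConfig,
    locus: str,
    rng: np.random.Generator,
    db: GermlineDatabase,
    productive: bool = True,
) -> tuple[str, dict]:
    """Simulate one recombined chain (pre-SHM) for ``locus``.

    Heavy chains are V + N1 + D + N2 + J, light chains V + N + J, with
    uniform trimming and uniform-random N nucleotides.  The number of N
    insertions is adjusted by 0-2 so the junction is in the V reading frame;
    junctions containing stop codons are resampled (bounded retries).
    """
    v_usage, d_usage, j_usage = default_usage(db)
    if config.v_usage and locus in config.v_usage:
        v_usage[locus] = config.v_usage[locus]
    if config.d_usage:
        d_usage = config.d_usage
    if config.j_usage and locus in config.j_usage:
        j_usage[locus] = config.j_usage[locus]

    for attempt in range(_MAX_RESAMPLE):
        v = db[_draw(v_usage[locus], rng)]
        j = db[_draw(j_usage[locus], rng)]
        d = db[_draw(d_usage, rng)] if locus == "IGH" else None

        t_v = int(rng.integers(0, min(config.trim_max, v.v_tail_length) + 1))
        t_j = int(rng.integers(0, min(config.trim_max, j.j_motif_start) + 1))
        v_part = v.sequence[: len(v.sequence) - t_v]
        j_part = j.sequence[t_j:]
        if d is not None:
            t_d5 = int(rng.integers(0, config.trim_max + 1))
            t_d3 = int(rng.integers(0, config.trim_max + 1))
            if t_d5 + t_d3 >= len(d.sequence):
                continue  # over-trimmed draw; resample
            d_part = d.sequence[t_d5 : len(d.sequence) - t_d3]
        else:
            d_part = ""
        n1 = int(rng.integers(0, config.n_insert_max + 1))
        n2 = int(rng.integers(0, config.n_insert_max + 1)) if d is not None else 0

        # force the J motif codon into the V reading frame
        motif_pos = len(v_part) + n1 + len(d_part) + n2 + (j.j_motif_start - t_j)
        fix = (-motif_pos) % 3
        if d is not None:
            n2 += fix
        else:
            n1 += fix
        if not productive:
            if d is not None:
                n2 += 1
            else:
                n1 += 1
        insert1 = _random_nt(n1, rng)
        insert2 = _random_nt(n2, rng)
        seq = v_part + insert1 + d_part + insert2 + j_part

        junction_start = v.cys_codon_start
        motif_pos = len(v_part) + n1 + len(d_part) + n2 + (j.j_motif_start - t_j)
        junction_end = motif_pos + 3
        junction_nt = seq[junction_start:junction_end]
        if productive:
            if "*" in translate(seq[: len(seq) - len(seq) % 3]):
                continue
            junction_aa = translate(junction_nt)
        else:
            junction_aa = ""
        truth = dict(
            v_allele=v.allele_id,
            d_allele=d.allele_id if d is not None else "",
            j_allele=j.allele_id,
            junction_start=junction_start,
            junction_end=junction_end,
            junction_nt=junction_nt,
            junction_aa=junction_aa,
            productive=productive,
        )
        return seq, truth
    raise RuntimeError(f"could not simulate a valid {locus} rearrangement "
                       f"after {_MAX_RESAMPLE} attempts")


def planted_junction_nt(cdr3_aa: str, j_segment: GermlineSegment) -> str:
    """Nucleotide junction encoding C + cdr3_aa + the germline J motif codon."""
    motif_codon = j_segment.sequence[j_segment.j_motif_start : j_segment.j_motif_start + 3]
    return "TGT" + reverse_translate(cdr3_aa) + motif_codon


def _planted_chain(
    v: GermlineSegment, j: GermlineSegment, junction_nt: str
) -> tuple[str, dict]:
    seq = v.sequence[: v.cys_codon_start] + junction_nt + j.sequence[j.j_motif_start + 3 :]
    truth = dict(
        v_allele=v.allele_id,
        d_allele="",
        j_allele=j.allele_id,
        junction_start=v.cys_codon_start,
        junction_end=v.cys_codon_start + len(junction_nt),
        junction_nt=junction_nt,
        junction_aa=translate(junction_nt),
        productive=True,
    )
    return seq, truth


def simulate_cohort(config: SimulationConfig, db: GermlineDatabase) -> CohortTruth:
    """Simulate the full multi-patient cohort.

    Planted clones are emitted first for each of their patients; remaining
    cells are independent random rearrangements.  A fraction of the random
    cells is made incomplete, either by dropping one chain class or by
    duplicating both chains with fresh SHM (a doublet mimic: two heavy and
    two light chains).  Planted cells receive SHM outside their junction
    only, so the planted clonal identity survives mutation.
    """
    findings = config.validate(db)
    if findings:
        raise ValueError("invalid SimulationConfig: " + "; ".join(findings))
    rng = np.random.default_rng(config.seed)
    cells: list[SimulatedCell] = []

    def light_locus() -> str:
        has_igl = bool(db.select(locus="IGL", segment_type="V"))
        has_igk = bool(db.select(locus="IGK", segment_type="V"))
        if has_igl and has_igk:
            return "IGL" if rng.random() < config.lambda_fraction else "IGK"
        return "IGL" if has_igl else "IGK"

    def make_chain(cell_id: str, patient: str, locus: str, k: int,
                   planted: PlantedClone | None = None) -> SimulatedChain:
        sequence_id = f"{cell_id}_{locus}_{k}"
        if planted is not None:
            if locus == "IGH":
                v, j, junc = planted.heavy_v, planted.heavy_j, planted.heavy_junction_nt
            else:
                v, j, junc = planted.light_v, planted.light_j, planted.light_junction_nt
            seq, truth = _planted_chain(db[v], db[j], junc)
            protect = (truth["junction_start"], truth["junction_end"])
        else:
            productive = bool(rng.random() < config.productive_fraction)
            seq, truth = simulate_rearrangement(config, locus, rng, db, productive)
            protect = None
        seq, positions = apply_shm(seq, config.shm_rate, rng, protect=protect)
        return SimulatedChain(
            sequence_id=sequence_id,
            sequence=seq,
            truth=ChainTruth(
                sequence_id=sequence_id,
                patient_id=patient,
                cell_id=cell_id,
                locus=locus,
                shm_positions=positions,
                planted_clone_id=planted.clone_id if planted else "",
                **truth,
            ),
        )

    for p_idx, patient in enumerate(config.patient_ids()):
        n_cells = config.cells_for(p_idx)
        cell_counter = 0

        for clone in config.planted_clones:
            if patient not in clone.patient_ids:
                continue
            light = clone.light_v.split("*")[0][:3]
            for _ in range(clone.cells_each):
                cell_id = f"{patient}_c{cell_counter:04d}"
                cell_counter += 1
                chains = [
                    make_chain(cell_id, patient, "IGH", 0, planted=clone),
                    make_chain(cell_id, patient, light, 0, planted=clone),
                ]
                cells.append(SimulatedCell(cell_id, patient, chains, "complete", clone.clone_id))

        while cell_counter < n_cells:
            cell_id = f"{patient}_c{cell_counter:04d}"
            cell_counter += 1
            loc = light_locus()
            heavy = [make_chain(cell_id, patient, "IGH", 0)]
            light = [make_chain(cell_id, patient, loc, 0)]
            completeness = "complete"
            if rng.random() < config.incomplete_fraction:
                completeness = "incomplete"
                if rng.random() < 0.5:  # drop one chain class
                    if rng.random() < 0.5:
                        heavy = []
                    else:
                        light = []
                else:  # doublet mimic: duplicate both chains with fresh SHM
                    heavy.append(make_chain(cell_id, patient, "IGH", 1))
                    light.append(make_chain(cell_id, patient, loc, 1))
            cells.append(SimulatedCell(cell_id, patient, heavy + light, completeness))

    return CohortTruth(cells=cells)


def write_cohort(
    cohort: CohortTruth, config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write per-patient FASTA, truth.tsv and config_used.yaml; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    by_patient: dict[str, list[SimulatedCell]] = {}
    for cell in cohort.cells:
        by_patient.setdefault(cell.patient_id, []).append(cell)
    for patient in sorted(by_patient):
        path = out_dir / f"patient_{patient}.fasta"
        with open(path, "w", encoding="utf-8") as fh:
            for cell in by_patient[patient]:
                for chain in cell.chains:
                    fh.write(
                        f">{chain.sequence_id} patient_id={patient} "
                        f"cell_id={cell.cell_id}\n{chain.sequence}\n"
                    )
        paths[patient] = path
    truth_path = out_dir / "truth.tsv"
    cohort.chain_frame().to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    config_path = out_dir / "config_used.yaml"
    cfg = asdict(config)
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    paths["config"] = config_path
    return paths
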