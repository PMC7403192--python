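# scbcr

Single-cell B-cell receptor (BCR) repertoire analysis: annotate paired
heavy/light immunoglobulin chain sequences against a germline segment
database, assemble them into cells, cluster clones and paired clonotypes,
detect clones and clonotypes shared across patients, and compute standard
repertoire statistics. A built-in cohort simulator with full ground truth
makes every step testable end to end.

## Background

B cells assemble their antigen receptors by V(D)J recombination: a heavy
chain joins one V, one D and one J germline segment (a light chain joins V
and J only), with nucleotide trimming and untemplated N-nucleotide insertion
at the joins. The resulting **junction** — the span from the conserved
second cysteine of the V segment through the conserved W/F of the J segment,
inclusive — encodes **CDR3**, the principal antigen-contact loop (the
junction minus its two anchor residues). A rearrangement is **productive**
when its junction is in frame and free of stop codons.

In single-cell data each cell contributes one heavy and one light chain, so
receptors can be analysed as pairs:

- A **clone** groups same-locus chains with the same V gene, same J gene and
  identical junction amino acids; a *common clone* recurs in two or more
  patients.
- A **clonotype** groups complete cells with the same heavy V and J, same
  light V and J, and identical CDR3 amino acids on both chains; a *shared
  clonotype* spans two or more patients. Shared clonotypes across unrelated
  individuals are the signature of convergent, antigen-driven selection.
- A cell is **complete** when both chain classes are present and at most one
  of them is duplicated (one heavy with one or more lights, or vice versa);
  cells with multiple chains of both classes (likely doublets) or a single
  chain class are *incomplete* and excluded from pairing analyses.
- The **somatic hypermutation (SHM) rate** of a chain is its V-segment
  mismatch count divided by the aligned germline length, junction excluded.

## Worked example: shared clonotypes

The package bundles a small paired-chain example cohort: 13 complete B
cells from 9 patients, each with known heavy and light V/(D)/J alleles and
CDR3s. Grouping the cells into clonotypes and keeping the cross-patient
groups (`examples/01_shared_clonotypes.py`):

```python
import scbcr
from scbcr.datasets import shared_clonotype_example_cells

cells = shared_clonotype_example_cells()
shared = scbcr.find_shared_clonotypes(cells, min_patients=2, level="allele")
print(scbcr.clonotype_table(shared).to_string(index=False))
```

prints four shared clonotype groups:

```
                patients  n_patients  n_cells     heavy_v  heavy_j     heavy_cdr3_aa                 light_v           light_j light_cdr3_aa
PA21 PA22 PA23 PA25 PA29           5        5 IGHV1-18*04 IGHJ3*02    ARVGSKYGFETFDI             IGLV1-44*01          IGLJ3*02   AAWDDSLNGPV
          PA21 PA22 PA23           3        3 IGHV1-18*04 IGHJ3*02    ARVGSKYGFETFDI IGLV1-40*01/IGLV1-40*02          IGLJ3*02  QSYDRSLSGYWV
           PA22 PA30 PA8           3        3 IGHV1-18*04 IGHJ3*02    ARVGSKYGFETFDI             IGLV1-44*01 IGLJ2*01/IGLJ3*01   AAWDDSLTGVV
               PA11 PA31           2        2 IGHV4-39*01 IGHJ4*02 ARRSSGVRIAARRPFDC             IGLV2-11*01          IGLJ3*02      SSYVRAWV
```

(heavy D column elided here for width). Three of the four groups carry the
same recurrent 14-residue heavy CDR3, `ARVGSKYGFETFDI`, paired with
*different* light chains — the classic picture of a convergent heavy chain.
The heavy V-J matrix of this cohort contains exactly two combinations,
(IGHV1-18\*04, IGHJ3\*02) and (IGHV4-39\*01, IGHJ4\*02).

## Simulation round trip

`examples/02_simulate_and_annotate.py` simulates a 6-patient cohort with a
convergent clone planted in patients PA01, PA02 and PA05, annotates the raw
nucleotide reads from scratch, and recovers the clone:

```
simulated 60 cells (116 chains) for 6 patients
annotated 116 chains, 111 productive
53 of 60 cells are complete (both chain classes, at most one duplicated)
shared clonotype ARVGSKYGFETFDI / AAWDDSLNGPV in patients ['PA01', 'PA02', 'PA05']
```

`examples/03_repertoire_statistics.py` computes the descriptive panel
(V family usage, V-J matrix, CDR3 lengths with a Shapiro-Wilk normality
check, SHM rates, kappa/lambda balance) on a simulated cohort.

## Command line

The `scbcr` console script wraps the library as thin verbs:

```bash
scbcr simulate --out cohort/ --seed 4          # FASTA per patient + truth.tsv
scbcr annotate --in cohort/patient_PA01.fasta --out rearr.tsv
scbcr cells --in rearr.tsv --out cells.tsv
scbcr clones --in rearr.tsv --out clones.tsv --min-patients 2
scbcr clonotypes --in rearr.tsv --out clonotypes.tsv
scbcr stats --in rearr.tsv --out-dir stats/
scbcr search --cdr3 ARVGSKYGFETFDI --in control.tsv --dialect mixcr-like
scbcr run --config run.yaml                    # full pipeline + manifest
```

`scbcr run` executes every stage (simulate or ingest → annotate → cells →
clones/clonotypes → statistics → cross-cohort search) and writes a
`manifest.json` recording the seed, resolved parameters, germline checksum
and every output file with row counts. Runs are deterministic given config
and seed.

## Documentation

See `docs/methods.md` for the underlying model, the simulator's parameter
defaults and scope, numerical conventions (alignment scoring, tie handling,
fractional usage weighting) and known limitations. The bundled germline
segment set is synthetic (see `src/scbcr/data/synthetic_germline.fasta`);
for real analyses supply an IMGT-derived reference via `--germline`.
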