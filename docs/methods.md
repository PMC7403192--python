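# Methods

This document records the model behind each stage, the parameter defaults
and their rationale, the numerical conventions, and the limitations. All
empirical numbers quoted here are computed by the test suite or the bundled
example scripts.

## Germline reference

A germline reference is a FASTA of V, D and J segment alleles named in IMGT
style (`IGHV1-18*04` = family IGHV1, gene IGHV1-18, allele 04), plus a
sidecar anchor TSV giving, per V allele, the 0-based start of the conserved
second-cysteine codon and, per J allele, the start of the conserved W/F
anchor codon. Loading validates that every V cysteine codon translates to C
and every J anchor to W or F, that V alleles are long enough to contain
their anchor, and that allele IDs are unique.

The bundled set (`src/scbcr/data/synthetic_germline.fasta`) is **synthetic**:
33 segments across IGH, IGK and IGL generated once with a fixed RNG, with
realistic lengths (V = 150 nt, anchors near the 3' end, J = 36–51 nt) and
IMGT-style names. It exists so that examples and tests are self-contained
and distributable; it shares no sequence with any real germline database,
and real analyses should supply an IMGT-derived reference.

## Annotation

Each read is aligned locally against every germline segment in both
orientations using affine-gap local alignment (match +2, mismatch −2, gap of
length k scores −(5 + k)). Implementation is Biopython's
`PairwiseAligner`; the convention maps to `open_gap_score=-6`,
`extend_gap_score=-1`. The test suite cross-checks the scores against an
independent brute-force dynamic-programming implementation on 500 random
instances.

Assignment cascades V → J → D: the V call anchors the read, J is searched
downstream of the V end, and D (heavy only) inside the V–J gap, requiring at
least `min_d_length` (default 5) aligned nucleotides — shorter D remnants
are unreliable and left uncalled. Score floors (`v_min_score` 50,
`j_min_score` 20) reject unannotatable reads. Equal-scoring segments are
reported as a tied, lexicographically sorted call list; downstream matching
treats tied calls as a set.

The junction is read off the alignment: from the V cysteine codon (mapped
through the V alignment) to the end of the J anchor codon (mapped through
the J alignment). A chain is productive when the junction length is a
multiple of 3 and its translation contains no stop. The SHM count is the
number of V-segment mismatches outside the junction; the rate divides by
the aligned germline length, so reads truncated at the 5' end are not
penalised.

## Cells, clones, clonotypes

Records sharing `(patient_id, cell_id)` form a cell. Completeness follows
the paired-chain cardinality rule: both chain classes present and at most
one class duplicated → complete; multiple chains of both classes (likely
doublet) or one class only → incomplete. Only complete cells enter
clonotype analysis.

Clone matching (same V gene set intersection, same J gene set intersection,
identical junction amino acids, at `allele` or `gene` level) is not
transitive when tied calls are involved, so clones and clonotypes are built
as connected components (union-find) within blocks pre-partitioned by locus
and CDR3/junction amino acids. Usage statistics weight an n-way tied call
1/n per candidate so each record contributes total weight 1; the V-J matrix
weights 1/(|V ties| · |J ties|) so its marginals equal the usage counts.

## Simulator

`simulate_cohort` draws, per chain, V/(D)/J segments from configurable
per-locus usage vectors, trims up to `trim_max` nt at each join, inserts up
to `n_insert_max` untemplated nucleotides, forces the junction in frame (or
deliberately out of frame for non-productive chains), resamples junctions
containing stop codons, and applies uniform per-site point mutation at
`shm_rate` to the V and J flanks. Planted clones are written verbatim:
their junction nucleotides are never mutated, so planted clonal identity is
preserved at any mutation rate.

Defaults model a small autoreactive single-cell cohort:

| parameter             | default | rationale                                                    |
| --------------------- | ------- | ------------------------------------------------------------ |
| `n_patients`          | 12      | small clinical cohort scale                                  |
| `cells_per_patient`   | 20      | tens of sorted B cells per CSF sample                        |
| `v_usage` / `j_usage` | geometric decay (factor 0.5) | repertoires are skewed: a few families dominate |
| `shm_rate`            | 0.005   | hypomutated chains, consistent with a naive/early-activated compartment |
| `lambda_fraction`     | 0.7     | lambda class exceeding kappa                                 |
| `incomplete_fraction` | 0.2     | dropout/doublet rate typical of single-cell sorting          |
| `trim_max`            | 4 nt    | moderate exonuclease trimming                                |
| `n_insert_max`        | 6 nt    | moderate N-insertion                                         |
| `productive_fraction` | 1.0     | sorted, surface-Ig⁺ cells are productive                     |

Incomplete cells are produced by either dropping one chain class (dropout)
or duplicating both classes (2 heavy + 2 light, a doublet mimic); the
latter duplicates *both* classes because a cell with a single heavy and two
lights still classifies as complete under the cardinality rule.

The simulator does **not** emulate: targeted SHM hotspot motifs or
insertion/deletion SHM, isotype switching dynamics, allelic inclusion,
sequencing error profiles, P-nucleotides, or clonal lineage trees. It is a
ground-truth generator for pipeline validation, not a biological model of
affinity maturation.

## Statistics

- **Usage tables / V-J matrix** at family, gene or allele level with the
  fractional tie weighting above; permutation-invariant in input order.
- **CDR3 length distribution** with Shapiro-Wilk normality (α = 0.05,
  undefined for constant vectors). Note integer CDR3 lengths are inherently
  discretised; at n in the hundreds, Shapiro-Wilk detects this whenever the
  spread is within a few length units, so real repertoires typically test
  non-normal.
- **SHM summary**: per-chain rates with a five-number summary; zero-length
  alignments are excluded and counted.
- **Group comparison**: Shapiro-Wilk per group; both normal → two-sample
  t-test, otherwise Wilcoxon rank-sum (Mann-Whitney U, two-sided); three or
  more groups → one-way ANOVA. All-equal degenerate input returns statistic
  0, p = 1 by convention. α is fixed at 0.05 two-tailed; no
  multiple-testing correction is applied.
- **Light-chain balance**: IGK vs IGL counts with a two-sided exact
  binomial test against 0.5.

Statistical routines are scipy.stats; the test suite pins Shapiro-Wilk
against reference values computed independently with R's `shapiro.test`.

## Pipeline and reproducibility

`run_pipeline` validates the configuration (exactly one input mode, all
paths exist, usage vectors sum to 1) before writing anything, then runs
simulate/ingest → annotate → cells → clones/clonotypes → statistics →
search. Every stage writes TSV and reads its predecessor's TSV, so stages
are individually re-runnable. All randomness derives from the single config
seed through `numpy.random.SeedSequence` substreams; the manifest records
the seed, resolved parameters, a germline FASTA checksum, and each output
file with its row count. Seeds are reduced modulo 2³¹ for portability.

## Limitations

- The bundled germline set is synthetic and deliberately small; allele
  calls on real data require a real reference.
- Alignment-based annotation has no statistical significance model (no
  E-values); score floors are the only filter.
- Tied allele calls are possible by construction when a read lacks the
  segment region distinguishing two alleles (e.g. a junction that replaces
  the J segment's pre-anchor nucleotides); they are reported as sets rather
  than resolved arbitrarily.
- Clone definitions use exact junction/CDR3 amino-acid identity; no
  similarity-threshold (e.g. Hamming-distance) clonal grouping is provided
  beyond the explicit `search_cdr3` mismatch search.
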