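"""Shared clonotypes in a small paired-chain cohort.

Thirteen complete B cells from nine patients, each carrying one heavy and
one light chain with known V/(D)/J alleles and CDR3s (the bundled example
cohort).  We group the cells into clonotypes — same heavy V and J, same
light V and J, identical CDR3 amino acids on both chains — and keep the
groups that span at least two patients.
"""

import scbcr
from scbcr.datasets import COMMON_CLONE_CDR3, shared_clonotype_example_cells

cells = shared_clonotype_example_cells()
print(f"{len(cells)} complete cells from "
      f"{len({c.patient_id for c in cells})} patients")

shared = scbcr.find_shared_clonotypes(cells, min_patients=2, level="allele")
print(f"{len(shared)} shared clonotype groups:\n")
print(scbcr.clonotype_table(shared).to_string(index=False))

n_common = sum(ct.heavy_cdr3_aa == COMMON_CLONE_CDR3 for ct in shared)
print(f"\n{n_common} of {len(shared)} groups carry the recurrent heavy CDR3 "
      f"{COMMON_CLONE_CDR3} ({len(COMMON_CLONE_CDR3)} residues) on different "
      "light chains — convergent heavy chains pairing with distinct lights.")
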