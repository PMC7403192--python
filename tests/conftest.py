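"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import scbcr


def dp_local_score(a: str, b: str, match=2.0, mismatch=-2.0, open_=-5.0, extend=-1.0):
    """Brute-force Gotoh local alignment score.

    Independent of the package's aligner: plain dynamic programming with the
    same convention (a gap of length k scores open + k*extend).  Returns the
    optimal local score.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    best = 0.0
    first_gap = open_ + extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = max(0.0, diag + s)
            Ix[i][j] = max(M[i - 1][j] + first_gap, Ix[i - 1][j] + extend)
            Iy[i][j] = max(M[i][j - 1] + first_gap, Iy[i][j - 1] + extend)
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


def random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def db() -> scbcr.GermlineDatabase:
    return scbcr.load_default_germline()


@pytest.fixture(scope="session")
def clean_cohort(db):
    """Noise-free cohort: no trimming, no N insertion, no SHM, all complete."""
    cfg = scbcr.SimulationConfig(
        n_patients=3, cells_per_patient=6, trim_max=0, n_insert_max=0,
        shm_rate=0.0, incomplete_fraction=0.0, seed=11,
    )
    return cfg, scbcr.simulate_cohort(cfg, db)


@pytest.fixture(scope="session")
def annotated_clean(clean_cohort, db):
    """Records annotated from the clean cohort, paired with their truths."""
    _, cohort = clean_cohort
    pairs = []
    for cell in cohort.cells:
        for chain in cell.chains:
            rec = scbcr.annotate_sequence(
                chain.sequence, db, sequence_id=chain.sequence_id,
                patient_id=chain.truth.patient_id, cell_id=chain.truth.cell_id,
            )
            pairs.append((rec, chain.truth))
    return pairs
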