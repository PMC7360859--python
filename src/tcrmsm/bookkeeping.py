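"""Ensemble bookkeeping for the published receptor set.

Each receptor's enhanced-sampling run was clustered into seed structures,
and every seed spawned one 100 ns production clone; the aggregate sampling
time per receptor is therefore (number of seed clusters) × 0.1 μs. The seed
counts below are the published inputs for the five receptors studied.
"""

from __future__ import annotations

CLONE_LENGTH_NS = 100.0

#: seed-cluster count per receptor (average-linkage RMSD clustering, 1.2 Å cutoff)
SEED_CLUSTERS = {
    "B4.2.3": 218,   # anti P18-I10/H2-Dd
    "MAIT": 287,     # MR1-restricted mucosal-associated invariant TCR
    "003": 182,      # anti HIV p17 Gag / HLA-A*02:01
    "E8": 93,        # anti triosephosphate-isomerase epitope / HLA-DR1
    "42F3": 230,     # alloreactive, p3A1/H2-Ld
}


def aggregate_sampling_us(receptor: str,
                          clone_length_ns: float = CLONE_LENGTH_NS) -> float:
    """Aggregate production sampling per receptor in μs."""
    return SEED_CLUSTERS[receptor] * clone_length_ns / 1000.0
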