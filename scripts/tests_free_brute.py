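"""Independent brute-force statement of the greedy neighbour-count
clustering rule, used by the acceptance script as its oracle."""

from __future__ import annotations

import numpy as np


def brute_force_gromos(m: np.ndarray, cutoff: float):
    """Explicit set-scan re-derivation: at each round, scan every remaining
    frame, collect its within-cutoff neighbourhood, keep the largest
    (lowest index on ties), remove it, repeat."""
    n = m.shape[0]
    remaining = set(range(n))
    partition = []
    while remaining:
        best_rep, best_members = None, None
        for cand in sorted(remaining):
            members = {j for j in remaining if m[cand, j] <= cutoff} | {cand}
            if best_members is None or len(members) > len(best_members):
                best_rep, best_members = cand, members
        partition.append((best_rep, frozenset(best_members)))
        remaining -= best_members
    return partition
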