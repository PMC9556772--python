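import numpy as np
import pandas as pd
import pytest

from momstrat import CandidateTreatment, LesionMatrix, NormalizedMatrix


@pytest.fixture
def worked_instance():
    """4-patient / 3-drug / 2-lesion instance with hand-enumerable optima.

    Exhaustive enumeration over every (ordered candidate subset, default
    drug) gives objective -4.5 at K=1 (D1/D2 tie, D1 canonical), -8.0 at
    K=2 (level (b2, D2), default D1) and -8.5 at K=3.
    """
    norm = NormalizedMatrix(
        pd.DataFrame(
            [[-3, -1, 0, -0.5], [0, -2, -2.5, 0], [-1, -1, -1, -1]],
            index=["D1", "D2", "D3"],
            columns=["P1", "P2", "P3", "P4"],
            dtype=float,
        )
    )
    lesions = LesionMatrix(
        pd.DataFrame(
            [[1, 1, 0, 0], [0, 1, 1, 0]],
            index=["b1", "b2"],
            columns=["P1", "P2", "P3", "P4"],
        )
    )
    candidates = [
        CandidateTreatment("b1", "D1", 1.0, 0.01),
        CandidateTreatment("b2", "D2", 1.0, 0.01),
    ]
    return norm, lesions, candidates


def random_instance(rng):
    """A random small stratification instance for oracle-equivalence tests."""
    P = int(rng.integers(3, 9))
    T = int(rng.integers(2, 6))
    B = int(rng.integers(1, 5))
    K = int(rng.integers(1, 4))
    S = -np.round(rng.random((T, P)) * 3, 3)
    S -= S.max(axis=1, keepdims=True)
    drugs = [f"D{j}" for j in range(T)]
    pats = [f"P{j}" for j in range(P)]
    lesn = [f"L{j}" for j in range(B)]
    norm = NormalizedMatrix(pd.DataFrame(S, index=drugs, columns=pats))
    les = LesionMatrix(
        pd.DataFrame(rng.integers(0, 2, (B, P)), index=lesn, columns=pats)
    )
    n_cand = int(rng.integers(0, min(5, T * B) + 1))
    pairs = set()
    while len(pairs) < n_cand:
        pairs.add((lesn[int(rng.integers(B))], drugs[int(rng.integers(T))]))
    cands = [CandidateTreatment(l, d, 1.0, 0.01) for l, d in sorted(pairs)]
    return norm, les, cands, K
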