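"""Independent oracles used by the test suite."""

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
_NEG = float("-inf")


def naive_local_affine(a: str, b: str, open_cost: int = 12, extend_cost: int = 1) -> int:
    """Reference Smith–Waterman with Gotoh affine gaps.

    A gap of length k costs (open_cost - extend_cost) + k*extend_cost,
    i.e. 11 + k with the defaults — the same scheme as the production
    aligner, implemented independently as a full three-matrix dynamic
    programme.
    """
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[_NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = _B62[a[i - 1]][b[j - 1]]
            M[i][j] = max(
                0.0, max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + sub
            )
            Ix[i][j] = max(M[i - 1][j] - open_cost, Ix[i - 1][j] - extend_cost)
            Iy[i][j] = max(M[i][j - 1] - open_cost, Iy[i][j - 1] - extend_cost)
            best = max(best, M[i][j])
    return int(best)
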