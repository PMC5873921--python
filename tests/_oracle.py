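"""Independent brute-force oracles used by the test suite.

Deliberately simple, quadratic, pure-Python implementations kept apart
from the package's kernels so they can validate them.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_score(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -4,
    gap_extend: int = -1,
) -> int:
    """Optimal global affine-gap alignment score (three-state DP).

    A gap of length g costs -(gap_open + g*gap_extend) applied as
    open+extend on the first gap base.
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = gap_open + i * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai in "ACGT") else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + gap_open + gap_extend,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open + gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open + gap_extend,
                X[i][j - 1] + gap_open + gap_extend,
                Y[i][j - 1] + gap_extend,
            )
    return int(max(M[n][m], X[n][m], Y[n][m]))


def hamming_identity(a: str, b: str) -> float:
    """Identity of two equal-length strings (substitution-only oracle)."""
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def reconstruct_b(a: str, records) -> str:
    """Rebuild sequence b from sequence a plus classified differences.

    Applies SNPs/insertions/deletions at their a-coordinates, right to
    left, trusting each record's alleles.  Serves as a round-trip oracle
    for classify_differences.
    """
    seq = a
    # right-to-left; at equal positions substitutions/deletions go first so
    # an insertion lands before the (possibly substituted) base
    order = sorted(records, key=lambda r: (-r.pos_a, r.kind == "insertion"))
    for r in order:
        if r.kind == "snp":
            assert seq[r.pos_a] == r.alleles[0]
            seq = seq[: r.pos_a] + r.alleles[1] + seq[r.pos_a + 1 :]
        elif r.kind == "deletion":
            assert seq[r.pos_a : r.pos_a + r.length] == r.alleles[0]
            seq = seq[: r.pos_a] + seq[r.pos_a + r.length :]
        elif r.kind == "insertion":
            seq = seq[: r.pos_a] + r.alleles[1] + seq[r.pos_a :]
    return seq
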