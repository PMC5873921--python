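"""Pairwise alignment kernels.

Global alignment uses affine-gap Needleman-Wunsch (Gotoh's three-state
recurrence) with the pipeline's fixed scoring: match +1, mismatch -2,
gap open -4, gap extend -1 (a gap of length g costs 4 + g).  Local
alignment for identity screening uses Smith-Waterman with linear gaps
(match +1, mismatch -1, gap -2).  Both kernels are numba-compiled; the
DP is quadratic, so long contigs are aligned by chaining unique k-mer
anchors and running the global kernel only on the short inter-anchor
segments.  Segments too large for the DP fall back to an edit-distance
path from edlib.

'N' matches nothing: N-vs-anything scores as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from numba import njit

NEG_INF = np.int32(-(10**9))

_ENCODE = np.full(256, 4, dtype=np.uint8)  # 4 == N / unknown, matches nothing
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


class StructuralDivergenceError(ValueError):
    """Raised when two sequences share no collinear anchor chain."""


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -4  # charged once per gap run, on top of extend
    gap_extend: int = -1

    def gap_cost(self, length: int) -> int:
        return self.gap_open + length * self.gap_extend


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=False)
def _gotoh_kernel(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    Ix = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # gap in b (a base vs -)
    Iy = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # gap in a (- vs b base)
    tM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + i * gap_extend
        tX[i, 0] = 1
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + j * gap_extend
        tY[0, j] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            # match state
            best = M[i - 1, j - 1]
            ptr = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                ptr = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            tM[i, j] = ptr
            # gap in b (consume a)
            bo = M[i - 1, j] + gap_open + gap_extend
            ptr = 0
            if Ix[i - 1, j] + gap_extend > bo:
                bo = Ix[i - 1, j] + gap_extend
                ptr = 1
            if Iy[i - 1, j] + gap_open + gap_extend > bo:
                bo = Iy[i - 1, j] + gap_open + gap_extend
                ptr = 2
            Ix[i, j] = bo
            tX[i, j] = ptr
            # gap in a (consume b)
            bo = M[i, j - 1] + gap_open + gap_extend
            ptr = 0
            if Ix[i, j - 1] + gap_open + gap_extend > bo:
                bo = Ix[i, j - 1] + gap_open + gap_extend
                ptr = 1
            if Iy[i, j - 1] + gap_extend > bo:
                bo = Iy[i, j - 1] + gap_extend
                ptr = 2
            Iy[i, j] = bo
            tY[i, j] = ptr
    # traceback
    state = 0
    score = M[n, m]
    if Ix[n, m] > score:
        score = Ix[n, m]
        state = 1
    if Iy[n, m] > score:
        score = Iy[n, m]
        state = 2
    ops = np.empty(n + m, dtype=np.uint8)  # 0 diag, 1 up (gap in b), 2 left (gap in a)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ops[k] = 0
            state = tM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            state = tX[i, j]
            i -= 1
        else:
            ops[k] = 2
            state = tY[i, j]
            j -= 1
        k += 1
    return score, ops[:k][::-1].copy()


@njit(cache=False)
def _sw_kernel(a, b, match, mismatch, gap):  # pragma: no cover
    """Linear-gap Smith-Waterman; returns best score, end cell, and H matrix."""
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            v = H[i - 1, j - 1] + s
            if H[i - 1, j] + gap > v:
                v = H[i - 1, j] + gap
            if H[i, j - 1] + gap > v:
                v = H[i, j - 1] + gap
            if v < 0:
                v = 0
            H[i, j] = v
            if v > best:
                best = v
                bi = i
                bj = j
    return best, bi, bj, H


@njit(cache=False)
def _sw_traceback(a, b, H, bi, bj, match, mismatch, gap):  # pragma: no cover
    """Walk back from the best cell; returns (matches, columns, ai0, bj0)."""
    i, j = bi, bj
    matches = 0
    columns = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matches += 1
            columns += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return matches, columns, i, j


def _ops_to_gapped(a: str, b: str, ops: np.ndarray) -> tuple[str, str]:
    ga, gb = [], []
    i = j = 0
    for op in ops:
        if op == 0:
            ga.append(a[i])
            gb.append(b[j])
            i += 1
            j += 1
        elif op == 1:
            ga.append(a[i])
            gb.append("-")
            i += 1
        else:
            ga.append("-")
            gb.append(b[j])
            j += 1
    return "".join(ga), "".join(gb)


def nw_align(a: str, b: str, scoring: Scoring = Scoring()) -> tuple[str, str, int]:
    """Global affine-gap alignment; returns (gapped_a, gapped_b, score)."""
    if not a and not b:
        return "", "", 0
    if not a:
        return "-" * len(b), b, scoring.gap_cost(len(b))
    if not b:
        return a, "-" * len(a), scoring.gap_cost(len(a))
    score, ops = _gotoh_kernel(
        encode(a), encode(b),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    ga, gb = _ops_to_gapped(a, b, ops)
    return ga, gb, int(score)


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment between two sequences (identity screening)."""

    score: int
    matches: int
    columns: int
    a_interval: tuple[int, int]  # 0-based half-open on a
    b_interval: tuple[int, int]

    @property
    def identity(self) -> float:
        """Matches over alignment columns; gaps count against identity."""
        return self.matches / self.columns if self.columns else 0.0


def sw_local(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2) -> LocalHit:
    """Best local alignment under linear-gap scoring (default +1/-1/-2)."""
    if not a or not b:
        raise ValueError("empty sequence in local alignment")
    ea, eb = encode(a), encode(b)
    score, bi, bj, H = _sw_kernel(ea, eb, match, mismatch, gap)
    if score <= 0:
        return LocalHit(0, 0, 0, (0, 0), (0, 0))
    matches, columns, ai0, bj0 = _sw_traceback(ea, eb, H, bi, bj, match, mismatch, gap)
    return LocalHit(int(score), int(matches), int(columns), (int(ai0), int(bi)), (int(bj0), int(bj)))


def alignment_score(gapped_a: str, gapped_b: str, scoring: Scoring = Scoring()) -> int:
    """Score an existing gapped pair under the affine model (for audits)."""
    if len(gapped_a) != len(gapped_b):
        raise ValueError("gapped rows differ in length")
    score = 0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(gapped_a, gapped_b):
        if ca == "-" and cb == "-":
            raise ValueError("column with gap in both rows")
        if ca == "-":
            score += scoring.gap_extend + (0 if in_gap_a else scoring.gap_open)
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score += scoring.gap_extend + (0 if in_gap_b else scoring.gap_open)
            in_gap_a, in_gap_b = False, True
        else:
            score += scoring.match if (ca == cb and ca in "ACGT") else scoring.mismatch
            in_gap_a = in_gap_b = False
    return score


# ---------------------------------------------------------------------------
# anchors + chaining for long near-collinear sequences
# ---------------------------------------------------------------------------


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in seen:
            del seen[km]
            dup.add(km)
        else:
            seen[km] = i
    return seen


def anchor_runs(a: str, b: str, k: int = 21) -> list[tuple[int, int, int]]:
    """Maximal runs (pos_a, pos_b, length) of matched k-mers unique in both."""
    ka = _unique_kmer_positions(a, k)
    kb = _unique_kmer_positions(b, k)
    matches = sorted((pa, kb[km]) for km, pa in ka.items() if km in kb)
    runs: list[tuple[int, int, int]] = []
    for pa, pb in matches:
        if runs:
            la, lb, ln = runs[-1]
            if pa == la + ln - k + 1 and pb == lb + ln - k + 1:
                runs[-1] = (la, lb, ln + 1)
                continue
        runs.append((pa, pb, k))
    return runs


def chain_anchors(runs: list[tuple[int, int, int]], max_runs: int = 5000) -> list[tuple[int, int, int]]:
    """Highest-coverage collinear chain (weighted LIS on run length).

    Runs must be sorted by pos_a.  Overlaps between chained neighbours are
    trimmed so inter-anchor segments are disjoint.
    """
    if not runs:
        return []
    if len(runs) > max_runs:
        keep = sorted(sorted(runs, key=lambda r: -r[2])[:max_runs])
        runs = keep
    n = len(runs)
    best = [r[2] for r in runs]
    prev = [-1] * n
    for i in range(n):
        pa, pb, ln = runs[i]
        for j in range(i):
            qa, qb, qn = runs[j]
            if qa < pa and qb < pb and best[j] + ln > best[i]:
                best[i] = best[j] + ln
                prev[i] = j
    end = int(np.argmax(best))
    chain = []
    while end != -1:
        chain.append(runs[end])
        end = prev[end]
    chain.reverse()
    # trim overlaps between successive runs
    trimmed: list[tuple[int, int, int]] = []
    for pa, pb, ln in chain:
        if trimmed:
            qa, qb, qn = trimmed[-1]
            cut = max(qa + qn - pa, qb + qn - pb, 0)
            if cut >= ln:
                continue
            pa, pb, ln = pa + cut, pb + cut, ln - cut
        trimmed.append((pa, pb, ln))
    return trimmed


def _edlib_gapped(a: str, b: str) -> tuple[str, str]:
    """Edit-distance global path via edlib, as gapped strings."""
    res = edlib.align(a, b, mode="NW", task="path")
    ga, gb = [], []
    i = j = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch in "=X":
            ga.append(a[i : i + ln])
            gb.append(b[j : j + ln])
            i += ln
            j += ln
        elif ch == "I":  # extra in query a
            ga.append(a[i : i + ln])
            gb.append("-" * ln)
            i += ln
        elif ch == "D":  # extra in target b
            ga.append("-" * ln)
            gb.append(b[j : j + ln])
            j += ln
        else:  # pragma: no cover
            raise ValueError(f"unexpected edlib cigar op {ch!r}")
    return "".join(ga), "".join(gb)


def _segment_gapped(a: str, b: str, scoring: Scoring, dp_limit: int) -> tuple[str, str]:
    if not a and not b:
        return "", ""
    if not a:
        return "-" * len(b), b
    if not b:
        return a, "-" * len(a)
    if max(len(a), len(b)) <= dp_limit:
        ga, gb, _ = nw_align(a, b, scoring)
        return ga, gb
    return _edlib_gapped(a, b)


def anchored_global_align(
    a: str,
    b: str,
    scoring: Scoring = Scoring(),
    k: int = 21,
    dp_limit: int = 6000,
) -> tuple[str, str]:
    """Global alignment of long sequences via unique k-mer anchor chaining."""
    chain = chain_anchors(anchor_runs(a, b, k=k))
    if not chain:
        raise StructuralDivergenceError(
            "no collinear anchor chain between sequences; run structural comparison"
        )
    ga_parts: list[str] = []
    gb_parts: list[str] = []
    ca = cb = 0
    for pa, pb, ln in chain:
        sa, sb = _segment_gapped(a[ca:pa], b[cb:pb], scoring, dp_limit)
        ga_parts.append(sa)
        gb_parts.append(sb)
        ga_parts.append(a[pa : pa + ln])
        gb_parts.append(b[pb : pb + ln])
        ca, cb = pa + ln, pb + ln
    sa, sb = _segment_gapped(a[ca:], b[cb:], scoring, dp_limit)
    ga_parts.append(sa)
    gb_parts.append(sb)
    return "".join(ga_parts), "".join(gb_parts)
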