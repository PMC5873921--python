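"""Circularisation and vector trimming of linear BAC draft assemblies.

A non-split assembly of a circular molecule (insert ligated into a
cloning vector) produces a linear contig whose two ends carry the same
sequence.  This module detects that end-overlap (k-mer seeded, verified
by alignment), trims the redundant terminal copy to recover the circle,
locates the cloning vector on either strand (allowing the match to wrap
the origin), and removes it to yield the linear insert.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import edlib

from .contig import Contig, revcomp

SEED_K = 15  # seeding k-mer for end-overlap detection
END_SLACK = 5  # bp of terminal consensus noise tolerated at contig ends


@dataclass(frozen=True)
class OverlapHit:
    """An end-anchored alignment between a contig's two ends.

    ``prefix_interval`` covers the 5' copy, ``suffix_interval`` the 3'
    copy of the duplicated overlap, both 0-based half-open on the same
    contig.  ``length`` is the prefix copy length.
    """

    prefix_interval: tuple[int, int]
    suffix_interval: tuple[int, int]
    length: int
    identity: float

    def __post_init__(self) -> None:
        if self.prefix_interval[1] > self.suffix_interval[0]:
            raise ValueError("overlap copies overlap each other")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity out of [0, 1]")


def _identity_from_cigar(cigar: str) -> tuple[float, int]:
    """(matches / alignment columns, columns) from an edlib extended CIGAR."""
    matches = cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        ln, num = int(num), ""
        cols += ln
        if ch == "=":
            matches += ln
    return (matches / cols if cols else 0.0), cols


def detect_end_overlap(
    c: Contig, min_len: int = 500, min_identity: float = 0.95
) -> OverlapHit | None:
    """Find the duplicated end-overlap of a linear assembly of a circle.

    Matches unique ``SEED_K``-mers between the first and last
    ``min(4*min_len, L/2)`` bases, reads the overlap length off the
    dominant diagonal, and verifies by global alignment of the two
    candidate copies.  The hit must be end-anchored: it reaches the 5'
    start and 3' end within ``END_SLACK`` bp.  Returns None when no
    candidate meets the thresholds.
    """
    if min_len < 50:
        raise ValueError("min_len must be >= 50")
    if not 0.8 <= min_identity <= 1.0:
        raise ValueError("min_identity must lie in [0.8, 1.0]")
    L = len(c)
    if L < 2 * min_len:
        raise ValueError(f"{c.id}: contig shorter than 2*min_len")
    if c.circular:
        raise ValueError("end-overlap detection applies to linear contigs")
    # window sized to catch overlaps much longer than min_len (a non-split
    # circle assembly duplicates ~10% of the contig, not just min_len bases)
    W = min(max(4 * min_len, L // 4), L // 2)
    head, tail = c.seq[:W], c.seq[L - W :]

    # seed: k-mer positions, histogram of implied overlap lengths
    k = SEED_K
    tail_index: dict[str, list[int]] = {}
    for j in range(W - k + 1):
        tail_index.setdefault(tail[j : j + k], []).append(j)
    votes: dict[int, int] = {}
    for i in range(W - k + 1):
        for j in tail_index.get(head[i : i + k], ()):
            # head pos i corresponds to global tail pos (L - W + j);
            # a duplicated overlap of length ell satisfies tail = L - ell + i
            ell = L - (L - W + j) + i
            if ell >= min_len:
                votes[ell] = votes.get(ell, 0) + 1
    if not votes:
        return None

    best_hit: OverlapHit | None = None
    for ell, _n in sorted(votes.items(), key=lambda kv: -kv[1])[:5]:
        # verify: prefix copy vs suffix copy, allowing small length drift
        lo = max(min_len, ell - END_SLACK)
        hi = min(L // 2, ell + END_SLACK)
        prefix = c.seq[:ell]
        best = None
        for ell_s in range(lo, hi + 1):
            res = edlib.align(prefix, c.seq[L - ell_s :], mode="NW", task="path")
            ident, cols = _identity_from_cigar(res["cigar"])
            if best is None or ident > best[0]:
                best = (ident, ell_s)
        ident, ell_s = best
        if ident >= min_identity:
            hit = OverlapHit(
                prefix_interval=(0, ell),
                suffix_interval=(L - ell_s, L),
                length=ell,
                identity=ident,
            )
            if best_hit is None or hit.identity * hit.length > best_hit.identity * best_hit.length:
                best_hit = hit
    return best_hit


def trim_and_circularize(c: Contig, hit: OverlapHit) -> Contig:
    """Remove the terminal overlap copy and mark the contig circular."""
    L = len(c)
    s, e = hit.suffix_interval
    if e != L or not (0 < s < L):
        raise ValueError("overlap hit inconsistent with contig")
    return replace(
        c,
        seq=c.seq[:s],
        circular=True,
        provenance=c.provenance + f" | circularised (trimmed {e - s} bp end-overlap)",
    )


def find_and_trim_vector(
    c: Contig, vector: Contig, min_identity: float = 0.95
) -> tuple[Contig, bool]:
    """Locate and excise the cloning vector from a circular contig.

    Searches both strands, allowing the vector match to wrap the origin,
    and returns the LINEAR insert starting at the base following the
    vector's 3' end on the contig's forward strand.  When no match covers
    at least 90% of the vector at ``min_identity``, the input is returned
    unchanged together with a warning flag (second return value True).
    """
    if not c.circular:
        raise ValueError("vector trimming applies to circular contigs")
    if vector.circular:
        raise ValueError("vector must be linear")
    if len(vector) > len(c):
        raise ValueError("vector longer than contig")
    L = len(c)
    wrap = c.seq + c.seq[: len(vector) + 50]  # let the match cross the origin

    best = None  # (identity, start, end, strand) on the doubled sequence
    for strand, query in (("+", vector.seq), ("-", revcomp(vector.seq))):
        res = edlib.align(query, wrap, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        ident, cols = _identity_from_cigar(res["cigar"])
        s, e = res["locations"][0]
        e += 1  # edlib end is inclusive
        coverage = cols / len(vector)
        if coverage >= 0.9 and (best is None or ident > best[0]):
            best = (ident, s, e, strand)

    if best is None or best[0] < min_identity:
        return c, True
    _ident, s, e, strand = best
    insert = (c.seq[e:] + c.seq[:s]) if e <= L else c.seq[e - L : s]
    return (
        Contig(
            id=c.id + "_insert",
            seq=insert,
            circular=False,
            provenance=c.provenance
            + f" | vector removed ({strand} strand, identity {_ident:.4f})",
        ),
        False,
    )


def circularize_report(hit: OverlapHit | None, before: Contig, after: Contig) -> str:
    return json.dumps(
        {
            "input_len": len(before),
            "output_len": len(after),
            "overlap_found": hit is not None,
            "overlap_len": hit.length if hit else 0,
            "overlap_identity": hit.identity if hit else None,
        },
        indent=2,
    )
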