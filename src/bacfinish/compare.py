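"""Replicate-assembly comparison: alignment, difference classification,
per-bp error rates, and structural screening.

Two finished assemblies of the same BAC molecule should differ only by
residual consensus errors, which for long-read assemblies are dominated
by short indels.  This module aligns two contigs globally, classifies
every differing alignment column into SNP / insertion / deletion records,
and summarises them as per-base-pair error rates over a stated
denominator.  A separate anchor-based screen reports inversions,
translocations and large indels, so that base-level rates are only
interpreted on structurally concordant pairs.

Counting conventions
--------------------
* each maximal run of gap columns in one row is ONE indel whose length is
  the run length (a 2-column gap run is one 2 bp indel, not two 1 bp ones);
* every mismatch column is one SNP; adjacent SNPs stay separate records;
* a gap run adjacent to a mismatch column is one indel plus one SNP —
  alignment columns are read naively, with no re-alignment normalisation;
* columns where either row is N are excluded from both SNP and match
  counting and tallied separately;
* indels are left-aligned (shifted maximally left within equal-base
  context) so reported positions do not depend on the aligner's tie-breaks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._align import (
    Scoring,
    StructuralDivergenceError,
    anchored_global_align,
    nw_align,
)
from .contig import Contig, revcomp

DIRECT_DP_LIMIT = 3000  # full-matrix DP below this, anchor chaining above


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment as two equal-length gapped rows.

    ``excluded`` optionally marks columns that were never aligned (e.g.
    between AXT blocks); such columns never count as conserved or as
    differences.
    """

    gapped_a: str
    gapped_b: str
    id_a: str = "a"
    id_b: str = "b"
    excluded: np.ndarray | None = None  # bool per column

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped rows differ in length")
        for ca, cb in zip(self.gapped_a, self.gapped_b):
            if ca == "-" and cb == "-":
                raise ValueError("alignment column with gap in both rows")
        if self.excluded is not None and len(self.excluded) != len(self.gapped_a):
            raise ValueError("excluded mask length mismatch")

    @property
    def aln_len(self) -> int:
        return len(self.gapped_a)

    @property
    def ungapped_a(self) -> str:
        return self.gapped_a.replace("-", "")

    @property
    def ungapped_b(self) -> str:
        return self.gapped_b.replace("-", "")

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-column 0-based positions on each ungapped row (-1 at gaps)."""
        arr_a = np.frombuffer(self.gapped_a.encode(), dtype=np.uint8)
        arr_b = np.frombuffer(self.gapped_b.encode(), dtype=np.uint8)
        gap = ord("-")
        pa = np.where(arr_a != gap, np.cumsum(arr_a != gap) - 1, -1)
        pb = np.where(arr_b != gap, np.cumsum(arr_b != gap) - 1, -1)
        return pa, pb


@dataclass(frozen=True)
class DifferenceRecord:
    """One classified discrepancy between two aligned sequences.

    ``kind='insertion'`` means sequence b carries extra bases absent from a;
    ``kind='deletion'`` means b lacks bases present in a.  Positions are
    0-based on each ungapped sequence; for indels they point at the first
    base of the affected run (after left-alignment), and on the sequence
    without the bases they give the position the bases would occupy.
    """

    kind: Literal["snp", "insertion", "deletion"]
    pos_a: int
    pos_b: int
    length: int
    alleles: tuple[str, str]


@dataclass
class ErrorRateReport:
    """Counts and per-bp rates of SNPs and indels over a stated denominator."""

    n_snp: int
    n_indel: int
    indel_length_histogram: dict[int, int]
    denominator_len: int
    denominator_kind: str = "alignment_length"
    excluded_cols: int = 0

    def __post_init__(self) -> None:
        if self.denominator_len <= 0:
            raise ValueError("denominator length must be positive")
        if sum(self.indel_length_histogram.values()) != self.n_indel:
            raise ValueError("indel histogram does not sum to n_indel")

    @property
    def snp_rate(self) -> float:
        return self.n_snp / self.denominator_len

    @property
    def indel_rate(self) -> float:
        return self.n_indel / self.denominator_len

    @property
    def single_to_double_ratio(self) -> float | None:
        """count(length 1) / count(length 2); None when no 2 bp indels."""
        doubles = self.indel_length_histogram.get(2, 0)
        if doubles == 0:
            return None
        return self.indel_length_histogram.get(1, 0) / doubles

    @staticmethod
    def _sig2(x: float) -> str:
        return f"{x:.1e}" if x else "0"

    def to_dict(self) -> dict:
        return {
            "n_snp": self.n_snp,
            "n_indel": self.n_indel,
            "indel_length_histogram": {str(k): v for k, v in sorted(self.indel_length_histogram.items())},
            "denominator_len": self.denominator_len,
            "denominator_kind": self.denominator_kind,
            "snp_rate": self.snp_rate,
            "indel_rate": self.indel_rate,
            "snp_rate_2sf": self._sig2(self.snp_rate),
            "indel_rate_2sf": self._sig2(self.indel_rate),
            "single_to_double_ratio": self.single_to_double_ratio,
            "excluded_cols": self.excluded_cols,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


@dataclass
class StructuralReport:
    """Anchor map and breakpoint calls between two assemblies."""

    anchors: list[tuple[int, int, int, str]]  # (pos_a, pos_b, len, strand)
    breakpoints: list[dict] = field(default_factory=list)

    @property
    def collinear(self) -> bool:
        return not self.breakpoints

    def to_dict(self) -> dict:
        return {
            "n_anchors": len(self.anchors),
            "collinear": self.collinear,
            "breakpoints": self.breakpoints,
            "anchors": [
                {"pos_a": a, "pos_b": b, "len": ln, "strand": s}
                for a, b, ln, s in self.anchors
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


# ---------------------------------------------------------------------------


def align_pair(a: Contig, b: Contig, scoring: Scoring = Scoring()) -> PairwiseAlignment:
    """Globally align two assemblies of the same molecule.

    Short pairs (≤ 3 kb) get a full affine-gap DP; longer pairs are aligned
    by chaining unique 21-mer anchors and closing the short gaps between
    them with the same DP.  Raises :class:`StructuralDivergenceError` when
    no collinear anchor chain exists — run :func:`check_structure` then.
    """
    for c in (a, b):
        if len(c) > 1_000_000:
            raise ValueError(f"{c.id}: contig exceeds 1 Mb comparison limit")
    if max(len(a), len(b)) <= DIRECT_DP_LIMIT:
        ga, gb, _ = nw_align(a.seq, b.seq, scoring)
    else:
        ga, gb = anchored_global_align(a.seq, b.seq, scoring)
    return PairwiseAlignment(ga, gb, id_a=a.id, id_b=b.id)


def _left_align(seq: str, pos: int, length: int) -> int:
    """Shift an indel's start maximally left within equal-base context."""
    while pos > 0 and seq[pos - 1] == seq[pos + length - 1]:
        pos -= 1
    return pos


def classify_differences(aln: PairwiseAlignment) -> list[DifferenceRecord]:
    """Read the alignment column by column into SNP and indel records."""
    a, b = aln.gapped_a, aln.gapped_b
    ua, ub = aln.ungapped_a, aln.ungapped_b
    excluded = aln.excluded
    records: list[DifferenceRecord] = []
    pa = pb = 0
    i = 0
    n = aln.aln_len
    while i < n:
        ca, cb = a[i], b[i]
        if excluded is not None and excluded[i]:
            pa += ca != "-"
            pb += cb != "-"
            i += 1
            continue
        if ca == "-" or cb == "-":
            gap_in_a = ca == "-"
            j = i
            while j < n and ((a[j] == "-") if gap_in_a else (b[j] == "-")) and not (
                excluded is not None and excluded[j]
            ):
                j += 1
            length = j - i
            if gap_in_a:
                pos_b = _left_align(ub, pb, length)
                shift = pb - pos_b
                records.append(
                    DifferenceRecord("insertion", pa - shift, pos_b, length,
                                     ("-", ub[pos_b : pos_b + length]))
                )
                pb += length
            else:
                pos_a = _left_align(ua, pa, length)
                shift = pa - pos_a
                records.append(
                    DifferenceRecord("deletion", pos_a, pb - shift, length,
                                     (ua[pos_a : pos_a + length], "-"))
                )
                pa += length
            i = j
            continue
        if ca != cb and ca in "ACGT" and cb in "ACGT":
            records.append(DifferenceRecord("snp", pa, pb, 1, (ca, cb)))
        pa += 1
        pb += 1
        i += 1
    records.sort(key=lambda r: (r.pos_a, r.pos_b))
    return records


def count_excluded_columns(aln: PairwiseAlignment) -> int:
    """Columns removed from SNP/match counting: N-containing or unaligned."""
    n_cols = sum(
        1 for ca, cb in zip(aln.gapped_a, aln.gapped_b) if "N" in (ca, cb)
    )
    if aln.excluded is not None:
        n_cols += int(aln.excluded.sum())
    return n_cols


def error_rates(
    diffs: list[DifferenceRecord],
    denominator_len: int,
    denominator_kind: str = "alignment_length",
    excluded_cols: int = 0,
) -> ErrorRateReport:
    """Summarise difference records as per-bp SNP and indel error rates.

    The indel rate is the number of insertion plus deletion events divided
    by the stated denominator (alignment length for assembly-vs-assembly
    comparison, sequence length for read-consensus polishing).
    """
    if denominator_len <= 0:
        raise ValueError("denominator length must be positive")
    n_snp = sum(1 for d in diffs if d.kind == "snp")
    hist: dict[int, int] = {}
    for d in diffs:
        if d.kind != "snp":
            hist[d.length] = hist.get(d.length, 0) + 1
    return ErrorRateReport(
        n_snp=n_snp,
        n_indel=sum(hist.values()),
        indel_length_histogram=hist,
        denominator_len=denominator_len,
        denominator_kind=denominator_kind,
        excluded_cols=excluded_cols,
    )


# ---------------------------------------------------------------------------
# structural screen
# ---------------------------------------------------------------------------


def _unique_mer_map(seq: str, k: int) -> dict[str, int]:
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


def _merge_diagonal(matches: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    runs: list[tuple[int, int, int]] = []
    for pa, pb in sorted(matches):
        if runs:
            la, lb, ln = runs[-1]
            if pa == la + ln - k + 1 and pb == lb + ln - k + 1:
                runs[-1] = (la, lb, ln + 1)
                continue
        runs.append((pa, pb, k))
    return runs


def check_structure(
    a: Contig,
    b: Contig,
    min_anchor: int = 100,
    large_indel_threshold: int = 50,
) -> StructuralReport:
    """Screen two assemblies for rearrangements via unique exact anchors.

    Maximal exact matches of unique ``min_anchor``-mers (both strands) are
    merged into anchor blocks and chained collinearly.  Reverse-strand
    blocks become inversion breakpoints, blocks violating the chain order
    become translocations, and inter-anchor length discrepancies above the
    threshold become large-indel breakpoints.  An empty breakpoint list
    means the assemblies are structurally concordant.
    """
    k = min_anchor
    ma = _unique_mer_map(a.seq, k)
    mb = _unique_mer_map(b.seq, k)
    rb = revcomp(b.seq)
    mrb = _unique_mer_map(rb, k)
    fwd = [(pa, mb[km]) for km, pa in ma.items() if km in mb]
    rev = [(pa, mrb[km]) for km, pa in ma.items() if km in mrb]
    fwd_runs = _merge_diagonal(fwd, k)
    # reverse-strand run positions reported on b's forward strand
    rev_runs = [
        (pa, len(b.seq) - (pr + ln), ln, "-")
        for pa, pr, ln in _merge_diagonal(rev, k)
    ]
    anchors = [(pa, pb, ln, "+") for pa, pb, ln in fwd_runs] + rev_runs
    anchors.sort()
    anchors = _drop_overlaps(anchors)

    breakpoints: list[dict] = []
    plus = [r for r in anchors if r[3] == "+"]
    minus = [r for r in anchors if r[3] == "-"]

    chain = _weighted_lis(plus)
    chain_set = set(chain)
    off_chain = [r for r in plus if r not in chain_set]

    # inversions: merge minus-strand blocks that are adjacent on a
    for blk in _merge_events(minus):
        breakpoints.append({"kind": "inversion", "a_interval": blk[0], "b_interval": blk[1]})
    # translocations: maximal runs of off-chain plus blocks
    for blk in _merge_events(off_chain):
        breakpoints.append({"kind": "translocation", "a_interval": blk[0], "b_interval": blk[1]})

    # large indels between consecutive chain anchors, unless another event
    # already occupies the gap
    occupied = [r for r in minus] + off_chain
    for (pa1, pb1, ln1, _), (pa2, pb2, ln2, _) in zip(chain, chain[1:]):
        ga = pa2 - (pa1 + ln1)
        gb = pb2 - (pb1 + ln1)
        if abs(ga - gb) > large_indel_threshold:
            gap_has_event = any(
                pa1 < r[0] < pa2 or pb1 < r[1] < pb2 for r in occupied
            )
            if not gap_has_event:
                breakpoints.append(
                    {
                        "kind": "large_indel",
                        "a_interval": (pa1 + ln1, pa2),
                        "b_interval": (pb1 + ln1, pb2),
                        "delta": int(gb - ga),
                    }
                )
    return StructuralReport(anchors=anchors, breakpoints=breakpoints)


def _drop_overlaps(anchors: list[tuple[int, int, int, str]]) -> list[tuple[int, int, int, str]]:
    """Make anchors non-overlapping on each sequence.

    Longest anchors win; shorter ones are trimmed where they overlap a
    kept anchor (junction k-mers can extend a run a base or two past a
    block boundary) and dropped only when nothing remains.
    """
    kept: list[tuple[int, int, int, str]] = []
    for pa, pb, ln, s in sorted(anchors, key=lambda r: -r[2]):
        for qa, qb, qn, _ in kept:
            if ln <= 0:
                break
            # a-axis overlap
            if pa < qa + qn and qa < pa + ln:
                if qa <= pa:
                    cut = min(qa + qn - pa, ln)
                    pa, pb, ln = pa + cut, pb + cut, ln - cut
                else:
                    ln = qa - pa
            if ln <= 0:
                break
            # b-axis overlap
            if pb < qb + qn and qb < pb + ln:
                if qb <= pb:
                    cut = min(qb + qn - pb, ln)
                    pa, pb, ln = pa + cut, pb + cut, ln - cut
                else:
                    ln = qb - pb
        if ln > 0:
            kept.append((pa, pb, ln, s))
    kept.sort()
    return kept


def _weighted_lis(runs: list[tuple[int, int, int, str]]) -> list[tuple[int, int, int, str]]:
    """Longest chain by total anchored length, increasing in both coords."""
    if not runs:
        return []
    n = len(runs)
    best = [r[2] for r in runs]
    prev = [-1] * n
    for i in range(n):
        pa, pb, ln, _ = runs[i]
        for j in range(i):
            qa, qb, qn, _ = runs[j]
            if qa + qn <= pa and qb + qn <= pb and best[j] + ln > best[i]:
                best[i] = best[j] + ln
                prev[i] = j
    end = int(np.argmax(best))
    chain = []
    while end != -1:
        chain.append(runs[end])
        end = prev[end]
    chain.reverse()
    return chain


def _merge_events(
    blocks: list[tuple[int, int, int, str]], join_gap: int = 5000
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Group blocks adjacent on sequence a into single breakpoint events."""
    events = []
    for pa, pb, ln, _ in sorted(blocks):
        if events and pa - events[-1][0][1] <= join_gap:
            (a0, a1), (b0, b1) = events[-1]
            events[-1] = ((a0, max(a1, pa + ln)), (min(b0, pb), max(b1, pb + ln)))
        else:
            events.append(((pa, pa + ln), (pb, pb + ln)))
    return events


def write_differences_tsv(diffs: list[DifferenceRecord], path) -> None:
    """TSV of difference records, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("kind\tpos_a\tpos_b\tlength\tallele_a\tallele_b\n")
        for d in diffs:
            fh.write(
                f"{d.kind}\t{d.pos_a + 1}\t{d.pos_b + 1}\t{d.length}\t"
                f"{d.alleles[0]}\t{d.alleles[1]}\n"
            )
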