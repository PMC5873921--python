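"""Short-read consensus indel correction of a draft assembly.

Long-read consensus assemblies carry residual short-indel errors that
accurate short reads can fix: reads are mapped to the draft (consumed
here as SAM), a per-position pileup is built, positions where the read
consensus supports an insertion or deletion relative to the draft become
correction targets, and the targets are applied to produce the polished
sequence.  Only indels are corrected; SNP disagreements are reported in
a side channel but never change the draft, matching the observation that
consensus errors of this process are indels, not substitutions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .compare import ErrorRateReport
from .contig import Contig

_ALLOWED_OPS = set("MIDSH")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class MalformedRecordError(ValueError):
    pass


@dataclass(frozen=True)
class PileupColumn:
    """Read support at one draft position.

    ``depth = sum(base_counts.values()) + del_count`` exactly; insertions
    immediately AFTER this position are keyed by inserted string.
    """

    ref_pos: int
    depth: int
    base_counts: dict[str, int]
    del_count: int
    ins_counts: dict[str, int]


class Pileup:
    """Column store over every position of the draft (array-backed)."""

    def __init__(self, draft: Contig):
        self.draft = draft
        L = len(draft)
        self.base_counts = np.zeros((5, L), dtype=np.int32)  # A C G T N
        self.del_count = np.zeros(L, dtype=np.int32)
        self.ins_counts: dict[int, Counter] = {}
        self.n_reads_used = 0

    def __len__(self) -> int:
        return len(self.draft)

    @property
    def depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=0) + self.del_count

    def __getitem__(self, pos: int) -> PileupColumn:
        counts = {
            b: int(self.base_counts[i, pos])
            for b, i in _BASE_INDEX.items()
            if self.base_counts[i, pos]
        }
        return PileupColumn(
            ref_pos=pos,
            depth=int(self.depth[pos]),
            base_counts=counts,
            del_count=int(self.del_count[pos]),
            ins_counts=dict(self.ins_counts.get(pos, {})),
        )

    def __iter__(self) -> Iterator[PileupColumn]:
        for pos in range(len(self)):
            yield self[pos]


def _iter_records(sam, draft_id: str):
    if isinstance(sam, (str, Path)):
        try:
            with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
                yield from fh
        except (ValueError, OSError) as exc:
            raise MalformedRecordError(f"unparseable SAM record in {sam}: {exc}") from exc
    elif isinstance(sam, pysam.AlignmentFile):
        yield from sam
    else:  # iterable of AlignedSegment
        yield from sam


def build_pileup(sam, draft: Contig, min_mapq: int = 20) -> Pileup:
    """Accumulate a pileup over every draft position from SAM records.

    Accepts a path to a SAM file, an open pysam.AlignmentFile, or an
    iterable of AlignedSegment.  Unmapped reads and records below
    ``min_mapq`` are skipped; soft/hard-clipped bases are ignored;
    insertions are attributed to the draft position preceding them.
    CIGAR ops outside M/I/D/S/H are rejected loudly.
    """
    pile = Pileup(draft)
    L = len(draft)
    base_of = np.full(256, 4, dtype=np.intp)
    for b, i in _BASE_INDEX.items():
        base_of[ord(b)] = i

    for rec in _iter_records(sam, draft.id):
        if rec.is_unmapped or rec.cigartuples is None:
            continue
        if rec.mapping_quality < min_mapq:
            continue
        if rec.reference_name not in (None, draft.id):
            raise MalformedRecordError(
                f"read {rec.query_name}: reference {rec.reference_name!r} is not the draft"
            )
        cig = rec.cigarstring or ""
        if any(op not in _ALLOWED_OPS and not op.isdigit() for op in cig):
            raise MalformedRecordError(
                f"read {rec.query_name}: unsupported CIGAR op in {cig!r}"
            )
        seq = rec.query_sequence or ""
        consumed = sum(ln for op, ln in rec.cigartuples if op in (0, 1, 4))
        if consumed != len(seq):
            raise MalformedRecordError(
                f"read {rec.query_name}: CIGAR consumes {consumed} bases but SEQ has {len(seq)}"
            )
        rpos = rec.reference_start
        qpos = 0
        for op, ln in rec.cigartuples:
            if op == 0:  # M
                end = min(rpos + ln, L)
                span = end - rpos
                if span > 0:
                    codes = base_of[np.frombuffer(seq[qpos : qpos + span].encode(), np.uint8)]
                    np.add.at(pile.base_counts, (codes, np.arange(rpos, end)), 1)
                rpos += ln
                qpos += ln
            elif op == 1:  # I -> attributed to preceding draft position
                if 0 < rpos <= L:
                    pile.ins_counts.setdefault(rpos - 1, Counter())[seq[qpos : qpos + ln]] += 1
                qpos += ln
            elif op == 2:  # D
                end = min(rpos + ln, L)
                if end > rpos:
                    pile.del_count[rpos:end] += 1
                rpos += ln
            elif op == 4:  # S
                qpos += ln
            elif op == 5:  # H
                pass
            else:
                raise MalformedRecordError(
                    f"read {rec.query_name}: unsupported CIGAR op code {op}"
                )
        pile.n_reads_used += 1
    return pile


@dataclass(frozen=True)
class IndelTarget:
    """One consensus-supported correction on the draft.

    Insertions insert ``seq`` AFTER ``ref_pos``; deletions remove
    ``length`` bases starting AT ``ref_pos``.
    """

    ref_pos: int
    kind: str  # insertion | deletion
    seq: str = ""
    length: int = 0
    support_fraction: float = 0.0
    depth: int = 0

    @property
    def net_length_change(self) -> int:
        return len(self.seq) if self.kind == "insertion" else -self.length


def call_indel_targets(
    pileup: Pileup,
    min_depth: int = 10,
    min_fraction: float = 0.7,
) -> tuple[list[IndelTarget], list[dict]]:
    """Call consensus indel targets from the pileup; one pass, indels only.

    A deletion is called where the fraction of reads deleting a position
    reaches ``min_fraction`` at depth >= ``min_depth`` (consecutive
    deletion columns merge into one target); an insertion is called where
    the modal inserted string reaches the same support.  Positions inside
    called deletions are masked from further calling.  SNP-like base
    disagreements are returned as a side channel and never become
    targets.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not 0.5 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0.5, 1.0]")
    L = len(pileup)
    depth = pileup.depth
    draft_seq = pileup.draft.seq

    del_supported = (depth >= min_depth) & (pileup.del_count >= min_fraction * depth) & (depth > 0)
    targets: list[IndelTarget] = []
    masked = np.zeros(L, dtype=bool)
    i = 0
    while i < L:
        if not del_supported[i]:
            i += 1
            continue
        j = i
        while j < L and del_supported[j]:
            j += 1
        frac = float((pileup.del_count[i:j] / depth[i:j]).min())
        targets.append(
            IndelTarget(
                ref_pos=i,
                kind="deletion",
                length=j - i,
                support_fraction=frac,
                depth=int(depth[i:j].min()),
            )
        )
        masked[i:j] = True
        i = j

    for pos, counter in sorted(pileup.ins_counts.items()):
        if masked[pos] or depth[pos] < min_depth or depth[pos] == 0:
            continue
        # deterministic modal choice: highest count, then lexicographic
        best_seq, best_n = min(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        frac = best_n / depth[pos]
        if frac >= min_fraction:
            targets.append(
                IndelTarget(
                    ref_pos=pos,
                    kind="insertion",
                    seq=best_seq,
                    support_fraction=float(frac),
                    depth=int(depth[pos]),
                )
            )
    targets.sort(key=lambda t: (t.ref_pos, t.kind))

    snp_channel: list[dict] = []
    bc = pileup.base_counts[:4]
    covered = np.nonzero(depth >= min_depth)[0]
    modal = bc[:, covered].argmax(axis=0)
    modal_n = bc[:, covered].max(axis=0)
    for idx, pos in enumerate(covered):
        base = "ACGT"[modal[idx]]
        if base != draft_seq[pos] and modal_n[idx] >= min_fraction * depth[pos]:
            snp_channel.append(
                {"ref_pos": int(pos), "draft_base": draft_seq[pos], "consensus_base": base,
                 "support": int(modal_n[idx]), "depth": int(depth[pos])}
            )
    return targets, snp_channel


class CoordinateMap:
    """Old-draft to corrected-draft position translation for unedited bases."""

    def __init__(self, targets: list[IndelTarget], old_len: int):
        self._breaks: list[tuple[int, int]] = [(0, 0)]  # (old_pos, cumulative shift)
        shift = 0
        for t in sorted(targets, key=lambda t: t.ref_pos):
            if t.kind == "insertion":
                shift += len(t.seq)
                self._breaks.append((t.ref_pos + 1, shift))
            else:
                shift -= t.length
                self._breaks.append((t.ref_pos + t.length, shift))
        self._deleted = [
            (t.ref_pos, t.ref_pos + t.length) for t in targets if t.kind == "deletion"
        ]
        self.old_len = old_len

    def __call__(self, old_pos: int) -> int:
        if not 0 <= old_pos < self.old_len:
            raise IndexError(old_pos)
        for s, e in self._deleted:
            if s <= old_pos < e:
                raise KeyError(f"position {old_pos} was deleted")
        shift = 0
        for bp, sh in self._breaks:
            if bp <= old_pos:
                shift = sh
        return old_pos + shift


def apply_targets(draft: Contig, targets: list[IndelTarget]) -> tuple[Contig, CoordinateMap]:
    """Apply sorted, non-overlapping targets right-to-left.

    Output length = input length + sum(insertions) - sum(deletions).
    """
    ordered = sorted(targets, key=lambda t: t.ref_pos)
    for t1, t2 in zip(ordered, ordered[1:]):
        end1 = t1.ref_pos + (t1.length if t1.kind == "deletion" else 0)
        if t2.ref_pos < end1 or (t1.ref_pos == t2.ref_pos):
            raise ValueError(f"overlapping targets at {t1.ref_pos} and {t2.ref_pos}")
    seq = draft.seq
    for t in reversed(ordered):
        if t.kind == "insertion":
            seq = seq[: t.ref_pos + 1] + t.seq + seq[t.ref_pos + 1 :]
        elif t.kind == "deletion":
            seq = seq[: t.ref_pos] + seq[t.ref_pos + t.length :]
        else:
            raise ValueError(f"unknown target kind {t.kind!r}")
    corrected = Contig(
        id=draft.id + "_polished",
        seq=seq,
        circular=draft.circular,
        provenance=draft.provenance + f" | {len(ordered)} consensus indel corrections",
    )
    return corrected, CoordinateMap(ordered, len(draft))


def polish_report(targets: list[IndelTarget], denominator_len: int) -> ErrorRateReport:
    """Indel error rate: number of targets over the stated sequence length."""
    hist: dict[int, int] = {}
    for t in targets:
        ln = len(t.seq) if t.kind == "insertion" else t.length
        hist[ln] = hist.get(ln, 0) + 1
    return ErrorRateReport(
        n_snp=0,
        n_indel=len(targets),
        indel_length_histogram=hist,
        denominator_len=denominator_len,
        denominator_kind="sequence_length",
    )


def write_targets_tsv(targets: Iterable[IndelTarget], path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tkind\tseq_or_len\tdepth\tsupport\n")
        for t in targets:
            val = t.seq if t.kind == "insertion" else str(t.length)
            fh.write(f"{t.ref_pos + 1}\t{t.kind}\t{val}\t{t.depth}\t{t.support_fraction:.3f}\n")
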