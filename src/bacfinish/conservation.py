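"""Windowed sequence conservation along a pairwise alignment.

Conservation between two S-locus haplotypes is summarised as the
proportion of conserved bases per fixed-size window (default 250 bp)
laid along the first (query) sequence's ungapped coordinates.  The
alignment is consumed either as an AXT file (the blocks of a local
aligner, concatenated in target order with unaligned target spans kept
as excluded stretches) or as a 2-record aligned FASTA.

Conventions (declared, since tools differ): a query position aligned to
a gap in the other sequence counts as non-conserved; unaligned/excluded
spans count as non-conserved and are additionally tallied in
``excluded_cols``; comparison is case-insensitive and N never matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .compare import PairwiseAlignment


@dataclass(frozen=True)
class ConservationWindow:
    window_index: int
    ref_interval: tuple[int, int]  # 0-based half-open on A's ungapped coords
    conserved_fraction: float
    aligned_cols: int
    excluded_cols: int


def _parse_axt_text(text: str) -> PairwiseAlignment:
    blocks = []
    lines = [ln.rstrip("\n") for ln in text.splitlines()]
    i = 0
    while i < len(lines):
        if not lines[i].strip() or lines[i].startswith("#"):
            i += 1
            continue
        header = lines[i].split()
        if len(header) < 9:
            raise ValueError(f"malformed AXT header: {lines[i]!r}")
        t_start, t_end = int(header[2]), int(header[3])
        if i + 2 >= len(lines):
            raise ValueError("truncated AXT block")
        seq_t, seq_q = lines[i + 1].strip().upper(), lines[i + 2].strip().upper()
        if len(seq_t) != len(seq_q):
            raise ValueError("AXT block rows differ in length")
        if len(seq_t.replace("-", "")) != t_end - t_start + 1:
            raise ValueError("AXT target span disagrees with sequence length")
        blocks.append((t_start, t_end, seq_t, seq_q))
        i += 3
    if not blocks:
        raise ValueError("no AXT blocks found")
    blocks.sort(key=lambda b: b[0])
    for (s1, e1, *_), (s2, *_rest) in zip(blocks, blocks[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping AXT target blocks at {s2}")

    ga, gb, excl = [], [], []
    prev_end = 0  # AXT coordinates are 1-based; cover the target from base 1
    for t_start, t_end, seq_t, seq_q in blocks:
        gap = t_start - 1 - prev_end
        if gap > 0:
            ga.append("N" * gap)
            gb.append("-" * gap)
            excl.extend([True] * gap)
        ga.append(seq_t)
        gb.append(seq_q)
        excl.extend([False] * len(seq_t))
        prev_end = t_end
    return PairwiseAlignment(
        "".join(ga), "".join(gb), excluded=np.array(excl, dtype=bool)
    )


def _parse_aligned_fasta(path: str | Path) -> PairwiseAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"aligned FASTA must hold exactly 2 records, found {len(records)}")
    a, b = (str(r.seq).upper() for r in records)
    if len(a) != len(b):
        raise ValueError("aligned FASTA rows differ in gapped length")
    return PairwiseAlignment(a, b, id_a=records[0].id, id_b=records[1].id)


def read_pairwise_alignment(source: str | Path) -> PairwiseAlignment:
    """Load a pairwise alignment from an AXT file or a 2-record aligned FASTA.

    Format is decided by extension (.axt) or by sniffing for a '>' header.
    """
    path = Path(source)
    text = path.read_text()
    if path.suffix.lower() == ".axt" or not text.lstrip().startswith(">"):
        return _parse_axt_text(text)
    return _parse_aligned_fasta(path)


def window_conservation(
    aln: PairwiseAlignment, window: int = 250, step: int | None = None
) -> list[ConservationWindow]:
    """Proportion of conserved bases per window of sequence A.

    Windows tile A's ungapped coordinates in consecutive ``window`` bp
    blocks (``step`` defaults to ``window``, i.e. fixed non-overlapping
    windows; a smaller step gives a true sliding window).  The final
    partial window is reported with its true length as denominator.
    """
    if window < 10:
        raise ValueError("window must be >= 10")
    step = step or window
    if step < 1:
        raise ValueError("step must be >= 1")
    arr_a = np.frombuffer(aln.gapped_a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(aln.gapped_b.encode(), dtype=np.uint8)
    gap = ord("-")
    a_cols = arr_a != gap
    n_a = int(a_cols.sum())
    excl_cols = (
        aln.excluded if aln.excluded is not None else np.zeros(len(arr_a), dtype=bool)
    )
    acgt = np.zeros(256, dtype=bool)
    for ch in "ACGTacgt":
        acgt[ord(ch)] = True
    upper = np.arange(256, dtype=np.uint8)
    upper[ord("a") : ord("z") + 1] -= 32
    conserved_col = (
        (upper[arr_a] == upper[arr_b]) & acgt[arr_a] & acgt[arr_b] & ~excl_cols
    )
    # project onto A's ungapped positions
    conserved = conserved_col[a_cols]
    aligned = ((arr_b != gap) & ~excl_cols)[a_cols]
    excluded = (excl_cols | (upper[arr_a] == ord("N")))[a_cols]

    out: list[ConservationWindow] = []
    idx = 0
    for start in range(0, n_a, step):
        end = min(start + window, n_a)
        size = end - start
        out.append(
            ConservationWindow(
                window_index=idx,
                ref_interval=(start, end),
                conserved_fraction=float(conserved[start:end].sum()) / size,
                aligned_cols=int(aligned[start:end].sum()),
                excluded_cols=int(excluded[start:end].sum()),
            )
        )
        idx += 1
        if end >= n_a:
            break
    return out


def write_windows_tsv(windows: list[ConservationWindow], path) -> None:
    """TSV with 1-based inclusive intervals and fractions to 4 decimals."""
    with open(path, "w") as fh:
        fh.write("window\tstart\tend\tconserved_fraction\taligned_cols\texcluded_cols\n")
        for w in windows:
            s, e = w.ref_interval
            fh.write(
                f"{w.window_index}\t{s + 1}\t{e}\t{w.conserved_fraction:.4f}\t"
                f"{w.aligned_cols}\t{w.excluded_cols}\n"
            )
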