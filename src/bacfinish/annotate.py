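"""S-locus annotation: primer-anchored SRK candidate extraction,
identity-based SRK/ARK3 classification, and 8-cysteine SCR detection.

The pistil-side self-incompatibility gene SRK is located by degenerate
primer sites for its exon 1 (forward SLGF, reverse SLGR); candidate
regions are the amplicon between a compatible primer pair, or 1 kb of
flank around a lone site.  Candidates are accepted as SRK or rejected as
the confusable flanking kinase ARK3 by best local-alignment identity
against reference allele sets (>= 90% by default).  The pollen-side gene
SCR evades homology search; its exon 2 is instead recognised by an open
reading frame whose translation carries the conserved pattern of 8
cysteine residues within a short span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from ._align import sw_local
from .contig import Contig, revcomp

IUPAC = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011, "B": 0b1110, "D": 0b1101,
    "H": 0b1011, "V": 0b0111, "N": 0b1111,
}
_SEQ_BITS = np.zeros(256, dtype=np.uint8)
for _b, _m in (("A", 1), ("C", 2), ("G", 4), ("T", 8)):
    _SEQ_BITS[ord(_b)] = _m
# N in the subject sequence matches nothing (bits stay 0)

_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp_iupac(primer: str) -> str:
    return primer.translate(_IUPAC_COMP)[::-1]


@dataclass(frozen=True)
class PrimerHit:
    """One primer binding site on the contig's forward-strand coordinates."""

    primer_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    mismatches: int


@dataclass
class CandidateRegion:
    """A putative SRK exon-1 region with its classification evidence."""

    interval: tuple[int, int]  # 0-based half-open
    anchor: str  # both_primers | single_primer
    verdict: str = "undetermined"  # srk | ark3 | undetermined
    best_identity_srk: float = 0.0
    best_identity_ark3: float = 0.0
    hits: list[PrimerHit] = field(default_factory=list)


@dataclass(frozen=True)
class ScrHit:
    """An ORF whose translation shows the 8-cysteine SCR signature."""

    orf_interval: tuple[int, int]  # 0-based half-open, contig forward strand
    strand: str
    frame: int  # 0,1,2 on the reading strand
    cys_positions: tuple[int, ...]  # protein coordinates of the 8 cysteines
    span_aa: int  # residues from first to last cysteine, inclusive


def _primer_mask(primer: str) -> np.ndarray:
    try:
        return np.array([IUPAC[b] for b in primer.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"primer contains non-IUPAC character {exc.args[0]!r}") from exc


def find_primer_sites(
    c: Contig, primers: dict[str, str], max_mismatch: int = 3
) -> list[PrimerHit]:
    """All Hamming matches of each primer on both strands, sorted by start.

    Degenerate IUPAC bases in the primer match their base set at zero
    cost; N in the contig matches nothing.  No indels are considered —
    primer sites are short enough that substitution-only matching is the
    appropriate model.
    """
    if not primers:
        raise ValueError("no primers given")
    seq_bits = _SEQ_BITS[np.frombuffer(c.seq.encode(), dtype=np.uint8)]
    L = len(c)
    hits: list[PrimerHit] = []
    for pid, primer in primers.items():
        plen = len(primer)
        if plen == 0:
            raise ValueError(f"primer {pid!r} is empty")
        if max_mismatch > plen // 4:
            raise ValueError("max_mismatch must be <= primer length / 4")
        if plen > L:
            continue
        for strand, pseq in (("+", primer), ("-", _revcomp_iupac(primer))):
            mask = _primer_mask(pseq)
            n_windows = L - plen + 1
            mism = np.zeros(n_windows, dtype=np.int16)
            for j in range(plen):
                mism += (seq_bits[j : j + n_windows] & mask[j]) == 0
            for start in np.nonzero(mism <= max_mismatch)[0]:
                hits.append(PrimerHit(pid, int(start), int(start) + plen, strand, int(mism[start])))
    hits.sort(key=lambda h: (h.start, h.primer_id, h.strand))
    return hits


def extract_candidates(
    c: Contig,
    hits: list[PrimerHit],
    max_pair_span: int = 5000,
    flank: int = 1000,
    fwd_id: str = "SLGF",
    rev_id: str = "SLGR",
) -> list[CandidateRegion]:
    """Candidate regions from primer hits: amplicons and lone-site flanks.

    Each compatible forward/reverse pair (opposite orientations, within
    ``max_pair_span``) yields one region spanning both primers inclusive;
    every unpaired hit yields a region of 1 kb up- and downstream of the
    primer, truncated at contig ends.
    """
    L = len(c)
    fwd = [h for h in hits if h.primer_id == fwd_id]
    rev = [h for h in hits if h.primer_id == rev_id]
    used: set[tuple] = set()
    regions: list[CandidateRegion] = []
    for f in fwd:
        for r in rev:
            if f.strand == r.strand:
                continue
            lo = min(f.start, r.start)
            hi = max(f.end, r.end)
            if hi - lo > max_pair_span:
                continue
            # amplicon geometry: the + primer must lie 5' of the - primer
            left, right = (f, r) if f.start <= r.start else (r, f)
            if left.strand != "+" or right.strand != "-":
                continue
            regions.append(CandidateRegion((lo, hi), "both_primers", hits=[f, r]))
            used.add((f.start, f.primer_id, f.strand))
            used.add((r.start, r.primer_id, r.strand))
    for h in hits:
        if h.primer_id not in (fwd_id, rev_id):
            continue
        if (h.start, h.primer_id, h.strand) in used:
            continue
        regions.append(
            CandidateRegion(
                (max(0, h.start - flank), min(L, h.end + flank)),
                "single_primer",
                hits=[h],
            )
        )
    regions.sort(key=lambda r: r.interval)
    return regions


def classify_candidate(
    region_seq: str,
    srk_refs: list[Contig],
    ark3_refs: list[Contig],
    threshold: float = 0.90,
    min_cols: int = 100,
) -> tuple[str, float, float]:
    """(verdict, best_identity_srk, best_identity_ark3) for a candidate.

    Identity is matches over alignment columns of the best local
    alignment (match +1, mismatch -1, gap -2), both strands, against
    every reference in each set.  Alignments shorter than ``min_cols``
    columns are ignored (a 20 bp chance match to an unrelated reference
    would otherwise report near-perfect identity).  Verdict ``srk``
    requires identity >= ``threshold`` (inclusive) AND strictly greater
    than the ARK3 best; ``ark3`` symmetric; otherwise ``undetermined``.
    """
    if not region_seq:
        raise ValueError("empty candidate sequence")
    if not srk_refs or not ark3_refs:
        raise ValueError("reference sets must be non-empty")

    def best_identity(refs: list[Contig]) -> float:
        best = 0.0
        for ref in refs:
            for query in (region_seq, revcomp(region_seq)):
                hit = sw_local(query, ref.seq)
                if hit.columns >= min_cols and hit.identity > best:
                    best = hit.identity
        return best

    srk_id = best_identity(srk_refs)
    ark3_id = best_identity(ark3_refs)
    if srk_id >= threshold and srk_id > ark3_id:
        verdict = "srk"
    elif ark3_id >= threshold and ark3_id > srk_id:
        verdict = "ark3"
    else:
        verdict = "undetermined"
    return verdict, srk_id, ark3_id


def classify_regions(
    c: Contig,
    regions: list[CandidateRegion],
    srk_refs: list[Contig],
    ark3_refs: list[Contig],
    threshold: float = 0.90,
) -> list[CandidateRegion]:
    """Fill verdict fields of every candidate region in place."""
    for r in regions:
        s, e = r.interval
        r.verdict, r.best_identity_srk, r.best_identity_ark3 = classify_candidate(
            c.seq[s:e], srk_refs, ark3_refs, threshold
        )
    return regions


# ---------------------------------------------------------------------------
# SCR: 8-cysteine ORF scan
# ---------------------------------------------------------------------------


def _orfs_in_frame(seq: str, frame: int, min_aa: int):
    """Yield (nt_start, nt_end, protein) for ATG->stop ORFs in one frame.

    Coordinates are on ``seq``; nt_end includes the stop codon.
    """
    sub = seq[frame:]
    prot = str(Seq(sub[: len(sub) - len(sub) % 3]).translate())
    start = None
    for i, aa in enumerate(prot):
        if aa == "*":
            if start is not None and i - start >= min_aa:
                yield frame + 3 * start, frame + 3 * (i + 1), prot[start:i]
            start = None
        elif aa == "M" and start is None:
            start = i


def _window_groups(cys: list[int], window: int) -> list[tuple[int, ...]]:
    """Groups of 8 cysteines coverable by a window of exactly 8 cysteines.

    A group of 8 consecutive cysteine positions qualifies when some
    placement of a ``window``-residue window contains all 8 and excludes
    the neighbouring cysteines on both sides.
    """
    out = []
    n = len(cys)
    for i in range(n - 7):
        grp = cys[i : i + 8]
        span = grp[-1] - grp[0] + 1
        if span > window:
            continue
        left_bound = cys[i - 1] + 1 if i > 0 else -(10**9)
        right_bound = cys[i + 8] - 1 if i + 8 < n else 10**9
        lo = max(grp[-1] - window + 1, left_bound)
        hi = min(grp[0], right_bound - window + 1)
        if lo <= hi:
            out.append(tuple(grp))
    return out


def find_scr(
    c: Contig, min_orf_aa: int = 50, cys_window_aa: int = 90
) -> list[ScrHit]:
    """Scan all six reading frames for ORFs with the SCR cysteine motif.

    Enumerates ATG->stop ORFs of at least ``min_orf_aa`` residues, slides
    a ``cys_window_aa``-residue window (1-residue step) over each
    translation, and reports ORFs where some window contains exactly 8
    cysteines.  Overlapping windows within one ORF are merged to the
    group with the smallest first-to-last span.
    """
    if min_orf_aa < 30:
        raise ValueError("min_orf_aa must be >= 30")
    L = len(c)
    hits: list[ScrHit] = []
    for strand in ("+", "-"):
        seq = c.seq if strand == "+" else revcomp(c.seq)
        for frame in range(3):
            for nt_start, nt_end, prot in _orfs_in_frame(seq, frame, min_orf_aa):
                cys = [i for i, aa in enumerate(prot) if aa == "C"]
                if len(cys) < 8:
                    continue
                groups = _window_groups(cys, cys_window_aa)
                if not groups:
                    continue
                best = min(groups, key=lambda g: (g[-1] - g[0], g[0]))
                if strand == "+":
                    interval = (nt_start, nt_end)
                else:
                    interval = (L - nt_end, L - nt_start)
                hits.append(
                    ScrHit(
                        orf_interval=interval,
                        strand=strand,
                        frame=frame,
                        cys_positions=best,
                        span_aa=best[-1] - best[0] + 1,
                    )
                )
    hits.sort(key=lambda h: h.orf_interval)
    return hits


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_gff3(
    c: Contig,
    primer_hits: list[PrimerHit],
    regions: list[CandidateRegion],
    scr_hits: list[ScrHit],
    path,
) -> None:
    """GFF3 (1-based inclusive) of primer sites, candidate regions, ORFs."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {c.id} 1 {len(c)}\n")
        for h in primer_hits:
            fh.write(
                f"{c.id}\tbacfinish\tprimer_binding_site\t{h.start + 1}\t{h.end}\t"
                f"{h.mismatches}\t{h.strand}\t.\tID={h.primer_id}_{h.start + 1};"
                f"mismatches={h.mismatches}\n"
            )
        for i, r in enumerate(regions):
            s, e = r.interval
            fh.write(
                f"{c.id}\tbacfinish\tregion\t{s + 1}\t{e}\t.\t+\t.\t"
                f"ID=candidate_{i};anchor={r.anchor};verdict={r.verdict};"
                f"identity_srk={r.best_identity_srk:.4f};identity_ark3={r.best_identity_ark3:.4f}\n"
            )
        for i, h in enumerate(scr_hits):
            s, e = h.orf_interval
            fh.write(
                f"{c.id}\tbacfinish\tORF\t{s + 1}\t{e}\t.\t{h.strand}\t{h.frame}\t"
                f"ID=scr_orf_{i};cys_span_aa={h.span_aa}\n"
            )


def write_candidate_tsv(regions: list[CandidateRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tanchor\tverdict\tidentity_srk\tidentity_ark3\n")
        for r in regions:
            s, e = r.interval
            fh.write(
                f"{s + 1}\t{e}\t{r.anchor}\t{r.verdict}\t"
                f"{r.best_identity_srk:.4f}\t{r.best_identity_ark3:.4f}\n"
            )
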