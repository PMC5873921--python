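"""Contig container and small sequence utilities.

A :class:`Contig` is the unit that flows through the pipeline: a named,
uppercase DNA sequence with a circularity flag and a free-text provenance
trail.  FASTA round-tripping goes through Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Contig:
    """A named DNA sequence over {A,C,G,T,N}.

    Parameters
    ----------
    id : str
        Sequence name (FASTA header word).
    seq : str
        Uppercase DNA string; lowercase input is canonicalised on creation.
    circular : bool
        Whether the molecule is circular (a BAC insert+vector circle) or a
        linear assembly of it.
    provenance : str
        Free-text processing history, appended to by pipeline stages.
    """

    id: str
    seq: str
    circular: bool = False
    provenance: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(f"contig {self.id!r}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, id: str | None = None) -> "Contig":
        return replace(
            self,
            id=id or self.id,
            seq=revcomp(self.seq),
            provenance=self.provenance + " | reverse-complemented",
        )

    def rotated(self, origin: int) -> "Contig":
        """Rotate a circular contig so that ``origin`` becomes position 0."""
        if not self.circular:
            raise ValueError("rotation is only defined for circular contigs")
        origin %= len(self.seq)
        return replace(
            self,
            seq=self.seq[origin:] + self.seq[:origin],
            provenance=self.provenance + f" | rotated to origin {origin}",
        )


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def circular_equal(a: str, b: str, *, allow_revcomp: bool = True) -> bool:
    """True if ``a`` equals ``b`` up to rotation (and optionally strand).

    Uses substring search in a doubled copy, so O(n) with C string matching.
    """
    if len(a) != len(b):
        return False
    doubled = b + b
    if a in doubled:
        return True
    return allow_revcomp and revcomp(a) in doubled


def read_fasta(path: str | Path) -> list[Contig]:
    """Read all records of a FASTA file as linear contigs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circular = "circular=true" in rec.description.lower()
        out.append(Contig(rec.id, str(rec.seq), circular=circular, provenance=f"read from {path}"))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def read_single_fasta(path: str | Path) -> Contig:
    recs = read_fasta(path)
    if len(recs) != 1:
        raise ValueError(f"{path}: expected exactly 1 record, found {len(recs)}")
    return recs[0]


def write_fasta(contigs: Iterable[Contig] | Contig, path: str | Path, *, width: int = 80) -> None:
    """Write contigs as wrapped FASTA (default 80 columns)."""
    if isinstance(contigs, Contig):
        contigs = [contigs]
    records = [
        SeqRecord(
            Seq(c.seq),
            id=c.id,
            description=f"circular=true length={len(c)}" if c.circular else f"length={len(c)}",
        )
        for c in contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
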