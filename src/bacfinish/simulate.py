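"""Synthetic BAC constructs, error-injected drafts, and short reads.

Everything downstream of wet-lab sequencing is exercisable on data from
this module: it builds a circular BAC molecule (a large S-locus-like
insert ligated into a ~8 kb cloning vector), emits the linear draft an
assembler would produce from it (rotated to a random origin, with the
first ``overlap_len`` bases duplicated at the end, plus injected
indel-dominated consensus errors), and samples paired-end short reads
with a truth SAM.  Every planted feature, injected edit and read
placement is recorded in a :class:`TruthLedger` so tests have an exact
oracle.

The insert carries analogues of the locus features the pipeline must
find: two flanking genes, an SRK-exon-1-like region bracketed by exact
forward/reverse primer sites, an ORF whose translation contains exactly
8 cysteines within a configurable span (the SCR signature), and
interspersed tandem-repeat blocks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from .contig import Contig, revcomp

# Configurable stand-ins for the SRK exon-1 primer pair (the real primer
# sequences are literature-cited runtime inputs, not constants of this
# package).  SLGR is given 5'->3' on its own strand, as primers are.
DEFAULT_SLGF = "ATGCGGTCATTGCAGAAACG"
DEFAULT_SLGR = "TGCACCTAGAAGCGTTCCAT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_STOPS = {"TAA", "TAG", "TGA"}
_CYS = {"TGT", "TGC"}


@dataclass
class SimParams:
    """Simulation parameters; defaults mirror the dimensions of a real
    S-locus BAC project (~148 kb insert in a ~8.1 kb vector, 250 bp
    paired-end reads, indel-dominated consensus errors around 1e-5/bp
    with twice as many single- as double-bp indels)."""

    seed: int = 0
    insert_len: int = 148_000
    vector_len: int = 8_100
    overlap_len: int = 15_000
    snp_rate: float = 0.0
    indel_rate: float = 5.7e-5
    single_to_double_indel_ratio: float = 2.0
    read_len: int = 250
    n_read_pairs: int = 10_000
    fragment_len_mean: float = 600.0
    fragment_len_sd: float = 60.0
    read_error_rate: float = 0.0
    # feature sizing
    primer_fwd: str = DEFAULT_SLGF
    primer_rev: str = DEFAULT_SLGR
    flank_len: int = 2_000
    srk_core_len: int = 1_300
    scr_orf_aa: int = 110
    scr_cys_span_aa: int = 70
    n_repeat_blocks: int = 6
    repeat_unit_len: int = 400
    repeat_copies: int = 5

    def validate(self) -> None:
        for name in ("insert_len", "vector_len", "overlap_len", "read_len",
                     "flank_len", "srk_core_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("snp_rate", "indel_rate", "read_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.01:
                raise ValueError(f"{name} must lie in [0, 0.01]")
        if self.overlap_len >= self.insert_len + self.vector_len:
            raise ValueError("overlap_len must be shorter than the construct")
        if self.fragment_len_mean < self.read_len:
            raise ValueError("fragment_len_mean must be >= read_len")
        if self.single_to_double_indel_ratio < 0:
            raise ValueError("single_to_double_indel_ratio must be >= 0")
        feature_len = (
            2 * self.flank_len
            + self.srk_core_len
            + len(self.primer_fwd)
            + len(self.primer_rev)
            + 3 * (self.scr_orf_aa + 1)
            + 3
            + self.n_repeat_blocks * self.repeat_unit_len * self.repeat_copies
        )
        if feature_len > self.insert_len:
            raise ValueError(
                f"planted features ({feature_len} bp) exceed insert_len ({self.insert_len} bp)"
            )


@dataclass(frozen=True)
class Feature:
    name: str
    start: int  # 0-based half-open
    end: int
    strand: str = "+"

    def extract(self, seq: str) -> str:
        s = seq[self.start : self.end]
        return s if self.strand == "+" else revcomp(s)


@dataclass(frozen=True)
class Edit:
    """One injected error on a template, in pre-edit template coordinates.

    ``snp``: replace base at ``pos`` with ``alt``.
    ``ins``: insert ``alt`` before ``pos``.
    ``del``: delete ``length`` bases starting at ``pos``.
    """

    pos: int
    kind: str  # snp | ins | del
    length: int
    alt: str = ""


@dataclass
class TruthLedger:
    """The generator's record of everything it planted — the test oracle."""

    construct_seq: str = ""
    insert_seq: str = ""
    vector_seq: str = ""
    planted_features: list[Feature] = field(default_factory=list)
    injected_edits: list[Edit] = field(default_factory=list)
    read_placements: list[tuple] = field(default_factory=list)
    template_seq: str = ""  # error-free linear draft template
    rotation_origin: int | None = None
    draft_features: list[Feature] = field(default_factory=list)

    def feature(self, name: str, *, on_draft: bool = False) -> Feature:
        pool = self.draft_features if on_draft else self.planted_features
        for f in pool:
            if f.name == name:
                return f
        raise KeyError(name)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        d = json.loads(text)
        d["planted_features"] = [Feature(**f) for f in d["planted_features"]]
        d["draft_features"] = [Feature(**f) for f in d.get("draft_features", [])]
        d["injected_edits"] = [Edit(**e) for e in d["injected_edits"]]
        d["read_placements"] = [tuple(p) for p in d["read_placements"]]
        return cls(**d)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def mutate_sequence(seq: str, sub_rate: float, rng: np.random.Generator) -> str:
    """Substitute bases i.i.d. at ``sub_rate`` (always to a different base)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.shape[0]) < sub_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


# ---------------------------------------------------------------------------
# construct
# ---------------------------------------------------------------------------


def _random_codon(rng: np.random.Generator, forbid: set[str]) -> str:
    while True:
        c = random_dna(rng, 3)
        if c not in forbid:
            return c


def _make_scr_orf(rng: np.random.Generator, n_aa: int, cys_span: int) -> tuple[str, list[int]]:
    """Build ATG + codons + stop with exactly 8 cysteine codons clustered
    within ``cys_span`` residues; returns (dna, protein cys positions)."""
    if cys_span < 8 or n_aa < cys_span + 2:
        raise ValueError("scr ORF too short for the cysteine span")
    first = int(rng.integers(2, n_aa - cys_span))
    cys_pos = sorted(rng.choice(np.arange(first, first + cys_span), size=8, replace=False).tolist())
    codons = ["ATG"]
    for i in range(1, n_aa):
        if i in cys_pos:
            codons.append("TGT" if rng.random() < 0.5 else "TGC")
        else:
            codons.append(_random_codon(rng, _STOPS | _CYS))
    codons.append("TAA")
    return "".join(codons), cys_pos


def make_bac_construct(params: SimParams) -> tuple[Contig, TruthLedger]:
    """Build the circular BAC molecule (insert + vector) and its ledger.

    The insert carries, in order: flanking-gene analogue A, half the
    repeat blocks, the SRK-exon-1 analogue bracketed by exact primer
    copies (reverse primer planted as its reverse complement), the
    8-cysteine SCR-like ORF, the remaining repeat blocks, and
    flanking-gene analogue B.  Identical params give bit-identical output.
    """
    params.validate()
    rng = _stage_rng(params.seed, 1)

    pieces: list[str] = []
    features: list[Feature] = []
    cursor = 0

    def emit(seq: str, name: str | None = None, strand: str = "+") -> None:
        nonlocal cursor
        if name is not None:
            features.append(Feature(name, cursor, cursor + len(seq), strand))
        pieces.append(seq)
        cursor += len(seq)

    orf_dna, _cys = _make_scr_orf(rng, params.scr_orf_aa, params.scr_cys_span_aa)
    repeat_blocks = []
    for i in range(params.n_repeat_blocks):
        unit = random_dna(rng, params.repeat_unit_len)
        repeat_blocks.append(unit * params.repeat_copies)

    srk_core = random_dna(rng, params.srk_core_len)
    fixed_len = (
        2 * params.flank_len
        + len(params.primer_fwd) + params.srk_core_len + len(params.primer_rev)
        + len(orf_dna) + 3  # in-frame stop shield before the ORF
        + sum(len(b) for b in repeat_blocks)
    )
    n_half = params.n_repeat_blocks // 2
    n_spacers = 5 + params.n_repeat_blocks
    free = params.insert_len - fixed_len
    if free < n_spacers:
        raise ValueError("insert_len too small for features plus spacers")
    cuts = np.sort(rng.integers(0, free + 1, n_spacers - 1))
    spacer_lens = np.diff(np.concatenate([[0], cuts, [free]])).tolist()
    spacers = iter(spacer_lens)

    emit(random_dna(rng, params.flank_len), "flankA")
    emit(random_dna(rng, next(spacers)))
    for i in range(n_half):
        emit(repeat_blocks[i], f"repeat_{i}")
        emit(random_dna(rng, next(spacers)))
    srk_start = cursor
    emit(params.primer_fwd, "primer_fwd", "+")
    emit(srk_core)
    emit(revcomp(params.primer_rev), "primer_rev", "-")
    features.append(Feature("srk_exon1", srk_start, cursor, "+"))
    emit(random_dna(rng, next(spacers)))
    emit("TAA")  # stop shield: keeps upstream in-frame sequence out of the ORF
    emit(orf_dna, "scr_orf", "+")
    emit(random_dna(rng, next(spacers)))
    for i in range(n_half, params.n_repeat_blocks):
        emit(repeat_blocks[i], f"repeat_{i}")
        emit(random_dna(rng, next(spacers)))
    emit(random_dna(rng, next(spacers)))
    emit(random_dna(rng, params.flank_len), "flankB")
    insert = "".join(pieces)
    pad = params.insert_len - len(insert)
    insert += random_dna(rng, pad)
    assert len(insert) == params.insert_len

    vector = random_dna(rng, params.vector_len)
    features.append(Feature("vector", params.insert_len, params.insert_len + params.vector_len))

    construct = Contig(
        id=f"construct_seed{params.seed}",
        seq=insert + vector,
        circular=True,
        provenance="synthetic BAC construct",
    )
    ledger = TruthLedger(
        construct_seq=construct.seq,
        insert_seq=insert,
        vector_seq=vector,
        planted_features=features,
    )
    return construct, ledger


# ---------------------------------------------------------------------------
# edits
# ---------------------------------------------------------------------------


def draw_edits(
    rng: np.random.Generator,
    template: str,
    snp_rate: float,
    indel_rate: float,
    single_to_double_ratio: float,
    protected: list[tuple[int, int]] | None = None,
    min_spacing: int = 5,
) -> list[Edit]:
    """Draw i.i.d. uniform SNP and 1-2 bp indel edits at the given rates.

    Counts are binomial in the template length; positions avoid
    ``protected`` intervals and keep ``min_spacing`` bp apart so edits do
    not interact.  Single vs double indel lengths follow the configured
    ratio; insertions and deletions are equiprobable.
    """
    L = len(template)
    forbidden = np.zeros(L, dtype=bool)
    for s, e in protected or []:
        forbidden[max(0, s - 2) : min(L, e + 2)] = True
    n_snp = rng.binomial(L, snp_rate) if snp_rate > 0 else 0
    n_indel = rng.binomial(L, indel_rate) if indel_rate > 0 else 0
    edits: list[Edit] = []
    taken = np.zeros(L, dtype=bool)
    r = single_to_double_ratio
    p_single = r / (r + 1.0) if r != np.inf else 1.0

    def pick_pos() -> int:
        for _ in range(10_000):
            p = int(rng.integers(2, L - 4))
            if forbidden[p] or taken[max(0, p - min_spacing) : p + min_spacing + 1].any():
                continue
            taken[p] = True
            return p
        raise RuntimeError("could not place edit; template too constrained")

    for _ in range(n_indel):
        p = pick_pos()
        length = 1 if rng.random() < p_single else 2
        if rng.random() < 0.5:
            edits.append(Edit(p, "ins", length, random_dna(rng, length)))
        else:
            edits.append(Edit(p, "del", length))
    for _ in range(n_snp):
        p = pick_pos()
        old = template[p]
        alt = old
        while alt == old:
            alt = "ACGT"[rng.integers(0, 4)]
        edits.append(Edit(p, "snp", 1, alt))
    edits.sort(key=lambda e: e.pos)
    return edits


def exact_indel_edits(
    rng: np.random.Generator,
    template: str,
    n_single: int,
    n_double: int,
    min_spacing: int = 20,
) -> list[Edit]:
    """Place exactly ``n_single`` 1 bp and ``n_double`` 2 bp indels,
    uniformly, well separated (for worked-value reconstructions)."""
    L = len(template)
    taken = np.zeros(L, dtype=bool)
    edits = []
    lengths = [1] * n_single + [2] * n_double
    for length in lengths:
        for _attempt in range(10_000):
            p = int(rng.integers(2, L - 4))
            if taken[max(0, p - min_spacing) : p + min_spacing + 1].any():
                continue
            taken[p] = True
            break
        else:
            raise ValueError(
                f"cannot place {len(lengths)} edits {min_spacing} bp apart on {L} bp"
            )
        if rng.random() < 0.5:
            edits.append(Edit(p, "ins", length, random_dna(rng, length)))
        else:
            edits.append(Edit(p, "del", length))
    edits.sort(key=lambda e: e.pos)
    return edits


def apply_edits(template: str, edits: list[Edit]) -> str:
    """Apply edits (template coordinates) right-to-left."""
    seq = template
    for e in sorted(edits, key=lambda e: -e.pos):
        if e.kind == "snp":
            seq = seq[: e.pos] + e.alt + seq[e.pos + 1 :]
        elif e.kind == "ins":
            seq = seq[: e.pos] + e.alt + seq[e.pos :]
        elif e.kind == "del":
            seq = seq[: e.pos] + seq[e.pos + e.length :]
        else:
            raise ValueError(f"unknown edit kind {e.kind!r}")
    return seq


# ---------------------------------------------------------------------------
# draft assembly
# ---------------------------------------------------------------------------


def simulate_draft_assembly(
    construct: Contig, ledger: TruthLedger, params: SimParams
) -> tuple[Contig, TruthLedger]:
    """Emit the linear draft an assembler would produce from the circle.

    The circle is rotated to a uniform random origin, the first
    ``overlap_len`` bases are appended again at the end (the duplicated
    end-overlap of a non-split assembly of a circular molecule), and
    SNP/indel errors are injected at the configured rates.  Primer sites
    are protected from injected errors so annotation oracles stay exact.
    """
    if not construct.circular:
        raise ValueError("draft simulation needs a circular construct")
    params.validate()
    rng = _stage_rng(params.seed, 2)
    L = len(construct)
    origin = int(rng.integers(0, L))
    rotated = construct.seq[origin:] + construct.seq[:origin]
    template = rotated + rotated[: params.overlap_len]

    draft_features: list[Feature] = []
    for f in ledger.planted_features:
        s = (f.start - origin) % L
        e = s + (f.end - f.start)
        if e <= len(template):
            draft_features.append(Feature(f.name, s, e, f.strand))
            # duplicated copy inside the appended overlap
            if e - L <= params.overlap_len and s + L < len(template) and e + L <= len(template):
                draft_features.append(Feature(f.name + "_dup", s + L, e + L, f.strand))

    protected = [
        (f.start, f.end)
        for f in draft_features
        if f.name.startswith("primer") or f.name.startswith("srk") or f.name.startswith("scr")
    ]
    edits = draw_edits(
        rng,
        template,
        params.snp_rate,
        params.indel_rate,
        params.single_to_double_indel_ratio,
        protected=protected,
    )
    draft_seq = apply_edits(template, edits)
    draft = Contig(
        id=construct.id.replace("construct", "draft"),
        seq=draft_seq,
        circular=False,
        provenance=construct.provenance + f" | draft (origin {origin}, {len(edits)} edits)",
    )
    new_ledger = dataclasses.replace(
        ledger,
        injected_edits=edits,
        template_seq=template,
        rotation_origin=origin,
        draft_features=draft_features,
    )
    return draft, new_ledger


# ---------------------------------------------------------------------------
# replicate pairs (assembly-vs-assembly error-rate studies)
# ---------------------------------------------------------------------------


def simulate_replicate_pair(
    length: int,
    indel_rate: float,
    seed: int,
    snp_rate: float = 0.0,
    single_to_double_ratio: float = 2.0,
    exact_counts: tuple[int, int] | None = None,
) -> tuple[Contig, Contig, list[Edit]]:
    """A truth sequence and an error-bearing replicate assembly of it.

    Models two finished assemblies of the same BAC whose differences are
    consensus errors; all injected error lies in the second copy, so the
    measured inter-assembly difference rate estimates ``indel_rate``
    directly.  ``exact_counts=(n_single, n_double)`` plants exact indel
    counts instead of binomial draws.
    """
    rng = np.random.default_rng([seed, 3])
    truth = random_dna(rng, length)
    if exact_counts is not None:
        edits = exact_indel_edits(rng, truth, *exact_counts)
    else:
        edits = draw_edits(rng, truth, snp_rate, indel_rate, single_to_double_ratio)
    a = Contig(f"assembly1_seed{seed}", truth, provenance="synthetic replicate truth")
    b = Contig(
        f"assembly2_seed{seed}",
        apply_edits(truth, edits),
        provenance=f"synthetic replicate with {len(edits)} injected edits",
    )
    return a, b, edits


def coverage_depth(total_read_bases: float, assembly_len: int) -> float:
    """Sequencing depth: total read bases over assembly length."""
    if assembly_len <= 0:
        raise ValueError("assembly length must be positive")
    return total_read_bases / assembly_len


# ---------------------------------------------------------------------------
# short reads
# ---------------------------------------------------------------------------


@dataclass
class ShortReadSet:
    """Simulated paired-end reads plus their truth placements.

    ``placements`` holds (read_id, fragment_start, fragment_len, strand)
    on the template; FASTQ text carries as-sequenced orientation, SAM text
    carries reference-forward orientation with correct POS/CIGAR/FLAG.
    """

    template_id: str
    template_len: int
    read_len: int
    placements: list[tuple[str, int, int, str]]
    seq1: list[str]  # ref-forward orientation of mate 1
    seq2: list[str]
    r1_reverse: list[bool]  # whether mate 1 maps to the reverse strand

    @property
    def n_pairs(self) -> int:
        return len(self.placements)

    @property
    def expected_depth(self) -> float:
        return self.n_pairs * 2 * self.read_len / self.template_len

    def _fastq(self, seqs: list[str], reverse_flags: list[bool], mate: int) -> str:
        qual = "F" * self.read_len  # constant Q37
        out = []
        for (rid, *_), seq, rev in zip(self.placements, seqs, reverse_flags):
            read = revcomp(seq) if rev else seq
            out.append(f"@{rid}/{mate}\n{read}\n+\n{qual}\n")
        return "".join(out)

    def fastq1(self) -> str:
        return self._fastq(self.seq1, self.r1_reverse, 1)

    def fastq2(self) -> str:
        return self._fastq(self.seq2, [not r for r in self.r1_reverse], 2)

    def sam_text(self) -> str:
        """Truth SAM against the template (all reads are full matches)."""
        rl = self.read_len
        cigar = f"{rl}M"
        qual = "F" * rl
        lines = [
            "@HD\tVN:1.6\tSO:unsorted",
            f"@SQ\tSN:{self.template_id}\tLN:{self.template_len}",
        ]
        for (rid, fs, fl, strand), s1, s2 in zip(self.placements, self.seq1, self.seq2):
            p1, p2 = fs, fs + fl - rl
            if strand == "+":
                f1, f2 = 99, 147
                pos1, pos2 = p1, p2
                tlen1 = fl
            else:
                f1, f2 = 83, 163
                pos1, pos2 = p2, p1
                tlen1 = -fl
            lines.append(
                f"{rid}\t{f1}\t{self.template_id}\t{pos1 + 1}\t60\t{cigar}\t=\t"
                f"{pos2 + 1}\t{tlen1}\t{s1}\t{qual}"
            )
            lines.append(
                f"{rid}\t{f2}\t{self.template_id}\t{pos2 + 1}\t60\t{cigar}\t=\t"
                f"{pos1 + 1}\t{-tlen1}\t{s2}\t{qual}"
            )
        return "\n".join(lines) + "\n"


def simulate_short_reads(
    template: Contig, params: SimParams, ledger: TruthLedger | None = None
) -> tuple[ShortReadSet, TruthLedger | None]:
    """Sample paired-end reads from normal-length fragments of the template.

    Per-base substitution errors at ``read_error_rate``; no indel errors
    (quality strings are constant Q37, emulating quality-filtered data).
    Same seed gives byte-identical FASTQ/SAM output.
    """
    if template.circular:
        raise ValueError("read simulation needs a linear template")
    params.validate()
    rng = _stage_rng(params.seed, 4)
    L = len(template)
    rl = params.read_len
    if L < params.fragment_len_mean:
        raise ValueError("template shorter than mean fragment length")

    frag_lens = np.rint(
        rng.normal(params.fragment_len_mean, params.fragment_len_sd, params.n_read_pairs)
    ).astype(int)
    frag_lens = np.clip(frag_lens, rl, L)
    starts = rng.integers(0, L - frag_lens + 1)
    strands = np.where(rng.random(params.n_read_pairs) < 0.5, "+", "-")

    placements = []
    seq1, seq2, r1_rev = [], [], []
    err = params.read_error_rate
    for i in range(params.n_read_pairs):
        fs, fl, st = int(starts[i]), int(frag_lens[i]), str(strands[i])
        rid = f"sim_{template.id}_{i:07d}"
        left = template.seq[fs : fs + rl]
        right = template.seq[fs + fl - rl : fs + fl]
        if err > 0:
            left = mutate_sequence(left, err, rng)
            right = mutate_sequence(right, err, rng)
        if st == "+":
            s1, s2, rev1 = left, right, False  # mate1 forward-left
        else:
            s1, s2, rev1 = right, left, True  # mate1 reverse-right
        placements.append((rid, fs, fl, st))
        seq1.append(s1)
        seq2.append(s2)
        r1_rev.append(rev1)

    reads = ShortReadSet(
        template_id=template.id,
        template_len=L,
        read_len=rl,
        placements=placements,
        seq1=seq1,
        seq2=seq2,
        r1_reverse=r1_rev,
    )
    if ledger is not None:
        ledger = dataclasses.replace(ledger, read_placements=list(placements))
    return reads, ledger


def _clean_cigar(ops: list[tuple[int, str]], pos: int) -> tuple[list[tuple[int, str]], int]:
    """SAM hygiene: no leading/trailing D; terminal I becomes soft-clip."""
    while ops and ops[0][1] == "D":
        pos += ops[0][0]
        ops = ops[1:]
    while ops and ops[-1][1] == "D":
        ops = ops[:-1]
    if ops and ops[0][1] == "I":
        ops[0] = (ops[0][0], "S")
    if ops and ops[-1][1] == "I":
        ops[-1] = (ops[-1][0], "S")
    return ops, pos


def realign_reads(reads: ShortReadSet, reference: Contig, pad: int = 60) -> str:
    """SAM of the simulated reads against ``reference`` (e.g. the draft).

    Synthetic stand-in for a read mapper: each read is aligned with edlib
    to the reference window around its known template placement, which is
    valid because reference and template differ only by a handful of
    short edits.  Deterministic; MAPQ fixed at 60.
    """
    L = len(reference)
    rl = reads.read_len
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{reference.id}\tLN:{L}",
    ]
    qual = "F" * rl

    def align_one(seq: str, tpos: int) -> tuple[int, str] | None:
        ws = max(0, tpos - pad)
        we = min(L, tpos + rl + pad)
        res = edlib.align(seq, reference.seq[ws:we], mode="HW", task="path")
        if res["editDistance"] < 0:
            return None
        ops: list[tuple[int, str]] = []
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            ln, num = int(num), ""
            op = "M" if ch in "=X" else ch
            if ops and ops[-1][1] == op:
                ops[-1] = (ops[-1][0] + ln, op)
            else:
                ops.append((ln, op))
        start = ws + res["locations"][0][0]
        ops, start = _clean_cigar(ops, start)
        cigar = "".join(f"{n}{o}" for n, o in ops)
        return start, cigar

    for (rid, fs, fl, strand), s1, s2, rev1 in zip(
        reads.placements, reads.seq1, reads.seq2, reads.r1_reverse
    ):
        p1, p2 = (fs, fs + fl - rl)
        if strand == "+":
            mates = [(s1, p1, 99), (s2, p2, 147)]
        else:
            mates = [(s1, p2, 83), (s2, p1, 163)]
        aligned = []
        for seq, tpos, flag in mates:
            hit = align_one(seq, tpos)
            if hit is None:
                aligned = []
                break
            aligned.append((seq, hit[0], hit[1], flag))
        if not aligned:
            continue
        (sA, posA, cigA, flA), (sB, posB, cigB, flB) = aligned
        tlen = (max(posA, posB) + rl) - min(posA, posB)
        tlA = tlen if posA <= posB else -tlen
        lines.append(
            f"{rid}\t{flA}\t{reference.id}\t{posA + 1}\t60\t{cigA}\t=\t{posB + 1}\t{tlA}\t{sA}\t{qual}"
        )
        lines.append(
            f"{rid}\t{flB}\t{reference.id}\t{posB + 1}\t60\t{cigB}\t=\t{posA + 1}\t{-tlA}\t{sB}\t{qual}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# reference sets for annotation tests
# ---------------------------------------------------------------------------


def make_reference_sets(
    ledger: TruthLedger,
    params: SimParams,
    n_refs: int = 3,
    srk_divergence: float = 0.03,
    ark3_divergence: float = 0.20,
) -> tuple[list[Contig], list[Contig]]:
    """Allele sets for candidate classification, sampled around the
    planted SRK region: the SRK set diverges a few percent (same allele
    lineage), the ARK3 set is a paralogue-like 20%-diverged family."""
    rng = _stage_rng(params.seed, 5)
    srk = ledger.feature("srk_exon1").extract(ledger.insert_seq)
    srk_refs = [
        Contig(f"srk_ref_{i}", mutate_sequence(srk, srk_divergence, rng))
        for i in range(n_refs)
    ]
    ark3_base = mutate_sequence(srk, ark3_divergence, rng)
    ark3_refs = [
        Contig(f"ark3_ref_{i}", mutate_sequence(ark3_base, 0.02, rng))
        for i in range(n_refs)
    ]
    return srk_refs, ark3_refs
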