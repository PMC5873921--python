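"""Pileup construction, consensus indel calling, and correction."""

import numpy as np
import pytest

from bacfinish.contig import Contig
from bacfinish.polish import (
    IndelTarget,
    MalformedRecordError,
    apply_targets,
    build_pileup,
    call_indel_targets,
    polish_report,
)
from bacfinish.simulate import (
    SimParams,
    apply_edits,
    exact_indel_edits,
    random_dna,
    realign_reads,
    simulate_short_reads,
)

HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:draft\tLN:{}\n"


def _sam(draft_len: int, rows: list[str]) -> str:
    return HEADER.format(draft_len) + "".join(r + "\n" for r in rows)


def _row(qname, flag, pos, cigar, seq, mapq=60):
    qual = "F" * len(seq)
    return f"{qname}\t{flag}\t{draft_id()}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}"


def draft_id():
    return "draft"


@pytest.fixture(scope="module")
def draft():
    rng = np.random.default_rng(9)
    return Contig("draft", random_dna(rng, 2000))


def test_concordant_reads_fill_matching_columns(draft, tmp_path):
    rows = [_row(f"r{i}", 0, 101, "250M", draft.seq[100:350]) for i in range(10)]
    sam = tmp_path / "a.sam"
    sam.write_text(_sam(len(draft), rows))
    pile = build_pileup(sam, draft)
    col = pile[200]
    assert col.depth == 10
    assert col.base_counts == {draft.seq[200]: 10}
    assert col.del_count == 0 and col.ins_counts == {}
    assert pile[50].depth == 0


def test_insertion_is_attributed_to_preceding_position(draft, tmp_path):
    seq = draft.seq[100:200] + "G" + draft.seq[200:349]
    rows = [_row("r0", 0, 101, "100M1I149M", seq)]
    sam = tmp_path / "b.sam"
    sam.write_text(_sam(len(draft), rows))
    pile = build_pileup(sam, draft)
    # insertion sits between draft positions 199 and 200 -> keyed to 199
    assert pile[199].ins_counts == {"G": 1}
    assert pile[199].depth == 1


def test_deletion_and_clipping_handling(draft, tmp_path):
    seq = draft.seq[100:200] + draft.seq[202:352]
    rows = [
        _row("rdel", 0, 101, "100M2D150M", seq),
        _row("rclip", 0, 151, "20S230M", "A" * 20 + draft.seq[150:380]),
    ]
    sam = tmp_path / "c.sam"
    sam.write_text(_sam(len(draft), rows))
    pile = build_pileup(sam, draft)
    assert pile[200].del_count == 1 and pile[201].del_count == 1
    # invariant: depth = base counts + deletions, clips contribute nothing
    assert pile[200].depth == sum(pile[200].base_counts.values()) + pile[200].del_count
    assert pile[149].depth == 1  # clip region before rclip's first aligned base


def test_unmapped_and_low_mapq_records_are_skipped(draft, tmp_path):
    rows = [
        _row("skip1", 4, 0, "*", draft.seq[:250]).replace("\t0\t60\t*\t", "\t0\t60\t250M\t"),
        _row("skip2", 0, 101, "250M", draft.seq[100:350], mapq=5),
    ]
    sam = tmp_path / "d.sam"
    sam.write_text(_sam(len(draft), rows))
    pile = build_pileup(sam, draft, min_mapq=20)
    assert pile.depth.sum() == 0


def test_cigar_sequence_length_mismatch_names_the_read(draft, tmp_path):
    import pysam

    # a SAM file with an inconsistent record is rejected loudly
    rows = [_row("badread", 0, 101, "251M", draft.seq[100:350])]
    sam = tmp_path / "e.sam"
    sam.write_text(_sam(len(draft), rows))
    with pytest.raises(MalformedRecordError):
        build_pileup(sam, draft)

    # an in-memory record with a mismatched CIGAR is reported by read name
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "draft", "LN": len(draft)}]}
    )
    rec = pysam.AlignedSegment(header)
    rec.query_name = "badread"
    rec.query_sequence = draft.seq[100:350]
    rec.reference_id = 0
    rec.reference_start = 100
    rec.mapping_quality = 60
    rec.cigartuples = [(0, 251)]
    with pytest.raises(MalformedRecordError, match="badread"):
        build_pileup([rec], draft)


def test_call_targets_thresholds(draft, tmp_path):
    # 30 reads insert A after draft position 1000 -> support 1.0
    ins_seq = draft.seq[900:1001] + "A" + draft.seq[1001:1149]
    rows = [_row(f"i{k}", 0, 901, "101M1I148M", ins_seq) for k in range(30)]
    # 15 of 30 reads delete position 500: below a 0.6 fraction -> no target
    del_seq = draft.seq[400:500] + draft.seq[501:651]
    rows += [_row(f"d{k}", 0, 401, "100M1D150M", del_seq) for k in range(15)]
    rows += [_row(f"c{k}", 0, 401, "250M", draft.seq[400:650]) for k in range(15)]
    sam = tmp_path / "f.sam"
    sam.write_text(_sam(len(draft), rows))
    pile = build_pileup(sam, draft)
    targets, snps = call_indel_targets(pile, min_depth=10, min_fraction=0.6)
    assert len(targets) == 1
    t = targets[0]
    assert t.kind == "insertion" and t.ref_pos == 1000 and t.seq == "A"
    assert t.support_fraction == 1.0 and t.depth == 30


def test_concordant_pileup_yields_no_targets(draft, tmp_path):
    rows = [_row(f"r{i}", 0, 1 + i * 100, "250M", draft.seq[i * 100 : i * 100 + 250])
            for i in range(15)]
    sam = tmp_path / "g.sam"
    sam.write_text(_sam(len(draft), rows))
    targets, _ = call_indel_targets(build_pileup(sam, draft), min_depth=1, min_fraction=0.6)
    assert targets == []


def test_apply_targets_bookkeeping(draft):
    targets = [
        IndelTarget(100, "insertion", seq="AC", support_fraction=1.0, depth=30),
        IndelTarget(500, "deletion", length=1, support_fraction=1.0, depth=30),
        IndelTarget(900, "deletion", length=2, support_fraction=1.0, depth=30),
    ]
    corrected, cmap = apply_targets(draft, targets)
    assert len(corrected) == len(draft) + 2 - 1 - 2
    assert corrected.seq[101:103] == "AC"
    assert cmap(50) == 50
    assert cmap(200) == 202
    assert cmap(600) == 601
    assert cmap(1000) == 999
    with pytest.raises(KeyError):
        cmap(500)  # deleted base has no image


def test_apply_empty_target_list_is_identity(draft):
    corrected, cmap = apply_targets(draft, [])
    assert corrected.seq == draft.seq
    assert all(cmap(p) == p for p in (0, 1000, len(draft) - 1))


def test_overlapping_targets_are_rejected(draft):
    targets = [
        IndelTarget(100, "deletion", length=5, support_fraction=1.0, depth=30),
        IndelTarget(102, "insertion", seq="A", support_fraction=1.0, depth=30),
    ]
    with pytest.raises(ValueError, match="overlap"):
        apply_targets(draft, targets)


def test_polish_report_paper_worked_values():
    """3 targets over 153,563 bp prints as 2.0e-5 per bp; 9 over 156,644
    as 5.7e-5; no targets means rate zero."""
    singles = [IndelTarget(i * 1000, "deletion", length=1, support_fraction=1.0, depth=99)
               for i in range(3)]
    rep = polish_report(singles, 153_563)
    assert rep.to_dict()["indel_rate_2sf"] == "2.0e-05"
    assert rep.denominator_kind == "sequence_length"
    nine = [IndelTarget(i * 1000, "deletion", length=1, support_fraction=1.0, depth=99)
            for i in range(9)]
    assert polish_report(nine, 156_644).to_dict()["indel_rate_2sf"] == "5.7e-05"
    assert polish_report([], 1000).indel_rate == 0.0


def test_three_single_bp_deletions_shrink_draft_by_three():
    rng = np.random.default_rng(21)
    seq = random_dna(rng, 153_563 // 100)  # scaled: arithmetic is length-free
    draft = Contig("d", seq)
    targets = [IndelTarget(p, "deletion", length=1, support_fraction=1.0, depth=50)
               for p in (100, 400, 900)]
    corrected, _ = apply_targets(draft, targets)
    assert len(corrected) == len(draft) - 3


def test_noisy_reads_end_to_end_recall(tmp_path):
    """50x coverage with 1% read error: every injected indel is called,
    no false targets, corrected draft equals the truth template."""
    rng = np.random.default_rng(4)
    truth = random_dna(rng, 20_000)
    edits = exact_indel_edits(rng, truth, 3, 1)
    draft = Contig("draft", apply_edits(truth, edits))
    template = Contig("tmpl", truth)
    p = SimParams(seed=8, n_read_pairs=2_000, read_error_rate=0.01)
    reads, _ = simulate_short_reads(template, p)
    sam = tmp_path / "noisy.sam"
    sam.write_text(realign_reads(reads, draft))
    pile = build_pileup(sam, draft)
    targets, _ = call_indel_targets(pile, min_depth=10, min_fraction=0.7)
    assert len(targets) == len(edits)
    corrected, _ = apply_targets(draft, targets)
    assert corrected.seq == truth
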