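"""Synthetic-data generator: determinism, feature plumbing, error models."""

import io

import numpy as np
import pysam
import pytest
from Bio.Seq import Seq

from bacfinish.contig import Contig, revcomp
from bacfinish.simulate import (
    SimParams,
    apply_edits,
    coverage_depth,
    draw_edits,
    make_bac_construct,
    random_dna,
    realign_reads,
    simulate_draft_assembly,
    simulate_short_reads,
)


def test_construct_length_and_circularity(small_params):
    construct, ledger = make_bac_construct(small_params)
    assert len(construct) == small_params.insert_len + small_params.vector_len
    assert construct.circular
    assert ledger.construct_seq == ledger.insert_seq + ledger.vector_seq


def test_default_dimensions_give_bac_scale_molecule():
    p = SimParams(seed=1)
    construct, _ = make_bac_construct(p)
    assert len(construct) == 156_100  # 148 kb insert + 8.1 kb vector


def test_construct_is_deterministic(small_params):
    c1, l1 = make_bac_construct(small_params)
    c2, l2 = make_bac_construct(small_params)
    assert c1.seq == c2.seq
    assert l1.planted_features == l2.planted_features


def test_scr_orf_translates_to_exactly_eight_cysteines(small_construct):
    construct, ledger = small_construct
    orf = ledger.feature("scr_orf")
    prot = str(Seq(orf.extract(ledger.insert_seq)).translate())
    assert prot.startswith("M") and prot.endswith("*")
    assert prot.count("C") == 8
    assert len(orf.extract(ledger.insert_seq)) >= 300


def test_planted_features_address_their_sequences(small_construct):
    construct, ledger = small_construct
    fwd = ledger.feature("primer_fwd")
    rev = ledger.feature("primer_rev")
    p = SimParams(seed=101)
    assert fwd.extract(construct.seq) == p.primer_fwd
    assert rev.extract(construct.seq) == p.primer_rev  # strand-aware extraction


def test_feature_sizing_error():
    # too small for the default feature complement
    p = SimParams(seed=0, insert_len=5_000, overlap_len=2_000)
    with pytest.raises(ValueError, match="exceed"):
        p.validate()


def test_zero_error_draft_has_exact_end_duplication(small_params, small_construct):
    import dataclasses

    construct, ledger = small_construct
    p = dataclasses.replace(small_params, snp_rate=0.0, indel_rate=0.0)
    draft, led2 = simulate_draft_assembly(construct, ledger, p)
    ov = p.overlap_len
    assert len(draft) == len(construct) + ov
    assert draft.seq[:ov] == draft.seq[-ov:]
    assert led2.injected_edits == []


def test_draft_features_address_their_sequences(small_params, small_construct):
    construct, ledger = small_construct
    draft, led2 = simulate_draft_assembly(construct, ledger, small_params)
    p = SimParams(seed=101)
    assert led2.feature("primer_fwd", on_draft=True).extract(led2.template_seq) == p.primer_fwd
    srk = led2.feature("srk_exon1", on_draft=True)
    assert srk.extract(led2.template_seq) == ledger.feature("srk_exon1").extract(
        ledger.insert_seq
    )


def test_injected_edit_count_matches_binomial_expectation():
    """Mean injected indels over replicates sits within 3 SE of n*p."""
    rng = np.random.default_rng(5)
    template = random_dna(rng, 156_644)
    rate = 5.7e-5
    n_rep = 200
    counts = []
    for seed in range(n_rep):
        r = np.random.default_rng([seed, 77])
        edits = draw_edits(r, template, 0.0, rate, 2.0)
        counts.append(len(edits))
    expected = len(template) * rate  # 8.93
    se = np.sqrt(len(template) * rate * (1 - rate)) / np.sqrt(n_rep)
    assert abs(np.mean(counts) - expected) < 3 * se


def test_single_to_double_ratio_converges():
    """Pooled indel lengths match the configured 2:1 single:double mix
    within 5% over ~10,000 draws."""
    rng = np.random.default_rng(6)
    template = random_dna(rng, 300_000)
    singles = doubles = 0
    for seed in range(7):
        r = np.random.default_rng([seed, 88])
        for e in draw_edits(r, template, 0.0, 0.005, 2.0):
            if e.length == 1:
                singles += 1
            else:
                doubles += 1
    assert singles + doubles >= 10_000
    assert abs(singles / doubles - 2.0) <= 0.05 * 2.0


def test_edits_never_hit_primer_sites(small_params, small_construct):
    import dataclasses

    construct, ledger = small_construct
    p = dataclasses.replace(small_params, indel_rate=0.005, snp_rate=0.005, seed=9)
    draft, led2 = simulate_draft_assembly(construct, ledger, p)
    protected = [
        (f.start, f.end)
        for f in led2.draft_features
        if "primer" in f.name or "srk" in f.name or "scr" in f.name
    ]
    for e in led2.injected_edits:
        for s, epos in protected:
            assert not (s - 2 <= e.pos < epos + 2)


# ---------------------------------------------------------------------------
# short reads
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def template_and_reads():
    rng = np.random.default_rng(1)
    template = Contig("tmpl", random_dna(rng, 20_000))
    p = SimParams(seed=42, n_read_pairs=1_000)
    reads, _ = simulate_short_reads(template, p)
    return template, p, reads


def test_fastq_record_counts_and_lengths(template_and_reads):
    _, p, reads = template_and_reads
    for text in (reads.fastq1(), reads.fastq2()):
        lines = text.strip().split("\n")
        assert len(lines) == 4 * p.n_read_pairs
        seqs = lines[1::4]
        assert all(len(s) == p.read_len for s in seqs)


def test_zero_error_reads_match_template_at_cigar_placement(template_and_reads, tmp_path):
    template, p, reads = template_and_reads
    sam = tmp_path / "truth.sam"
    sam.write_text(reads.sam_text())
    n = 0
    with pysam.AlignmentFile(str(sam)) as fh:
        for rec in fh:
            assert rec.cigarstring == f"{p.read_len}M"
            start = rec.reference_start
            assert rec.query_sequence == template.seq[start : start + p.read_len]
            assert rec.is_paired and rec.is_proper_pair
            n += 1
    assert n == 2 * p.n_read_pairs


def test_read_simulation_is_deterministic(template_and_reads):
    template, p, reads = template_and_reads
    reads2, _ = simulate_short_reads(template, p)
    assert reads2.fastq1() == reads.fastq1()
    assert reads2.sam_text() == reads.sam_text()


def test_mean_depth_matches_coverage_identity(template_and_reads, tmp_path):
    """Observed mean pileup depth within 5% of 2*n*read_len/L."""
    template, p, reads = template_and_reads
    depth = np.zeros(len(template))
    for (rid, fs, fl, strand) in reads.placements:
        depth[fs : fs + p.read_len] += 1
        depth[fs + fl - p.read_len : fs + fl] += 1
    observed = depth.mean()
    assert observed == pytest.approx(reads.expected_depth, rel=0.05)


def test_fragment_shorter_than_read_is_rejected():
    p = SimParams(seed=0, fragment_len_mean=100.0)
    with pytest.raises(ValueError, match="fragment_len_mean"):
        p.validate()


def test_read_errors_are_substitutions_at_configured_rate():
    rng = np.random.default_rng(2)
    template = Contig("t", random_dna(rng, 30_000))
    p = SimParams(seed=3, n_read_pairs=2_000, read_error_rate=0.01)
    reads, _ = simulate_short_reads(template, p)
    mismatches = bases = 0
    for (rid, fs, fl, strand), s1 in zip(reads.placements, reads.seq1):
        ref = template.seq[fs : fs + p.read_len] if strand == "+" else template.seq[
            fs + fl - p.read_len : fs + fl
        ]
        mismatches += sum(x != y for x, y in zip(s1, ref))
        bases += p.read_len
    assert mismatches / bases == pytest.approx(0.01, rel=0.15)


def test_realign_reads_against_template_is_all_matches(template_and_reads, tmp_path):
    template, p, reads = template_and_reads
    sam = tmp_path / "re.sam"
    sam.write_text(realign_reads(reads, template))
    with pysam.AlignmentFile(str(sam)) as fh:
        recs = list(fh)
    assert len(recs) == 2 * p.n_read_pairs
    assert all(r.cigarstring == f"{p.read_len}M" for r in recs)


def test_coverage_depth_identity():
    assert coverage_depth(1000.0, 100) == 10.0
    with pytest.raises(ValueError):
        coverage_depth(10, 0)
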