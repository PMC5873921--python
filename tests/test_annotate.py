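"""Primer-site search, candidate extraction/classification, SCR scan."""

import numpy as np
import pytest

from bacfinish.annotate import (
    PrimerHit,
    classify_candidate,
    extract_candidates,
    find_primer_sites,
    find_scr,
)
from bacfinish.contig import Contig, revcomp
from bacfinish.simulate import (
    SimParams,
    make_bac_construct,
    make_reference_sets,
    random_dna,
)

PRIMERS = {"SLGF": SimParams().primer_fwd, "SLGR": SimParams().primer_rev}


@pytest.fixture(scope="module")
def insert(small_params_mod):
    construct, ledger = make_bac_construct(small_params_mod)
    return Contig("insert", ledger.insert_seq), ledger, small_params_mod


@pytest.fixture(scope="module")
def small_params_mod():
    return SimParams(seed=101, insert_len=20_000, vector_len=4_000, overlap_len=4_000)


def test_planted_primers_found_at_ledger_coordinates(insert):
    contig, ledger, p = insert
    hits = find_primer_sites(contig, PRIMERS, max_mismatch=3)
    fwd = [h for h in hits if h.primer_id == "SLGF"]
    rev = [h for h in hits if h.primer_id == "SLGR"]
    f_led, r_led = ledger.feature("primer_fwd"), ledger.feature("primer_rev")
    assert any(h.start == f_led.start and h.strand == "+" and h.mismatches == 0 for h in fwd)
    assert any(h.start == r_led.start and h.strand == "-" and h.mismatches == 0 for h in rev)


def test_mismatched_primer_site_reports_distance(rng):
    primer = PRIMERS["SLGF"]
    mutated = "T" + primer[1:] if primer[0] != "T" else "A" + primer[1:]
    seq = random_dna(rng, 500) + mutated + random_dna(rng, 500)
    hits = find_primer_sites(Contig("c", seq), {"SLGF": primer}, max_mismatch=2)
    assert any(h.start == 500 and h.mismatches == 1 for h in hits)


def test_degenerate_primer_bases_match_at_zero_cost(rng):
    site = "ACGTACGTACGTACGTACGT"
    primer = "ACGTACGTNCGTACGWACGT"  # N and W cover the planted bases
    seq = random_dna(rng, 300) + site + random_dna(rng, 300)
    hits = find_primer_sites(Contig("c", seq), {"P": primer}, max_mismatch=0)
    assert [h.start for h in hits if h.strand == "+"] == [300]


def test_non_iupac_primer_is_rejected(random_contig):
    with pytest.raises(ValueError, match="IUPAC"):
        find_primer_sites(random_contig, {"bad": "ACGTX"}, 0)


def test_strand_symmetry_of_primer_search(insert):
    contig, _, _ = insert
    L = len(contig)
    fwd_hits = find_primer_sites(contig, PRIMERS, 3)
    rc_hits = find_primer_sites(contig.reverse_complement(), PRIMERS, 3)
    mirrored = sorted((L - h.end, L - h.start, h.primer_id, "-" if h.strand == "+" else "+")
                      for h in rc_hits)
    assert mirrored == sorted((h.start, h.end, h.primer_id, h.strand) for h in fwd_hits)


def test_candidate_from_compatible_pair():
    c = Contig("c", "A" * 12_000)
    hits = [
        PrimerHit("SLGF", 10_000, 10_020, "+", 0),
        PrimerHit("SLGR", 11_480, 11_500, "-", 0),
    ]
    regions = extract_candidates(c, hits)
    assert len(regions) == 1
    assert regions[0].interval == (10_000, 11_500)
    assert regions[0].anchor == "both_primers"


def test_candidate_from_single_primer_and_boundary_clamp():
    c = Contig("c", "A" * 12_000)
    regions = extract_candidates(c, [PrimerHit("SLGF", 10_000, 10_020, "+", 0)])
    assert regions[0].interval == (9_000, 11_020)
    assert regions[0].anchor == "single_primer"
    clamped = extract_candidates(c, [PrimerHit("SLGF", 300, 320, "+", 0)])
    assert clamped[0].interval == (0, 1_320)


def test_distant_pair_is_not_joined():
    c = Contig("c", "A" * 30_000)
    hits = [
        PrimerHit("SLGF", 1_000, 1_020, "+", 0),
        PrimerHit("SLGR", 20_000, 20_020, "-", 0),
    ]
    regions = extract_candidates(c, hits)
    assert all(r.anchor == "single_primer" for r in regions)
    assert len(regions) == 2


def test_classification_of_verbatim_references(rng):
    srk = [Contig("s", random_dna(rng, 1200))]
    ark = [Contig("a", random_dna(rng, 1200))]
    verdict, id_s, id_a = classify_candidate(srk[0].seq, srk, ark)
    assert verdict == "srk" and id_s == 1.0
    verdict, id_s, id_a = classify_candidate(ark[0].seq, srk, ark)
    assert verdict == "ark3" and id_a == 1.0


def test_threshold_is_inclusive(rng):
    """A candidate whose best SRK identity equals the threshold exactly
    is accepted (>= is inclusive); any higher threshold rejects it."""
    cand = random_dna(rng, 200)
    positions = np.arange(10, 190, 9)[:20]
    bases = "ACGT"
    srk_seq = list(cand)
    for p in positions:
        srk_seq[p] = bases[(bases.index(srk_seq[p]) + int(rng.integers(1, 4))) % 4]
    srk = [Contig("s", "".join(srk_seq))]
    ark = [Contig("a", random_dna(rng, 200))]
    _, id_s, id_a = classify_candidate(cand, srk, ark, threshold=0.5)
    assert 0.85 <= id_s <= 0.95 and id_a < id_s  # ~10% diverged construction
    at_boundary, *_ = classify_candidate(cand, srk, ark, threshold=id_s)
    assert at_boundary == "srk"
    above, *_ = classify_candidate(cand, srk, ark, threshold=id_s + 1e-9)
    assert above == "undetermined"


def test_candidate_reverse_complement_still_classified(rng):
    srk = [Contig("s", random_dna(rng, 800))]
    ark = [Contig("a", random_dna(rng, 800))]
    verdict, id_s, _ = classify_candidate(revcomp(srk[0].seq), srk, ark)
    assert verdict == "srk" and id_s == 1.0


def test_empty_candidate_is_an_error(rng):
    with pytest.raises(ValueError, match="empty"):
        classify_candidate("", [Contig("s", "ACGT")], [Contig("a", "ACGT")])


def test_scr_orf_found_at_ledger_coordinates(insert):
    contig, ledger, p = insert
    hits = find_scr(contig)
    feat = ledger.feature("scr_orf")
    assert any(h.orf_interval == (feat.start, feat.end) and h.strand == "+" for h in hits)
    planted = [h for h in hits if h.orf_interval == (feat.start, feat.end)]
    assert planted[0].span_aa <= p.scr_cys_span_aa
    assert len(planted[0].cys_positions) == 8


def _orf_with_cys(n_cys: int, spacing: int, pad_aa: int = 20) -> str:
    codons = ["ATG"] + ["GCT"] * pad_aa
    for i in range(n_cys):
        codons.append("TGT")
        codons += ["GCT"] * (spacing - 1)
    codons += ["GCT"] * pad_aa + ["TAA"]
    return "".join(codons)


def test_seven_cysteines_is_not_a_hit():
    seq = "TAATAA" + _orf_with_cys(7, 3) + "TAATAA"
    assert find_scr(Contig("c", seq), min_orf_aa=30) == []


def test_eight_cysteines_spread_beyond_window_is_not_a_hit():
    # 8 cysteines spaced 29 aa apart span ~200 aa: invisible to a 90 aa window
    seq = "TAATAA" + _orf_with_cys(8, 29) + "TAATAA"
    assert find_scr(Contig("c", seq), min_orf_aa=30, cys_window_aa=90) == []
    # the same 8 within a tight span is a hit
    seq2 = "TAATAA" + _orf_with_cys(8, 8) + "TAATAA"
    hits = find_scr(Contig("c", seq2), min_orf_aa=30, cys_window_aa=90)
    assert len(hits) == 1 and hits[0].span_aa == 7 * 8 + 1


def test_scr_strand_symmetry(insert):
    contig, ledger, _ = insert
    L = len(contig)
    fwd = find_scr(contig)
    rc = find_scr(contig.reverse_complement())
    mirrored = sorted((L - e, L - s) for (s, e), *_ in [(h.orf_interval,) for h in rc])
    assert mirrored == sorted(h.orf_interval for h in fwd)


def test_planted_candidate_classified_srk_against_sampled_refs(insert):
    contig, ledger, p = insert
    hits = find_primer_sites(contig, PRIMERS, 3)
    regions = extract_candidates(contig, hits)
    srk_feat = ledger.feature("srk_exon1")
    planted = [r for r in regions
               if r.interval[0] <= srk_feat.start and r.interval[1] >= srk_feat.end]
    assert planted, "planted SRK region not extracted"
    srk_refs, ark3_refs = make_reference_sets(ledger, p)
    s, e = planted[0].interval
    verdict, id_s, id_a = classify_candidate(contig.seq[s:e], srk_refs, ark3_refs)
    assert verdict == "srk"
    assert id_s >= 0.90 and id_s > id_a
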