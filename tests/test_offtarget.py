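"""Guide scanning, off-target enumeration, design filter, amplicon scan."""

import numpy as np
import pytest

from crisprembryo.reads import CcsRead, revcomp
from crisprembryo.offtarget import (
    GuideRNA,
    enumerate_offtargets,
    guide_passes_filter,
    scan_candidate_guides,
    scan_offtarget_amplicon,
    seed_positions,
)
from crisprembryo.synthetic import make_amplicon, plant_offtarget_genome


def naive_offtarget_scan(protospacer, genome, max_mm):
    """Independent per-position Hamming scan oracle (no PAM prefilter,
    no vectorization)."""
    hits = set()
    for i in range(len(genome) - 22):
        block = genome[i : i + 23]
        if block[21:23] == "GG":
            mm = sum(a != b for a, b in zip(block[:20], protospacer))
            if mm <= max_mm:
                hits.add((i, "+", mm))
        if block[0:2] == "CC":
            ori = revcomp(block)
            mm = sum(a != b for a, b in zip(ori[:20], protospacer))
            if mm <= max_mm:
                hits.add((i, "-", mm))
    return hits


def random_genome(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def random_guide(rng):
    return GuideRNA(
        protospacer=random_genome(rng, 20),
        pam=random_genome(rng, 1) + "GG",
    )


def test_seed_region_convention():
    # 8-11 bp upstream of the PAM = protospacer indices 9..12
    # (0-based from the PAM-distal end; index 19 is adjacent to the PAM)
    assert seed_positions() == frozenset({9, 10, 11, 12})
    assert seed_positions(1, 1) == frozenset({19})


def test_guide_validation():
    with pytest.raises(ValueError):
        GuideRNA(protospacer="ACGT", pam="AGG")
    with pytest.raises(ValueError):
        GuideRNA(protospacer="A" * 20, pam="ATT")


def test_scan_candidate_guides_both_strands():
    # one NGG on the plus strand and one CCN (NGG on minus) upstream
    seq = "TT" + "CCA" + "A" * 20 + "T" * 5 + "G" * 20 + "TGG" + "AA"
    guides = scan_candidate_guides(seq)
    strands = {(g.start, g.strand) for g in guides}
    # plus-strand guide: protospacer ends right before "TGG"
    plus = [g for g in guides if g.strand == "+"]
    minus = [g for g in guides if g.strand == "-"]
    assert plus and minus
    for g in plus:
        assert seq[g.start + 21 : g.start + 23] == "GG"
    for g in minus:
        assert seq[g.start - 3 : g.start - 1] == "CC"
        assert revcomp(seq[g.start : g.start + 20]) == g.protospacer


def test_scan_no_pam_dinucleotide():
    assert scan_candidate_guides("ATATATATATATATATATATATATATAT") == []


def test_scan_matches_regex_style_oracle(rng):
    import re

    seq = random_genome(rng, 3000)
    guides = scan_candidate_guides(seq)
    n_plus = len([m for m in re.finditer(r"(?=GG)", seq) if m.start() >= 21])
    n_minus = len(
        [m for m in re.finditer(r"(?=CC)", seq) if m.start() + 23 <= len(seq)]
    )
    assert len([g for g in guides if g.strand == "+"]) == n_plus
    assert len([g for g in guides if g.strand == "-"]) == n_minus


def test_enumeration_matches_naive_oracle_random_guides(rng):
    genome = random_genome(rng, 12_000)
    for _ in range(6):
        guide = random_guide(rng)
        # plant the guide itself so at least one hit exists
        pos = int(rng.integers(0, len(genome) - 23))
        genome2 = genome[:pos] + guide.sequence + genome[pos + 23 :]
        got = {
            (s.start, s.strand, s.n_mismatches)
            for s in enumerate_offtargets(guide, genome2, max_mm=4)
        }
        assert got == naive_offtarget_scan(guide.protospacer, genome2, 4)


def test_planted_sites_annotated_exactly():
    amp = make_amplicon(seed=3)
    genome, _bed = plant_offtarget_genome(
        amp.guide,
        planted=[({2, 5, 9}, "+", 4000), (set(), "-", 8000)],
        genome_length=20_000,
        seed=9,
    )
    sites = {(s.start, s.strand): s for s in enumerate_offtargets(amp.guide, genome, 3)}
    s = sites[(4000, "+")]
    assert s.n_mismatches == 3 and s.mismatch_positions == frozenset({2, 5, 9})
    assert s.n_seed_mismatches == 1  # position 9 is in the seed
    assert s.predicted_cut == 4017
    on = sites[(8000, "-")]
    assert on.n_mismatches == 0
    assert on.predicted_cut == 8006


def test_four_mismatch_site_absent_at_max3():
    amp = make_amplicon(seed=3)
    genome, _ = plant_offtarget_genome(
        amp.guide, [({0, 3, 6, 9}, "+", 4000)], 10_000, seed=2
    )
    starts = {s.start for s in enumerate_offtargets(amp.guide, genome, max_mm=3)}
    assert 4000 not in starts


def test_strand_symmetry(rng):
    """Enumerating on the reverse-complemented genome yields the mirror
    site set with exactly remapped coordinates."""
    genome = random_genome(rng, 5000)
    guide = random_guide(rng)
    pos = 1234
    genome = genome[:pos] + guide.sequence + genome[pos + 23 :]
    fwd = enumerate_offtargets(guide, genome, max_mm=3)
    rev = enumerate_offtargets(guide, revcomp(genome), max_mm=3)
    L = len(genome)
    mirror = {(L - s.end, "-" if s.strand == "+" else "+", s.n_mismatches) for s in fwd}
    assert {(s.start, s.strand, s.n_mismatches) for s in rev} == mirror


def test_guide_filter_rules():
    amp = make_amplicon(seed=4)
    guide = amp.guide
    # plant: a clean >=3-mismatch-with-seed site passes; a 2-mismatch site
    # and a 3-mismatch/0-seed site each fail with that site cited
    genome, _ = plant_offtarget_genome(
        guide, [({1, 5, 10}, "+", 500)], 3000, seed=5
    )
    sites = [
        s for s in enumerate_offtargets(guide, genome, 4) if s.n_mismatches > 0
    ]
    ok, reasons = guide_passes_filter(guide, sites, min_mm=3, require_seed_mm=True)
    assert ok and not reasons

    genome, _ = plant_offtarget_genome(guide, [({1, 5}, "+", 500)], 3000, seed=6)
    sites = [s for s in enumerate_offtargets(guide, genome, 4) if s.n_mismatches > 0]
    ok, reasons = guide_passes_filter(guide, sites, min_mm=3)
    assert not ok and any("2 mismatches" in r for r in reasons)

    # PAM-distal-only mismatches: fails only when a seed mismatch is required
    genome, _ = plant_offtarget_genome(guide, [({0, 2, 4}, "+", 500)], 3000, seed=7)
    sites = [s for s in enumerate_offtargets(guide, genome, 4) if s.n_mismatches > 0]
    ok, reasons = guide_passes_filter(guide, sites, min_mm=3, require_seed_mm=True)
    assert not ok and any("seed" in r for r in reasons)
    ok, _ = guide_passes_filter(guide, sites, min_mm=3, require_seed_mm=False)
    assert ok


def test_filter_monotonic_in_min_mm():
    amp = make_amplicon(seed=8)
    genome, _ = plant_offtarget_genome(amp.guide, [({1, 5, 10}, "+", 500)], 3000, seed=8)
    sites = [s for s in enumerate_offtargets(amp.guide, genome, 4) if s.n_mismatches > 0]
    for k in (3, 2, 1):
        if guide_passes_filter(amp.guide, sites, min_mm=k)[0]:
            for lower in range(1, k):
                assert guide_passes_filter(amp.guide, sites, min_mm=lower)[0]


# ---------------------------------------------------------------------------
# Off-target amplicon scan
# ---------------------------------------------------------------------------

def make_site_reads(reference, n_wt, n_mut, mut_seq):
    reads = []
    for i in range(n_wt):
        reads.append(CcsRead(f"wt{i}", reference, [40] * len(reference), 9, 0.999))
    for i in range(n_mut):
        reads.append(CcsRead(f"mut{i}", mut_seq, [40] * len(mut_seq), 9, 0.999))
    return reads


def test_scan_offtarget_detects_planted_deletion():
    """A 12-bp deletion 26 bp downstream of the cut in ~6.8% of reads is
    reported with its offset and fraction."""
    amp = make_amplicon(seed=12, length=300, guide_offset=100)
    cut = amp.cut_site
    ref = amp.sequence
    mut = ref[: cut + 26] + ref[cut + 38 :]
    reads = make_site_reads(ref, n_wt=930, n_mut=68, mut_seq=mut)
    rep = scan_offtarget_amplicon(reads, ref, cut, report_window=50)
    assert rep.total_reads == 998
    assert len(rep.rows) == 1
    row = rep.rows[0]
    assert (row.kind, row.size) == ("deletion", 12)
    assert row.fraction_of_reads == pytest.approx(68 / 998)
    # left-alignment may shift the reported start; the footprint stays
    # within a base or two of the planted +26 offset
    assert abs(row.offset_from_predicted_cut - 26) <= 3


def test_scan_offtarget_wt_reads_clean():
    amp = make_amplicon(seed=13, length=300, guide_offset=100)
    reads = make_site_reads(amp.sequence, 50, 0, amp.sequence)
    rep = scan_offtarget_amplicon(reads, amp.sequence, amp.cut_site)
    assert rep.rows == []


def test_scan_offtarget_flags_known_variant():
    amp = make_amplicon(seed=14, length=300, guide_offset=100)
    cut = amp.cut_site
    ref = amp.sequence
    mut = ref[: cut + 10] + ref[cut + 22 :]  # 12-bp deletion at +10
    reads = make_site_reads(ref, 80, 20, mut)
    rep = scan_offtarget_amplicon(
        reads, ref, cut, report_window=50,
        known_variants=[("deletion", 12, cut + 8)],  # overlapping annotation
    )
    assert len(rep.rows) == 1
    assert rep.rows[0].known_variant
    assert rep.known_variant_overlaps == [("deletion", 12, cut + 8)]
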