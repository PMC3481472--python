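"""Locus discovery: mapping caps, windows, duplex geometry, support, verdicts."""

import itertools

import numpy as np
import pytest

from mirnascape.discovery import (DiscoveryParams, DuplexCall, ReadAlignment,
                                  SeedRegion, call_duplex, candidate_windows,
                                  decide_verdict, evaluate_support,
                                  extract_candidates, homology_check,
                                  map_reads, offset_distance,
                                  select_representatives, seed_regions,
                                  discover)
from mirnascape.folding import SecondaryStructure
from mirnascape.genome_io import GenomeBundle, ReadRecord
from mirnascape.sequences import revcomp
from mirnascape.synthetic import (SimulationSpec, generate_genome,
                                  miniature_catalog, simulate_reads)


def _repeat_genome(unit: str, copies: int, spacer_len: int = 50,
                   seed: int = 0) -> GenomeBundle:
    rng = np.random.default_rng(seed)
    parts = []
    for _ in range(copies):
        parts.append("".join("ACGT"[i] for i in rng.integers(0, 4, spacer_len)))
        parts.append(unit)
    parts.append("".join("ACGT"[i] for i in rng.integers(0, 4, spacer_len)))
    return GenomeBundle({"chr1": "".join(parts)}, [])


UNIT = "AACCTTGGACTGACTGAAGTC"  # 21 nt, chosen non-palindromic


def test_unique_read_maps_once_with_hit_count_one():
    genome = _repeat_genome(UNIT, 1)
    alns = map_reads([ReadRecord(UNIT, 5)], genome)
    assert len(alns) == 1
    assert alns[0].strand == "+" and alns[0].n_genomic_hits == 1


def test_multimapper_boundary_is_strictly_more_than_35():
    read = [ReadRecord(UNIT, 5)]
    at_cap = map_reads(read, _repeat_genome(UNIT, 35))
    over_cap = map_reads(read, _repeat_genome(UNIT, 36))
    assert len(at_cap) == 35 and at_cap[0].n_genomic_hits == 35
    assert over_cap == []


def test_minus_strand_placement_is_reported():
    genome = _repeat_genome(UNIT, 1)
    alns = map_reads([ReadRecord(revcomp(UNIT), 2)], genome)
    assert len(alns) == 1 and alns[0].strand == "-"


def test_single_stack_yields_full_flank_grid_before_dedup():
    genome = _repeat_genome(UNIT, 1, spacer_len=400)
    alns = map_reads([ReadRecord(UNIT, 5)], genome)
    (region,) = seed_regions(alns)
    assert len(candidate_windows(region, genome)) == 25  # 5x5 grid
    (region2, dedup) = extract_candidates(alns, genome)[0]
    assert len(set(dedup)) == len(dedup)
    assert all(w[1] - w[0] + 1 <= 320 for w in dedup)


def test_nearby_stacks_merge_into_one_seed_region():
    rng = np.random.default_rng(1)
    bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
    a, b = bg[100:121], bg[146:167]  # stacks 25 nt apart
    genome = GenomeBundle({"chr1": bg}, [])
    alns = [a for a in map_reads([ReadRecord(a, 3), ReadRecord(b, 2)], genome)
            if a.strand == "+"]
    regions = seed_regions(alns)
    assert len(regions) == 1
    assert regions[0].start == 101 and regions[0].end == 167


def test_candidate_window_contains_planted_precursor(sim_bundle, catalog):
    genome, truth, reads = sim_bundle
    alns = map_reads(reads, genome)
    for locus in truth.loci[:3]:
        found = False
        for region, windows in extract_candidates(alns, genome):
            if region.chrom != locus.chrom:
                continue
            for ws, we in windows:
                if ws <= locus.precursor[0] and locus.precursor[1] <= we:
                    found = True
        assert found, locus


# ---------------------------------------------------------------------------
# duplex calling on hand-built structures


def _hairpin_structure(pairs):
    return SecondaryStructure("A" * 130, pairs, score=0)


MATURE = (11, 31)  # 21-nt mature at positions 11..31


def test_duplex_perfect_stem_has_clean_overhangs():
    pairs = {(i, 120 - i) for i in range(11, 32)}
    d = call_duplex(_hairpin_structure(pairs), MATURE)
    assert d.n_mismatches == 0 and d.bulges == []
    assert d.overhang_3p_mature == 2 and d.overhang_3p_star == 2
    assert d.star_span == (91, 111)


def test_duplex_counts_symmetric_mismatches():
    pairs = {(i, 120 - i) for i in range(11, 32) if i not in (15, 20, 25)}
    d = call_duplex(_hairpin_structure(pairs), MATURE)
    assert d.n_mismatches == 3 and d.bulges == []


def test_duplex_five_mismatches_fails_the_mismatch_rule():
    drop = (13, 16, 19, 22, 25)
    pairs = {(i, 120 - i) for i in range(11, 32) if i not in drop}
    d = call_duplex(_hairpin_structure(pairs), MATURE)
    assert d.n_mismatches == 5  # annotate() flags mismatch_ok False


def test_duplex_detects_single_star_bulge_of_two():
    pairs = {(i, 120 - i) for i in range(11, 21)}
    pairs |= {(i, 118 - i) for i in range(21, 32)}  # star side skips 2 nt
    d = call_duplex(_hairpin_structure(pairs), MATURE)
    assert d.bulges == [("star", 2)] and d.n_mismatches == 0


def test_duplex_detects_mature_bulge():
    pairs = {(i, 120 - i) for i in range(11, 21)}
    pairs |= {(i, 122 - i) for i in range(23, 32)}  # mature 21,22 unpaired
    d = call_duplex(_hairpin_structure(pairs), MATURE)
    assert ("mature", 2) in d.bulges


def test_duplex_requires_sixty_percent_pairing():
    pairs = {(i, 120 - i) for i in range(11, 21)}  # 10 of 21 paired
    assert call_duplex(_hairpin_structure(pairs), MATURE) is None


# ---------------------------------------------------------------------------
# support evaluation


def _aln(seq_len, start, count, chrom="chr1"):
    return ReadAlignment(ReadRecord("A" * seq_len, count), chrom, start, "+", 1)


def test_support_duplex_majority_passes_25_percent():
    mature, star = (100, 120), (140, 160)
    alns = [_aln(21, 100, 50), _aln(21, 140, 30), _aln(21, 125, 20)]
    support, flags = evaluate_support((80, 180), mature, star, alns)
    assert support == (80, 100, 50)
    assert flags["support25_ok"] and not flags["abundance10_ok"]


def test_support_low_duplex_with_star_present_rejected():
    mature, star = (100, 120), (140, 160)
    alns = [_aln(21, 100, 15), _aln(21, 140, 5), _aln(21, 125, 80)]
    support, flags = evaluate_support((80, 180), mature, star, alns)
    assert support[0] / support[1] < 0.25
    assert not flags["support25_ok"] and not flags["abundance10_ok"]


def test_support_abundance_fallback_at_threshold():
    mature = (100, 120)
    alns = [_aln(21, 100, 10), _aln(21, 125, 80)]
    _support, flags = evaluate_support((80, 180), mature, None, alns)
    assert flags["abundance10_ok"]  # >= 10 reads, star absent
    _support, flags9 = evaluate_support(
        (80, 180), mature, None, [_aln(21, 100, 9), _aln(21, 125, 80)]
    )
    assert not flags9["abundance10_ok"]


# ---------------------------------------------------------------------------
# representatives and homology


def test_representative_single_variant():
    assert select_representatives([ReadRecord("ACGTACGTACGTACGTACGTA", 30)]) == (
        "ACGTACGTACGTACGTACGTA", None)


def test_representative_prefers_containing_variant_above_ten_percent():
    short = "ACGTACGTACGTACGTACGTA"
    long = "G" + short + "T"
    out = select_representatives([ReadRecord(short, 100), ReadRecord(long, 15)])
    assert out == (long, short)  # 15/115 = 13% >= 10%


def test_representative_ignores_containing_variant_below_ten_percent():
    short = "ACGTACGTACGTACGTACGTA"
    long = "G" + short + "T"
    out = select_representatives([ReadRecord(short, 100), ReadRecord(long, 9)])
    assert out == (short, None)  # 9/109 = 8.3% < 10%


def test_homology_exact_and_over_threshold(catalog):
    entry = catalog[0]
    hit, family = homology_check(entry.sequence, catalog)
    assert hit and family == entry.family
    mutated = list(entry.sequence)
    for i, b in zip((3, 7, 11, 15), "TTTT"):
        mutated[i] = "A" if mutated[i] != "A" else "C"
    hit4, _ = homology_check("".join(mutated), [entry])
    assert not hit4  # 4 substitutions exceed the 3-mismatch cap


def test_offset_distance_matches_naive_all_offsets_oracle():
    def oracle(a, b):
        best = None
        for s in range(-2, 3):
            lo, hi = max(0, s), min(len(a), len(b) + s)
            if hi <= lo or abs(s) > 2 or abs(len(a) - s - len(b)) > 2:
                continue
            mm = sum(a[i] != b[i - s] for i in range(lo, hi))
            best = mm if best is None else min(best, mm)
        return best

    rng = np.random.default_rng(21)
    for _ in range(50):
        la, lb = rng.integers(19, 25, size=2)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, la))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, lb))
        assert offset_distance(a, b) == oracle(a, b)


# ---------------------------------------------------------------------------
# verdict logic and end-to-end recovery


GATING = ("duplex_found", "overhang_ok", "mismatch_ok", "bulge_ok",
          "support25_ok", "abundance10_ok")


def test_verdict_equals_stated_conjunction_over_all_flag_combinations():
    for bits in itertools.product([False, True], repeat=len(GATING)):
        flags = dict(zip(GATING, bits))
        expected = (flags["duplex_found"] and flags["overhang_ok"]
                    and flags["mismatch_ok"] and flags["bulge_ok"]
                    and (flags["support25_ok"] or flags["abundance10_ok"]))
        assert (decide_verdict(flags) == "annotated") == expected
        # secondary flags never change the verdict
        flags2 = dict(flags, conservation_hit=True, target_predicted=True)
        assert decide_verdict(flags2) == decide_verdict(flags)
        if expected:
            assert decide_verdict(flags, representative_len=24) == "excluded_24nt"


def test_support_flags_are_monotone_in_thresholds():
    mature, star = (100, 120), (140, 160)
    alns = [_aln(21, 100, 12), _aln(21, 140, 4), _aln(21, 125, 40)]
    strict = DiscoveryParams(min_abundance=10, min_duplex_frac=0.5)
    loose = DiscoveryParams(min_abundance=5, min_duplex_frac=0.25)
    _s, f_strict = evaluate_support((80, 180), mature, star, alns, strict)
    _s, f_loose = evaluate_support((80, 180), mature, star, alns, loose)
    for key in ("support25_ok", "abundance10_ok"):
        assert f_loose[key] >= f_strict[key]


def test_planted_loci_recovered_and_decoys_rejected(sim_bundle, discovered_loci):
    genome, truth, _reads = sim_bundle
    annotated = [l for l in discovered_loci if l.verdict == "annotated"]
    assert len(annotated) == len(truth.loci)
    recovered = {l.mature_genomic for l in annotated if l.strand == "+"}
    for locus in truth.loci:
        hit = any(abs(m[0] - locus.mature[0]) <= 1 and abs(m[1] - locus.mature[1]) <= 1
                  for m in recovered)
        assert hit, locus.mature
    # no annotated locus on the decoy chromosome, none outside planted truth
    assert all(l.chrom == "chr1" for l in annotated)
    for l in annotated:
        assert any(l.start <= p.precursor[1] and p.precursor[0] <= l.end
                   for p in truth.loci)


def test_24nt_mature_loci_are_excluded():
    spec = SimulationSpec(seed=2, n_mir_loci=2, chrom_length=60_000,
                          mature_length=24, background_reads=5)
    genome, truth = generate_genome(spec)
    reads = simulate_reads(spec, truth, genome)
    loci = discover(reads, genome, miniature_catalog())
    verdicts = {l.verdict for l in loci
                if any(l.start <= p.precursor[1] and p.precursor[0] <= l.end
                       for p in truth.loci) and l.chrom == "chr1"}
    assert "excluded_24nt" in verdicts
    assert "annotated" not in verdicts
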