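"""Hairpin-based miRNA locus discovery from mapped small-RNA reads.

The stage mirrors community practice for annotating plant miRNAs:
perfect-match read mapping with a multimapper cap, candidate precursor
windows around read stacks, secondary-structure prediction, excision of
the mature/star duplex with 2-nt 3' overhangs, bounded mismatches and
at most one small asymmetric bulge, and read-support thresholds (the
duplex must carry >= 25% of stem-loop reads, or - when no star read is
seen - the mature must reach a minimum absolute abundance).  Loci whose
representative mature is 24 nt are excluded from downstream analyses
because such species are ambiguous between long miRNAs and
heterochromatic siRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .folding import BACKENDS, MIN_FOLD_LEN, SecondaryStructure
from .genome_io import CatalogEntry, GenomeBundle, ReadRecord
from .sequences import revcomp

log = logging.getLogger(__name__)

FLAG_NAMES = (
    "duplex_found", "overhang_ok", "mismatch_ok", "bulge_ok",
    "support25_ok", "abundance10_ok", "conservation_hit",
    "target_predicted", "excluded_24nt",
)


@dataclass
class DiscoveryParams:
    max_hits: int = 35  # drop reads matching more genomic positions than this
    min_abundance: int = 10  # mature-count fallback when no star read exists
    min_duplex_frac: float = 0.25
    duplex_read_tolerance: int = 0  # nt of end slack when matching duplex reads
    gap_merge: int = 30  # read stacks closer than this merge into one region
    flanks: tuple[int, ...] = (20, 60, 100, 160, 250)
    max_window: int = 320
    min_pair_frac: float = 0.6  # mature positions paired to one arm to call a duplex
    homology_max_mm: int = 3
    fold_backend: str = "pairmax"


@dataclass(frozen=True)
class ReadAlignment:
    """A perfect full-length placement of a read on the genome."""

    read: ReadRecord
    chrom: str
    start: int  # 1-based leftmost genomic position
    strand: str
    n_genomic_hits: int

    @property
    def end(self) -> int:
        return self.start + len(self.read.sequence) - 1


@dataclass
class SeedRegion:
    chrom: str
    strand: str
    start: int
    end: int
    alignments: list[ReadAlignment]


@dataclass
class DuplexCall:
    """The excised mature/star duplex read off a folded precursor."""

    mature_span: tuple[int, int]  # 1-based within the precursor window
    star_span: tuple[int, int]
    n_mismatches: int
    bulges: list[tuple[str, int]]  # (arm, length)
    overhang_3p_mature: int
    overhang_3p_star: int


@dataclass
class MirnaLocus:
    """A candidate/annotated precursor with structure, duplex and verdict."""

    FLAG_NAMES = FLAG_NAMES

    chrom: str
    strand: str
    start: int  # precursor window, genomic 1-based inclusive
    end: int
    structure: SecondaryStructure | None
    duplex: DuplexCall | None
    read_support: tuple[int, int, int]  # (duplex, stemloop, mature) counts
    criteria_flags: dict[str, bool]
    verdict: str  # annotated | rejected | excluded_24nt
    representative_id1: str | None = None
    representative_id2: str | None = None
    mature_genomic: tuple[int, int] | None = None
    star_genomic: tuple[int, int] | None = None

    def mature_spans(self) -> list[tuple[int, int]]:
        spans = []
        if self.mature_genomic:
            spans.append(self.mature_genomic)
        if self.star_genomic:
            spans.append(self.star_genomic)
        return spans


# ---------------------------------------------------------------------------
# mapping


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i + 1)  # 1-based
        i = haystack.find(needle, i + 1)
    return out


def map_reads(reads: list[ReadRecord], genome: GenomeBundle,
              params: DiscoveryParams | None = None) -> list[ReadAlignment]:
    """All perfect full-length placements on both strands.

    Reads hitting more than ``max_hits`` genomic positions are repeat
    candidates rather than miRNAs and are dropped (logged with their
    hit count); a read with exactly ``max_hits`` placements is kept.
    """
    params = params or DiscoveryParams()
    alignments: list[ReadAlignment] = []
    for read in reads:
        hits: list[tuple[str, int, str]] = []
        rc = revcomp(read.sequence)
        for chrom, seq in genome.chromosomes.items():
            hits += [(chrom, p, "+") for p in _find_all(seq, read.sequence)]
            hits += [(chrom, p, "-") for p in _find_all(seq, rc)]
        if not hits:
            continue
        if len(hits) > params.max_hits:
            log.info("dropping read %s: %d genomic hits (> %d)",
                     read.sequence, len(hits), params.max_hits)
            continue
        for chrom, pos, strand in hits:
            alignments.append(ReadAlignment(read, chrom, pos, strand, len(hits)))
    return alignments


# ---------------------------------------------------------------------------
# candidate windows


def seed_regions(alignments: list[ReadAlignment],
                 params: DiscoveryParams | None = None) -> list[SeedRegion]:
    """Merge positionally clustered alignments (gap <= gap_merge) per strand."""
    params = params or DiscoveryParams()
    by_key: dict[tuple[str, str], list[ReadAlignment]] = {}
    for aln in alignments:
        by_key.setdefault((aln.chrom, aln.strand), []).append(aln)
    regions: list[SeedRegion] = []
    for (chrom, strand), alns in sorted(by_key.items()):
        alns.sort(key=lambda a: (a.start, a.end))
        current: list[ReadAlignment] = []
        cur_end = None
        for aln in alns:
            if current and aln.start - cur_end - 1 > params.gap_merge:
                regions.append(SeedRegion(chrom, strand, current[0].start,
                                          cur_end, current))
                current = []
            if not current:
                current = [aln]
                cur_end = aln.end
            else:
                current.append(aln)
                cur_end = max(cur_end, aln.end)
        if current:
            regions.append(SeedRegion(chrom, strand, current[0].start, cur_end, current))
    return regions


def candidate_windows(region: SeedRegion, genome: GenomeBundle,
                      params: DiscoveryParams | None = None) -> list[tuple[int, int]]:
    """Precursor windows over the flank grid, before deduplication.

    Windows longer than ``max_window`` are trimmed symmetrically around
    the seed region rather than dropped, so the grid combinatorics are
    preserved.
    """
    params = params or DiscoveryParams()
    chrom_len = len(genome.chromosomes[region.chrom])
    windows = []
    for fl in params.flanks:
        for fr in params.flanks:
            ws = max(1, region.start - fl)
            we = min(chrom_len, region.end + fr)
            excess = (we - ws + 1) - params.max_window
            if excess > 0:
                # trim from both flanks, never into the seed region
                left_room = region.start - ws
                right_room = we - region.end
                trim_left = min(excess // 2, left_room)
                trim_right = min(excess - trim_left, right_room)
                ws += trim_left
                we -= trim_right
            windows.append((ws, we))
    return windows


def extract_candidates(alignments: list[ReadAlignment], genome: GenomeBundle,
                       params: DiscoveryParams | None = None
                       ) -> list[tuple[SeedRegion, list[tuple[int, int]]]]:
    """Seed regions with their deduplicated candidate windows (smallest first)."""
    params = params or DiscoveryParams()
    out = []
    for region in seed_regions(alignments, params):
        seen = set()
        dedup = []
        for w in candidate_windows(region, genome, params):
            if w not in seen:
                seen.add(w)
                dedup.append(w)
        dedup.sort(key=lambda w: (w[1] - w[0], w[0]))
        out.append((region, dedup))
    return out


# ---------------------------------------------------------------------------
# duplex calling


def call_duplex(structure: SecondaryStructure,
                mature_span: tuple[int, int],
                min_pair_frac: float = 0.6) -> DuplexCall | None:
    """Excise the mature/star duplex from a folded precursor.

    The star span is derived from the pairing partners of the mature
    positions (the partner of the mature 5' end, extended 2 nt at the
    star 3' end; the partner of mature position length-2, marking the
    star 5' end), which encodes the 2-nt 3' overhang geometry of dicing.
    Returns None when fewer than ``min_pair_frac`` of mature positions
    pair to a single opposite arm.
    """
    m1, m2 = mature_span
    L = m2 - m1 + 1
    partners = {i: structure.partner(i) for i in range(m1, m2 + 1)}
    left = [(i, p) for i, p in partners.items() if p is not None and p < m1]
    right = [(i, p) for i, p in partners.items() if p is not None and p > m2]
    arm = left if len(left) > len(right) else right
    if len(arm) / L < min_pair_frac:
        return None
    arm.sort()
    # anchors within the duplex: mature 5' end .. position L-2 (3' overhang)
    anchors = [(i, p) for i, p in arm if i <= m2 - 2]
    if not anchors:
        return None
    i5, p5 = anchors[0]
    i3, p3 = anchors[-1]
    star_span = (p3, p5 + 2)
    n_mm = (i5 - m1) + (m2 - 2 - i3)  # unpaired duplex ends face the other arm
    bulges: list[tuple[str, int]] = []
    for (ia, pa), (ib, pb) in zip(anchors, anchors[1:]):
        a = ib - ia - 1  # unpaired mature positions
        b = pa - pb - 1  # unpaired star positions
        if b < 0:  # non-nested outlier pairing; treat the step as unpairable
            n_mm += a
            continue
        n_mm += min(a, b)
        if a > b:
            bulges.append(("mature", a - b))
        elif b > a:
            bulges.append(("star", b - a))
    return DuplexCall(
        mature_span=mature_span,
        star_span=star_span,
        n_mismatches=n_mm,
        bulges=bulges,
        overhang_3p_mature=m2 - i3,
        overhang_3p_star=2 - (i5 - m1),
    )


# ---------------------------------------------------------------------------
# support, representatives, homology


def evaluate_support(window: tuple[int, int],
                     mature_genomic: tuple[int, int],
                     star_genomic: tuple[int, int] | None,
                     alignments: list[ReadAlignment],
                     params: DiscoveryParams | None = None
                     ) -> tuple[tuple[int, int, int], dict[str, bool]]:
    """Count duplex/stem-loop/mature reads and evaluate the support flags."""
    params = params or DiscoveryParams()
    tol = params.duplex_read_tolerance
    ws, we = window

    def span_matches(aln: ReadAlignment, span: tuple[int, int] | None) -> bool:
        if span is None:
            return False
        return abs(aln.start - span[0]) <= tol and abs(aln.end - span[1]) <= tol

    stemloop = duplex = mature = 0
    star_present = False
    for aln in alignments:
        if aln.end < ws or aln.start > we:
            continue
        stemloop += aln.read.count
        is_mature = span_matches(aln, mature_genomic)
        is_star = span_matches(aln, star_genomic)
        if is_mature:
            mature += aln.read.count
        if is_star:
            star_present = True
        if is_mature or is_star:
            duplex += aln.read.count
    flags = {
        "support25_ok": stemloop > 0 and duplex / stemloop >= params.min_duplex_frac,
        "abundance10_ok": (not star_present) and mature >= params.min_abundance,
    }
    return (duplex, stemloop, mature), flags


def select_representatives(variants: list[ReadRecord]) -> tuple[str, str | None]:
    """Representative mature ID(s) for a locus from its mature-stack variants.

    The most abundant variant is the default representative.  When that
    sequence is contained in a longer co-located variant carrying at
    least 10% of the locus total abundance, the longer variant becomes
    ID1 and the shorter one ID2.
    """
    if not variants:
        raise ValueError("no mature variants supplied")
    total = sum(v.count for v in variants)
    ordered = sorted(variants, key=lambda v: (-v.count, v.sequence))
    top = ordered[0]
    containers = [
        v for v in ordered[1:]
        if len(v.sequence) > len(top.sequence)
        and top.sequence in v.sequence
        and v.count / total >= 0.10
    ]
    if containers:
        longer = max(containers, key=lambda v: (v.count, v.sequence))
        return longer.sequence, top.sequence
    return top.sequence, None


def offset_distance(a: str, b: str, max_shift: int = 2) -> int | None:
    """Hamming distance under the best ungapped offset with +-2 nt end slack.

    Offsets shift one sequence against the other by up to ``max_shift``;
    unmatched overhangs longer than the slack disqualify the offset.
    Returns None when no admissible offset exists.
    """
    best: int | None = None
    for s in range(-max_shift, max_shift + 1):
        lo = max(0, s)
        hi = min(len(a), len(b) + s)
        if hi <= lo:
            continue
        left_over = abs(s)
        right_over = abs(len(a) - s - len(b))
        if left_over > max_shift or right_over > max_shift:
            continue
        mm = sum(1 for i in range(lo, hi) if a[i] != b[i - s])
        if best is None or mm < best:
            best = mm
    return best


def homology_check(mature: str, catalog: list[CatalogEntry],
                   max_mismatch: int = 3) -> tuple[bool, str | None]:
    """Conservation hit: any catalog mature within ``max_mismatch`` substitutions.

    Ties are broken by lowest distance, then lexicographic family name.
    """
    best: tuple[int, str] | None = None
    for entry in catalog:
        d = offset_distance(mature, entry.sequence)
        if d is None or d > max_mismatch:
            continue
        if best is None or (d, entry.family) < best:
            best = (d, entry.family)
    if best is None:
        return False, None
    return True, best[1]


# ---------------------------------------------------------------------------
# verdict and annotation


def decide_verdict(flags: dict[str, bool], representative_len: int | None = None) -> str:
    """The annotation decision as a pure function of the criteria flags."""
    annotated = (
        flags.get("duplex_found", False)
        and flags.get("overhang_ok", False)
        and flags.get("mismatch_ok", False)
        and flags.get("bulge_ok", False)
        and (flags.get("support25_ok", False) or flags.get("abundance10_ok", False))
    )
    if annotated and representative_len == 24:
        return "excluded_24nt"
    return "annotated" if annotated else "rejected"


def _local_span(window: tuple[int, int], strand: str,
                genomic: tuple[int, int]) -> tuple[int, int]:
    ws, we = window
    s, e = genomic
    if strand == "+":
        return (s - ws + 1, e - ws + 1)
    return (we - e + 1, we - s + 1)


def _genomic_span(window: tuple[int, int], strand: str,
                  local: tuple[int, int]) -> tuple[int, int]:
    ws, we = window
    i, j = local
    if strand == "+":
        return (ws + i - 1, ws + j - 1)
    return (we - j + 1, we - i + 1)


def _window_sequence(genome: GenomeBundle, chrom: str, strand: str,
                     window: tuple[int, int]) -> str:
    seq = genome.fetch(chrom, window[0], window[1])
    return seq if strand == "+" else revcomp(seq)


def annotate(candidates: list[tuple[SeedRegion, list[tuple[int, int]]]],
             genome: GenomeBundle,
             catalog: list[CatalogEntry] | None = None,
             params: DiscoveryParams | None = None) -> list[MirnaLocus]:
    """Evaluate candidate windows per seed region and call the verdict.

    Windows are tried smallest-first; the first window whose locus
    reaches verdict ``annotated`` wins.  When no window annotates, the
    best-supported attempt is kept (flags recorded) with verdict
    ``rejected`` so the report shows why the region failed.
    """
    params = params or DiscoveryParams()
    fold_fn = BACKENDS[params.fold_backend]
    loci: list[MirnaLocus] = []
    for region, windows in candidates:
        top = max(region.alignments, key=lambda a: (a.read.count, a.read.sequence))
        mature_genomic = (top.start, top.end)
        best_locus: MirnaLocus | None = None
        for window in windows:
            ws, we = window
            if we - ws + 1 < MIN_FOLD_LEN:
                continue
            if not (ws <= mature_genomic[0] and mature_genomic[1] <= we):
                continue
            seq = _window_sequence(genome, region.chrom, region.strand, window)
            try:
                structure = fold_fn(seq)
            except ValueError:
                continue
            mature_local = _local_span(window, region.strand, mature_genomic)
            duplex = call_duplex(structure, mature_local, params.min_pair_frac)
            flags = dict.fromkeys(FLAG_NAMES, False)
            flags["duplex_found"] = duplex is not None
            star_genomic = None
            if duplex is not None:
                flags["overhang_ok"] = (
                    duplex.overhang_3p_mature == 2 and duplex.overhang_3p_star == 2
                )
                flags["mismatch_ok"] = duplex.n_mismatches <= 4
                flags["bulge_ok"] = (
                    len(duplex.bulges) <= 1
                    and all(ln <= 2 for _, ln in duplex.bulges)
                )
                star_local = duplex.star_span
                if 1 <= star_local[0] and star_local[1] <= we - ws + 1:
                    star_genomic = _genomic_span(window, region.strand, star_local)
            support, support_flags = evaluate_support(
                window, mature_genomic, star_genomic, region.alignments, params
            )
            flags.update(support_flags)

            variants = _mature_variants(region, mature_genomic)
            id1, id2 = select_representatives(variants)
            if catalog:
                hit, _family = homology_check(id1, catalog, params.homology_max_mm)
                flags["conservation_hit"] = hit
            verdict = decide_verdict(flags, len(id1))
            flags["excluded_24nt"] = verdict == "excluded_24nt"
            locus = MirnaLocus(
                chrom=region.chrom, strand=region.strand, start=ws, end=we,
                structure=structure, duplex=duplex, read_support=support,
                criteria_flags=flags, verdict=verdict,
                representative_id1=id1, representative_id2=id2,
                mature_genomic=mature_genomic, star_genomic=star_genomic,
            )
            if verdict == "annotated":
                best_locus = locus
                break
            if best_locus is None or _flag_score(locus) > _flag_score(best_locus):
                best_locus = locus
        if best_locus is not None:
            loci.append(best_locus)
    return loci


def _flag_score(locus: MirnaLocus) -> int:
    return sum(locus.criteria_flags.get(f, False) for f in FLAG_NAMES[:6])


def _mature_variants(region: SeedRegion,
                     mature_genomic: tuple[int, int]) -> list[ReadRecord]:
    """Reads stacked at the mature position (co-located isoforms)."""
    ms, me = mature_genomic
    variants: dict[str, int] = {}
    for aln in region.alignments:
        if aln.start <= me and aln.end >= ms:  # overlaps the mature stack
            overlap = min(aln.end, me) - max(aln.start, ms) + 1
            if overlap >= 0.75 * (me - ms + 1):
                variants[aln.read.sequence] = max(
                    variants.get(aln.read.sequence, 0), aln.read.count
                )
    return [ReadRecord(s, c) for s, c in variants.items()]


def deduplicate_strand_mirrors(loci: list[MirnaLocus]) -> list[MirnaLocus]:
    """Collapse opposite-strand re-detections of the same hairpin.

    A perfect inverted repeat is strand-symmetric under exact-match
    mapping: the mature and star reads also place on the opposite
    strand, so one genomic hairpin can annotate twice.  Overlapping
    same-chromosome loci on opposite strands are reported once,
    preferring the annotated verdict, then higher duplex-read support,
    then the plus strand.
    """
    def rank(l: MirnaLocus) -> tuple:
        return (l.verdict == "annotated", l.read_support[0], l.strand == "+")

    kept: list[MirnaLocus] = []
    for locus in sorted(loci, key=rank, reverse=True):
        clash = any(
            k.chrom == locus.chrom and k.strand != locus.strand
            and k.start <= locus.end and locus.start <= k.end
            for k in kept
        )
        if not clash:
            kept.append(locus)
    kept.sort(key=lambda l: (l.chrom, l.start, l.strand))
    return kept


def discover(reads: list[ReadRecord], genome: GenomeBundle,
             catalog: list[CatalogEntry] | None = None,
             params: DiscoveryParams | None = None) -> list[MirnaLocus]:
    """Full discovery: map reads, extract candidates, fold and annotate."""
    params = params or DiscoveryParams()
    alignments = map_reads(reads, genome, params)
    log.info("mapped %d alignments from %d reads", len(alignments), len(reads))
    candidates = extract_candidates(alignments, genome, params)
    log.info("extracted %d seed regions", len(candidates))
    loci = deduplicate_strand_mirrors(annotate(candidates, genome, catalog, params))
    n_ok = sum(1 for l in loci if l.verdict == "annotated")
    log.info("annotated %d / %d candidate loci", n_ok, len(loci))
    return loci
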