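"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure a soybean-style
small-RNA discovery run assumes: a genome carrying inverted-repeat MIR
loci whose arms excise a mature/star duplex with 2-nt 3' overhangs,
repeat-derived multimapping decoys, protein-coding genes planted at
known distances to exercise genomic-context classes, transcripts with
designed target-site mismatch patterns, phased-siRNA read sets, and
organ-level Ct tables.  Everything is a pure function of its spec and
seed: rerunning with the same seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GeneFeature, GenomeBundle, ReadRecord, CatalogEntry, _sorted_reads
from .sequences import revcomp

_BASES = np.array(list("ACGT"))

ORGANS = ["R", "N", "S", "L", "F", "P"]


@dataclass
class SimulationSpec:
    """Parameters of the planted-locus simulation.

    Defaults describe the study conditions the discovery stage is
    designed for: 10 MIR loci with perfectly complementary arms, exact
    dicing (no end jitter), duplex reads dominating each locus
    (fraction 0.8), a star arm at a quarter of the mature abundance,
    and two repeat families copied to 40 genomic positions to exercise
    the multimapper filter.
    """

    seed: int = 1
    n_mir_loci: int = 10
    n_decoy_repeat_loci: int = 2
    chrom_length: int = 100_000
    hairpin_mismatches: int = 0
    duplex_read_fraction: float = 0.8
    star_to_mature_ratio: float = 0.25
    dicer_jitter_prob: float = 0.0
    read_depth: float = 60.0
    # secondary knobs
    decoy_copies: int = 40
    background_reads: int = 40
    mature_length: int = 21
    phasing_read_count: int = 60
    phased_in_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("duplex_read_fraction", "star_to_mature_ratio",
                     "dicer_jitter_prob", "phased_in_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.chrom_length < 10 * (self.n_mir_loci * 300):
            raise ValueError("chrom_length too small for the requested locus count")


@dataclass
class PlantedLocus:
    chrom: str
    strand: str
    precursor: tuple[int, int]  # 1-based inclusive
    mature: tuple[int, int]
    star: tuple[int, int]
    mature_seq: str
    star_seq: str
    context: str = "intergenic"  # designed genomic-context class


@dataclass
class PlantedTarget:
    transcript_id: str
    mirna_index: int
    site_start: int  # 1-based on transcript
    site_end: int
    pattern: str
    expect_emitted: bool
    expect_pass: bool


@dataclass
class PlantedPhasedLocus:
    transcript_id: str
    mirna_index: int
    cleavage_pos: int
    in_phase_fraction: float


@dataclass
class PlantedTruth:
    """Ground truth for recovery tests; filled in by the generators."""

    loci: list[PlantedLocus] = field(default_factory=list)
    decoy_units: list[str] = field(default_factory=list)
    decoy_positions: list[list[tuple[str, int]]] = field(default_factory=list)
    tandem_pairs: list[tuple[int, int, int]] = field(default_factory=list)  # (i, j, gap)
    targets: list[PlantedTarget] = field(default_factory=list)
    phased: list[PlantedPhasedLocus] = field(default_factory=list)
    read_tally: dict = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _substitute(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply exactly n_subs substitutions at distinct random positions."""
    if n_subs == 0:
        return seq
    s = list(seq)
    for pos in rng.choice(len(s), size=n_subs, replace=False):
        choices = [b for b in "ACGT" if b != s[pos]]
        s[pos] = choices[rng.integers(0, 3)]
    return "".join(s)


# ---------------------------------------------------------------------------
# genome


def generate_genome(spec: SimulationSpec) -> tuple[GenomeBundle, PlantedTruth]:
    """Plant MIR hairpins, context genes and repeat decoys in a 2-chromosome genome.

    Each MIR locus is a perfect inverted repeat (arm = 3-nt flank +
    mature + 2-nt flank, so the stem extends beyond the duplex on both
    sides) whose right arm carries ``hairpin_mismatches`` substitutions.
    The geometry guarantees that the excised mature/star duplex has 2-nt
    3' overhangs on both strands.  Five loci get a protein-coding gene
    planted at a designed relation (inside CDS, inside UTR, 500 bp, 748
    bp and 1500 bp away); three locus pairs are placed 4/4/6 kb apart to
    exercise cluster detection.
    """
    rng = np.random.default_rng([spec.seed, 0])
    truth = PlantedTruth()

    chr1 = list(_random_seq(rng, spec.chrom_length))
    chr2 = list(_random_seq(rng, spec.chrom_length))
    genes: list[GeneFeature] = []

    n = spec.n_mir_loci
    L = spec.mature_length

    # start-to-start gaps; pairs near the end of the layout are the
    # tandem-cluster probes (4 kb, 4 kb and 6 kb apart)
    gaps = [8000] * n
    pair_plan: list[tuple[int, int, int]] = []
    if n >= 6:
        pair_plan = [(n - 6, n - 5, 4000), (n - 4, n - 3, 4000), (n - 2, n - 1, 6000)]
        for i, j, gap in pair_plan:
            gaps[j] = gap
    cursor = 2500
    context_plan = ["intragenic_CDS", "intragenic_UTR", "proximal_500",
                    "proximal_748", "intergenic_1500"]

    for i in range(n):
        if i > 0:
            cursor += gaps[i]
        mature = _random_seq(rng, L)
        f5 = _random_seq(rng, 3)
        f3 = _random_seq(rng, 2)
        left_arm = f5 + mature + f3  # length L + 5
        loop = _random_seq(rng, int(rng.integers(12, 21)))
        right_arm = _substitute(rng, revcomp(left_arm), spec.hairpin_mismatches)
        precursor = left_arm + loop + right_arm

        A = cursor  # 1-based start of left arm
        if A + len(precursor) + 3000 > spec.chrom_length:
            raise ValueError("infeasible packing: increase chrom_length")
        chr1[A - 1 : A - 1 + len(precursor)] = list(precursor)

        arm = len(left_arm)
        B = A + arm + len(loop)  # 1-based start of right arm
        mature_span = (A + 3, A + L + 2)
        # position A+i pairs B+(L+4-i); star = partners of mature[1..L-2]
        # extended 2 nt at its 3' end, giving the 2-nt overhang geometry
        star_span = (B + 4, B + L + 3)
        star_seq = "".join(chr1[star_span[0] - 1 : star_span[1]])
        ctx = context_plan[i] if i < len(context_plan) else "intergenic"
        prec_span = (A, A + len(precursor) - 1)
        truth.loci.append(
            PlantedLocus("chr1", "+", prec_span, mature_span, star_span,
                         mature, star_seq, context=ctx)
        )
        genes.extend(_plant_context_gene(ctx, prec_span, i))
        cursor = A
    truth.tandem_pairs = pair_plan

    # repeat decoys scattered over chr2
    for d in range(spec.n_decoy_repeat_loci):
        unit = _random_seq(rng, L)
        positions = []
        taken: list[int] = []
        while len(positions) < spec.decoy_copies:
            p = int(rng.integers(1000, spec.chrom_length - 1000))
            if all(abs(p - q) > 2 * L for q in taken):
                chr2[p - 1 : p - 1 + L] = list(unit)
                positions.append(("chr2", p))
                taken.append(p)
        truth.decoy_units.append(unit)
        truth.decoy_positions.append(positions)

    bundle = GenomeBundle(
        chromosomes={"chr1": "".join(chr1), "chr2": "".join(chr2)}, genes=genes
    )
    return bundle, truth


def _plant_context_gene(ctx: str, prec: tuple[int, int], idx: int) -> list[GeneFeature]:
    ps, pe = prec
    gid = f"SynGene{idx:02d}"
    if ctx == "intragenic_CDS":
        gs, ge = ps - 300, pe + 300
        subs = [("UTR5", gs, gs + 49), ("CDS", gs + 50, ge - 50), ("UTR3", ge - 49, ge)]
    elif ctx == "intragenic_UTR":
        gs, ge = ps - 300, pe + 50
        subs = [("CDS", gs, ps - 60), ("UTR3", ps - 59, ge)]
    elif ctx == "proximal_500":
        ge = ps - 500
        gs = ge - 900
        subs = [("CDS", gs, ge)]
    elif ctx == "proximal_748":
        ge = ps - 748
        gs = ge - 900
        subs = [("CDS", gs, ge)]
    elif ctx == "intergenic_1500":
        ge = ps - 1500
        gs = ge - 900
        subs = [("CDS", gs, ge)]
    else:
        return []
    return [GeneFeature(gid, "chr1", gs, ge, "+", subs)]


# ---------------------------------------------------------------------------
# reads


def simulate_reads(spec: SimulationSpec, truth: PlantedTruth,
                   genome: GenomeBundle) -> list[ReadRecord]:
    """Draw a collapsed read set from the planted loci plus background.

    Per locus, a Poisson(read_depth) number of reads is split into exact
    duplex reads (probability ``duplex_read_fraction``; star chosen at
    ``star_to_mature_ratio`` relative to mature) and non-duplex stem-loop
    reads (end-jittered mature reads or random precursor fragments).
    Decoy repeats emit their unit sequence; background reads are uniform
    over the genome, 18-26 nt, both strands.  The realized per-source
    counts are recorded in ``truth.read_tally``.
    """
    rng = np.random.default_rng([spec.seed, 1])
    counts: dict[str, int] = {}
    tally = {"loci": [], "decoys": [], "background": 0}

    def add(seq: str, n: int = 1) -> None:
        counts[seq] = counts.get(seq, 0) + n

    r = spec.star_to_mature_ratio
    p_star = r / (1.0 + r)
    for locus in truth.loci:
        chrom_seq = genome.chromosomes[locus.chrom]
        n_reads = max(1, int(rng.poisson(spec.read_depth)))
        for _ in range(n_reads):
            if rng.random() < spec.duplex_read_fraction:
                seq = locus.star_seq if rng.random() < p_star else locus.mature_seq
            elif rng.random() < 0.5:
                # jittered mature-arm read
                s, e = locus.mature
                if rng.random() < spec.dicer_jitter_prob:
                    s += int(rng.integers(-1, 2))
                if rng.random() < spec.dicer_jitter_prob:
                    e += int(rng.integers(-1, 2))
                seq = chrom_seq[s - 1 : e]
            else:
                # other stem-loop fragment
                ps, pe = locus.precursor
                ln = int(rng.integers(18, 27))
                start = int(rng.integers(ps, max(ps + 1, pe - ln + 1)))
                seq = chrom_seq[start - 1 : start - 1 + ln]
            add(seq)
        tally["loci"].append(n_reads)

    for unit in truth.decoy_units:
        n = int(rng.integers(5, 15))
        add(unit, n)
        tally["decoys"].append(n)

    for _ in range(spec.background_reads):
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        seq_full = genome.chromosomes[chrom]
        ln = int(rng.integers(18, 27))
        start = int(rng.integers(1, len(seq_full) - ln))
        seq = seq_full[start - 1 : start - 1 + ln]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        add(seq)
        tally["background"] += 1

    tally["total"] = sum(tally["loci"]) + sum(tally["decoys"]) + tally["background"]
    truth.read_tally = tally
    return _sorted_reads(counts)


# ---------------------------------------------------------------------------
# targets and phasing


def _non_pairing_base(mirna_base: str) -> str:
    """A transcript base that neither Watson-Crick-pairs nor wobbles."""
    forbidden = {"A": {"T"}, "C": {"G"}, "G": {"C", "T"}, "T": {"A", "G"}}[mirna_base]
    for b in "ACGT":
        if b not in forbidden:
            return b
    raise AssertionError


def _plant_site(transcript: list[str], mature: str, start: int,
                mismatch_positions: tuple[int, ...] = ()) -> tuple[int, int]:
    """Write a (possibly mismatched) target site into the transcript.

    ``start`` is 1-based; miRNA position i (from its 5' end) faces
    transcript position start + L - i, so position 1 pairs the site's
    3'-most base.
    """
    L = len(mature)
    site = list(revcomp(mature))
    for p in mismatch_positions:
        site[L - p] = _non_pairing_base(mature[p - 1])
    transcript[start - 1 : start - 1 + L] = site
    return (start, start + L - 1)


def generate_targets_and_phasing(
    spec: SimulationSpec, truth: PlantedTruth
) -> tuple[dict[str, str], list[ReadRecord]]:
    """Emit transcripts with designed target sites plus transcript-mapped reads.

    Sites cover the positional-rule edge cases (perfect; 1 mismatch at
    miRNA position 5; 1 mismatch at position 10, which must not be
    emitted; 5 mismatches after position 12, which must fail), a
    dual-targeting transcript with sites for two distinct miRNAs ~600 nt
    apart, a phased-siRNA transcript with a stated in-phase read
    fraction downstream of the predicted cleavage site, and a uniform
    control.  Requires at least 6 planted loci.
    """
    if len(truth.loci) < 6:
        raise ValueError("need at least 6 planted loci for the target designs")
    rng = np.random.default_rng([spec.seed, 2])
    matures = [loc.mature_seq for loc in truth.loci]
    L = spec.mature_length
    transcripts: dict[str, str] = {}
    counts: dict[str, int] = {}

    def new_transcript(name: str, length: int) -> list[str]:
        return list(_random_seq(rng, length))

    designs = [
        ("T_perfect", 0, (), "perfect", True, True),
        ("T_mm5", 1, (5,), "mm_at_5", True, True),
        ("T_mm10", 2, (10,), "mm_at_10", False, False),
        ("T_after12", 3, (13, 15, 17, 19, 21), "five_mm_after_12", False, False),
    ]
    for name, mi, mms, pattern, emitted, passes in designs:
        t = new_transcript(name, 300)
        span = _plant_site(t, matures[mi], 100, mms)
        transcripts[name] = "".join(t)
        truth.targets.append(
            PlantedTarget(name, mi, span[0], span[1], pattern, emitted, passes)
        )

    # dual-targeting transcript: two families, sites ~600 nt apart
    t = new_transcript("T_dual", 820)
    s1 = _plant_site(t, matures[4], 100)
    s2 = _plant_site(t, matures[5], 700)
    transcripts["T_dual"] = "".join(t)
    truth.targets.append(PlantedTarget("T_dual", 4, s1[0], s1[1], "dual_a", True, True))
    truth.targets.append(PlantedTarget("T_dual", 5, s2[0], s2[1], "dual_b", True, True))

    # phased transcript: reads downstream of the cleavage site
    t = new_transcript("T_phased", 600)
    span = _plant_site(t, matures[0], 100)
    transcripts["T_phased"] = "".join(t)
    truth.targets.append(PlantedTarget("T_phased", 0, span[0], span[1], "phased", True, True))
    cleavage = span[1] - 9  # first base of the 3' fragment
    truth.phased.append(
        PlantedPhasedLocus("T_phased", 0, cleavage, spec.phased_in_fraction)
    )
    n_in = int(round(spec.phasing_read_count * spec.phased_in_fraction))
    seq = transcripts["T_phased"]
    for k in range(n_in):
        cycle = int(rng.integers(0, 10))
        if rng.random() < 0.25:  # antisense in-phase read (2-nt offset geometry)
            five_prime = cleavage + 21 * cycle - 2
            read = revcomp(seq[five_prime - 21 : five_prime])
        else:
            pos = cleavage + 21 * cycle
            read = seq[pos - 1 : pos - 1 + 21]
        counts[read] = counts.get(read, 0) + 1
    for k in range(spec.phasing_read_count - n_in):
        pos = cleavage + int(rng.integers(0, 10)) * 21 + int(rng.integers(1, 21))
        read = seq[pos - 1 : pos - 1 + 21]
        counts[read] = counts.get(read, 0) + 1

    # unphased control transcript: reads cover the 21 registers evenly
    # (extras go to out-of-phase registers), so the in-phase register can
    # never exceed the median of the others
    t = new_transcript("T_uniform", 600)
    span = _plant_site(t, matures[1], 100)
    transcripts["T_uniform"] = "".join(t)
    truth.targets.append(PlantedTarget("T_uniform", 1, span[0], span[1], "control", True, True))
    seq = transcripts["T_uniform"]
    ctrl_cleavage = span[1] - 9
    truth.phased.append(PlantedPhasedLocus("T_uniform", 1, ctrl_cleavage, 0.0))
    for i in range(spec.phasing_read_count):
        cycle, register = divmod(i, 21)
        if cycle >= spec.phasing_read_count // 21:
            register = 1 + i % 20  # remainder skips the in-phase register
        pos = ctrl_cleavage + 21 * (cycle % 10) + register
        read = seq[pos - 1 : pos - 1 + 21]
        counts[read] = counts.get(read, 0) + 1

    return transcripts, _sorted_reads(counts)


# ---------------------------------------------------------------------------
# expression


def generate_expression_table(
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """Ct tables over the six organs plus the miRNA-target pairing list.

    Contains one constructed inverse pair (root-high/nodule-low miRNA
    against a root-low/nodule-high target) and one flat pair, on top of
    the uniformly expressed references (miR1515 for miRNAs, Actin for
    targets).  Small seeded Ct noise (sd 0.05 cycles) is added so the
    tables are not artificially exact.
    """
    rng = np.random.default_rng([seed, 3])

    def noisy(base: dict[str, float]) -> list[float]:
        return [base[o] + rng.normal(0.0, 0.05) for o in ORGANS]

    flat = {o: 22.0 for o in ORGANS}
    mirna_ct = pd.DataFrame(
        {
            "miR1515": [22.0] * len(ORGANS),  # reference: exactly uniform
            "miR-roothigh": noisy({"R": 18.0, "N": 26.0, "S": 22.0, "L": 22.0,
                                   "F": 22.0, "P": 22.0}),
            "miR-flat": noisy(flat),
        },
        index=ORGANS,
    ).T
    target_ct = pd.DataFrame(
        {
            "Actin": [20.0] * len(ORGANS),
            "Tgt-inverse": noisy({"R": 26.0, "N": 18.0, "S": 22.0, "L": 22.0,
                                  "F": 22.0, "P": 22.0}),
            "Tgt-flat": noisy(flat),
        },
        index=ORGANS,
    ).T
    pairs = [("miR-roothigh", "Tgt-inverse"), ("miR-flat", "Tgt-flat")]
    return mirna_ct, target_ct, pairs


# ---------------------------------------------------------------------------
# miniature reference catalog


def miniature_catalog() -> list[CatalogEntry]:
    """A small fixed mature-miRNA catalog spanning three species.

    Covers a non-Fabaceae species (Arabidopsis thaliana), a Fabaceae
    species other than Glycine max (Glycine soja) and Glycine max
    itself, so every conservation class is reachable in tests.
    """
    rows = [
        ("ath-miR166a", "TCGGACCAGGCTTCATTCCCC", "miR166", "Arabidopsis thaliana", "Brassicaceae"),
        ("ath-miR169a", "CAGCCAAGGATGACTTGCCGA", "miR169", "Arabidopsis thaliana", "Brassicaceae"),
        ("ath-miR395a", "CTGAAGTGTTTGGGGGAACTC", "miR395", "Arabidopsis thaliana", "Brassicaceae"),
        ("gso-miR1510a", "TGTTGTTTTACCTATTCCACC", "miR1510", "Glycine soja", "Fabaceae"),
        ("gso-miR2109", "TGGTAGCAAGAGAGATGACGC", "miR2109", "Glycine soja", "Fabaceae"),
        ("gma-miR2118a", "TTGCCGATTCCACCCATTCCTA", "miR2118", "Glycine max", "Fabaceae"),
        ("gma-miR2218", "TTGCCGATTCCACCCATTCCCA", "miR2218", "Glycine max", "Fabaceae"),
        ("gma-miR1515a", "TCATTTTGCGTGCAATGATCC", "miR1515", "Glycine max", "Fabaceae"),
    ]
    return [CatalogEntry(*row) for row in rows]


# ---------------------------------------------------------------------------
# synthetic reconstruction of the genome-wide compiled locus table


def compiled_locus_table() -> pd.DataFrame:
    """SYNTHETIC reconstruction of the genome-wide compiled miRNA locus table.

    The original genome-scale compilation (285 annotated loci in 108
    families after criteria re-checks and 24-nt exclusion) is not
    shipped with this package; this function rebuilds a table with the
    same published marginal structure so the family-characteristics
    stage can be exercised end to end: 26 conserved / 9 legume-specific
    / 73 soybean-specific families, legume families of one (1/3) or two
    (2/3) members, 83.6% soybean-specific singletons with four
    three-member families (three of them producing all-distinct
    matures), a 12-member conserved family with identical matures, a
    19-member and a single-member conserved family, and per-class
    mature-sequence diversity of ~2.6 / ~1.1 / ~1.1 members per unique
    mature.  Rows that fail the annotation criteria or carry a 24-nt
    representative are included (flagged) so the inclusion filters have
    something to remove.  Fully deterministic.
    """
    rng = np.random.default_rng(20120504)

    # (family, size, n_unique_matures, mature_length)
    conserved = [
        ("miR164", 12, 1, 21), ("miR828", 1, 1, 21), ("miR162", 2, 1, 21),
        ("miR168", 2, 1, 21), ("miR398", 3, 1, 21), ("miR399", 3, 1, 21),
        ("miR403", 4, 1, 22), ("miR2111", 4, 1, 21), ("miR482", 5, 1, 22),
        ("miR167", 6, 1, 21), ("miR4376", 6, 1, 21), ("miR535", 9, 1, 21),
        ("miR166", 19, 8, 21), ("miR169", 14, 5, 21), ("miR156", 12, 5, 21),
        ("miR171", 11, 5, 21), ("miR172", 10, 5, 21), ("miR319", 9, 4, 21),
        ("miR159", 8, 4, 21), ("miR393", 8, 4, 22), ("miR390", 7, 4, 21),
        ("miR160", 6, 3, 21), ("miR396", 5, 3, 21), ("miR395", 5, 3, 22),
        ("miR394", 4, 3, 21), ("miR408", 4, 1, 21),
    ]
    legume = [
        ("miR1508", 1, 1, 21), ("miR1509", 1, 1, 22), ("miR1514", 1, 1, 21),
        ("miR1510", 2, 2, 21), ("miR1511", 2, 2, 21), ("miR1512", 2, 2, 21),
        ("miR2109", 2, 2, 21), ("miR4413", 2, 2, 22), ("miR2118/2218", 2, 1, 22),
    ]
    soybean = []
    for i in range(61):  # singletons
        soybean.append((f"miR-Seq{i + 1:03d}", 1, 1, 22 if i % 2 == 0 else 21))
    soybean += [
        ("miR-Seq062", 3, 3, 21), ("miR-Seq063", 3, 3, 22), ("miR-Seq064", 3, 3, 21),
        ("miR-Seq065", 3, 2, 22),
        ("miR-Seq066", 2, 2, 21), ("miR-Seq067", 2, 2, 22),
        ("miR-Seq068", 2, 1, 21), ("miR-Seq069", 2, 1, 22), ("miR-Seq070", 2, 1, 21),
        ("miR-Seq071", 2, 1, 22), ("miR-Seq072", 2, 1, 21),
        ("miR-Seq073", 4, 2, 22),
    ]

    rows = []
    used: set[str] = set()

    def fresh_seq(length: int) -> str:
        while True:
            s = _random_seq(rng, length)
            if s not in used:
                used.add(s)
                return s

    locus_no = 0
    for klass, fams in (("conserved", conserved), ("legume_specific", legume),
                        ("soybean_specific", soybean)):
        for fam, size, n_unique, length in fams:
            base = fresh_seq(length)
            variants = [base]
            for _ in range(n_unique - 1):
                while True:
                    v = _substitute(rng, base, 1)
                    if v not in used:
                        used.add(v)
                        variants.append(v)
                        break
            for m in range(size):
                locus_no += 1
                mature = variants[m % n_unique]
                rows.append(
                    {"locus_id": f"GmaMIR{locus_no:04d}", "family": fam,
                     "conservation": klass, "mature": mature,
                     "mature_length": len(mature), "passes_criteria": True,
                     "is_24nt": False}
                )

    # flagged rows the inclusion filters must remove
    for i in range(8):  # 24-nt species that pass the structural criteria
        locus_no += 1
        rows.append(
            {"locus_id": f"GmaMIR{locus_no:04d}", "family": f"miR-24nt{i:02d}",
             "conservation": "soybean_specific", "mature": fresh_seq(24),
             "mature_length": 24, "passes_criteria": True, "is_24nt": True}
        )
    for i in range(12):  # hairpins failing the annotation criteria
        locus_no += 1
        rows.append(
            {"locus_id": f"GmaMIR{locus_no:04d}", "family": f"miR-fail{i:02d}",
             "conservation": "soybean_specific", "mature": fresh_seq(21),
             "mature_length": 21, "passes_criteria": False, "is_24nt": False}
        )
    return pd.DataFrame(rows)
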