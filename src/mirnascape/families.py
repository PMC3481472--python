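"""Family clustering, conservation classes, genomic context and statistics.

Families group loci whose mature sequences are near-identical
(single-linkage at Hamming distance <= 2 under the best ungapped
offset); clusters anchor to named reference families when any member
lies within distance 4 of a catalog mature.  Conservation classes
follow the phylogenetic-presence definition: conserved families have
homologs outside the Fabaceae, legume-specific families only within
Fabaceae species other than Glycine max (G. soja counts as "other"),
and soybean-specific families nowhere else.  Genomic context classifies
each locus against the protein-coding annotation (intragenic in CDS or
UTR, proximal below 1 kb, else intergenic), and cluster detection
chains loci within 5 kb with no intervening protein-coding gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import offset_distance
from .genome_io import CatalogEntry, GeneFeature

PROXIMAL_BP = 1000
CLUSTER_BP = 5000
FAMILY_DIST = 2  # member-to-member single-linkage threshold
CATALOG_DIST = 4  # cluster-to-catalog anchoring threshold

FABACEAE = "Fabaceae"


@dataclass
class MirnaFamily:
    family_id: str
    members: list[str]  # locus ids
    mature_sequences: list[str]  # unique set, deterministic order
    conservation: str | None = None
    catalog_anchor: bool = False

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def matures_per_sequence(self) -> float:
        return self.size / len(self.mature_sequences)


@dataclass
class GenomicContext:
    locus_id: str
    context: str  # intergenic | intragenic_CDS | intragenic_UTR | proximal
    nearest_gene: str | None
    distance: int  # 0 if intragenic
    side: str | None  # 5' | 3' | within


@dataclass
class LocusCluster:
    members: list[str]
    chrom: str
    span: tuple[int, int]
    orientations: list[str]
    arrangement: str  # tandem | head_to_head | tail_to_tail | mixed


# ---------------------------------------------------------------------------
# family clustering


def cluster_families(matures: dict[str, str],
                     catalog: list[CatalogEntry] | None = None
                     ) -> list[MirnaFamily]:
    """Single-linkage clustering of representative matures into families.

    ``matures`` maps locus id -> representative mature sequence.  A
    cluster is merged into a named catalog family when any member lies
    within ``CATALOG_DIST`` of a catalog mature; when catalog labels
    from both the miR2118 and miR2218 families land on one cluster it
    is named "miR2118/2218".  Unanchored clusters get sequential ids.
    Deterministic and invariant to input order.
    """
    ids = sorted(matures)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d = offset_distance(matures[a], matures[b])
            if d is not None and d <= FAMILY_DIST:
                union(a, b)

    clusters: dict[str, list[str]] = {}
    for lid in ids:
        clusters.setdefault(find(lid), []).append(lid)

    families: list[MirnaFamily] = []
    new_id = 0
    for root in sorted(clusters):
        members = sorted(clusters[root])
        seqs = sorted({matures[m] for m in members})
        anchor_families: set[str] = set()
        if catalog:
            for seq in seqs:
                for entry in catalog:
                    d = offset_distance(seq, entry.sequence)
                    if d is not None and d <= CATALOG_DIST:
                        anchor_families.add(entry.family)
        if anchor_families:
            stripped = {f.replace("miR", "") for f in anchor_families}
            if {"2118", "2218"} <= stripped:
                name = "miR2118/2218"
            else:
                name = sorted(anchor_families)[0]
            anchored = True
        else:
            new_id += 1
            name = f"fam-new-{new_id:03d}"
            anchored = False
        families.append(MirnaFamily(name, members, seqs, catalog_anchor=anchored))
    return families


def classify_conservation(family: MirnaFamily,
                          catalog: list[CatalogEntry]) -> str:
    """Conservation class from catalog homologs of the family's matures."""
    if any(e.plant_family is None for e in catalog):
        raise ValueError("catalog entries must carry plant-family (species) labels")
    hit_non_fabaceae = False
    hit_other_fabaceae = False
    for seq in family.mature_sequences:
        for entry in catalog:
            d = offset_distance(seq, entry.sequence)
            if d is None or d > CATALOG_DIST:
                continue
            if entry.plant_family != FABACEAE:
                hit_non_fabaceae = True
            elif entry.species != "Glycine max":
                # any Fabaceae other than G. max, including G. soja
                hit_other_fabaceae = True
    if hit_non_fabaceae:
        return "conserved"
    if hit_other_fabaceae:
        return "legume_specific"
    return "soybean_specific"


# ---------------------------------------------------------------------------
# genomic context


def classify_context(locus_id: str, span: tuple[int, int], chrom: str,
                     genes: list[GeneFeature]) -> GenomicContext:
    """Position of a locus relative to the protein-coding annotation.

    Overlap with a CDS wins over UTR; otherwise the distance to the
    nearest gene edge decides proximal (< 1000 bp, strictly) versus
    intergenic, with the side reported relative to the gene's strand.
    """
    s, e = span
    same_chrom = [g for g in genes if g.chrom == chrom]
    overlapping = [g for g in same_chrom if g.start <= e and s <= g.end]
    for g in overlapping:
        kinds = {
            kind for kind, ks, ke in g.subfeatures if ks <= e and s <= ke
        } or {"CDS"}  # genes without subfeatures count as all-CDS
        if "CDS" in kinds:
            return GenomicContext(locus_id, "intragenic_CDS", g.gene_id, 0, "within")
    for g in overlapping:
        kinds = {kind for kind, ks, ke in g.subfeatures if ks <= e and s <= ke}
        if kinds & {"UTR5", "UTR3"}:
            return GenomicContext(locus_id, "intragenic_UTR", g.gene_id, 0, "within")
    if overlapping:  # inside the gene span but in no annotated subfeature
        g = overlapping[0]
        return GenomicContext(locus_id, "intragenic_UTR", g.gene_id, 0, "within")

    best: tuple[int, GeneFeature] | None = None
    for g in same_chrom:
        if g.end < s:
            d = s - g.end
        elif e < g.start:
            d = g.start - e
        else:  # pragma: no cover - handled above
            d = 0
        if best is None or d < best[0]:
            best = (d, g)
    if best is None:
        return GenomicContext(locus_id, "intergenic", None, -1, None)
    d, g = best
    if d < PROXIMAL_BP:
        locus_is_right = s > g.end
        # side relative to the gene's strand
        if g.strand == "+":
            side = "3'" if locus_is_right else "5'"
        else:
            side = "5'" if locus_is_right else "3'"
        return GenomicContext(locus_id, "proximal", g.gene_id, d, side)
    return GenomicContext(locus_id, "intergenic", g.gene_id, d, None)


# ---------------------------------------------------------------------------
# clusters of miRNA genes


def detect_clusters(loci: list[tuple[str, str, int, int, str]],
                    genes: list[GeneFeature]) -> list[LocusCluster]:
    """Greedy chaining of loci within 5 kb with no intervening gene.

    ``loci`` rows are (locus_id, chrom, start, end, strand).  The
    arrangement is labeled from member strands: all equal -> tandem; a
    divergent +/- pair (5' ends facing away) -> head_to_head; a
    convergent pair -> tail_to_tail; anything else mixed.
    """
    def gene_between(chrom: str, a_end: int, b_start: int) -> bool:
        return any(
            g.chrom == chrom and g.start > a_end and g.end < b_start
            for g in genes
        )

    clusters: list[LocusCluster] = []
    by_chrom: dict[str, list[tuple[str, str, int, int, str]]] = {}
    for row in loci:
        by_chrom.setdefault(row[1], []).append(row)
    for chrom in sorted(by_chrom):
        rows = sorted(by_chrom[chrom], key=lambda r: (r[2], r[3]))
        chain = [rows[0]]
        for prev, cur in zip(rows, rows[1:]):
            gap = cur[2] - prev[3]
            if gap <= CLUSTER_BP and not gene_between(chrom, prev[3], cur[2]):
                chain.append(cur)
            else:
                if len(chain) > 1:
                    clusters.append(_make_cluster(chain))
                chain = [cur]
        if len(chain) > 1:
            clusters.append(_make_cluster(chain))
    return clusters


def _make_cluster(chain: list[tuple[str, str, int, int, str]]) -> LocusCluster:
    strands = [r[4] for r in chain]
    if len(set(strands)) == 1:
        arrangement = "tandem"
    elif len(chain) == 2:
        # left member then right member in genomic order
        arrangement = "tail_to_tail" if strands == ["+", "-"] else "head_to_head"
    else:
        arrangement = "mixed"
    return LocusCluster(
        members=[r[0] for r in chain],
        chrom=chain[0][1],
        span=(chain[0][2], chain[-1][3]),
        orientations=strands,
        arrangement=arrangement,
    )


# ---------------------------------------------------------------------------
# statistics


def welch_t_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Two-sample unequal-variance (Welch) t-test, two-tailed.

    Returns (t, Welch-Satterthwaite df, p).  Degenerate samples (fewer
    than 2 values, or zero variance in both) raise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    for name, x in (("sample_a", a), ("sample_b", b)):
        if x.size < 2:
            raise ValueError(f"{name}: need at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both samples have zero variance with unequal means")
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def family_statistics(families: list[MirnaFamily]) -> dict:
    """Per-conservation-class summary of family characteristics.

    Emits, per class: the family-size vector, mean size, the share of
    families whose members all produce one identical mature, members
    per unique mature both as the class aggregate (class loci / class
    unique matures) and as the mean of per-family ratios, the
    mature-length class split (<=21 vs >=22 nt, per family by its first
    mature), and the position-wise nucleotide frequency matrix.
    """
    out: dict[str, dict] = {}
    for klass in ("conserved", "legume_specific", "soybean_specific"):
        fams = [f for f in families if f.conservation == klass]
        if not fams:
            out[klass] = {"n_families": 0}
            continue
        sizes = [f.size for f in fams]
        n_loci = sum(sizes)
        n_unique = sum(len(f.mature_sequences) for f in fams)
        # families whose *different* members produce one identical mature;
        # singletons are trivially uniform and do not count
        identical = [f for f in fams
                     if f.size >= 2 and len(f.mature_sequences) == 1]
        le21 = sum(1 for f in fams if len(f.mature_sequences[0]) <= 21)
        seqs = [s for f in fams for s in f.mature_sequences]
        out[klass] = {
            "n_families": len(fams),
            "n_loci": n_loci,
            "sizes": sizes,
            "mean_size": n_loci / len(fams),
            "pct_identical_matures": 100.0 * len(identical) / len(fams),
            "members_per_unique_mature": n_loci / n_unique,
            "mean_family_members_per_mature": float(
                np.mean([f.matures_per_sequence for f in fams])
            ),
            "n_le21": le21,
            "n_ge22": len(fams) - le21,
            "nucleotide_frequencies": position_frequencies(seqs),
        }
    return out


def position_frequencies(seqs: list[str], max_len: int = 24) -> pd.DataFrame:
    """Per-position A/C/G/U frequencies over a set of mature sequences."""
    counts = np.zeros((max_len, 4))
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    for s in seqs:
        for i, c in enumerate(s[:max_len]):
            counts[i, order[c]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, np.nan)
    return pd.DataFrame(freqs, columns=["A", "C", "G", "U"],
                        index=pd.RangeIndex(1, max_len + 1, name="position"))


# ---------------------------------------------------------------------------
# compiled-table workflow (genome-wide list analysis)


def filter_compiled_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the inclusion filters to a compiled locus table.

    Keeps loci that pass the annotation criteria and do not produce a
    24-nt representative mature.
    """
    keep = table["passes_criteria"] & ~table["is_24nt"]
    return table.loc[keep].reset_index(drop=True)


def families_from_table(table: pd.DataFrame) -> list[MirnaFamily]:
    """Build family objects from a (filtered) compiled locus table."""
    fams = []
    for fam_id, group in table.groupby("family", sort=True):
        fams.append(
            MirnaFamily(
                family_id=str(fam_id),
                members=list(group["locus_id"]),
                mature_sequences=sorted(set(group["mature"])),
                conservation=group["conservation"].iloc[0],
            )
        )
    return fams


def summarize_compiled_table(table: pd.DataFrame) -> dict:
    """Counts, class statistics and the family-size Welch tests.

    The summary reproduces, on whatever table it is given, the
    genome-wide characterization: total genes and families after the
    inclusion filters, the per-class family counts and statistics, and
    the pairwise family-size t-tests between conservation classes.
    """
    included = filter_compiled_table(table)
    families = families_from_table(included)
    by_class = {
        k: [f for f in families if f.conservation == k]
        for k in ("conserved", "legume_specific", "soybean_specific")
    }
    stats_ = family_statistics(families)
    sizes = {k: [f.size for f in v] for k, v in by_class.items()}
    tests = {}
    for a, b in (("conserved", "legume_specific"),
                 ("conserved", "soybean_specific"),
                 ("legume_specific", "soybean_specific")):
        t, df, p = welch_t_test(sizes[a], sizes[b])
        tests[f"{a}_vs_{b}"] = {"t": t, "df": df, "p": p}
    return {
        "n_genes": int(len(included)),
        "n_families": len(families),
        "class_counts": {k: len(v) for k, v in by_class.items()},
        "class_stats": stats_,
        "family_size_tests": tests,
    }
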