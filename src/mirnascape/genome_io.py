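"""Readers and writers for the genomic formats the pipeline touches.

Coordinate convention: 1-based, inclusive on both ends (GFF3 convention)
everywhere inside the package.  The optional BED export converts to
0-based half-open on the way out.

Only a deliberately small slice of GFF3 is consumed: ``gene`` features
and their CDS / five_prime_UTR / three_prime_UTR / exon children.
Unknown feature types are ignored with a logged warning.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO

from .sequences import check_alphabet, normalize

log = logging.getLogger(__name__)

#: GFF3 child feature types mapped onto the internal subfeature kinds
_SUBFEATURE_KINDS = {
    "CDS": "CDS",
    "five_prime_UTR": "UTR5",
    "three_prime_UTR": "UTR3",
    "exon": "exon",
}


@dataclass
class GeneFeature:
    """A protein-coding gene with optional CDS/UTR/exon structure."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    subfeatures: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for kind, s, e in self.subfeatures:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(
                    f"gene {self.gene_id}: subfeature {kind} {s}-{e} outside gene span"
                )


@dataclass
class GenomeBundle:
    """Chromosome sequences plus protein-coding gene annotations."""

    chromosomes: dict[str, str]
    genes: list[GeneFeature]

    def __post_init__(self) -> None:
        for gene in self.genes:
            if gene.chrom not in self.chromosomes:
                raise ValueError(
                    f"gene {gene.gene_id} references unknown chromosome {gene.chrom!r}"
                )
            if gene.end > len(self.chromosomes[gene.chrom]):
                raise ValueError(
                    f"gene {gene.gene_id} extends past the end of {gene.chrom}"
                )

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence in 1-based inclusive coordinates."""
        return self.chromosomes[chrom][start - 1 : end]


@dataclass(frozen=True)
class ReadRecord:
    """A collapsed small-RNA read: unique sequence plus its count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"read {self.sequence}: count must be >= 1")
        check_alphabet(self.sequence)


@dataclass(frozen=True)
class CatalogEntry:
    """A reference mature miRNA with family/species labels (miRBase-like)."""

    mature_id: str
    sequence: str
    family: str
    species: str
    plant_family: str | None = None  # botanical family, e.g. "Fabaceae"

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError(f"catalog entry {self.mature_id}: empty family")
        check_alphabet(self.sequence)


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> name -> normalized sequence (duplicate names rejected)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record {rec.id!r} in {path}")
        out[rec.id] = normalize(str(rec.seq))
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def read_genome(fasta_path: str | Path, gff3_path: str | Path) -> GenomeBundle:
    """Load a genome FASTA plus gene GFF3 into a validated bundle."""
    chromosomes = {name: seq for name, seq in read_fasta(fasta_path).items()}
    for name, seq in chromosomes.items():
        check_alphabet(seq, allow_n=True)

    with tempfile.NamedTemporaryFile(suffix=".db", delete=True) as tmp:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=tmp.name,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes: list[GeneFeature] = []
        for feat in db.features_of_type("gene", order_by=("seqid", "start")):
            if feat.seqid not in chromosomes:
                raise ValueError(
                    f"GFF3 feature {feat.id!r} on unknown chromosome {feat.seqid!r}"
                )
            subs = []
            for child in db.children(feat, order_by="start"):
                kind = _SUBFEATURE_KINDS.get(child.featuretype)
                if kind is None:
                    log.warning(
                        "ignoring GFF3 feature type %r under gene %s",
                        child.featuretype,
                        feat.id,
                    )
                    continue
                subs.append((kind, child.start, child.end))
            genes.append(
                GeneFeature(
                    gene_id=feat.id,
                    chrom=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "+",
                    subfeatures=subs,
                )
            )
        unknown = {
            f.featuretype
            for f in db.all_features()
            if f.featuretype != "gene" and f.featuretype not in _SUBFEATURE_KINDS
        }
        for ftype in sorted(unknown):
            log.warning("ignoring GFF3 feature type %r", ftype)
    return GenomeBundle(chromosomes=chromosomes, genes=genes)


def _sorted_reads(records: dict[str, int]) -> list[ReadRecord]:
    # deterministic order: descending count, then lexicographic sequence
    return [
        ReadRecord(seq, n)
        for seq, n in sorted(records.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def read_reads(path: str | Path) -> list[ReadRecord]:
    """Read a collapsed small-RNA set (collapsed FASTA or 2-column TSV).

    Collapsed FASTA headers carry the count as ``>id_xCOUNT``.  Duplicate
    sequences are merged by summing counts; the returned order is
    deterministic (descending count, then lexicographic).
    """
    path = Path(path)
    merged: dict[str, int] = {}
    text = path.read_text()
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.id
            if "_x" not in header:
                raise ValueError(f"collapsed FASTA header without _xCOUNT: {header!r}")
            try:
                count = int(header.rsplit("_x", 1)[1])
            except ValueError as exc:
                raise ValueError(f"bad count in header {header!r}") from exc
            _merge_read(merged, normalize(str(rec.seq)), count, header)
    else:
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            seq, count_s = parts
            _merge_read(merged, normalize(seq), int(count_s), f"{path}:{lineno}")
    return _sorted_reads(merged)


def _merge_read(merged: dict[str, int], seq: str, count: int, where: str) -> None:
    if count <= 0:
        raise ValueError(f"{where}: read count must be positive, got {count}")
    check_alphabet(seq)
    merged[seq] = merged.get(seq, 0) + count


def read_catalog(path: str | Path) -> list[CatalogEntry]:
    """TSV catalog: mature_id, sequence, family, species[, plant_family]."""
    entries = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) not in (4, 5):
            raise ValueError(f"{path}:{lineno}: expected 4 or 5 columns")
        plant_family = parts[4] if len(parts) == 5 and parts[4] else None
        entries.append(
            CatalogEntry(parts[0], normalize(parts[1]), parts[2], parts[3], plant_family)
        )
    return entries


# ---------------------------------------------------------------------------
# writers


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_reads_tsv(reads: list[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in reads:
            fh.write(f"{rec.sequence}\t{rec.count}\n")


def write_gene_gff3(genes: list[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tmirnascape\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for kind, s, e in g.subfeatures:
                gff_type = {v: k for k, v in _SUBFEATURE_KINDS.items()}[kind]
                fh.write(
                    f"{g.chrom}\tmirnascape\t{gff_type}\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={g.gene_id}\n"
                )


def write_locus_report(loci, gff3_path: str | Path, tsv_path: str | Path) -> None:
    """Write annotated loci as GFF3 plus a TSV carrying every criteria flag.

    Only loci with verdict ``annotated`` are emitted to the GFF3
    (precursor rows typed ``miRNA_primary_transcript``, mature rows typed
    ``miRNA``); every locus, including rejected and 24-nt-excluded ones,
    appears in the TSV with its flags.
    """
    from .discovery import MirnaLocus  # local import to avoid a cycle

    flag_names = MirnaLocus.FLAG_NAMES
    with open(gff3_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for i, locus in enumerate(loci, 1):
            if locus.verdict != "annotated":
                continue
            lid = f"MIRLOCUS{i:04d}"
            gff.write(
                f"{locus.chrom}\tmirnascape\tmiRNA_primary_transcript\t"
                f"{locus.start}\t{locus.end}\t.\t{locus.strand}\t.\tID={lid}\n"
            )
            for j, (ms, me) in enumerate(locus.mature_spans(), 1):
                gff.write(
                    f"{locus.chrom}\tmirnascape\tmiRNA\t{ms}\t{me}\t.\t"
                    f"{locus.strand}\t.\tID={lid}.mature{j};Parent={lid}\n"
                )
    with open(tsv_path, "w") as tsv:
        header = [
            "chrom", "start", "end", "strand", "verdict",
            "representative_id1", "representative_id2",
            "duplex_reads", "stemloop_reads", "mature_reads",
        ] + list(flag_names)
        tsv.write("\t".join(header) + "\n")
        for locus in loci:
            row = [
                locus.chrom, str(locus.start), str(locus.end), locus.strand,
                locus.verdict,
                locus.representative_id1 or ".",
                locus.representative_id2 or ".",
                str(locus.read_support[0]), str(locus.read_support[1]),
                str(locus.read_support[2]),
            ] + [str(int(locus.criteria_flags.get(f, False))) for f in flag_names]
            tsv.write("\t".join(row) + "\n")


def write_bed(intervals: list[tuple[str, int, int, str, str]], path: str | Path) -> None:
    """Optional BED export; converts 1-based inclusive to 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, start, end, name, strand in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t0\t{strand}\n")
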