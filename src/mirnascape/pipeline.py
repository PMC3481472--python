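"""End-to-end orchestration: simulate -> discover -> characterize -> targets
-> phasing -> expression, with a manifest of every threshold used.

Identical (config, inputs, seed) produce byte-identical outputs; the
manifest records the full configuration plus SHA-256 digests of the
inputs so a run can be reproduced flag-free.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .discovery import DiscoveryParams, discover
from .expression import ExpressionMatrix, inverse_pairs, relative_expression
from .families import (classify_context, cluster_families, classify_conservation,
                       detect_clusters, family_statistics)
from .genome_io import (read_catalog, read_fasta, read_genome, read_reads,
                        write_fasta, write_gene_gff3, write_locus_report,
                        write_reads_tsv)
from .phasing import DEFAULT_WINDOW, screen_two_hit_loci
from .synthetic import (SimulationSpec, generate_expression_table,
                        generate_genome, generate_targets_and_phasing,
                        miniature_catalog, simulate_reads)
from .targets import SCORE_MIN, detect_dual_targeting, scan_transcript


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, with study defaults."""

    seed: int = 1
    max_hits: int = 35
    min_abundance: int = 10
    min_duplex_frac: float = 0.25
    duplex_read_tolerance: int = 0
    family_dist: int = 2
    catalog_dist: int = 4
    proximal_bp: int = 1000
    cluster_bp: int = 5000
    score_min: float = SCORE_MIN
    wobble_as_match: bool = False
    phase_window: int = DEFAULT_WINDOW
    fold_backend: str = "pairmax"

    def discovery_params(self) -> DiscoveryParams:
        return DiscoveryParams(
            max_hits=self.max_hits, min_abundance=self.min_abundance,
            min_duplex_frac=self.min_duplex_frac,
            duplex_read_tolerance=self.duplex_read_tolerance,
            fold_backend=self.fold_backend,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.where(pd.notna(obj), None).to_dict(orient="index"))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_inputs(spec: SimulationSpec, outdir: str | Path) -> Path:
    """Write a complete synthetic input bundle (CLI `simulate`)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = generate_genome(spec)
    reads = simulate_reads(spec, truth, genome)
    transcripts, transcript_reads = generate_targets_and_phasing(spec, truth)
    mirna_ct, target_ct, pairs = generate_expression_table(spec.seed)

    write_fasta(genome.chromosomes, outdir / "genome.fa")
    write_gene_gff3(genome.genes, outdir / "genes.gff3")
    write_reads_tsv(reads, outdir / "reads.tsv")
    write_fasta(transcripts, outdir / "transcripts.fa")
    write_reads_tsv(transcript_reads, outdir / "transcript_reads.tsv")
    mirna_ct.to_csv(outdir / "ct_mirna.tsv", sep="\t")
    target_ct.to_csv(outdir / "ct_targets.tsv", sep="\t")
    (outdir / "pairs.tsv").write_text(
        "".join(f"{m}\t{t}\n" for m, t in pairs)
    )
    with open(outdir / "catalog.tsv", "w") as fh:
        for e in miniature_catalog():
            fh.write(f"{e.mature_id}\t{e.sequence}\t{e.family}\t{e.species}\t"
                     f"{e.plant_family}\n")
    (outdir / "truth.json").write_text(
        json.dumps(_jsonable(dataclasses.asdict(truth)), indent=1, sort_keys=True)
    )
    return outdir


def run_all(config: RunConfig, outdir: str | Path,
            input_dir: str | Path | None = None) -> Path:
    """Run every stage; returns the output directory.

    Without ``input_dir`` a synthetic bundle is simulated first (seeded
    from the config).  Stage failures abort with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if input_dir is None:
        input_dir = simulate_inputs(SimulationSpec(seed=config.seed),
                                    outdir / "inputs")
    input_dir = Path(input_dir)

    required = ["genome.fa", "genes.gff3", "reads.tsv", "transcripts.fa",
                "transcript_reads.tsv", "ct_mirna.tsv", "ct_targets.tsv",
                "pairs.tsv", "catalog.tsv"]
    for name in required:
        if not (input_dir / name).exists():
            raise FileNotFoundError(f"stage inputs: missing {input_dir / name}")

    stage = "discover"
    try:
        genome = read_genome(input_dir / "genome.fa", input_dir / "genes.gff3")
        reads = read_reads(input_dir / "reads.tsv")
        catalog = read_catalog(input_dir / "catalog.tsv")
        loci = discover(reads, genome, catalog, config.discovery_params())
        write_locus_report(loci, outdir / "loci.gff3", outdir / "loci.tsv")

        stage = "characterize"
        annotated = [l for l in loci if l.verdict == "annotated"]
        matures = {f"locus{i:03d}": l.representative_id1
                   for i, l in enumerate(annotated)}
        families = cluster_families(matures, catalog)
        for fam in families:
            fam.conservation = classify_conservation(fam, catalog)
        locus_by_id = dict(zip(matures, annotated))
        contexts = [
            classify_context(lid, (locus_by_id[lid].start, locus_by_id[lid].end),
                             locus_by_id[lid].chrom, genome.genes)
            for lid in matures
        ]
        clusters = detect_clusters(
            [(lid, locus_by_id[lid].chrom, locus_by_id[lid].start,
              locus_by_id[lid].end, locus_by_id[lid].strand) for lid in matures],
            genome.genes,
        )
        _write_characterization(outdir, families, contexts, clusters)

        stage = "targets"
        transcripts = read_fasta(input_dir / "transcripts.fa")
        sites = []
        for lid, mature in sorted(matures.items()):
            if not 19 <= len(mature) <= 24:
                continue
            for tid, tseq in sorted(transcripts.items()):
                sites.extend(
                    scan_transcript(mature, tseq, tid, family=lid,
                                    wobble_as_match=config.wobble_as_match,
                                    min_score=config.score_min)
                )
        pairs_dual = detect_dual_targeting(sites)
        _write_targets(outdir, sites, pairs_dual)

        stage = "phasing"
        transcript_reads = read_reads(input_dir / "transcript_reads.tsv")
        profiles = screen_two_hit_loci(
            [s for s in sites if s.passes], transcripts, transcript_reads,
            window=config.phase_window,
        )
        _write_phasing(outdir, profiles)

        stage = "expression"
        mirna_ct = pd.read_csv(input_dir / "ct_mirna.tsv", sep="\t", index_col=0)
        target_ct = pd.read_csv(input_dir / "ct_targets.tsv", sep="\t", index_col=0)
        pair_rows = [
            tuple(line.split("\t"))
            for line in (input_dir / "pairs.tsv").read_text().splitlines()
            if line.strip()
        ]
        m_rel = relative_expression(ExpressionMatrix(mirna_ct, "ct", "miR1515"))
        t_rel = relative_expression(ExpressionMatrix(target_ct, "ct", "Actin"))
        calls = inverse_pairs(m_rel, t_rel, pair_rows)
        _write_expression(outdir, m_rel, t_rel, calls)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "version": __version__,
        "inputs": {name: _digest(input_dir / name) for name in required},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return outdir


def _write_characterization(outdir: Path, families, contexts, clusters) -> None:
    with open(outdir / "families.tsv", "w") as fh:
        fh.write("family_id\tconservation\tsize\tn_unique_matures\tmembers\n")
        for f in families:
            fh.write(f"{f.family_id}\t{f.conservation}\t{f.size}\t"
                     f"{len(f.mature_sequences)}\t{','.join(f.members)}\n")
    with open(outdir / "contexts.tsv", "w") as fh:
        fh.write("locus_id\tcontext\tnearest_gene\tdistance\tside\n")
        for c in contexts:
            fh.write(f"{c.locus_id}\t{c.context}\t{c.nearest_gene or '.'}\t"
                     f"{c.distance}\t{c.side or '.'}\n")
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tarrangement\tmembers\n")
        for cl in clusters:
            fh.write(f"{cl.chrom}\t{cl.span[0]}\t{cl.span[1]}\t"
                     f"{cl.arrangement}\t{','.join(cl.members)}\n")
    stats = family_statistics(families)
    (outdir / "stats.json").write_text(
        json.dumps(_jsonable(stats), indent=1, sort_keys=True)
    )


def _write_targets(outdir: Path, sites, pairs_dual) -> None:
    with open(outdir / "targets.tsv", "w") as fh:
        fh.write("family\ttranscript\tstart\tend\tmm_2_9\tmm_10_11\tmm_after_12\t"
                 "max_consec\tduplex_energy\tperfect_energy\tscore\tcleavage\tpasses\n")
        for s in sites:
            fh.write(f"{s.family}\t{s.transcript_id}\t{s.site_span[0]}\t"
                     f"{s.site_span[1]}\t{s.mm_2_9}\t{s.mm_10_11}\t{s.mm_after_12}\t"
                     f"{s.max_consecutive_after_12}\t{s.duplex_energy:.2f}\t"
                     f"{s.perfect_energy:.2f}\t{s.score:.2f}\t{s.cleavage_pos}\t"
                     f"{int(s.passes)}\n")
    with open(outdir / "pairs.tsv", "w") as fh:
        fh.write("transcript\tfamily_a\tsite_a\tfamily_b\tsite_b\tseparation\n")
        for p in pairs_dual:
            fh.write(f"{p.transcript_id}\t{p.family_a}\t{p.site_a[0]}-{p.site_a[1]}\t"
                     f"{p.family_b}\t{p.site_b[0]}-{p.site_b[1]}\t{p.separation}\n")


def _write_phasing(outdir: Path, profiles) -> None:
    with open(outdir / "phasing.tsv", "w") as fh:
        fh.write("transcript\tcleavage\ttotal\tphased_fraction\tmedian_other\t"
                 "verdict\tregisters\n")
        for p in profiles:
            regs = ",".join(map(str, p.register_abundance.tolist()))
            fh.write(f"{p.transcript_id}\t{p.cleavage_pos}\t{p.total}\t"
                     f"{p.phased_fraction:.4f}\t{p.median_other:.1f}\t"
                     f"{int(p.verdict)}\t{regs}\n")


def _write_expression(outdir: Path, m_rel, t_rel, calls) -> None:
    m_rel.values.to_csv(outdir / "levels_mirna.tsv", sep="\t",
                        float_format="%.6g")
    t_rel.values.to_csv(outdir / "levels_targets.tsv", sep="\t",
                        float_format="%.6g")
    with open(outdir / "inverse_pairs.tsv", "w") as fh:
        fh.write("mirna\ttarget\tinverse\tevidence_organs\tspearman_rho\n")
        for c in calls:
            fh.write(f"{c.mirna}\t{c.target}\t{int(c.inverse)}\t"
                     f"{','.join(c.evidence_organs) or '.'}\t{c.spearman_rho:.3f}\n")
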