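"""Discover miRNA loci in a synthetic genome with planted hairpins.

Builds the default study bundle (10 inverted-repeat MIR loci, repeat
decoys copied to 40 genomic positions, background reads), runs the full
discovery stage and compares the annotated loci with the planted truth.
"""

from mirnascape import (SimulationSpec, discover, generate_genome,
                        miniature_catalog, simulate_reads)

spec = SimulationSpec(seed=1)
genome, truth = generate_genome(spec)
reads = simulate_reads(spec, truth, genome)
print(f"simulated {len(reads)} unique reads "
      f"({sum(r.count for r in reads)} total) over {len(truth.loci)} planted loci")

loci = discover(reads, genome, miniature_catalog())
annotated = [l for l in loci if l.verdict == "annotated"]
print(f"annotated {len(annotated)} loci out of {len(loci)} candidate regions\n")
for locus in annotated:
    d = locus.duplex
    print(f"  {locus.chrom}:{locus.start}-{locus.end}({locus.strand}) "
          f"mature={locus.mature_genomic} star={locus.star_genomic} "
          f"mismatches={d.n_mismatches} overhangs={d.overhang_3p_mature}/"
          f"{d.overhang_3p_star} support={locus.read_support}")

planted = {tuple(l.mature) for l in truth.loci}
recovered = {l.mature_genomic for l in annotated} & planted
print(f"\nrecovered {len(recovered)}/{len(planted)} planted mature positions "
      f"exactly; a 2/2 overhang pair and 0 mismatches reflect the precise "
      f"excision geometry the annotation criteria require.")
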