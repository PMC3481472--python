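"""Detect tasiRNA-style phased reads downstream of a cleavage site.

Generates a transcript whose reads sit in perfect 21-nt register with
the predicted miRNA cleavage position, plus an unphased control, and
applies the register-decomposition statistic to both.
"""

from mirnascape import (SimulationSpec, generate_genome,
                        generate_targets_and_phasing)
from mirnascape.phasing import map_reads_to_transcript, phase_profile

spec = SimulationSpec(seed=1)
_genome, truth = generate_genome(spec)
transcripts, reads = generate_targets_and_phasing(spec, truth)

for planted in truth.phased:
    placements = map_reads_to_transcript(reads, transcripts[planted.transcript_id])
    prof = phase_profile(placements, planted.cleavage_pos,
                         transcript_id=planted.transcript_id)
    regs = ",".join(map(str, prof.register_abundance.tolist()))
    print(f"{planted.transcript_id}: cleavage at {planted.cleavage_pos}, "
          f"{prof.total} windowed reads")
    print(f"  registers [{regs}]")
    print(f"  in-phase fraction {prof.phased_fraction:.3f}, median of other "
          f"registers {prof.median_other:.1f} -> "
          f"{'PHASED' if prof.verdict else 'not phased'}\n")

print("A phased locus concentrates reads in register 0 (the cleavage "
      "frame); the evenly covered control never beats the median of the "
      "other 20 registers.")
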