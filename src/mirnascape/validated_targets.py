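"""Bundled reference set of validated soybean miRNA:target duplexes.

Six target sites whose miRNA-guided cleavage was confirmed by modified
5'RACE in soybean: four NF-Y-alpha transcription-factor transcripts
targeted by the miR169c/g family and two TIR-NBS-LRR disease-resistance
transcripts targeted by miR2118/2218a.  The miR169c and miR169g matures
differ only at their 3'-terminal base (A/G); the A variant is bundled,
as it Watson-Crick-pairs its printed sites where G would wobble.

The set serves as a fixed positive control: every duplex satisfies the
positional target rules and reaches the 70% MFE-ratio threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequences import normalize


@dataclass(frozen=True)
class ValidatedDuplex:
    mirna_name: str
    mirna: str  # mature, 5'->3'
    target_gene: str
    target_annotation: str
    site: str  # target site on the transcript, 5'->3'


_MIR169 = "AAGCCAAGGAUGACUUGCCGA"  # miR169c/g, 3'-terminal A variant
_MIR2118 = "UUGCCGAUUCCACCCAUUCCUA"  # miR2118/2218a

VALIDATED_DUPLEXES: tuple[ValidatedDuplex, ...] = tuple(
    ValidatedDuplex(name, normalize(mir), gene, note, normalize(site))
    for name, mir, gene, note, site in [
        ("miR169c/g", _MIR169, "Glyma10g10240",
         "transcription factor NF-Y alpha-related", "UAGGCAACUCAUCCUUGGCUC"),
        ("miR169c/g", _MIR169, "Glyma15g18970",
         "transcription factor NF-Y alpha-related", "CAGGCAAAUCAUCCUUGGCUU"),
        ("miR169c/g", _MIR169, "Glyma17g05920",
         "transcription factor NF-Y alpha-related", "CUGGCAAAUCAUCCUUGGCUU"),
        ("miR169c/g", _MIR169, "Glyma19g38800",
         "transcription factor NF-Y alpha-related", "UAGGCAAUCCAUCCUUGGCUC"),
        ("miR2118/2218a", _MIR2118, "Glyma12g03040",
         "LRR; TIR domain; NB-ARC domain", "AUGGAACCGGUGGAAUUGGCAA"),
        ("miR2118/2218a", _MIR2118, "Glyma20g06780",
         "LRR; TIR domain; NB-ARC domain", "AUGGAACUGGUGGAAUUGGCAA"),
    ]
)
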