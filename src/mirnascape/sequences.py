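"""Small sequence utilities shared across the package.

The internal alphabet is DNA (A/C/G/T, plus N in genomic sequence); RNA
input (U) is normalized on the way in and re-exposed as RNA only in
reports and duplex displays.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_READ_ALPHABET = set("ACGT")


def normalize(seq: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet (T)."""
    return seq.strip().upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render an internal DNA-alphabet sequence as RNA for display."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def check_alphabet(seq: str, allow_n: bool = False) -> None:
    allowed = VALID_READ_ALPHABET | ({"N"} if allow_n else set())
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
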