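"""miRNA target prediction with positional mismatch rules and MFE-ratio scoring.

A site passes when the ungapped miRNA:mRNA alignment obeys the
plant-target criteria - at most 1 mismatch between miRNA positions 2
and 9, none at positions 10-11, at most 4 after position 12 with no
more than 2 consecutive - and its duplex free energy reaches at least
70% of the energy of a perfect complement (the target prediction
score).  G:U wobbles count as mismatches for the positional rules
(matching the convention that wobbles are shown unpaired in duplex
displays) but still stack, weakly, in the energy model; a
``wobble_as_match`` switch flips the positional convention.

The bundled energy model is a fixed nearest-neighbor table with
standard Watson-Crick RNA stack free energies (kcal/mol at 37 C), a
flat stack term for steps involving a G:U pair, and a small positive
penalty for each helix interruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequences import normalize, revcomp, to_rna

SCORE_MIN = 0.70

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U in the internal DNA alphabet

#: Watson-Crick nearest-neighbor stacks, key = 5'XY3' on one strand
#: (the paired strand is implied), kcal/mol
_WC_STACKS = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}


@dataclass
class EnergyModel:
    """Stack-sum duplex energy model shared by duplex and perfect scoring."""

    wc_stacks: dict[str, float] = field(default_factory=lambda: dict(_WC_STACKS))
    wobble_stack: float = -1.0  # any stack step involving a G:U pair
    interruption_penalty: float = 0.5  # per mismatch/bulge region breaking a helix

    def stack(self, x: str, y: str, x_wobble: bool, y_wobble: bool) -> float:
        """Energy of the dinucleotide step 5'-xy-3' (miRNA strand)."""
        if x_wobble or y_wobble:
            return self.wobble_stack
        return self.wc_stacks[to_rna(x + y)]


DEFAULT_MODEL = EnergyModel()


@dataclass
class TargetSite:
    """An ungapped miRNA:mRNA alignment with rule counters and score."""

    transcript_id: str
    site_span: tuple[int, int]  # 1-based on the transcript
    mirna: str  # mature, internal DNA alphabet, 5'->3'
    site_sequence: str
    alignment: list[str]  # per miRNA position: match | wobble | mismatch
    mm_2_9: int
    mm_10_11: int
    mm_after_12: int
    max_consecutive_after_12: int
    duplex_energy: float
    perfect_energy: float
    score: float
    cleavage_pos: int
    passes: bool
    family: str | None = None


@dataclass(frozen=True)
class DualTargetPair:
    transcript_id: str
    family_a: str
    site_a: tuple[int, int]
    family_b: str
    site_b: tuple[int, int]
    separation: int


def _alignment_states(mirna: str, site: str, wobble_as_match: bool = False
                      ) -> list[str]:
    """Pair state per miRNA position (1 = miRNA 5' end).

    miRNA position i faces the site base at index L - i (0-based), i.e.
    position 1 always pairs the site's 3'-most base.
    """
    L = len(mirna)
    states = []
    for i in range(1, L + 1):
        m = mirna[i - 1]
        t = site[L - i]
        if _WC[m] == t:
            states.append("match")
        elif (m, t) in _WOBBLE:
            states.append("wobble" if not wobble_as_match else "match")
        else:
            states.append("mismatch")
    return states


def _rule_counters(states: list[str]) -> tuple[int, int, int, int]:
    """Positional mismatch counters; wobble counts as mismatch."""
    is_mm = [s != "match" for s in states]
    mm_2_9 = sum(is_mm[1:9])
    mm_10_11 = sum(is_mm[9:11])
    after = is_mm[12:]
    mm_after_12 = sum(after)
    run = best = 0
    for m in after:
        run = run + 1 if m else 0
        best = max(best, run)
    return mm_2_9, mm_10_11, mm_after_12, best


def duplex_energy(mirna: str, states: list[str],
                  model: EnergyModel = DEFAULT_MODEL) -> float:
    """Stack-sum energy of an aligned duplex.

    Consecutive paired positions (match or wobble) stack; every
    mismatch/bulge region interrupting the helix adds the model's
    penalty.  Terminal unpaired positions do not stack and carry no
    penalty.
    """
    energy = 0.0
    paired = [s in ("match", "wobble") for s in states]
    for i in range(len(states) - 1):
        if paired[i] and paired[i + 1]:
            energy += model.stack(
                mirna[i], mirna[i + 1],
                states[i] == "wobble", states[i + 1] == "wobble",
            )
    # interruption penalty per internal unpaired region
    first = next((i for i, p in enumerate(paired) if p), None)
    last = next((i for i in range(len(paired) - 1, -1, -1) if paired[i]), None)
    if first is not None:
        in_gap = False
        for i in range(first, last + 1):
            if not paired[i] and not in_gap:
                energy += model.interruption_penalty
                in_gap = True
            elif paired[i]:
                in_gap = False
    return energy


def perfect_energy(mirna: str, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Energy of the miRNA bound to its exact Watson-Crick complement."""
    return duplex_energy(mirna, ["match"] * len(mirna), model)


def score_alignment(mirna: str, states: list[str],
                    model: EnergyModel = DEFAULT_MODEL) -> tuple[float, float, float]:
    """(duplex energy, perfect energy, MFE-ratio score)."""
    e_duplex = duplex_energy(mirna, states, model)
    e_perfect = perfect_energy(mirna, model)
    score = e_duplex / e_perfect if e_perfect != 0 else 0.0
    return e_duplex, e_perfect, score


def predict_cleavage(site_span: tuple[int, int]) -> int:
    """Transcript coordinate of the first nucleotide of the 3' fragment.

    Cleavage occurs opposite the bond between miRNA positions 10 and
    11; with miRNA position 1 pairing the site's 3'-most base, position
    10 faces transcript coordinate site_end - 9, which is the first
    base 3' of the scissile bond.
    """
    return site_span[1] - 9


def scan_transcript(mirna: str, transcript: str, transcript_id: str = "t",
                    model: EnergyModel = DEFAULT_MODEL,
                    wobble_as_match: bool = False,
                    family: str | None = None,
                    min_score: float = SCORE_MIN) -> list[TargetSite]:
    """Slide the mature over the transcript and emit rule-passing sites.

    Sites satisfying the four positional rules are emitted with their
    energies and score; ``passes`` additionally requires score >=
    ``min_score``.
    """
    mirna = normalize(mirna)
    transcript = normalize(transcript)
    L = len(mirna)
    if not 19 <= L <= 24:
        raise ValueError(f"mature length must be 19-24 nt, got {L}")
    if len(transcript) < L:
        raise ValueError("transcript shorter than the mature sequence")
    sites = []
    for off in range(len(transcript) - L + 1):
        site_seq = transcript[off: off + L]
        states = _alignment_states(mirna, site_seq, wobble_as_match)
        mm29, mm1011, mm12, consec = _rule_counters(states)
        if mm29 > 1 or mm1011 > 0 or mm12 > 4 or consec > 2:
            continue
        e_d, e_p, score = score_alignment(mirna, states, model)
        span = (off + 1, off + L)
        sites.append(
            TargetSite(
                transcript_id=transcript_id, site_span=span, mirna=mirna,
                site_sequence=site_seq, alignment=states,
                mm_2_9=mm29, mm_10_11=mm1011, mm_after_12=mm12,
                max_consecutive_after_12=consec,
                duplex_energy=e_d, perfect_energy=e_p, score=score,
                cleavage_pos=predict_cleavage(span),
                passes=score >= min_score,
                family=family,
            )
        )
    return sites


def detect_dual_targeting(sites: list[TargetSite]) -> list[DualTargetPair]:
    """Cross-family non-overlapping site pairs on the same transcript.

    Separation is measured between site starts; pairs are sorted by
    transcript id then separation.
    """
    by_transcript: dict[str, list[TargetSite]] = {}
    for s in sites:
        if s.passes:
            by_transcript.setdefault(s.transcript_id, []).append(s)
    pairs = []
    for tid in sorted(by_transcript):
        ss = sorted(by_transcript[tid], key=lambda s: s.site_span)
        for i, a in enumerate(ss):
            for b in ss[i + 1:]:
                if (a.family or "") == (b.family or ""):
                    continue
                if a.site_span[1] >= b.site_span[0]:  # overlapping
                    continue
                pairs.append(
                    DualTargetPair(
                        transcript_id=tid,
                        family_a=a.family or "?", site_a=a.site_span,
                        family_b=b.family or "?", site_b=b.site_span,
                        separation=b.site_span[0] - a.site_span[0],
                    )
                )
    pairs.sort(key=lambda p: (p.transcript_id, p.separation))
    return pairs


def render_duplex(site: TargetSite) -> str:
    """Three-line duplex display: target 5'->3', pipes, miRNA 3'->5'.

    Wobbles are left unpiped, matching the customary display.
    """
    target = to_rna(site.site_sequence)
    mirna_3to5 = to_rna(site.mirna[::-1])
    pipes = "".join(
        "|" if site.alignment[len(site.mirna) - 1 - i] == "match" else " "
        for i in range(len(site.mirna))
    )
    return (f"5' {target} 3'\n   {pipes}\n3' {mirna_3to5} 5'")
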