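"""RNA secondary-structure prediction for candidate precursors.

The default backend is a weighted base-pair-maximization dynamic program
(Nussinov-style): each admissible pair contributes a composition weight
(G:C = 3, A:U = 2, G:U = 1), loops must span at least ``MIN_LOOP``
unpaired bases, and structures are nested (no pseudoknots).  The
traceback is deterministic: at every subproblem the 5'-most base is
paired with the smallest admissible partner that achieves the optimum,
otherwise left unpaired, so identical sequences always yield identical
structures.

Any callable returning a valid pair set may substitute as backend; a
thermodynamic backend using the ViennaRNA bindings (if importable) is
provided for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .sequences import check_alphabet, normalize

MIN_LOOP = 3
MIN_FOLD_LEN = 40
MAX_FOLD_LEN = 400

#: pair weights by base index (A=0, C=1, G=2, T/U=3); 0 = not pairable
_PAIR_WEIGHT = np.zeros((4, 4), dtype=np.int64)
for a, b, w in [(0, 3, 2), (3, 0, 2), (1, 2, 3), (2, 1, 3), (2, 3, 1), (3, 2, 1)]:
    _PAIR_WEIGHT[a, b] = w

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SecondaryStructure:
    """A nested pair set over a sequence, with the backend's score."""

    sequence: str  # internal DNA alphabet
    pairs: set[tuple[int, int]]  # 1-based (i, j), i < j
    score: float

    partner_map: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: dict[int, int] = {}
        for i, j in self.pairs:
            if not (1 <= i < j <= len(self.sequence)):
                raise ValueError(f"pair ({i},{j}) out of bounds")
            if j - i <= MIN_LOOP:
                raise ValueError(f"pair ({i},{j}) closes a loop shorter than {MIN_LOOP}")
            for p in (i, j):
                if p in seen:
                    raise ValueError(f"position {p} paired twice")
                seen[p] = 0
        sorted_pairs = sorted(self.pairs)
        for (i1, j1), (i2, j2) in zip(sorted_pairs, sorted_pairs[1:]):
            if i1 < i2 <= j1 < j2:  # crossing
                raise ValueError(f"pseudoknot: ({i1},{j1}) crosses ({i2},{j2})")
        self.partner_map = {}
        for i, j in self.pairs:
            self.partner_map[i] = j
            self.partner_map[j] = i

    def partner(self, i: int) -> int | None:
        return self.partner_map.get(i)


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)


@njit(cache=True)
def _fill_dp(idx, weight, min_loop):  # pragma: no cover - compiled
    n = idx.shape[0]
    M = np.zeros((n + 1, n + 1), dtype=np.int64)  # M[i,j], 0-based i..j inclusive
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                w = weight[idx[i], idx[k]]
                if w > 0:
                    inner = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    outer = M[k + 1, j] if k + 1 <= j else 0
                    cand = w + inner + outer
                    if cand > best:
                        best = cand
            M[i, j] = best
    return M


def _traceback(idx, weight, M, min_loop):
    pairs: set[tuple[int, int]] = set()
    stack = [(0, idx.shape[0] - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        target = M[i, j]
        if target == 0:
            continue
        # prefer pairing the 5'-most base with its smallest optimal partner
        chosen = None
        for k in range(i + min_loop + 1, j + 1):
            w = weight[idx[i], idx[k]]
            if w > 0:
                inner = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                outer = M[k + 1, j] if k + 1 <= j else 0
                if w + inner + outer == target:
                    chosen = k
                    break
        if chosen is None:
            stack.append((i + 1, j))
        else:
            pairs.add((i + 1, chosen + 1))  # to 1-based
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
    return pairs


def fold(sequence: str) -> SecondaryStructure:
    """Fold with the default weighted pair-maximization backend."""
    seq = normalize(sequence)
    if not (MIN_FOLD_LEN <= len(seq) <= MAX_FOLD_LEN):
        raise ValueError(
            f"fold expects {MIN_FOLD_LEN}-{MAX_FOLD_LEN} nt, got {len(seq)}"
        )
    check_alphabet(seq)
    idx = _encode(seq)
    M = _fill_dp(idx, _PAIR_WEIGHT, MIN_LOOP)
    pairs = _traceback(idx, _PAIR_WEIGHT, M, MIN_LOOP)
    return SecondaryStructure(sequence=seq, pairs=pairs, score=float(M[0, idx.shape[0] - 1]))


def brute_force_score(sequence: str) -> int:
    """Exhaustive optimum over all nested structures (oracle, length <= ~22)."""
    seq = normalize(sequence)
    idx = _encode(seq)
    n = len(seq)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= MIN_LOOP:
            return 0
        out = best(i + 1, j)
        for k in range(i + MIN_LOOP + 1, j + 1):
            w = int(_PAIR_WEIGHT[idx[i], idx[k]])
            if w > 0:
                out = max(out, w + best(i + 1, k - 1) + best(k + 1, j))
        return out

    return best(0, n - 1)


def fold_vienna(sequence: str) -> SecondaryStructure:
    """Thermodynamic MFE fold through the ViennaRNA bindings (optional)."""
    import RNA  # deferred: optional backend

    seq = normalize(sequence)
    if not (MIN_FOLD_LEN <= len(seq) <= MAX_FOLD_LEN):
        raise ValueError(
            f"fold expects {MIN_FOLD_LEN}-{MAX_FOLD_LEN} nt, got {len(seq)}"
        )
    db, mfe = RNA.fold(seq.replace("T", "U"))
    pairs = set()
    stack = []
    for pos, ch in enumerate(db, 1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            pairs.add((stack.pop(), pos))
    return SecondaryStructure(sequence=seq, pairs=pairs, score=float(mfe))


BACKENDS = {"pairmax": fold, "vienna": fold_vienna}
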