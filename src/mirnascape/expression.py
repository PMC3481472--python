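"""Organ-level expression: ddCt-style normalization and inverse-pattern detection.

miRNA Ct values are normalized to the uniformly expressed miR1515 and
target Ct values to Actin, using the standard 2^(Ct_ref - Ct_entity)
transform (amplification efficiency assumed 2.0 per cycle).  An organ
counts as high/low for an entity when its relative level is at least
two-fold above/below the entity's median over organs, and a
miRNA-target pair is called inverse when there is at least one organ
with miRNA high & target low and at least one with the reverse; a
Spearman rank correlation across organs is reported alongside but
never gates the call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ORGANS = ["R", "N", "S", "L", "F", "P"]
FOLD = 2.0


@dataclass
class ExpressionMatrix:
    """Entities x organs, either raw Ct or reference-normalized levels."""

    values: pd.DataFrame  # index = entity ids, columns = organs
    mode: str  # "ct" | "relative"
    reference: str  # reference entity id (miR1515 / Actin)

    def __post_init__(self) -> None:
        if self.mode not in ("ct", "relative"):
            raise ValueError(f"bad mode {self.mode!r}")
        if self.mode == "ct" and self.reference not in self.values.index:
            raise ValueError(f"reference {self.reference!r} missing from Ct table")


def relative_expression(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """2^(Ct_ref - Ct_entity) per organ; the reference maps to 1 everywhere."""
    if matrix.mode != "ct":
        raise ValueError("relative_expression expects a Ct-mode matrix")
    ref = matrix.values.loc[matrix.reference]
    if ref.isna().any():
        missing = list(ref.index[ref.isna()])
        raise ValueError(f"reference {matrix.reference!r} lacks Ct in organs {missing}")
    levels = np.power(2.0, ref.values[None, :] - matrix.values.values)
    out = pd.DataFrame(levels, index=matrix.values.index,
                       columns=matrix.values.columns)
    return ExpressionMatrix(out, "relative", matrix.reference)


def variation_flags(matrix: ExpressionMatrix, fold: float = FOLD) -> pd.DataFrame:
    """Per entity and organ: 'high', 'low' or '' by the two-fold rule.

    An organ is high when its level is at least ``fold`` times the
    entity's median over organs (inclusive), low when at most 1/fold of
    it.
    """
    if matrix.mode != "relative":
        raise ValueError("variation_flags expects a relative-mode matrix")
    med = matrix.values.median(axis=1)
    high = matrix.values.ge(fold * med, axis=0)
    low = matrix.values.le(med / fold, axis=0)
    flags = pd.DataFrame("", index=matrix.values.index,
                         columns=matrix.values.columns)
    flags = flags.mask(high, "high").mask(low, "low")
    return flags


@dataclass
class InverseCall:
    mirna: str
    target: str
    inverse: bool
    evidence_organs: list[str]  # organs supporting either direction
    spearman_rho: float


def inverse_pairs(mirna_matrix: ExpressionMatrix,
                  target_matrix: ExpressionMatrix,
                  pairs: list[tuple[str, str]]) -> list[InverseCall]:
    """Flag miRNA-target pairs with bidirectional inverse organ patterns."""
    for m in (mirna_matrix, target_matrix):
        if m.mode != "relative":
            raise ValueError("inverse_pairs expects relative-mode matrices")
    organs = [o for o in mirna_matrix.values.columns
              if o in target_matrix.values.columns]
    if not organs:
        raise ValueError("no shared organs between the matrices")
    mflags = variation_flags(mirna_matrix)[organs]
    tflags = variation_flags(target_matrix)[organs]
    calls = []
    for mirna, target in pairs:
        fwd = [o for o in organs
               if mflags.loc[mirna, o] == "high" and tflags.loc[target, o] == "low"]
        rev = [o for o in organs
               if mflags.loc[mirna, o] == "low" and tflags.loc[target, o] == "high"]
        mvals = mirna_matrix.values.loc[mirna, organs]
        tvals = target_matrix.values.loc[target, organs]
        if mvals.nunique() < 2 or tvals.nunique() < 2:
            rho = float("nan")  # rank correlation undefined on flat profiles
        else:
            rho = stats.spearmanr(mvals, tvals).statistic
        calls.append(
            InverseCall(
                mirna=mirna, target=target,
                inverse=bool(fwd and rev),
                evidence_organs=sorted(set(fwd + rev), key=organs.index),
                spearman_rho=float(rho),
            )
        )
    return calls
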