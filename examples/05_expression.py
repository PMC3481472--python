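"""Inverse miRNA-target expression across soybean organs.

Normalizes a synthetic Ct table to the uniformly expressed references
(miR1515 for miRNAs, Actin for targets), applies the two-fold rule per
organ, and flags miRNA-target pairs with bidirectional inverse
patterns (the signature of spatial restriction of a target by its
miRNA, e.g. between root and nodule).
"""

from mirnascape import (ExpressionMatrix, generate_expression_table,
                        inverse_pairs, relative_expression, variation_flags)

mirna_ct, target_ct, pairs = generate_expression_table(seed=1)
m_rel = relative_expression(ExpressionMatrix(mirna_ct, "ct", "miR1515"))
t_rel = relative_expression(ExpressionMatrix(target_ct, "ct", "Actin"))

print("relative miRNA levels (2^(Ct_ref - Ct)), organs R N S L F P:")
print(m_rel.values.round(2).to_string())
print("\ntwo-fold variation flags:")
print(variation_flags(m_rel).to_string())

print("\nmiRNA-target pair calls:")
for call in inverse_pairs(m_rel, t_rel, pairs):
    status = "INVERSE" if call.inverse else "not inverse"
    print(f"  {call.mirna} vs {call.target}: {status} "
          f"(evidence organs: {','.join(call.evidence_organs) or '-'}; "
          f"Spearman rho {call.spearman_rho:+.2f})")

print("\nAn inverse pair needs one organ where the miRNA is high and the "
      "target low AND one with the reverse - here root (R) and nodule (N).")
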