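"""Receptor-expression skew analysis of single-cell RNA-seq data.

Generates a zero-inflated two-gene expression set whose class
probabilities emulate a human-melanoma single-cell study (malignant
melanocytes, NK, CD4+ and CD8+ T cells), classifies every cell by
non-zero IL12RB1/IL12RB2 expression, and tests whether the class
distribution and the IL12RB2:IL12RB1 ratio differ between cell types.

To analyze the real deposit instead, download the TPM matrix and
annotations of Gene Expression Omnibus accession GSE115978 and pass them
through ``load_expression``.
"""

import numpy as np

from il12sig import (
    ScrnaDesign,
    chi_squared_contingency,
    classify_cells,
    compare_ratios,
    gen_scrna,
    ratio_distribution,
)

records = gen_scrna(ScrnaDesign(seed=0))
table = classify_cells(records)
print("class fractions (% of cells per type):")
print(table.fractions().round(1))

ratios = ratio_distribution(records)
for t in ("malignant", "CD8T"):
    print(
        f"{t}: {len(ratios[t])} both-non-zero cells,"
        f" median IL12RB2:IL12RB1 ratio = {np.median(ratios[t]):.3f}"
    )

stat, p, dof = chi_squared_contingency(table)
print(f"chi-squared ({dof} df) = {stat:.1f}, p = {p:.3g}")
print(f"malignant vs CD8 ratio shift: p = {compare_ratios(ratios['malignant'], ratios['CD8T']):.3g}")
print(
    "Interpretation: malignant cells skew toward IL12RB2 (ratio > 1)"
    " while CD8+ T cells are IL12RB1-dominant (ratio << 1) — the"
    " expression pattern that enables non-canonical homodimer signaling."
)
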