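"""Select among receptor-activation mechanisms with Bayes factors.

Generates IL12RB2-stratified phospho-Akt data from the hybrid mechanism
(ligand-dependent + spontaneous activation, 72 subset x dose rows, 5%
noise), fits all three candidate mechanisms by SSE minimization, and
tabulates the pairwise Bayes factors B_ij = (SSE_i/SSE_j)^(-N/2).
"""

import numpy as np

from il12sig import PhosphoDesign, gen_phospho, select_mechanism
from il12sig.synthetic_data import DEFAULT_PHOSPHO_CONTEXT

obs = gen_phospho(PhosphoDesign(seed=1), DEFAULT_PHOSPHO_CONTEXT)
matrix = select_mechanism(obs, DEFAULT_PHOSPHO_CONTEXT)

print(f"n_obs = {len(obs)}")
for m in matrix.models:
    f = matrix.fits[m]
    print(f"{m:>13}: SSE = {f.sse:12.1f}  params = {f.params}")
print("Bayes factors (row i over column j):")
with np.printoptions(precision=2):
    print(matrix.values)
print("grades:", matrix.grades)
print("ranking (best first):", matrix.ranked)
print(
    "Interpretation: B > 150 is very strong evidence; the hybrid"
    " mechanism should dominate because the data contain both a"
    " ligand dose response and activation of unstimulated cells that"
    " grows with receptor copies."
)
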