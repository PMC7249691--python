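"""Receptor-complex surface density and the total-Akt correction.

Compares the two cell-line arrangements on a common axis: the T-cell
line (2D6) signals through IL12RB1:IL12RB2 heterodimers (one complex per
IL12RB2 copy, 104 μm² membrane) while the melanoma line (B16F0) uses
IL12RB2 homodimers (one complex per two copies, 344 μm²).
"""

from il12sig import ReceptorContext, complex_density, total_akt_correction

t_cells = ReceptorContext(
    "2D6", stoichiometry="heterodimer", area_um2=104.0
).with_totrc_from_copies(19_500)
melanoma = ReceptorContext(
    "B16F0", stoichiometry="homodimer", area_um2=344.0
).with_totrc_from_copies(330_000)

for name, ctx in [("2D6 (heterodimer)", t_cells), ("B16F0 (homodimer)", melanoma)]:
    rho = complex_density(ctx)
    print(
        f"{name:>18}: {ctx.totrc:>9,.0f} complexes on {ctx.area_um2:.0f} um^2"
        f" -> {rho:7.1f} complexes/um^2;"
        f" estimated total Akt = {total_akt_correction(rho):.0f} MFI"
    )
print(
    "Interpretation: despite 17x more IL12RB2 copies, the larger"
    " melanoma membrane and homodimeric stoichiometry compress the"
    " density gap to ~2.6x — density, not raw copies, drives the"
    " crowding-dependent spontaneous activation."
)
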