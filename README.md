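# il12sig

Quantitative analysis of canonical and non-canonical interleukin-12
(IL-12) signaling in melanoma.

IL-12 normally signals through a 1:1 IL12RB1:IL12RB2 receptor
heterodimer and phosphorylates STAT4 — the canonical anti-tumor immune
response. Melanoma cells that overexpress IL12RB2 can instead assemble
IL12RB2 homodimers (helped by IL-12 binding and by molecular crowding on
the membrane) and phosphorylate Akt, a survival kinase. This package
implements the statistical pipeline for dissecting that rewiring, for
researchers analyzing viability plates, stratified phospho-flow tables,
and single-cell RNA-seq annotations:

1. **Dose-response rescue inference.** Viability under a drug challenge
   follows

   `Live % = 100 · [1 − C_Im / (C_Im + EC50 · (1 + α · C_IL12/(C_IL12 + K_d)))]`

   with K_d fixed at 40 ng/mL: IL-12 right-shifts the drug's EC50 by up
   to a factor (1 + α). The posterior of (EC50, α) is sampled with a
   Metropolis–Hastings MCMC (proposals tuned to a 0.2 acceptance
   fraction, three over-dispersed chains, classic Gelman–Rubin PSRF
   convergence check, SSE-marginalized likelihood `L ∝ SSE^(−N/2)`).
   A rescue is called significant when `P(α < 0) < 0.05`.

2. **Receptor-activation mechanism selection.** Three equilibrium
   mechanisms generate activated receptor complexes (ARC) from the
   per-subset total TOTRC — canonical
   `ARC = TOTRC·IL12/(K_C + IL12)`, non-canonical
   `ARC = TOTRC/(K_N + 1)`, and a hybrid with both pools — feeding the
   saturable phospho stage `pS = TOTS·ARC/(K_D + ARC)`. Each mechanism
   is fitted to IL12RB2-stratified phospho-MFI data by least squares
   (K_C shareable across readouts within a cell line), and mechanisms
   are compared with Bayes factors `B_ij = (SSE_i/SSE_j)^(−N/2)`
   graded on the 1/3/20/150 evidence scale.

3. **Surface-density bookkeeping** (complexes per μm², heterodimer vs
   homodimer stoichiometry, forward-scatter size normalization) and the
   empirical total-Akt correction
   `Total Akt (MFI) = 0.352 · density + 382`.

4. **Single-cell receptor skew.** Per-cell classification by non-zero
   IL12RB1/IL12RB2 TPM, IL12RB2:IL12RB1 ratio distributions for
   both-non-zero cells, Pearson chi-squared (and exact-style) contingency
   tests, and rank-sum ratio comparisons. Works with the deposited
   human-melanoma study (GEO accession GSE115978) or with the package's
   synthetic generator.

Every stage has a seeded synthetic-data generator
(`il12sig.synthetic_data`) emulating its input, so the whole pipeline is
testable offline.

## Worked example

```python
from il12sig import ViabilityDesign, fit_viability_posterior, gen_viability

obs = gen_viability(ViabilityDesign(seed=7))          # 16-well plate, truth EC50=10, α=1
result, summaries = fit_viability_posterior(obs, n_steps=50_000, seed=7)
```

Running `python examples/viability_rescue_mcmc.py` (which is exactly
this) prints:

```
chains converged: True (PSRF [1.0012 1.0009])
acceptance fraction per chain: [0.189 0.193 0.191]
EC50 posterior median 9.38 uM, 95% CI (8.507124593089278, 10.367970036395693)
alpha posterior median 1.20, 95% CI (0.919209659245146, 1.5183470968333679)
P(alpha < 0) = 0.0000 -> significant: True
```

The PSRF below 1.2 says the three chains agree; the EC50 posterior
centres on the generating 10 μM; α ≈ 1 means saturating IL-12 doubles
the effective EC50 (a 100% right-shift); and the zero tail probability
makes the rescue significant. The other scripts in `examples/` walk
through mechanism selection, receptor surface density, and the
single-cell skew analysis the same way.

A thin CLI mirrors the stages:

```bash
il12sig simulate viability --seed 7 --out via.csv
il12sig fit-viability --data via.csv --steps 50000 --seed 1 --out fit/
il12sig simulate phospho --seed 2 --out ph.csv
il12sig select-model --data ph.csv --out sel/
il12sig simulate scrna --seed 3 --out sc.csv
il12sig scrna --records sc.csv --out scout/
```

Each output directory carries a JSON run manifest (config, seed, input
digests) sufficient to re-run the deterministic stages bit-identically.

## Layout

- `src/il12sig/` — library modules: `dose_response`, `mcmc`,
  `receptor_models`, `model_selection`, `scrna_ratio`,
  `synthetic_data`, `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — models, assumptions, parameter choices and
  limitations.
- `tests/` — unit, property and end-to-end acceptance tests.
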