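# Methods

## Dose-response rescue model

The viability stage models the percent of live cells after a cytotoxic
challenge as

    Live % = 100 · [1 − C_Im / (C_Im + EC50 · (1 + α · C_IL12/(C_IL12 + K_d)))]

where `C_Im` is the drug (imatinib) concentration in μM, `C_IL12` the
cytokine concentration in ng/mL, `EC50` the drug concentration producing
a 50% viability drop without cytokine, and `α` the dimensionless rescue
effect: the effective EC50 at saturating IL-12 is `EC50·(1+α)`. The
IL-12 binding constant `K_d` is fixed at 40 ng/mL and exposed only as a
configuration override, never inferred — with four cytokine doses it is
not separately identifiable from `α`. Units are carried by the input
table; nothing in the code assumes a particular dose scale (jointly
rescaling doses and EC50 leaves the likelihood invariant, and the test
suite checks this).

Raw assay values above 100% are accepted unmodified; clipping before
residual computation would bias the error metric.

**Likelihood.** No explicit noise model is declared for the assay;
the SSE-marginalized form `L(θ) ∝ SSE(θ)^(−N/2)` is used, which is the
profile of a Gaussian likelihood over an unknown noise variance with a
Jeffreys-type prior. Consequently no σ parameter is sampled and the
Bayes-factor machinery below uses the same form. A perfect fit
(SSE = 0) is degenerate under this likelihood and is signalled
explicitly.

## MCMC sampler

Random-walk Metropolis–Hastings with independent zero-mean Gaussian
proposal increments per parameter, targeting the log posterior under an
improper uniform prior on the valid domain (EC50 > 0, α > −1);
out-of-domain proposals are rejected. Design choices:

- **Proposal tuning.** A discarded pilot phase runs in rounds of 500
  steps; after each round the proposal sd vector is scaled
  multiplicatively by `(acc + 0.1)/(target + 0.1)` until the pilot
  acceptance lands within 0.2 ± 0.05. The scale is then frozen for
  inference, preserving Markov-chain validity. A completely flat target
  (acceptance pinned near 1 regardless of scale) is detected and the
  initial sd returned.
- **Initialization.** Each of the (default 3) chains starts uniformly
  in a user-declared over-dispersed box (`init_center ± init_dispersion`,
  spanning several times the expected posterior scale) so that the
  between-chain variance term of the convergence diagnostic is
  meaningful. The viability-fit default box is EC50 ∈ (1, 39) μM,
  α ∈ (−0.9, 4.9).
- **Convergence.** Classic Gelman–Rubin potential scale reduction
  factor per parameter: with m chains of n post-burn-in draws,
  `W = mean_j s_j²`, `B/n = var_j(x̄_j)`, `V̂ = (n−1)/n·W + B/n`,
  `PSRF = sqrt(V̂/W)` — no rank normalization and no
  sampling-variability degrees-of-freedom correction; the exact formula
  is pinned by an independently coded oracle test at 1e-10. Convergence
  is declared when every PSRF < 1.2.
- **Burn-in** defaults to 50% of each chain (configurable); there is no
  automatic segmentation rule.
- **Summaries.** Posterior medians and central 95% intervals from the
  pooled post-burn-in sample; the "maximum-likelihood" parameter vector
  is the visited state with the highest log posterior (no separate
  optimizer); the significance criterion is the posterior tail
  probability `P(α < 0)` compared with 0.05.
- Runs are bit-reproducible for a fixed seed (per-chain substreams are
  spawned from one root `SeedSequence`).

## Receptor-activation mechanisms

Three equilibrium mechanisms produce activated receptor complexes (ARC)
from the per-subset total TOTRC:

- canonical (ligand-dependent): `ARC = TOTRC·IL12/(K_C + IL12)`,
  `K_C = k_r1/k_f1`;
- non-canonical (receptor-dependent, molecular crowding):
  `ARC = TOTRC/(K_N + 1)`, `K_N = k_r2/k_f2`, ligand-independent;
- hybrid: `ARC1 = TOTRC·f(1−g)/(1−fg)` with `f = IL12/(K_C+IL12)`,
  `g = 1/(K_N+1)`, and `ARC2 = (TOTRC − ARC1)/(K_N + 1)`.

The hybrid state reduces to the non-canonical one at zero ligand and to
the canonical one as K_N → ∞; unit tests verify both limits (1e-6
relative) and verify all three closed forms against an ODE relaxation of
the underlying mass-action kinetics (1e-4 relative) — the kinetic
simulation exists only as a test oracle, the user-facing pipeline is
equilibrium-only. For the pure non-canonical mechanism the convention
`arc1 = 0` keeps the activation-state container uniform across
mechanisms.

Both activated pools phosphorylate the signaling intermediate (Akt or
STAT4) with the same kinetics, opposed by a generic phosphatase, giving
`pS = TOTS·(ARC1+ARC2)/(K_D + ARC1 + ARC2)` with `K_D = k_D·PASE/k_A`.
Only the ratios K_C, K_N, TOTS, K_D are identifiable at equilibrium; the
raw rate constants never appear in the API.

**Stoichiometry and density.** Measured IL12RB2 copies map to receptor
complexes as copies (heterodimer, T-cell arrangement) or copies/2
(homodimer, melanoma arrangement). Surface density divides complexes by
the membrane area (defaults 104 μm² for the 2D6 T-cell line, 344 μm²
for B16F0 melanoma) times an optional forward-scatter size factor
`fsc_scale`, defined as subset mean FSC-A over the cell-line reference
mean and defaulting to 1 when FSC data are absent — the simplest
multiplicative reading of a size normalization.

**Total-Akt correction.** Total Akt co-varies with receptor density;
the empirical linear relationship
`Total Akt (MFI) = 0.352·density + 382` can replace the free TOTS
parameter per observation (then TOTS is no longer fitted and the
corrected ratio pS/TOTS is exposed). The correction is per-readout
configurable and off by default for STAT4, whose total abundance was
found density-independent.

**MFI handling.** Phospho-MFI is modeled directly, without background
subtraction; background enters through the fitted TOTS/K_D scale.
Subset copy numbers are representative values (geometric means of the
stratification bin edges); bin edges are configuration.

## Fitting and model selection

Each mechanism is fitted by minimizing `SSE = Σ(Y_u − Y_model)²` over
its free parameters (canonical: K_C, TOTS, K_D; non-canonical: K_N,
TOTS, K_D; hybrid: all four). Parameters are optimized on log10 scale
(positivity by construction, scales spanning decades) with Nelder–Mead
from a deterministic multi-start grid centered on data-driven scales
(±1.5 decades per axis); all starts get a coarse pass and the best three
are polished to tight tolerances. Exponents are clamped to ±15 decades
to avoid float under/overflow during line searches. Fits are
deterministic; no randomness is involved.

K_C reflects extracellular binding affinity and therefore must not
depend on the intracellular readout: `fit_shared_kc` couples a cell
line's pAkt and pSTAT4 fits through a single K_C while every other
parameter stays per-readout. For a single readout it reduces exactly to
the plain fit.

Bayes factors are estimated from the maximum-likelihood SSEs,
`B_ij = (SSE_i/SSE_j)^(−N_obs/2)`, and graded 1–3 weak, 3–20 positive,
20–150 strong, > 150 very strong (for B < 1 the reciprocal is graded —
evidence for the other model). Nested-model Bayes factors can dip below
1 only through optimizer noise; raw values are reported without
clamping. The identifiability guard requires N_obs > N_free. SSE is
unweighted; event-count weighting is deliberately not implemented (the
per-subset event counts are carried for reporting only).

## Single-cell receptor skew

"Non-zero reads" is operationalized as TPM > 0 exactly — the deposited
matrix is TPM and any positive threshold would make classification
depend on library-size rescaling (a property test pins scale
invariance). Cells are classified per type into both / IL12RB1-only /
IL12RB2-only / neither; the IL12RB2:IL12RB1 ratio is computed only for
both-non-zero cells, never imputed. The class-distribution comparison
across cell types uses a Pearson chi-squared test restricted to cells
expressing at least one subunit; because an exact test is also in
common use for this table, an exact-style alternative is provided
(Fisher for 2×2, otherwise a seeded Monte-Carlo p-value over random
tables with the observed margins) and both values are reported. Ratio
distributions are compared with a two-sided Wilcoxon rank-sum test on
log ratios — a declared default, checked against a permutation oracle
for order-of-magnitude agreement only.

The loader accepts a genes × cells CSV/TSV or an MTX triplet plus a
`cell_id, cell_type` annotation table, maps deposited labels through an
optional rename map, relabels unlisted types "other" (retained), and
fails loudly on missing genes or unreconciled cell ids. The intended
real input is GEO accession GSE115978, fetched outside the package;
which annotation field defines the malignant/T/NK subsets there is
configuration, not code.

## Synthetic-data generators

The generators define the conditions under which the pipeline is
validated:

- **Viability**: full-factorial plate of imatinib {0, 5, 10, 20} μM ×
  IL-12 {0, 40, 100, 200} ng/mL (16 wells at one replicate), truth
  EC50 = 10 μM, α = 1, additive Gaussian noise of 3 percent-viability
  units, unclipped. Additive noise in percent units is the natural
  error model for a percentage readout.
- **Phospho**: per-cell IL12RB2 copies log-normal (ln-mean ln 3·10⁴,
  ln-sd 1.6, 20,000 cells — the order of a typical flow acquisition)
  binned into 18 log-spaced subsets spanning 10³–10⁶ copies (covering
  both cell lines' measured ranges, 19,500–330,000), crossed with IL-12
  doses {0, 7, 100, 300} ng/mL → 72 rows, satisfying the N_obs ≥ 69
  identifiability condition. Truth for the hybrid default: K_C = 60.7
  ng/mL (the melanoma-line binding constant), K_N = 3, TOTS = 1000 MFI,
  K_D = 5·10⁴ complexes — chosen so the response spans most of its
  dynamic range across the copy distribution. Noise is multiplicative
  log-normal (MFI is positive and right-skewed) with the log-sd scaled
  so its magnitude matches the requested fraction of the noise-free
  dynamic range.
- **Single-cell**: per cell type a multinomial over the four expression
  classes with probabilities matching the published human-melanoma
  fractions (malignant n = 2018: 20.7/55.9/5.2% both/RB1-only/RB2-only;
  NK n = 92; CD4 n = 856; CD8 n = 1759: 10.3/81.6/0.3%), and
  conditional log-normal TPM whose per-type log-mean offsets set the
  designed ratio medians (malignant 3, CD8 0.085).

All generators are bit-reproducible under a fixed seed and emit exactly
the schemas the corresponding readers consume.

What the generators do *not* emulate: per-event flow-cytometry noise and
gating artifacts (they produce subset summaries directly), fluorescence
spillover, plate edge effects, cell-type misannotation, and the gene–gene
correlation structure of real transcriptomes. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
error models, not robustness to those real-data pathologies.

## Numerical choices and problem sizes

- MCMC validation runs 3 × 50,000 steps (posterior recovery,
  convergence, significance); interval-coverage checks use 50 seeded
  replicates of 3 × 3,000-step chains, a size at which the 95% intervals
  are already stable for this 2-parameter posterior.
- Mechanism-selection consistency uses 20 seeded replicates of the
  default 72-row design at 5% noise.
- Shared-K_C recovery at 2% noise is sampling-limited under the 4-dose
  design: the joint fit is exact on noise-free data and its SSE beats
  the SSE at the generating parameters on noisy data, but per-seed K_C
  errors of ~5–20% remain; the test asserts the computed bound for its
  frozen seed rather than a tighter nominal figure.
- Tie-breaks: the posterior "ML value" takes the first-visited maximum;
  evidence grades at the scale edges go to the weaker grade below 3 and
  20 and to "strong" at exactly 150.

## Known limitations

- The likelihood has no replicate/heteroscedasticity structure; all
  observations are weighted equally.
- The proposal scale is tuned globally (one scalar factor on the sd
  vector), which is adequate for the 2-parameter posterior but would be
  slow for strongly anisotropic targets.
- The exact-style contingency p-value for tables larger than 2×2 is
  Monte-Carlo, with resolution limited by the number of sampled tables.
- Equilibrium models only; no kinetics, no explicit JAK2/TYK2/PI3K
  species — the three-step signaling scheme is collapsed into the
  activation and phospho stages.
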