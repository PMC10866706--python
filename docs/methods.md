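# Methods

## The three-state thermodynamic model

Each KRAS–partner pair is modelled as an equilibrium between three states:
unfolded and unbound (uu), folded and unbound (fu), and folded and bound
(fb). The unfolded-and-bound state is assumed negligible. With Gibbs free
energies of folding ΔG_f and binding ΔG_b (measured so that lower is more
folded / more bound), the Boltzmann distribution gives

    p_f  = 1 / (1 + e^{ΔG_f/RT})                         (fraction folded)
    p_fb = 1 / (1 + e^{ΔG_b/RT} · (1 + e^{ΔG_f/RT}))     (fraction folded and bound)

with R = 0.001987 kcal K⁻¹ mol⁻¹ and T = 303 K (the selection temperature),
so RT = 0.602061 kcal/mol. Both fractions are computed through
`log1p`/`logaddexp` forms and saturate smoothly at the extremes.

Mutational effects combine **additively in energy space**: a variant's total
ΔG_f is the wild-type value plus the sum of per-substitution ΔΔG_f terms,
and likewise per partner for ΔG_b. Folding energies are shared across all
assays (intrinsic to KRAS); binding energies are partner-specific. The
unmeasured binding-partner concentration is absorbed into the wild-type
ΔG_b, which therefore is an *apparent* binding energy; only energy
*differences* (ΔΔG) are reported as biological quantities.

Measured fitness is linked to the bound/folded fraction by one affine map
per experiment (21 experiments in the full design: 3 mutagenesis blocks ×
(1 AbundancePCA + 6 BindingPCA)): ŷ = a_e + b_e·p. The affine layer and
the wild-type energies are only jointly identifiable; ΔΔG coefficients are
pinned by the curvature of the Boltzmann nonlinearity across genetic
backgrounds, which is why the library pairs every single substitution with
a median of ten mildly detrimental backgrounds.

Stop-codon variants are parsed and carried through fitness tables but
excluded from fitting: the model has no truncation state.

## Fitting

Internally all energies are dimensionless (θ = ΔG/RT). The loss is a
σ-weighted mean absolute error with light L2 regularization,

    L[θ] = (1/N) Σ_n |y_n − ŷ_n| / σ_n + λ₂‖θ‖²,   λ₂ = 10⁻⁶,

where ‖θ‖² runs over every trainable parameter (energy coefficients,
wild-type energies, affine intercepts and slopes; the penalty is
negligible except for otherwise-unconstrained coefficients). Optimization
is minibatch Adam (β = 0.9/0.999, default batch 1024) with an initial
learning rate of 0.05 for at most 1,000 epochs. The learning rate is
multiplied by γ = 0.98 whenever the mean validation loss over the last 10
epochs has not improved on the preceding 10; training stops early when the
wild-type θ terms have stabilized (sd over the last 10 epochs ≤ 10⁻³).
Because every variant carries at most two substitutions, the additive
layer is a gather and its gradient a scatter-add; gradients through the
Boltzmann fractions and affine maps are analytic, so the trainer is plain
NumPy and exactly reproducible from its seed.

A random 30% of **double-mutant genotypes** is held out (20% validation,
10% test); all observations of a genotype stay in one subset, and singles
and the wild type always train. Validation loss uses the same σ-weighted
form as training (documented choice). Hyperparameter search is restricted
to batch size: candidates are each trained 100 epochs and the smallest
validation loss wins, ties to the smaller batch.

Initialization: energies at 0; per experiment, slope = observed fitness
range and intercept = minimum observed fitness, which places the wild type
near the folded/bound plateau and fixes the sign of the fitness–fraction
relationship.

One degenerate regime deserves note: with exactly zero measurement noise
the σ-weights are dominated by the reporting floor (σ = 10⁻⁶) and the
wild-type parameters stabilize long before the slowly-moving, nearly
saturated binding coefficients finish converging, so the noiseless
recovery benchmark disables the early-stop rule and trains the full
schedule. All noisy paths keep the default stopping rule.

## Uncertainty

Confidence intervals come from a Monte-Carlo ensemble of 10 refits, each
with (1) an independent random train/validation/test split and (2) the
training fitness values replaced once, before training, by draws from
Normal(y_n, σ_n); validation and test values are left unaltered. Per
coefficient the ensemble mean and sd give a normal-approximation 95% CI
(mean ± 1.96 sd; a percentile mode exists but is unstable at n = 10).
Estimates with CI width < 1 kcal/mol are flagged *confident*. Significance
calls use z = (mean − null)/sd with the ensemble sd as the standard error,
two-sided normal p-values, and Benjamini–Hochberg correction within each
trait/partner family; "detrimental" additionally requires mean ΔΔG > 0.
At n = 10 the normal approximation undercovers slightly; empirical
coverage of the nominal 95% CI on synthetic data is ~90–93%.

## Structure annotation

Interface residues: minimal side-chain heavy-atom distance to any
partner-chain atom < 5 Å (strict). Glycine, having no side-chain heavy
atoms, uses Cα as surrogate (switchable; excluding glycine would silently
drop annotated interface positions). GTP pocket: distance to
GTP/GDP/GNP/Mg²⁺ atoms < 5 Å. Core: relative accessible surface area
< 0.25, with ASA from the Shrake–Rupley rolling-probe method (probe 1.4 Å,
100 sphere points) on the isolated KRAS chain, normalized by the Tien et
al. (2013) theoretical maxima. Alternate locations resolve to the highest
occupancy; hydrogens are ignored; unresolved residues get infinite
distances and missing rASA (never core). Secondary structure and surface
pockets use fixed residue ranges (P-loop 10–17; switch-I 25–40; switch-II
58–76; α1–α5 and β1–β6 ranges; pockets 1–4 as explicit residue sets);
pocket 2 can alternatively be recomputed from sotorasib contacts when a
ligand-bound structure is supplied.

## Allosteric mapping

The *interface threshold* is the weighted mean |ΔΔG_b| over all mutations
in interface residues, pooled over the requested partners (one partner for
a single-interaction map; all six for the multi-partner definition).
*Allosteric mutations* are non-interface mutations whose ΔΔG_b exceeds
that threshold by a two-sided z-test at FDR 0.05 (BH within the
non-interface family of the partner under test), additionally requiring
the point estimate above the threshold. *Major allosteric sites* are
non-interface residues whose position-wise weighted mean |ΔΔG_b| is **at
least** the threshold (inclusive).

Weighted means default to inverse-variance weights (1/sd²) from the
Monte-Carlo errors, switchable to uniform. Two related caveats:

- Position summaries and thresholds include **all** estimates by default
  rather than only confident ones. Strong binding defects saturate the
  selection assay, so their MC sds are the largest; a hard confidence
  cutoff would remove exactly the large interface effects that define the
  threshold and can invert downstream comparisons. Inverse-variance
  weighting already discounts uncertain estimates continuously; a
  `confident_only` flag restores the strict filter.
- For the ROC comparison of interface predictors (per-position mean
  |ΔΔG_b| vs per-position mean |binding fitness|) the package uses uniform
  weights on both scores: with inverse-variance weights the heteroscedastic
  censoring suppresses the strong-effect coefficients on the energy side
  only, making the comparison asymmetric.

ROC-AUC is the Mann–Whitney concordance probability (ties credited 0.5),
computed with trapezoidal integration. Enrichment uses the two-sided
Fisher exact test; the reported odds ratio is the sample OR ad/bc with a
Haldane 0.5 correction of all cells iff any cell is zero (flagged).
β-sheet decay reports per-strand weighted mean |ΔΔG_b| for strands ordered
by distance to the partner, plus the mutation-level Spearman correlation
between strand rank and |ΔΔG_b| (negative = decay).

## Synthetic data generator

The generator emulates the study design at reduced size so every stage is
testable without downloads. Defaults (the "study conditions"):

- **Positions**: the first n contiguous mutable positions of the real
  KRAS4B sequence (default presets: 150 for a full-scale run, 40 for the
  test preset), partitioned into three blocks of consecutive positions,
  each with its own experiments and affine maps (slope ~U(0.9, 1.1),
  intercept placing the wild-type fitness near 0).
- **Energies**: wild-type ΔG_f = −2.0 kcal/mol, apparent ΔG_b = −0.5
  kcal/mol per partner. ΔΔG_f is a three-component mixture: a point mass
  near zero (Normal(0, 0.05); weight 0.45 at surface positions, 0.10 in
  the core), a destabilizing Gamma(2, 0.8) component, and a small
  stabilizing tail (weight 0.05, −|Normal(0, 0.3)|) — the core is
  upweighted for destabilization as in real scans. ΔΔG_b is large
  (1.5 + Gamma(2, 0.6)) for a random half of substitutions at designated
  interface positions (interfaces tolerate conservative substitutions,
  which keeps the interface-average threshold realistic), Normal(2.0, 0.2)
  at designated allosteric positions, Normal(0, 0.05) elsewhere.
- **Library**: all singles; doubles pair each single with 10 backgrounds
  drawn from same-block singles whose true abundance effect lies in
  [−0.5, −0.05] on the wild-type-normalized scale (the mild-detrimental
  bias that makes energies identifiable).
- **Noise**: per-observation σ_n = σ·U(0.8, 1.2) with Gaussian errors
  (default σ = 0.1, roughly 10% of the fitness dynamic range), or a
  read-count mode (Poisson input counts at a requested depth, Poisson
  output counts around the exponentiated fitness, converted by the
  log-ratio estimator with its Poisson-approximation standard error).
- **Structure**: designated interface positions receive partner distances
  in (2.5, 4.5) Å, GTP-pocket positions ligand distances in (2.5, 4.5) Å,
  core positions rASA in (0.03, 0.2), everything else safely outside the
  thresholds; an optional toy coordinate file reproduces the emitted
  distances exactly when re-parsed (the table is derived from the written
  3-decimal coordinates). Interface, pocket and core sets are kept
  disjoint so the toy geometry is satisfiable.

What the generator does **not** emulate: codon-level library structure and
NNK bias, replicate correlation structure, epistasis beyond energy
additivity, position-dependent error profiles, and a folding confound as
strong as the real protein's (the default wild type is stable enough that
moderate destabilization only mildly reduces binding fitness). Passing
recovery tests on these data therefore demonstrates correctness of the
inference machinery under the stated model, not robustness to real-data
model violations.

## Identifiability and benchmark interpretation

The selection assays floor: once a variant is effectively unfolded or
unbound, further energy increases change fitness by less than the
measurement noise. Under the default noisy conditions (σ = 0.1, ~10
backgrounds per single), binding ΔΔG beyond ~3 kcal/mol is censored; such
coefficients scatter across ensemble members, their CIs exceed 1 kcal/mol,
and they are flagged non-confident. Recovery correlations are therefore
reported both over all coefficients (~0.92, pulled down by the censored
tail) and over confident estimates (≥0.95), the latter being the
deliverable the confidence definition exists for. With zero noise the
censoring disappears and all coefficients are recovered (r > 0.99,
RMSE < 0.1 kcal/mol).

## Problem sizes

Tests and the acceptance script run the 40-position preset
(~760 singles, ~7,400 doubles, ~57,000 observations, 5,320 energy
coefficients), a 10-member ensemble at 400 epochs per member, and a
30-position single-partner preset for the null-FDR and ROC-contrast
checks. These sizes were chosen so a full run completes in minutes on one
CPU while every coefficient retains ≥14 covering observations.
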