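# Methods

## Scope and modeling stance

`hepaflux` evaluates *metabolic capacities and functions* of individual
livers from label-free proteomes.  The kinetic engine is a reduced, lumped
network of central hepatic metabolism (`hepatocore`), written declaratively
so that a richer model file can replace it without code changes.  It is not
a reproduction of any published large-scale liver model: detailed
mitochondrial electrophysiology and ion homeostasis, the pentose-phosphate
and creatine subsystems, and amino-acid metabolism beyond
glutamine/glutamate exchange with a lumped nitrogen feed to the urea cycle
are deliberately out of scope.  Oxidative ATP production is a single
TCA + respiratory-chain lump with fixed stoichiometric yield; the
electrodiffusive character of mitochondrial/membrane carriers is retained
only as a Goldman–Hodgkin–Katz (GHK) rate-law kind with a fixed reduced
potential.

## The hepatocore network

31 reactions over 12 balanced intracellular pools (intracellular glucose,
hexose-6-phosphate, triose-phosphate, pyruvate, oxaloacetate, acetyl-CoA,
malonyl-CoA, fatty acyl-CoA, glycerol-3-phosphate, intracellular glutamate,
intracellular ammonium, acetaldehyde), 13 clamped plasma species and two
clamped stores (glycogen at 200 µmol glucosyl/g, TAG at 15 µmol/g).  Units:
concentrations mM (stores µmol/g wet liver), fluxes µmol·h⁻¹·g⁻¹ wet liver,
conventional for perfused-liver data.

Rate-law kinds:

- `irreversible_mm` — product of Michaelis–Menten saturation terms over all
  substrates, one Km each.
- `reversible_mm` — Haldane-consistent reversible form
  `v = vmax (S − P/Keq)/Kms / (1 + S/Kms + P/Kmp)`; the flux vanishes
  exactly at P = Keq·S.
- `ghk_transport` — `v = vmax z u (S − P e^(−u))/(1 − e^(−u))` with fixed
  reduced membrane potential u = 5 (dimensionless); tends to
  `vmax z (S − P)` as u → 0.  Used for electrodiffusive ammonium entry.
- Hill modulators multiply any rate: activation `X^n/(K^n + X^n)`,
  inhibition `K^n/(K^n + X^n)`.

Every rate is proportional to its maximal activity, which yields an exact
engine property: scaling all vmax by λ leaves steady-state concentrations
unchanged and scales every flux by λ (verified to machine precision in the
tests).

### Regulatory couplings in the reference model

- Pyruvate carboxylase is activated by acetyl-CoA (K = 0.05 mM, n = 2).
- β-oxidation is inhibited by malonyl-CoA (K = 0.01 mM, n = 2) — the
  malonyl-CoA/CPT1 switch that separates lipogenic from ketogenic states.
- The urea-cycle lump carries an N-acetylglutamate-type activation by
  intracellular glutamate (K = 0.5 mM, n = 1).
- Fatty-acid uptake carries acyl-CoA feedback inhibition (K = 2 mM, n = 2),
  and the fructolysis and glycerol-kinase lumps carry product inhibition by
  triose-phosphate and glycerol-3-phosphate respectively (K = 2 mM, n = 2).
  These feedbacks are far from engaging at reference operating points
  (factor > 0.97) and exist so that a saturating substrate load meets a
  finite disposal network gracefully: without them, individualized models
  with adversely drawn activities (e.g. high uptake, low oxidation) have no
  steady state under saturating titrations.  They also propagate downstream
  enzyme downregulation into entry capacities, which is how a reduced
  glycolytic lump lowers the fructose-utilization capacity.

### Hormone transfer functions and phosphorylation state

Plasma glucose is the single driving variable.  Insulin rises and glucagon
falls with glucose as Hill sigmoids (midpoints 7.0 and 6.5 mM, n = 4); NEFA
follows a declining sigmoid whose two amplitude coefficients are solved
exactly from the anchors **NEFA(3 mM) = 1.0 mM** and **NEFA(12 mM) = 0.2 mM**
(fasted/fed states).  The phosphorylated fraction γ of interconvertible
enzymes is a sigmoid of the glucagon share r = glucagon/(glucagon+insulin)
(midpoint 0.35, n = 3), strictly decreasing in insulin, with γ(3 mM) ≈ 0.95
and γ(12 mM) ≈ 0.01.  The functional forms are a phenomenological
reconstruction; only the two NEFA anchors and the monotonicity/fasted-fed
ordering are treated as fixed constraints.

Phosphorylation-sensitive reactions interpolate linearly between their
phospho- and dephospho-forms: glucokinase, lower glycolysis (pyruvate
kinase lump), PDH, glycogen synthase, ACC are dephospho-active; PEPCK leg,
glycogen phosphorylase, ketogenesis, lipolysis are phospho-active.  The
pyruvate-kinase and PDH lumps retain residual activity in the inactive form
(0.35 and 0.25) representing feed-forward activation — without this, a
fasted-state fructose load has no route to lactate.

### Stores

Glycogen and TAG are clamped at reference fill levels; protocols report net
synthesis fluxes ("glycogen storage" = synthase − phosphorylase flux,
"TAG content" readout = synthesis − lipolysis at the fed state).  This
avoids arbitrary time-integration windows; the cost is that store dynamics
(depletion, supercompensation) are outside the model.

### Steady-state solver

Internal concentrations are solved in log space (positivity by
construction) with a Powell-hybrid root find, warm-started along protocol
grids, falling back to stiff pseudo-transient integration (LSODA on
d log C/dt) followed by a final root polish.  Convergence contract:
`max |dC/dt| / max(C, 1) < 1e-8`; non-converged points are reported with
their residual and masked in capacity curves, never silently accepted.
The algebraic-first ordering (rather than integrate-first) was chosen
because protocols require thousands of steady states; the convergence
criterion and the fallback integrator are unchanged by the ordering.  The
solver is fully deterministic.

### Calibration of the reference model

Maximal activities were tuned once against control-liver anchors and frozen
in `hepatocore.yaml`:

- glucose-exchange neutral point at 8.3 mM plasma glucose (glucokinase vmax
  located by bisection at fixed G6Pase capacity);
- FFA uptake rising up to ≈ 0.8 mM plasma FFA and changing < 10 % from
  0.8 to 1.6 mM (uptake Km 0.15 mM);
- ketogenesis confined to the fasted state (γ-gating; fed flux < 2 % of
  fasted flux);
- steady states must exist across all protocol grids for ± 40 %
  multiplicative perturbations of every activity (individualized cohorts),
  verified by Monte-Carlo.

Absolute flux magnitudes are plausible for rat liver but are not calibration
targets; only the anchors above are.

## Individualization

`vmax_a = vmax_ref · E_a / E_ref` per reaction, where both abundances are
*sums* over the mapped isozymes/subunits (aggregation before the ratio).
This ordering makes the mean of individualized activities over control
animals equal the reference activity exactly, because the reference is
defined as the control mean.  Reactions with no mapped or no detected
protein, or a zero reference, keep the reference activity with provenance
`reference_fallback` — a missing protein group must not produce a
zero-capacity liver.  No shrinkage or ratio capping is applied by default
(a configurable cap exists, default off).  The shipped enzyme map covers the
reduced model's reactions with typical rat gene symbols; it is user-replaceable.

## Simulation protocols

- Substrate scans run at a glucose 6 mM background with hormone coupling
  active and the titrated substrate clamped: glucose 3–12 mM step 0.05;
  fructose/galactose/glycerol 0–10 mM step 0.25; FFA 0–1.6 mM step 0.05;
  ammonia 0–5 mM step 0.1; ethanol 0–20 mM step 0.5.  A mid-physiological
  background avoids extreme regulatory states; all grids are configurable.
- Maximal capacity = flux at the top grid point (saturation reading), not a
  fitted asymptote — reproducible and consistent with reading capacities at
  saturating substrate.
- The 14-function capacity panel: fructose/galactose/glycerol uptake,
  glucose production (fasted) and uptake (fed), glycogen storage (fed net
  flux), FFA uptake, TAG synthesis, fatty-acid synthesis (fed), VLDL
  export, β-hydroxybutyrate production (fasted), urea production, ammonia
  uptake, ethanol uptake.  The membership is a reconstruction of the
  functions named across capacity studies and is configurable; ketone-body
  production appears both as a capacity and as a fasted readout because its
  classification is ambiguous.
- Fed/fasted readouts are the sweep endpoints (12 and 3 mM glucose).
- The neutral point interpolates the first production→consumption zero
  crossing of net glucose exchange linearly; sign convention: production
  negative, consumption positive.

## Statistics

- Differential abundance: Welch (unequal-variance) two-sided *t*-tests on
  log2 intensities (zeros floored at half the smallest positive intensity),
  BH step-up over all proteins (delegated to statsmodels; an independent
  brute-force step-up oracle guards it in the tests).  Fold changes are
  log2 ratios of raw group means.  Volcano classes use the BH-adjusted p by
  default (configurable), thresholds p < 0.05 and |log2FC| > 1.
- Group comparisons are gated by a one-sample Kolmogorov–Smirnov normality
  check against a normal with the sample's own mean/SD (α = 0.05): Welch
  *t* when both groups pass, otherwise the unpaired Wilcoxon rank-sum test
  (the paired signed-rank test does not apply to independent groups).
- Enrichment: weighted KS running-sum ES (weight exponent 1 on |stat|),
  null by resampling same-size gene sets from the ranked universe
  (1000 permutations default), `p = (1 + #{|ES*| ≥ |ES|})/(n_perm + 1)`,
  BH FDR across pathways, significance at p ≤ 0.05 ∧ FDR ≤ 0.05.
- Clustering: per-row z-scoring, Euclidean distance, average linkage for
  rows and columns; the two-cluster column cut is exposed for
  group-separation checks.  PCA operates on centered log2 intensities with
  samples as observations.
- Structure–function: OLS of each function on each property over all
  samples pooled (control and case on one line), slope *t*-test p, R²,
  tiers significant (p < 0.05) / tendency (0.05 ≤ p < 0.1) / ns; no
  multiple-testing correction across the property × function grid by
  default (BH optional), since tiered raw p-values are the primary report.
- ADC: least-squares slope of −ln S vs b over the seven standard b-values
  (50…800 s/mm²); exact on noiseless input and scale-invariant in S0.

## Synthetic data: what it emulates and what it does not

Proteomes are log-normal around per-protein baselines drawn log-uniformly
over six decades (typical LFQ dynamic range); case means are multiplied by
2^(planted log2 effect); multiplicative noise has unit mean and configurable
CV (default 0.2 — the intra-group CV of LFQ data is not established, this is
a stated choice).  Optional left-censoring below an intensity threshold
emulates detection limits (default off; no imputation is modeled).  The
pregnancy profile fixture plants the qualitative enzyme directions of the
late-pregnant rat liver (fatty-acid uptake transporter ×0.8; urea-cycle
regulators, perilipin-3, short/long-chain acyl-CoA dehydrogenases and the
glycolytic lump ×0.6 — 0.6 being the default magnitude where none is
established; CGI-58 ×1.5; CPT1/CPT2 ×1.0).  Biophysical markers are linear
in a chosen capacity plus Gaussian noise; DWI signals are clean
mono-exponentials plus Gaussian noise.

Passing tests on these fixtures demonstrates that the pipeline recovers
*known* planted structure at realistic noise and cohort size.  They do not
demonstrate anything about peptide-level artifacts, shared-peptide protein
inference, batch effects, non-linear structure–function coupling, or the
quantitative accuracy of the reduced network against a real liver — all of
which are outside the generator.

## Numerical and design choices

- Seeds: every stochastic routine takes an explicit seed
  (`numpy.random.default_rng`); fixed seed ⇒ bit-identical outputs.
- Zero-variance proteins (both groups) get p = 1 with a warning; constant
  clustergram rows are dropped with a warning; a perfect regression fit
  (zero residual, nonzero slope) reports p = 0.
- Tie-breaks: ranking for the enrichment score uses a stable descending
  sort, so ties keep input order.
- Degenerate scans (no zero crossing in a sweep) return NaN with a warning
  rather than extrapolating.

## Known limitations

- The reduced network lumps entire pathways; per-enzyme signatures within a
  lump are only resolvable through the abundance aggregation, not through
  the kinetics.
- Clamped stores make "storage" a net flux, not an amount; integrated
  store dynamics are not simulated.
- The hormone transfer functions are monotone sigmoids constrained by two
  NEFA anchors; their shapes between anchors are assumptions.
- Internal ammonium can rise well above physiological levels at saturating
  ammonia loads when urea capacity is strongly downregulated; the GHK
  back-flux bounds it, but the value should be read as a model coordinate,
  not a prediction.
- Biophysical coupling in the generator is linear by construction; the
  structure–function stage therefore validates recovery, not discovery.
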