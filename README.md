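# hepaflux

Proteomics-individualized kinetic modeling of hepatic metabolic capacities,
with group statistics and correlation against biophysical imaging markers.

## The problem

How does the liver reorganize its metabolism — e.g. during late pregnancy —
and can those functional changes be read out from a label-free proteome and
related to non-invasive imaging markers?  Enzyme abundances alone do not
answer this: a metabolic function (glucose production, fatty-acid uptake,
urea synthesis, …) emerges from the whole network under hormonal control.
`hepaflux` implements the full computational chain used in
proteomics-constrained liver modeling studies:

1. **Differential proteomics** — per-protein Welch *t*-tests on log2 LFQ
   intensities with Benjamini–Hochberg control, volcano classification
   (p < 0.05, |log2FC| > 1), PCA, row-standardized hierarchical clustering,
   and a gene-set-permutation enrichment score (weighted running-sum ES).
2. **Per-animal model individualization** — each reaction's maximal activity
   is scaled by the abundance ratio of its enzymes to the control mean:

   $$v_{\max}^{(a)} = v_{\max}^{\mathrm{ref}} \cdot \frac{E_a}{E_{\mathrm{ref}}}$$

   where $E_a$ is the summed LFQ intensity of the mapped isozymes/subunits in
   animal $a$ and $E_{\mathrm{ref}}$ their mean over control livers.
3. **Steady-state capacity simulation** — a reduced, declaratively defined
   kinetic model of central hepatic metabolism (`hepatocore`: 31 lumped
   reactions, 12 balanced metabolite pools; Michaelis–Menten, reversible
   Haldane, Hill-modulated and Goldman–Hodgkin–Katz rate laws).  Plasma
   glucose drives insulin/glucagon/NEFA through calibrated transfer
   functions, and the hormones set a shared phosphorylation state γ of the
   interconvertible enzymes.  Protocols titrate substrates to saturation
   (14 maximal capacities), sweep glucose 3→12 mM (fasted→fed), and locate
   the **neutral point** — the glucose level where the liver switches from
   net glucose production to net consumption (8.3 mM for the shipped
   control-calibrated model).
4. **Structure–function analysis** — mono-exponential ADC fitting from DWI
   signals over seven b-values, group comparison of MRE/DWI markers
   (stiffness c, penetration rate a, ADC), and pooled OLS of every metabolic
   function on every biophysical property with significance (p < 0.05) and
   tendency (p < 0.1) tiers.

A synthetic-data module generates two-group proteomes with planted effects,
a fixed "pregnancy profile" of enzyme changes (fatty-acid uptake transporter
−20 %, urea-cycle enzymes down, CGI-58 up, CPT1/2 unchanged, …), coupled
biophysical markers and DWI decays — so the entire pipeline is testable with
known ground truth and no external download.

## Worked example

```python
from hepaflux.kinetics import default_model
from hepaflux.protocols import glucose_sweep, neutral_point, substrate_scan

model = default_model()
sweep = glucose_sweep(model)                      # 3-12 mM, hormone-coupled
print(f"neutral point: {neutral_point(sweep):.2f} mM")
ffa = substrate_scan(model, substrate="ffa")      # 0-1.6 mM plasma FFA
print(f"FFA uptake capacity: {ffa.max_capacity:.1f} umol/h/g")
```

prints

```
neutral point: 8.30 mM
FFA uptake capacity: 27.4 umol/h/g
```

i.e. the control-calibrated liver switches to net glucose consumption at
8.30 mM plasma glucose, and its fatty-acid uptake saturates near 27 µmol·h⁻¹·g⁻¹
(rising steeply up to ~0.8 mM plasma FFA, then < 10 % further).  On the
synthetic study-sized proteome (5004 proteins, 1068 planted effects, 7
control vs 8 case animals, CV 0.2):

```python
from hepaflux.synthetic import generate_proteome, planted_effects
from hepaflux.stats import differential_test

ids = [f"P{i+1:05d}" for i in range(5004)]
effects = planted_effects(ids, 1068, seed=1)
matrix = generate_proteome(7, 8, 5004, effects=effects, cv=0.2, seed=1)
res = differential_test(matrix)                   # Welch + BH at 0.05
```

recovers the planted truth with recall 0.973 at a realized FDR of 0.035 —
the detection operating point the downstream individualization relies on.

The full pipeline (differential table → individualized models → capacity
panel → clustering → structure–function regression) runs from one YAML
config:

```bash
hepaflux simulate-synthetic --seed 1 --out inputs/
hepaflux run --config pipeline.yaml --seed 1 --out results/
```

## Layout

- `src/hepaflux/synthetic.py` — synthetic proteomes, biophysics, DWI, profile fixture
- `src/hepaflux/proteomics.py` — abundance tables, enzyme map, reference profile
- `src/hepaflux/stats.py` — differential tests, BH, PCA, clustergram, enrichment
- `src/hepaflux/kinetics/` — model definition, rate laws, hormones, solver
- `src/hepaflux/individualize.py` — abundance-ratio vmax scaling per animal
- `src/hepaflux/protocols.py` — scans, glucose sweep, panel, group analyses
- `src/hepaflux/biophysics.py` — ADC fit, marker comparison, OLS tiers
- `src/hepaflux/pipeline.py`, `cli.py`, `plots.py` — orchestration, CLI, figures
- `src/hepaflux/data/hepatocore.yaml` — the shipped calibrated model
- `docs/methods.md` — model equations, assumptions, calibration and limitations
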