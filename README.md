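# cofactorflux

Constraint-based modelling of **non-consumed ion cofactors** (the iron
family: Fe ions, haems, Fe-S clusters) in genome-scale stoichiometric
models. The toolkit covers:

- **Model core** — a lightweight stoichiometric data model with SBML I/O
  (reads Level 3 + fbc and legacy Level 2 COBRA-notes dialects, writes
  Level 3 + fbc), dead-end detection and model diffing.
- **LP engine** — FBA growth maximisation and FVA on scipy's HiGHS
  backend, with a deterministic minimal-total-flux (parsimonious)
  selection rule and a precision guard for very small stoichiometric
  coefficients (with automatic cofactor unit rescaling).
- **Cofactor augmentation** — inject a cofactor X with coefficient x into
  a catalysed reaction either literally on both sides (net zero,
  non-binding, kept on record) or as a free→spent pool split (makes
  cofactor availability a binding LP constraint and gives turnover a
  measurable meaning); build the empty/sulphurated scaffold cycle for
  cluster biogenesis, the availability/depletion (PS/AS) signalling
  circuit around high-affinity uptake, haem-gene coupling of
  low-affinity uptake, and µM-threshold-derived uptake bounds.
- **Biomass cofactors** — derive per-entity biomass coefficients from
  amino-acid binding ratios, amino-acid biomass coefficients and
  proteome fractions, and inject them into the biomass reaction.
- **Essentiality** — GPR-aware single-gene deletions and confusion-matrix
  scoring (PPV/NPV/sensitivity/specificity/predictive success, with
  round-half-up integer percents).
- **Perturbation** — reduction-of-function (hemizygote-style 50% flux
  caps), exchange scaling (e.g. the 10% low-iron medium), flux-change
  classification (unchanged / scaled-as-expected / changed above a
  relative threshold / rewired) with threshold sensitivity sweeps, and
  qualitative up/down/same benchmarking of reporter fluxes.
- **Turnover** — coefficient sweeps with knee detection, total
  coefficient-weighted turnover of cofactor-recruiting enzymes
  (cross-checked against spent-pool influx) and FVA-based min/max
  bracketing.
- **Fixtures** — a deterministic miniature iron-metabolism network
  (≤60 reactions) with closed-form optima, reference essentiality
  labels and benchmark scenarios, so everything above is testable
  offline.

## CLI

A single `cofactorflux` entry point with subcommands:

```bash
cofactorflux fixture --seed 0 --out model.xml --bundle bundle.yaml
cofactorflux fba model.xml --out fluxes.tsv
cofactorflux fva model.xml --fraction 1.0 --out ranges.tsv
cofactorflux io deadends model.xml
cofactorflux io diff base.xml extended.xml
cofactorflux io convert legacy_l2.xml modern_l3.xml
cofactorflux augment model.xml --table cofactors.tsv --out augmented.xml
cofactorflux precision-guard model.xml --tolerance 1e-9
cofactorflux biomass --rules binding_rules.tsv --inputs biomass.yaml
cofactorflux essentiality model.xml --reference genes.tsv --threshold 0.01
cofactorflux benchmark model.xml --scenario scenario.yaml --reporters GROWTH,EX_o2
cofactorflux rewire --ref ref_fluxes.tsv --new new_fluxes.tsv --thresholds 0.15,0.25,0.35
cofactorflux sweep model.xml --table cofactors.tsv --magnitudes 0,1e-15,1e-14,1e-13
cofactorflux turnover model.xml --table cofactors.tsv
cofactorflux run --config run.yaml
```

The cofactor table is a TSV with columns
`reaction_id  cofactor_species  coefficient  [mode]`; the essentiality
reference is `gene  essential` with yes/no values; binding rules are
`entity  amino_acid  ratio` (one row per amino acid).

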