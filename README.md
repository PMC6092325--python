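# jellytroph

Trophic-ecology inference for gelatinous predators. The package implements,
as one tested pipeline, the statistical chain used in seasonal jellyfish diet
studies that combine stomach contents, stable isotopes and fatty-acid
biomarkers:

- **Prey electivity** — Pearre's index *C* on a diet-vs-environment 2×2
  contingency table, `C = (a_d·b_e − b_d·a_e)/√((a_d+a_e)(b_d+b_e)(a_d+b_d)(a_e+b_e))`,
  tested with the ordinary chi-square (`χ² = n·C²`, df = 1).
- **Trophic level** from nitrogen isotope enrichment:
  `TL = (δ¹⁵N_consumer − δ¹⁵N_baseline)/Δ¹⁵N + TL_baseline`, with calanoid
  copepods as baseline (TL 2) and Δ¹⁵N = 3.2 ‰ per level; δ values follow
  `δ = (R_sample/R_standard − 1)·10³`.
- **Bayesian diet-source mixing** (the SIAR model structure, implemented
  here): consumer isotopes are normal with mean `Σₖ pₖ(μⱼₖ + cⱼₖ)` and
  variance `Σₖ pₖ²(ωⱼₖ² + τⱼₖ²) + σⱼ²`, Dirichlet(1,…,1) prior on the source
  proportions **p**, half-normal prior on the residual scales σⱼ; inference
  by blockwise random-walk Metropolis with Gelman–Rubin diagnostics. Default
  trophic enrichment factors: 2 ± 0.3 ‰ (δ¹³C) and 3.2 ± 0.1 ‰ (δ¹⁵N).
- **Fatty-acid biomarkers** — shorthand parsing (`C20:5n-3` = EPA, …),
  SFA/MUFA/PUFA class totals, and the n3/n6, PUFA/SFA and EPA/DHA diet-tracer
  ratios per sample and per (month, sex, tissue) group.
- **PERMANOVA and SIMPER** — 1–3 crossed fixed factors with interactions on
  Euclidean or Bray–Curtis distances (sequential SS via the Gower-centered
  inner-product matrix, `SS_term = tr(H_term G)`), permutation or exhaustive
  p-values, and the additive per-variable SIMPER decomposition of
  between-group Bray–Curtis dissimilarity.
- **Synthetic data** — a seeded generator for seasonally structured
  environment/stomach/isotope/fatty-acid datasets with recorded ground truth
  (selectivity weights, true diet proportions, gonad:soma storage factor),
  so every estimator can be tested by parameter recovery.

It is aimed at quantitative ecologists who have per-predator stomach counts,
net-haul availability, δ¹³C/δ¹⁵N records and/or FA concentration profiles in
CSV form and want the full inference chain — or a transparent, dependency-light
reimplementation of any one stage — with reproducible seeds throughout.

## Worked example

`examples/` contains one short script per capability. Prey electivity on a
synthetic May community where copepods are actively selected (weight 3) and
ostracods avoided (weight 0.25):

```bash
$ python examples/selectivity_electivity.py
May: 25.2 +/- 1.1 prey per medusa
       taxon       C     chi2      p direction
    copepods  0.3083 120.0499 0.0000         +
   fish_eggs -0.1255  19.8961 0.0000         -
   ostracods -0.2515  79.8606 0.0000         -
chaetognaths -0.1115  15.6964 0.0001         -
```

Copepods are over-represented in stomachs relative to the water column
(C > 0, "+" = significant positive selection at α = 0.05) and ostracods
avoided. Electivity is relative, so with copepods dominating the diet even
neutral-weight taxa occupy a smaller diet share than environment share and
flag "−". Diet mixing from isotopes (`examples/mixing_model.py`, truth
p = 0.45/0.40/0.15):

```
    parameter  mean  median    lo    hi  rhat
    p_<200 um 0.446   0.446 0.431 0.462 1.000
p_200-1000 um 0.409   0.409 0.392 0.427 1.000
   p_>1000 um 0.144   0.144 0.130 0.158 1.001
   sigma_d13C 0.250   0.254 0.060 0.421 1.000
   sigma_d15N 0.196   0.197 0.030 0.342 1.000
acceptance rate 0.28, converged: True
```

Each `p_<source>` row is that plankton size class's estimated share of the
diet with a 95% equal-tailed credibility interval; means sum to 1 and land
within ~0.01 of the simulated truth.

The whole chain runs from one config (`examples/full_pipeline.py`), or from
the shell:

```bash
jellytroph synth --preset paper-like --seed 42 --out data/
jellytroph run config.yml        # validate → selectivity → TL → mixing → FA → PERMANOVA/SIMPER
```

Subcommands `validate`, `selectivity`, `trophic`, `mix`, `fatty`, `permanova`
expose the individual stages. Every stochastic stage takes a seed and reruns
bit-identically; each run writes a JSON manifest with config, input hashes,
seeds and per-stage status.

## Layout

```
src/jellytroph/     library (datamodel, io, selectivity, isotopes, mixing,
                    fatty_acids, permstats, synth, pipeline, cli)
examples/           one narrative script per capability
tests/              pytest suite (unit, property and end-to-end tests)
docs/methods.md     models, assumptions, numerical choices, limitations
```
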