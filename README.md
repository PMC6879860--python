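# stressmet

Systems modeling of neuroendocrine–metabolic dysregulation: a declarative
ODE modeling framework with metabolic control analysis, plus a cohort
statistics and causal/mediation pipeline, exercised end-to-end on a
reduced integrated reference model and synthetic cohorts with known
ground truth.

## What's inside

| module | purpose |
| --- | --- |
| `stressmet.kinetics` | semi-empirical rate-law building blocks: saturation, allosteric activation/deactivation/product-inhibition, Hill-type signaling/transcription multipliers, passive & facilitated transport |
| `stressmet.model` | declarative YAML model specs, mass-balance RHS assembly, stiff integration to steady state with root polish, trajectory simulation with step inputs and clamps, qualitative scenario checks; ships a reduced 30-species integrated reference model (HPA axis + inflammation + regulatory signaling + core metabolism) |
| `stressmet.mca` | finite-perturbation metabolite concentration response coefficients (0.5x/1.5x folds, glycogen clamp), parameter screening (per-feature ≥ 0.001, cumulative ≥ 0.1), dysfunction-signature matching (12-feature core / 16-feature extended), trichotomized regulatory-state matrices at a 1% threshold |
| `stressmet.stats` | log + median normalization, Mann–Whitney U (exact enumeration for combined n ≤ 20, tie-corrected asymptotic otherwise), Storey q-values with BH fallback, Cohen's d, Spearman correlation maps, between-group correlation fold change capped at 4 |
| `stressmet.causal` | entropy-balancing weights for continuous exposures, weighted log-log ACE with sandwich errors, simulated-confounder sensitivity scan (tau1/tau2), natural-effects mediation with a joint mediator complex (psi_d/psi_i/psi_t, bootstrap CIs) |
| `stressmet.synth` | synthetic two-group cohorts (83/82 by default) with linear-Gaussian log-scale structure and closed-form causal truth; signature-shifted cohorts; toy models with analytic steady states |

## CLI

```bash
stressmet steady --out steady.csv                      # reference model steady state
stressmet simulate --scenario stress_step --out out/   # trajectory + scenario check
stressmet mca --params n_gr_central,nx_gr_cytokine --signature extended16 --out out/
stressmet synth cohort --seed 1 --out cohort.csv       # + cohort.truth.json
stressmet stats group-diff --table cohort.csv --out out/
stressmet stats corr --table cohort.csv --components cortisol_suppression,HOMA_IR --subset all --out out/
stressmet causal ace --table cohort.csv --out ace.csv
stressmet causal mediate --table cohort.csv --boot 500 --seed 1 --out out/
stressmet pipeline --seed 7 --out out/                 # synth -> stats -> corr -> ACE -> mediation
```

`--model FILE` accepts any YAML model document in the same schema as the
shipped reference model (`src/stressmet/models/reference.yaml`); the
framework accepts full-size specs unchanged.

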