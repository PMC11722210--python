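# tsselect

Entropy-based model selection for ODE models calibrated against
time-stamped snapshot (TSS) single-cell data.

Single-cell technologies such as CyTOF measure protein abundances in
thousands of cells but cannot track an individual cell over time: the
population observed at time *t* is disjoint from the population observed at
time 0. `tsselect` is for modellers who want to decide, from such unpaired
snapshots, which of several mechanistic mass-action ODE models best explains
the signalling kinetics — when cell-to-cell variability comes from random
initial conditions (extrinsic noise) and no likelihood is available.

## Method

For candidate models *h₁ ⊂ h₂ ⊂ h₃* (nested by rate constraints), the
package:

1. estimates each candidate's free rates **θ̃ᵢ** by the generalized method
   of moments — matching means, variances and covariances of the observed
   time-*t* cells (a 20% estimation split) against the candidate pool of
   time-0 cells evolved to *t*;
2. builds each candidate's predictive density **ĥᵢ** via Sklar's theorem:
   log-scale Gaussian-kernel marginals composed with a Gaussian copula
   fitted on rank pseudo-observations;
3. scores each candidate by its **approximate cross-entropy** on the
   held-out 80% evaluation split,

   ACEᵢ = (1/𝒩) Σⱼ −log ĥᵢ(yⱼ | θ̃ᵢ),

   and selects the minimizer — equivalent to minimum Kullback–Leibler
   divergence, since the truth's entropy is candidate-independent;
4. cross-checks with an approximate AICc on observed-minus-predicted mean
   abundances, and quantifies support by bootstrap model-selection
   probabilities (the fraction of resamples in which each candidate attains
   the minimum ACE).

The bundled system is a minimal six-species NK-cell signalling network
(Syk, Vav1, Syk:Vav1, pVav1, SHP1, SHP1:pVav1) with three free rates, three
rates fixed at 0.12/0.14/0.05 1/s, and nesting constraints θ₂ = 9θ₁ and
θ₃ = 2θ₁. Alternative topologies load from a YAML file. See
`docs/methods.md` for the model, estimators and all numerical choices.

## Worked example

Simulate the MEDIUM scenario (ground truth = middle candidate, 8,000 cells,
t = 1.5 s) and run selection plus a 200-resample bootstrap:

```python
from tsselect.selection import run_scenario_bootstrap

bundle, report, boot = run_scenario_bootstrap("MEDIUM", seed=1, B=200)
print(dict(zip(report.candidate_ids, report.ace.round(3))))
print("selected by ACE :", report.selected_by_ace)
print("selected by AICc:", report.selected_by_aicc)
print(dict(zip(boot.candidate_ids, boot.selection_probabilities)))
```

prints

```
{1: 43.26, 2: 34.915, 3: 34.915}
selected by ACE : 2
selected by AICc: 2
{1: 0.0, 2: 0.96, 3: 0.04}
```

Reading: candidate 1 (over-constrained) pays ~8.3 nats of cross-entropy for
its misspecified θ₃ constraint; candidates 2 and 3 fit almost equally well
because model 3 nests model 2, and the tie breaks toward the more
parsimonious correct model. Across 200 bootstrap resamples the generating
model CM2 is selected 96% of the time.

The same pipeline is available from the shell:

```sh
tsselect simulate  --config run.yaml --out data/
tsselect select    --config run.yaml --data-dir data/ --out report.json
tsselect bootstrap --config run.yaml --data-dir data/ -B 200 --out boot/
```

Exit codes: 0 success, 2 config error, 3 data error, 4 numerical failure.

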