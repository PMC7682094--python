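# tallevo

Clonal evolution of adult T-cell acute lymphoblastic leukemia (T-ALL)
relapse, as a tested, reproducible pipeline. Paired primary/relapse tumor
genomes raise three quantitative questions that this package answers:

1. **When did the relapse clone split from the primary clone?**
   Clock-like SBS5 mutations accrue in blood at a near-constant healthy rate
   (~12.21 / year), accelerating upon malignization. From the counts of
   clonal SBS5 mutations private to the primary (*P*), private to the
   relapse (*R*), and shared (*S*), the divergence time is inferred under
   two bracketing acceleration models — a one-off jump to a constant rate μ,
   `N(t*) = N(t_n) + μ·(t* − t_n)`, and a per-day compounding increase *r*,
   `N(t*) = N(t_n)·(1+r)^(t*−t_n)` — over a grid of 120 acceleration times
   spanning the 10 years before diagnosis. Each hypothesis gets a
   simulation-based likelihood from 100 stochastic mutation curves
   (`N(t_m) ~ N(t_{m−1}) + BetaBinom(μ(t_m), ρ, 1)`, ρ = 2·10⁻⁴), a
   cohort-level Bayes posterior reweights the grids, and inverting the mean
   curve at *S* gives days-before-diagnosis estimates.
2. **How fast does the leukemic population grow, and how large was the
   relapse clone at diagnosis?** Blast fractions follow a logistic
   σ(t, a) = (1 + e^(−at))⁻¹ with doubling time T_D = ln 2 / a. Because
   clinical time annotations carry per-patient errors Δt_i, (a, Δt_1..Δt_n)
   are fitted jointly by multi-start cross-entropy minimization. The relapse
   clone seen at marrow fraction *f*, Δt days after diagnosis, back-projects
   to N_d = N_B · f · 2^(−Δt/T_D) cells at diagnosis (N_B ≈ 7.5·10¹¹).
3. **Is relapse driven by a genetic resistance mutation?** A clone-based
   Wright-Fisher simulator (10⁶ cells, per-site mutation rate 10⁻⁸, 100
   driver positions at selection 0.01, 150,000 neutral passenger positions)
   evolves a primary leukemia, applies treatment as a bottleneck — random
   survival vs. survival of the carriers of one low-frequency passenger
   "resistance" marker — regrows it, and compares the primary CCF
   distribution of mutations fixed at relapse. Only the resistant scenario
   fixes mutations that were undetectable (CCF < 0.1) in the primary.

The patient data behind the original analysis is access-controlled, so a
first-class synthetic-cohort module generates every input with known ground
truth; all recovery claims are tested against that truth.

## Worked example

```sh
tallevo run-all --out demo/ --seed 42
```

runs, at demo scale, the full chain — synthetic cohort → purity/CCF/clonality
annotation → SBS5 branch counts → divergence-time grids → doubling-time fit →
relapse-scenario simulation — and prints a report like:

```
Doubling time T_D = 11.04 d (Q1-Q3 11.04-11.04)

Per-patient divergence (days pre-diagnosis) and relapse-clone size:
  SYN1: divergence   174.7 d, N_d 624 cells, present at diagnosis
  SYN4: divergence   277.8 d, N_d 0.0721 cells, possibly absent at diagnosis
  SYN5: divergence   233.9 d, N_d 1.41e+08 cells, present at diagnosis
  ...
Scenario verdict (low-bin mass of relapse-fixed mutations):
  resistant: 1.000
  non_resistant: 0.000
```

Reading it: the cohort's blast growth implies a ~11-day doubling time; each
patient's relapse clone diverged the stated number of days before diagnosis
and back-projects to N_d cells at diagnosis (above one cell ⇒ the clone
predated treatment); and only the genetic-resistance scenario puts mass in
the lowest CCF bin, the signature observed in patients.

Every stage is also a library call (`tallevo.divergence_clock.estimate_cohort`,
`tallevo.doubling_time.fit_doubling_time`, `tallevo.wf_simulator.run_scenario`,
…) and a separate subcommand (`synth`, `clonality`, `divtime`, `doubling`,
`simulate`, `validate`).

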