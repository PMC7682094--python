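# Methods

This note documents the models implemented in `tallevo`, the defaults and
why they were chosen, the numerical decisions, and the known limits of what
the synthetic cohort can demonstrate.

## Clock-like mutation accumulation

SBS5 single-base substitutions behave as a molecular clock in blood. The
healthy baseline is a deterministic line: `N(t) = intercept + slope·t`, with
slope 12.21 mutations/year (the healthy hematopoietic regression) and
intercept 0 by default; ages are converted at 365.25 days/year everywhere.

Stochastic curves add one day at a time. The daily increment is
beta-binomial with mean μ(t), intra-class correlation ρ = 2·10⁻⁴ (the
overdispersion observed in healthy hematopoietic stem cells), and one trial
per step. With a single trial the beta mixture integrates out exactly — the
increment is Bernoulli(μ) regardless of ρ — and a day whose mean exceeds 1
is split into ⌈μ⌉ equal Bernoulli substeps, which is exactly one
Binomial(⌈μ⌉, μ/⌈μ⌉) draw. The code uses these identities as fast paths;
they are equalities, not approximations. The general beta-binomial
(mean, ρ, n trials) parameterization is implemented and property-tested for
n > 1, where ρ does matter.

## Divergence clock

Per patient the data are (P, S, R): clonal SBS5 counts private to primary,
shared, private to relapse, plus the two sampling ages. Hypotheses are grid
cells (model, t_n) — model ∈ {constant, linear}, t_n one of 120 evenly
spaced acceleration times covering the 10 years before diagnosis, both ends
inclusive. The accelerated rate is solved in closed form so the mean curve
passes through N(t*), the mean of the primary total (S+P) and the relapse
total (S+R), at t*, the midpoint of the two sampling ages:
μ = (N(t*) − N(t_n))/(t* − t_n) for the constant model and
r = (N(t*)/N(t_n))^(1/(t*−t_n)) − 1 for the linear model. The leukemic rate
can only exceed the healthy baseline, so hypotheses implying μ below the
baseline daily rate (or a non-positive r) are infeasible; they keep
likelihood 0 rather than being dropped, so grids stay aligned across
patients. Note that for the constant model feasibility is the same at every
t_n: it reduces to the patient showing an SBS5 excess over baseline at t*.

For each feasible cell, 100 stochastic curves start at the baseline count at
t_n and run through both sampling ages; the likelihood is the product of
Gaussian-KDE densities (Silverman bandwidth with a floor of 0.5 counts, so
degenerate zero-variance simulations stay well-defined) of the simulated
counts evaluated at the observed primary and relapse totals. A product of
marginals is used rather than a joint density over the two counts; the two
observations come from the same simulated lineage, so this discards their
correlation — a deliberate simplification, configurable only by replacing
the likelihood function.

Cohort pooling: each patient's likelihood profile is normalized and the
profiles are combined by a geometric mean in log space (an arithmetic mean
is available), giving a posterior over grid cells under a uniform prior.
Per-patient estimates are the likelihood-weighted (optionally
posterior-reweighted, the default) mean of the per-cell divergence times
over the top 10% of positive-weight cells; the truncation guards against a
long tail of poorly fitting scenarios dragging the mean.

Divergence per cell inverts the deterministic mean curve at S: on the
baseline segment if S is below the count at t_n, otherwise on the
accelerated segment; the result is clipped to [0, age at diagnosis]. When
S ≥ the primary total the divergence is 0 days.

Per-patient random streams are seeded from (seed, CRC32(patient id)), so
results are independent of patient ordering and bit-reproducible.

Under the default operating point (19 patients, truth: constant model,
acceleration 730 d before diagnosis at 1 mutation/day, divergence 365 d),
the cohort-median absolute error of the recovered divergence is ~10 days
and the generating grid cell is the posterior mode (see
`tests/test_acceptance.py`).

## Doubling time and relapse-clone size

Blast fractions follow σ(t, a) = (1+e^(−at))⁻¹ with t = 0 at the 50%
crossing; T_D = ln 2/a. Each patient contributes two (annotated time,
fraction) points sharing one annotation error Δt_i. The loss is the summed
cross-entropy −Σ_i [C(y_i0; t_i0; Δt_i) + C(y_i1; t_i1; Δt_i)] with
C(y; t; Δt) = y·log σ(t−Δt, a) + (1−y)·log(1−σ(t−Δt, a)); fractions of
exactly 0 or 1 (e.g. "0% blasts at remission") are clamped to
[10⁻⁴, 1−10⁻⁴], matching minimal-residual-disease detection limits.

Optimization is multi-start L-BFGS-B over (log a, Δt_1..Δt_n): 50 starts by
default, a ~ LogUniform(ln2/100, ln2/2) per day, Δt ~ Normal(0, 30 d). The
loss is invariant to shifting every annotated time together with every
offset; by default offsets are projected to mean zero inside the loss
(`anchor="zero_mean"`), which fixes that reporting gauge and is exact when
annotation errors are centered, as the generator's are; `anchor="free"` is
available. Strictly, given fixed data the parameters are identifiable even
without the anchor (each patient's two points over-determine its single
offset), so the anchor is a convention rather than a necessity. The (Q1, Q3)
of T_D across converged starts is reported as the interval; on easy
problems all starts coincide and the interval collapses.

N_d = N_B · f · 2^(−Δt/T_D) back-projects the relapse clone (marrow
fraction f at relapse, Δt days after diagnosis) to diagnosis, with
N_B = 7.5·10¹¹ bone-marrow cells by default (7·10¹¹ appears as an
alternative figure in the source literature; it is a function argument).
The biopsy fraction used is the relapse biopsy's, consistent with
back-projection from the relapse observation. Detectability flags compare
N_d with one cell, with the ~1:10,000 digital-PCR resolution, and with the
0.01% (~10⁸ cells) clinical-relapse threshold.

## Wright-Fisher relapse scenarios

State is clone-based: each mutation event founds a clone; genealogy lives in
an append-only store (one row per event), so a clone's mutation set is its
ancestor chain and mutation frequencies are subtree sums. All sampling is
exact — multinomial offspring counts proportional to clone size × fitness at
carrying capacity, multivariate hypergeometric bottlenecks, binomial
branching during regrowth — with no diffusion approximation.

Defaults: 10⁶ cells, per-site mutation rate 10⁻⁸ per cell per generation,
100 driver positions (selection coefficient 0.01 each, multiplicative
across drivers, additive available), 150,000 neutral passenger positions,
5000 burn-in generations, bottleneck removing Uniform(9·10⁴, 10⁶) cells,
regrowth for 20/40/60 generations (40 matches the doubling-time module's
Δt/T_D for typical diagnosis-relapse intervals). Regrowth doubles the
population per generation — each cell leaves Binomial(4, w/2w̄) offspring,
mean 2 per relative fitness unit — capped at carrying capacity by
hypergeometric downsampling, after which Wright-Fisher resampling resumes;
mutation continues throughout. The resistant bottleneck picks one passenger
with population frequency in (10⁻⁴, 10⁻²) uniformly as the resistance
marker and keeps exactly its carriers.

Mutation events are infinite-alleles: every event is a distinct mutation,
with a position label drawn uniformly from its namespace, and positions may
recur. A literal one-mutation-per-position rule is impossible at these
parameters (~1.5·10³ events per generation against 150,100 positions would
exhaust the pool within ~100 generations and extinguish all standing
variation), so the position counts act as rate multipliers. Fixation is
counted per position with the same criterion used for the primary/relapse
comparison — a position is fixed when the fraction of cells carrying a
mutant allele at it exceeds 0.9 — and independent origins at the same
position are merged by an exact union over the genealogy (soft sweeps
count).

**What fixation can reach under this model.** Every mutation shared by
(essentially) the whole population must lie on the ancestral line of
descent of the final population's (90%-)common ancestor, and mutations
arrive on any line at the per-cell rate μ·L = 10⁻⁸·150,000 = 1.5·10⁻³ per
generation. The expected number of fixed passengers in 5000 generations is
therefore bounded by ~7.5 — independent of population size, selection on
linked drivers, and offspring-distribution details — and measured values
are 0–8. Driver fixation is set by the rate of adaptation under clonal
interference and lands at ~2–8 per burn-in, consistent with the
multiple-mutations-regime estimate v/s ≈ 10⁻³ drivers per generation along
the winning lineage. Fixed-passenger counts in the hundreds are not
attainable under these parameter values in any Wright-Fisher model with
this mutation input; the simulator reports what the model actually
produces.

The scenario discriminator is robust to all of this: across full-scale
replicates, random-survivor bottlenecks never fix a mutation whose primary
CCF was below 0.1, while resistant bottlenecks always do (the marker and
its hitchhikers), giving the bimodal primary-CCF histogram of relapse-fixed
mutations seen in patients.

## Synthetic cohort

The generator forward-simulates what the protected patient data would
provide. Defaults, chosen once as the study conditions: 19 patients aged
20–65 at diagnosis; healthy clock slope 12.21/yr; constant-model
acceleration starting 1–6 years before diagnosis at 0.3–1.5 mutations/day
(the leukemic regression's ~400-mutation excess intercept accumulated over
1–2 years of acceleration); divergence 90–540 days before diagnosis;
relapse 120–540 days after diagnosis (relapse typically follows within
several months to a year and a half in adult T-ALL); blast-growth truth
a = ln 2/10.79 per day; 10-day annotation-error SD; logit-scale fraction
noise SD 0.25 (logit noise keeps fractions in (0,1) and the logistic model
well-specified). Read tables use purity 0.7–0.95, mean depth 80×, copy
number 2, a clonal peak at CCF 1 plus one subclone at CCF 0.15–0.4.

Branch counts are generated by simulating one lineage from birth,
duplicating it at the divergence age, and running both branches to their
sampling ages, so `primary total = shared + primary-private` holds exactly
and divergence may precede or follow acceleration onset. Per-patient seeds
are the cohort seed plus a fixed stride (7919·i), so any patient can be
regenerated in isolation.

What the generator does **not** emulate: trinucleotide contexts and
signature deconstruction (mutations are SBS5 by labeled construction),
copy-number heterogeneity beyond a fixed CN, sequencing artifacts, sample
contamination, multi-subclone architectures, or treatment mutagenesis.
Passing recovery tests therefore demonstrate correctness of the inference
under the stated generative model, not robustness to every failure mode of
real sequencing data.

## Purity and clonality

Purity is the mode of a Silverman-bandwidth Gaussian KDE of VAF × CN,
searched on (0.1, 1.1] to avoid the subclonal shoulder, clipped to (0, 1];
at least 30 covered mutations are required. CCF = VAF·CN/purity, clipped to
[0, 2] (no separate normal-contamination copy term: the cohorts modeled are
essentially diploid). The clonal read-count model is a beta-binomial fitted
by method of moments to mutations within ±0.1 of the purity mode; each
mutation's one-sided lower-tail probability under that model (subclonality
means too *few* alt reads) is compared with the threshold, 0.01 by default
(0.05 accommodates more complex clonal structures). The density-vs-tail and
sidedness choices are not dictated by the source analysis; both the
threshold and the fitted parameters are exposed.

## Problem sizes and determinism

Default test and acceptance runs use: 10 full-scale burn-in replicates
(each ~13 s), 20 bottleneck/regrowth replicates reusing them, 20 blast
cohorts of 20 patients, and 5 divergence-clock cohorts of 19 patients at
the full 120-point × 100-curve grid — sizes chosen so a complete run stays
in the minutes range on a single CPU while keeping Monte-Carlo standard
errors well inside the asserted tolerances. Every stochastic component
takes an explicit seed; fixed seeds reproduce results bit for bit, and
cohort results are invariant to patient ordering.
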