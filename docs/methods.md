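# Methods

## Model

Autophagic vesicle turnover is modelled as a linear three-step chain.
Isolation-membrane material enters the autophagosome (AP) pool at a constant
influx *J* (vesicles per hour); the isolation-membrane concentration and its
maturation rate constant only ever appear as a product, so they are lumped
into the single parameter *J* and are not separately identifiable. APs
convert to autolysosomes (ALs) at rate constant β (h⁻¹; amphisomes are
folded into the AL pool) and ALs are degraded at rate constant γ (h⁻¹):

    dAP/dt = J − β·AP,   dAL/dt = β·AP − γ·AL.

Assumptions: first-order kinetics with time-invariant parameters over the
observation window; no spatial structure; pools are continuous expected
counts (discreteness enters only through the observation model); the free
lysosome pool is not modelled, since it appears in no rate equation — β
already absorbs lysosome availability.

At steady state AP = J/β, AL = J/γ, the flux through every step equals *J*,
and AP/AL = γ/β exactly. The linear chain has a closed-form solution; the
repeated-eigenvalue case β = γ is handled by its own secular-term limit
(t·e^(−βt)), never by perturbing parameters. A numerical integrator
(LSODA, rtol 1e−10/atol 1e−12) is kept alongside purely as a cross-check;
the two agree to < 1e−6 absolute over 0–48 h across 1000 random parameter
sets spanning rate constants 0.05–20 h⁻¹.

Time is in hours throughout because the assay's read-out is two hours after
BafA injection.

## BafA perturbation and classification

BafA (a V-ATPase inhibitor) is modelled as multiplicative factors
(f_β, f_γ) on the rate constants with *J* unchanged — both arms use animals
of the same genotype and age, so upstream supply is assumed common. Under
that assumption the steady-state algebra inverts exactly:
f_β = AP_control/AP_BafA, f_γ = AL_control/AL_BafA. This inversion is exact
(machine precision) by construction and is round-trip-tested against the
forward model.

"No change" is operationalised as a two-group Poisson rate-ratio test at
α = 0.01 per pool (configurable); the weakest significance tier reported for
this kind of count data is p < 0.01. The classification is total over the
3×3 direction grid: (none, none) → blocked; (increase, decrease) → active /
complete acidification block; (increase, increase) → active / partial
(impaired hydrolase activity lets ALs accumulate); all other combinations →
active / other.

The assay premise that pools re-equilibrate by the 2-hour read-out is
checked in-model rather than assumed: `equilibration_fraction` computes how
far each pool has travelled toward its new steady state (sup-norm relative
to the total excursion), and `is_equilibrated` flags regimes below 95%.
Notably, for the canonical parameters (J=12, β=4, γ=2 under BafA folds
1/3, 1/2) the slow AL pool is only ~60% equilibrated at 2 h — equilibration
can genuinely vary with background, tissue and age, and this diagnostic
makes the caveat quantitative.

## Identifiability

For any fixed positive pools and any assumed flux, β = J/AP and γ = J/AL
reproduce the pools exactly; the scenario table tabulates this for candidate
fluxes (canonically 12, 24, 6 on pools AP=3, AL=6). The statistical
counterpart profiles the Poisson log-likelihood of steady-state-only counts
over flux, maximising over (β, γ) at each value: the profile is flat to
optimiser tolerance (~1e−13 spread in practice).

Flux becomes identifiable from transient data. `fit_timecourse` maximises a
Poisson likelihood of animal-level counts around the deterministic
trajectory from a known initial state, in log-parameter space
(Nelder–Mead, xatol 1e−10, fatol 1e−12), with 5 multi-starts (the supplied
guess plus 4 log-normal jitters, σ = 0.5); ties within 1e−8 break toward the
smaller parameter norm. Standard errors come from the inverse observed
information (central-difference Hessian, step 1e−4, delta method back to the
natural scale); a nonparametric bootstrap (resampling animals within each
time × vesicle cell) is available behind a flag. Least squares on cell
means is retained as a cross-check loss. Fits whose Hessian condition
number exceeds 1e3 raise an ill-conditioning warning: informative time
courses sit near condition 1e2, while steady-state-only data push the
flux direction toward singularity (≥ 1e4), so the threshold separates the
two regimes by an order of magnitude on each side.

The recovery study uses the assay's own transient as the design: counts
start at the control steady state (3, 6) and relax toward the
BafA-inhibited steady state (9, 12) under truth (J, β, γ) = (12, 4/3, 1),
sampled at t = 0, 0.5, 1, 2, 4, 6 h (the relaxation time scales are
1/β′ = 0.75 h and 1/γ′ = 1 h, so the grid brackets both) with 30 animals
per time point. Median relative errors over 200 replicates are ~8–10% per
parameter; problem sizes were chosen as the smallest that make the Monte
Carlo summaries stable.

## Synthetic data

The generator emulates the study design: genotypes WT, daf-2, glp-1 (plus
blocked-autophagy labels for schema purposes), tissues intestine, muscle,
pharynx, neurons (seam cells supported in the schema), adult days 1, 3, 5,
7, 10, treatments control / BafA / rab-7 RNAi, 30 animals per design cell,
one count per animal × vesicle type. Counts are independent Poisson around
the configured mean — matching the Poisson-regression analysis — with an
optional negative-binomial dispersion knob (off by default) because real
animal-to-animal variability likely exceeds Poisson. Default mean
trajectories are configuration data loosely shaped on the study's
qualitative trends (wild-type pools rise with age, muscle APs ~9-fold from
Day 1 to Day 10, ALs exceed APs, daf-2 elevated early); they are not
measured values and carry no evidential weight. The Day 7 neuron cells can
be dropped via config to mirror the study's missing time point.

Treated arms are not free: control means are converted to implied kinetic
parameters under a baseline flux (default 12 — the treated steady state is
invariant to this choice), the treatment's perturbation is applied
(BafA default folds 1/3 and 1/2; rab-7 RNAi 0.2 on β only), and counts are
drawn around the new steady state. Colocalisation splits mCherry-positive
punctae multinomially into GFP-positive / LysoTracker-positive / neither
with default fractions (0.10, 0.75, 0.15).

What passing tests on these data do **not** show about real data: no
between-animal overdispersion (unless the knob is on), no injection or
staining variability, no tissue-area normalisation (each tissue's
observation unit is treated as one cell of the design, as in the source
assays), no imaging or counting error, and treated arms are assumed fully
equilibrated even where the 2-hour diagnostic would flag them.

## Statistics

Two-group comparisons use a Poisson GLM with log link and a single group
indicator (statsmodels IRLS); the point estimate equals the closed-form MLE
mean(b)/mean(a) and the Wald standard error equals
sqrt(1/Σa + 1/Σb), both asserted in tests. Wald inference is the default; a
likelihood-ratio test is behind a flag. Age trends are day-vs-Day-1
contrasts, computed pairwise (for a categorical-day Poisson GLM the
per-contrast MLE and Wald SE coincide with the two-group ones). No
multiple-testing correction by default — per-comparison tiers are reported —
with a Bonferroni flag on the age scan. A group with all-zero counts yields
a flagged-undefined result (NaN p-value, conservative "none" call) rather
than a silent pseudocount; a 0.5 continuity adjustment to the group totals
exists behind an explicit flag. Under the Poisson null the test's empirical
type-I error at α = 0.01 sits inside the binomial 95% band over 2000
replicates; under negative-binomial truth it is anti-conservative, which is
asserted as a documented hazard, not fixed.

Because a blocked call requires *both* the AP and the AL test to be
non-significant, the expected blocked-call rate under a truly blocked system
is (1 − α)² ≈ 0.980 at α = 0.01, slightly below 1 − α; the observed rate is
checked against that conjunction value.

## Pipeline and reproducibility

The pipeline derives one child seed per design cell from the master seed via
`SeedSequence`, so results are independent of cell ordering and bit-identical
across reruns; the manifest records the seed and a hash of the scientific
configuration (output paths and log level excluded). All outputs are plain
CSV/JSON. The library is the single computational surface: the analysis
scripts, CLI, tests and the acceptance script all call the same functions.

## Known limitations

- The model is a two-pool linear cascade: no amphisome compartment distinct
  from ALs, no lysosome-pool dynamics, no saturation or feedback.
- *J* constant under BafA is an assumption inherited from the assay logic;
  if BafA altered AP formation, the inferred f_β would absorb it.
- The fitting stage presumes a known initial state and a known perturbation
  time; misspecifying either biases the rates.
- Default trajectories and effect sizes are plausible shapes, not data;
  conclusions from the synthetic study are about the method, not the worm.
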