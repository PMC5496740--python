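# autoflux

Kinetic modelling and count statistics for autophagic-flux assays in adult
*C. elegans*.

Counting autophagosomes (APs) and autolysosomes (ALs) in a tissue gives pool
*sizes*, not pathway *activity*: a large pool can mean vigorous autophagy or
a downstream block. This package makes the kinetic reasoning behind
tandem-reporter (mCherry::GFP::LGG-1) flux assays executable: a
three-compartment turnover model, inference of rate-constant changes from
paired Bafilomycin A (BafA) experiments, a formal demonstration that
steady-state pool sizes cannot determine flux, a synthetic puncta-count
generator shaped on the adult *C. elegans* study design, and the Poisson
regression used to compare counts. It is aimed at people designing or
interpreting vesicle-count flux assays, and at anyone who wants the model's
claims as testable code.

## The model

Isolation-membrane material forms APs at a constant rate *J* (vesicles/h),
APs mature into ALs with rate constant β (h⁻¹), and ALs are degraded with
rate constant γ (h⁻¹):

    dAP/dt = J − β·AP
    dAL/dt = β·AP − γ·AL

At steady state **AP = J/β**, **AL = J/γ**, and the flux through every step
equals *J* (J = AP·β = AL·γ). Three consequences drive everything here:

1. **Pool ratio:** AP/AL = γ/β, so the ubiquitous observation AP < AL
   implies γ < β (AL turnover is rate limiting).
2. **BafA inversion:** BafA lowers β and γ multiplicatively while leaving
   *J* unchanged, so rate fold-changes are the *inverse* of pool
   fold-changes — a 3-fold AP rise and 2-fold AL rise mean β fell 3-fold and
   γ fell 2-fold.
3. **Non-identifiability:** any assumed flux *J* reproduces fixed pools
   exactly via β = J/AP, γ = J/AL. Pool snapshots carry no flux
   information; only out-of-steady-state (time-course) data determine
   (J, β, γ).

The flux-assay decision logic follows: no significant change in either pool
after BafA ⇒ autophagy blocked; a change in either ⇒ active, with AP-up /
AL-down labelled *complete* acidification block and AP-up / AL-up *partial*.

## Worked example

```python
from autoflux import (KineticParameters, PoolState, steady_state_pools,
                      infer_rate_fold_changes, rates_from_pools)

params = KineticParameters(influx_J=12, beta=4, gamma=2)
print(steady_state_pools(params))
# PoolState(ap=3.0, al=6.0)

pert = infer_rate_fold_changes(control=PoolState(1, 1), bafa=PoolState(3, 2))
print(1 / pert.f_beta, 1 / pert.f_gamma)
# 3.0 2.0        <- BafA cut beta 3-fold and gamma 2-fold

for flux in (12, 24, 6):
    s = rates_from_pools(PoolState(3, 6), flux)
    print(flux, s.beta, s.gamma)
# 12 4.0 2.0     <- three different fluxes, one observed pool pair:
# 24 8.0 4.0        doubling or halving J just co-scales beta and gamma,
# 6  2.0 1.0        so the snapshot cannot tell them apart
```

The numbered scripts under `analysis/` run the full synthetic study:

```
python analysis/01_generate_counts.py   # study-shaped count dataset
python analysis/02_age_trends.py        # day-vs-Day-1 Poisson contrasts
python analysis/03_flux_assay.py        # paired BafA assay + classification
python analysis/04_identifiability.py   # scenario table + profile likelihood
```

`03_flux_assay.py`, for example, prints (seed 0):

```
wrote results/flux_assay: 60 design cells
flux_status  inhibition_pattern
active       partial               60
  median inferred beta fold-decrease: 3.04 (truth 3.00)
  median inferred gamma fold-decrease: 2.05 (truth 2.00)
```

— every cell of the active-autophagy design is called active with the
partial (AP-up/AL-up) pattern, and inverting the pool changes recovers the
rate folds the generator embedded. The same pipeline is available as a CLI
(`autoflux flux`, `autoflux identify`, …) with `--config/--seed/--out/--alpha`.

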