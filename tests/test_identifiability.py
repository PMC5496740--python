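"""Pool snapshots underdetermine flux; time courses determine it."""

import numpy as np
import pandas as pd
import pytest

from autoflux import (
    KineticParameters,
    PoolState,
    closed_form_timecourse,
    fit_timecourse,
    profile_flux_loglik,
    rates_from_pools,
    scenario_frame,
    scenario_table,
    steady_state_pools,
)
from autoflux.identifiability import IllConditionedWarning


@pytest.mark.parametrize(
    "flux,beta,gamma",
    [(12.0, 4.0, 2.0), (24.0, 8.0, 4.0), (6.0, 2.0, 1.0)],
)
def test_rates_from_pools_scenarios(canonical_pools, flux, beta, gamma):
    """Pools (3, 6) are consistent with flux 12, 24 or 6 via co-scaled rates."""
    scen = rates_from_pools(canonical_pools, flux)
    assert scen.beta == pytest.approx(beta)
    assert scen.gamma == pytest.approx(gamma)
    back = steady_state_pools(
        KineticParameters(scen.assumed_flux, scen.beta, scen.gamma)
    )
    assert back == canonical_pools


def test_scenario_table_shares_identical_pools(canonical_pools):
    rows = scenario_table(canonical_pools, [12.0, 24.0, 6.0])
    assert len(rows) == 3
    triples = {(r.assumed_flux, r.beta, r.gamma) for r in rows}
    assert len(triples) == 3  # three distinct parameter triples ...
    for r in rows:  # ... all reproducing the same observation
        back = steady_state_pools(KineticParameters(r.assumed_flux, r.beta, r.gamma))
        assert back == canonical_pools


def test_scenario_table_edge_sizes(canonical_pools):
    assert len(scenario_table(canonical_pools, [7.5])) == 1
    assert scenario_table(canonical_pools, []) == []
    frame = scenario_frame(canonical_pools, [])
    assert len(frame) == 0


def test_zero_pools_rejected():
    with pytest.raises(ValueError):
        rates_from_pools(PoolState(0.0, 6.0), 12.0)
    with pytest.raises(ValueError):
        rates_from_pools(PoolState(3.0, 6.0), 0.0)


def test_any_positive_pools_never_constrain_flux(rng):
    """For random pools and random fluxes the reconstruction is always exact."""
    for _ in range(200):
        pools = PoolState(rng.uniform(0.1, 30), rng.uniform(0.1, 30))
        flux = rng.uniform(0.1, 100)
        scen = rates_from_pools(pools, flux)
        back = steady_state_pools(
            KineticParameters(scen.assumed_flux, scen.beta, scen.gamma)
        )
        assert back.ap == pytest.approx(pools.ap, rel=1e-14)
        assert back.al == pytest.approx(pools.al, rel=1e-14)


def _timecourse_counts(truth, init, times, n_per_time, rng):
    traj = closed_form_timecourse(truth, init, times)
    frames = []
    for t, mu_ap, mu_al in zip(times, traj.ap, traj.al):
        frames.append(
            pd.DataFrame(
                {
                    "time": t,
                    "vesicle": ["AP"] * n_per_time + ["AL"] * n_per_time,
                    "count": np.r_[
                        rng.poisson(mu_ap, n_per_time), rng.poisson(mu_al, n_per_time)
                    ],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


BAFA_TRUTH = KineticParameters(12.0, 4.0 / 3.0, 1.0)
BAFA_INIT = PoolState(3.0, 6.0)
BAFA_TIMES = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 6.0])


class TestFitTimecourse:
    def test_zero_noise_limit_recovers_exactly(self):
        """Feeding the exact trajectory means returns the truth."""
        traj = closed_form_timecourse(BAFA_TRUTH, BAFA_INIT, BAFA_TIMES)
        df = pd.concat(
            [
                pd.DataFrame(
                    {"time": [t, t], "vesicle": ["AP", "AL"], "count": [a, l]}
                )
                for t, a, l in zip(BAFA_TIMES, traj.ap, traj.al)
            ],
            ignore_index=True,
        )
        for loss in ("poisson", "lsq"):
            fit = fit_timecourse(
                df, KineticParameters(5.0, 0.5, 0.3), BAFA_INIT,
                loss=loss, se_method="none",
            )
            assert fit.converged
            assert fit.estimate.influx_J == pytest.approx(12.0, rel=1e-4)
            assert fit.estimate.beta == pytest.approx(4 / 3, rel=1e-4)
            assert fit.estimate.gamma == pytest.approx(1.0, rel=1e-4)

    def test_noisy_recovery_within_tolerance(self, rng):
        """A handful of Poisson-noised replicates land near the truth."""
        errs = []
        for _ in range(10):
            df = _timecourse_counts(BAFA_TRUTH, BAFA_INIT, BAFA_TIMES, 30, rng)
            fit = fit_timecourse(
                df, KineticParameters(8.0, 2.0, 0.5), BAFA_INIT, se_method="none"
            )
            e = fit.estimate
            errs.append(
                [
                    abs(e.influx_J - 12) / 12,
                    abs(e.beta - 4 / 3) / (4 / 3),
                    abs(e.gamma - 1.0),
                ]
            )
        assert np.median(np.asarray(errs), axis=0).max() < 0.15

    def test_bias_shrinks_with_sample_size(self, rng):
        """Mean absolute parameter error decreases as animals per time grow."""
        mean_err = []
        for n in (10, 30, 100):
            errs = []
            for _ in range(8):
                df = _timecourse_counts(BAFA_TRUTH, BAFA_INIT, BAFA_TIMES, n, rng)
                fit = fit_timecourse(
                    df, KineticParameters(8.0, 2.0, 0.5), BAFA_INIT,
                    n_starts=2, se_method="none",
                )
                e = fit.estimate
                errs.append(
                    abs(e.influx_J - 12) / 12
                    + abs(e.beta - 4 / 3) / (4 / 3)
                    + abs(e.gamma - 1.0)
                )
            mean_err.append(np.mean(errs))
        assert mean_err[2] < mean_err[0]

    def test_standard_errors_are_positive_and_calibrated(self, rng):
        df = _timecourse_counts(BAFA_TRUTH, BAFA_INIT, BAFA_TIMES, 30, rng)
        fit = fit_timecourse(df, KineticParameters(8.0, 2.0, 0.5), BAFA_INIT)
        for name, true in (("influx_J", 12.0), ("beta", 4 / 3), ("gamma", 1.0)):
            se = fit.stderr[name]
            assert np.isfinite(se) and se > 0
            # truth within a generous Wald interval
            est = getattr(fit.estimate, name)
            assert abs(est - true) < 5 * se

    def test_bootstrap_se_agrees_in_magnitude(self, rng):
        df = _timecourse_counts(BAFA_TRUTH, BAFA_INIT, BAFA_TIMES, 30, rng)
        obs = fit_timecourse(df, KineticParameters(8.0, 2.0, 0.5), BAFA_INIT)
        boot = fit_timecourse(
            df, KineticParameters(8.0, 2.0, 0.5), BAFA_INIT,
            se_method="bootstrap", n_boot=30,
        )
        for name in ("influx_J", "beta", "gamma"):
            assert 0.2 < boot.stderr[name] / obs.stderr[name] < 5.0

    def test_too_few_time_points_rejected(self):
        df = pd.DataFrame(
            {"time": [0.0, 0.0, 1.0, 1.0], "vesicle": ["AP", "AL"] * 2,
             "count": [3, 6, 4, 7]}
        )
        with pytest.raises(ValueError, match="3 distinct time"):
            fit_timecourse(df, BAFA_TRUTH, BAFA_INIT)

    def test_steady_state_only_data_warns_ill_conditioned(self, rng):
        """Flat data cannot fix the flux scale; the fit must say so."""
        frames = [
            pd.DataFrame(
                {
                    "time": t,
                    "vesicle": ["AP"] * 20 + ["AL"] * 20,
                    "count": np.r_[rng.poisson(3, 20), rng.poisson(6, 20)],
                }
            )
            for t in (0.0, 1.0, 2.0, 3.0)
        ]
        with pytest.warns(IllConditionedWarning):
            fit_timecourse(
                pd.concat(frames, ignore_index=True),
                KineticParameters(12.0, 4.0, 2.0),
                PoolState(3.0, 6.0),
                n_starts=1,
            )


def test_profile_likelihood_is_flat_on_steady_state_data(rng):
    """Steady-state-only counts give the same maximised likelihood at flux
    6, 12 and 24 (and anything between): the statistical non-identifiability."""
    ap = rng.poisson(3.0, 60)
    al = rng.poisson(6.0, 60)
    prof = profile_flux_loglik(ap, al, [6.0, 12.0, 24.0, 48.0])
    spread = prof["loglik"].max() - prof["loglik"].min()
    assert spread < 1e-6
    # the optimised rates co-scale with the assumed flux
    ratios = prof["beta_hat"] / prof["flux"]
    assert ratios.max() - ratios.min() < 1e-6
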