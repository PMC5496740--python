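"""The synthetic puncta-count generator and its statistical contracts."""

import numpy as np
import pytest

from autoflux import (
    GeneratorConfig,
    PoolState,
    default_config,
    generate_colocalization,
    generate_count_dataset,
    generate_flux_assay,
    infer_rate_fold_changes,
)
from autoflux.bafa import Perturbation
from autoflux.simulate import COUNT_COLUMNS, ConfigError, DAYS


def single_cell_config(mean_ap=5.0, mean_al=10.0, n=30, **kw) -> GeneratorConfig:
    traj = {
        ("WT", "intestine", "AP"): {d: mean_ap for d in DAYS},
        ("WT", "intestine", "AL"): {d: mean_al for d in DAYS},
    }
    return GeneratorConfig(mean_trajectories=traj, n_animals_per_cell=n, **kw)


def test_same_seed_gives_identical_tables():
    cfg = default_config(n_animals_per_cell=5, seed=42)
    a = generate_count_dataset(cfg)
    b = generate_count_dataset(cfg)
    assert a.equals(b)
    c = generate_count_dataset(default_config(n_animals_per_cell=5, seed=43))
    assert not a["count"].equals(c["count"])


def test_schema_and_design_coverage():
    """Default design: 3 genotypes x 4 tissues x 5 days x 2 vesicle types."""
    df = generate_count_dataset(default_config(n_animals_per_cell=2))
    assert list(df.columns) == COUNT_COLUMNS
    assert df["genotype"].nunique() == 3
    assert df["tissue"].nunique() == 4
    assert sorted(df["day"].unique()) == [1, 3, 5, 7, 10]
    assert set(df["vesicle"]) == {"AP", "AL"}
    assert (df["count"] >= 0).all()
    # (animal_id, vesicle) unique within the dataset
    assert not df.duplicated(["animal_id", "vesicle"]).any()


def test_zero_means_give_zero_counts():
    cfg = single_cell_config(mean_ap=0.0, mean_al=0.0, n=50)
    df = generate_count_dataset(cfg)
    assert (df["count"] == 0).all()


def test_sample_mean_concentrates_on_configured_mean():
    """mean 5, n=10000: sample mean within 3*sqrt(5/10000) of 5."""
    cfg = single_cell_config(mean_ap=5.0, mean_al=5.0, n=10_000, seed=7)
    df = generate_count_dataset(cfg, days=[1])
    ap = df.loc[df["vesicle"] == "AP", "count"]
    assert abs(ap.mean() - 5.0) < 3 * np.sqrt(5.0 / 10_000)


def test_counts_are_poisson_dispersed():
    """Variance/mean ratio near 1 at n = 10^4 under the default model."""
    cfg = single_cell_config(mean_ap=6.0, mean_al=6.0, n=10_000, seed=11)
    df = generate_count_dataset(cfg, days=[1])
    x = df.loc[df["vesicle"] == "AL", "count"].to_numpy()
    vmr = x.var(ddof=1) / x.mean()
    assert abs(vmr - 1.0) < 0.05


def test_dispersion_knob_inflates_variance():
    cfg = single_cell_config(mean_ap=6.0, mean_al=6.0, n=10_000, seed=11,
                             nb_dispersion=2.0)
    df = generate_count_dataset(cfg, days=[1])
    x = df.loc[df["vesicle"] == "AL", "count"].to_numpy()
    vmr = x.var(ddof=1) / x.mean()
    # NB variance mu + mu^2/k with k=2, mu=6 -> VMR = 4
    assert vmr > 2.0


def test_missing_cell_error_names_the_cell():
    traj = {("WT", "intestine", "AP"): {d: 5.0 for d in DAYS}}  # AL missing
    cfg = GeneratorConfig(mean_trajectories=traj, n_animals_per_cell=2)
    with pytest.raises(ConfigError, match="vesicle='AL'"):
        generate_count_dataset(cfg)


def test_day7_neurons_can_be_dropped():
    cfg = default_config(n_animals_per_cell=1, drop_day7_neurons=True)
    df = generate_count_dataset(cfg)
    neurons7 = df[(df["tissue"] == "neurons") & (df["day"] == 7)]
    assert len(neurons7) == 0
    assert len(df[(df["tissue"] == "muscle") & (df["day"] == 7)]) > 0


class TestFluxAssay:
    def test_ground_truth_recovered_from_arm_means(self):
        """The embedded BafA perturbation is recovered from arm means."""
        cfg = single_cell_config(mean_ap=5.0, mean_al=10.0, n=4000, seed=3)
        paired, truth = generate_flux_assay(cfg, "WT", "intestine", 1)
        means = paired.groupby(["treatment", "vesicle"])["count"].mean()
        got = infer_rate_fold_changes(
            PoolState(means[("control", "AP")], means[("control", "AL")]),
            PoolState(means[("bafa", "AP")], means[("bafa", "AL")]),
        )
        assert got.f_beta == pytest.approx(truth.f_beta, rel=0.05)
        assert got.f_gamma == pytest.approx(truth.f_gamma, rel=0.05)

    def test_bafa_arm_sits_at_perturbed_steady_state(self):
        """Default BafA folds (1/3, 1/2) triple AP and double AL means."""
        cfg = single_cell_config(mean_ap=4.0, mean_al=8.0, n=4000, seed=5)
        paired, _ = generate_flux_assay(cfg, "WT", "intestine", 1)
        means = paired.groupby(["treatment", "vesicle"])["count"].mean()
        assert means[("bafa", "AP")] / means[("control", "AP")] == pytest.approx(
            3.0, rel=0.05
        )
        assert means[("bafa", "AL")] / means[("control", "AL")] == pytest.approx(
            2.0, rel=0.05
        )

    def test_fusion_block_raises_ap_and_lowers_al(self):
        """A rab-7-RNAi-like block (beta down, gamma unchanged) gives the
        AP-up / AL-down pattern."""
        cfg = single_cell_config(mean_ap=4.0, mean_al=8.0, n=4000, seed=9)
        paired, truth = generate_flux_assay(
            cfg, "WT", "intestine", 1, treatment="rab7_rnai"
        )
        assert truth == Perturbation(0.2, 1.0)
        means = paired.groupby(["treatment", "vesicle"])["count"].mean()
        assert means[("rab7_rnai", "AP")] > 2 * means[("control", "AP")]
        assert means[("rab7_rnai", "AL")] == pytest.approx(
            means[("control", "AL")], rel=0.1
        )

    def test_unknown_cell_or_treatment_rejected(self):
        cfg = single_cell_config()
        with pytest.raises(ConfigError):
            generate_flux_assay(cfg, "daf-2", "intestine", 1)
        with pytest.raises(ConfigError):
            generate_flux_assay(cfg, "WT", "intestine", 1, treatment="heat_shock")


class TestColocalization:
    def test_zero_punctae(self):
        assert generate_colocalization(0, default_config()) == (0, 0, 0)

    def test_degenerate_simplex(self):
        cfg = default_config(coloc_fractions=(1.0, 0.0, 0.0))
        assert generate_colocalization(500, cfg) == (500, 0, 0)

    def test_proportions_converge_to_defaults(self):
        """Defaults (0.10, 0.75, 0.15): GFP-colocalised, LysoTracker-
        colocalised, and neither; proportions within 0.005 at n = 10^6."""
        n = 10**6
        draw = np.array(generate_colocalization(n, default_config(seed=1))) / n
        np.testing.assert_allclose(draw, [0.10, 0.75, 0.15], atol=0.005)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            generate_colocalization(-1, default_config())


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_animals_per_cell=0),
        dict(coloc_fractions=(0.5, 0.5, 0.5)),
        dict(baseline_flux=0.0),
        dict(nb_dispersion=-1.0),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigError):
        default_config(**kwargs)


def test_config_yaml_round_trip(tmp_path):
    cfg = default_config(n_animals_per_cell=7, seed=99)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = GeneratorConfig.from_yaml(path)
    assert back == cfg
    assert generate_count_dataset(back).equals(generate_count_dataset(cfg))
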