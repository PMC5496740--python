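"""Synthetic puncta-count generator emulating the adult C. elegans study design.

The observable in the assays this package analyses is a per-animal count of
fluorescent vesicle punctae (autophagosomes scored as mCherry/GFP double
positives, autolysosomes as mCherry-only) in one defined observation unit
per tissue — a cell, a pharyngeal bulb, or a fixed-area optical slice.
Counts are small integers and are modelled as Poisson around a
genotype/tissue/age-dependent mean; an optional negative-binomial dispersion
knob represents extra animal-to-animal variability but is off by default,
matching the Poisson-regression analysis the counts feed.

The design axes are genotype (wild type and the long-lived daf-2 and glp-1
mutants, plus blocked-autophagy controls), tissue (intestine, body-wall
muscle, pharynx, nerve-ring neurons, hypodermal seam cells), adult day
(1, 3, 5, 7, 10), and treatment (DMSO control, Bafilomycin A injection, or
rab-7 RNAi which blocks autophagosome-lysosome fusion).  Treated means are
not free parameters: they follow the kinetic model, i.e. the new steady
state after applying the treatment's rate perturbation to the parameters
implied by the control means.

The default mean trajectories are configuration data loosely shaped on the
qualitative trends of the study (counts rise with age in wild type, with the
largest, roughly nine-fold, increase in muscle; ALs outnumber APs; daf-2
pools are elevated early), not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bafa import Perturbation, apply_perturbation
from .identifiability import rates_from_pools
from .kinetics import KineticParameters, PoolState, steady_state_pools

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "DAYS",
    "GENOTYPES",
    "TISSUES",
    "TREATMENTS",
    "VESICLES",
    "COUNT_COLUMNS",
    "default_mean_trajectories",
    "default_config",
    "generate_count_dataset",
    "generate_flux_assay",
    "generate_colocalization",
]

DAYS: tuple[int, ...] = (1, 3, 5, 7, 10)
GENOTYPES = ("WT", "daf-2", "glp-1", "cst-1", "atg-mutant")
TISSUES = ("intestine", "muscle", "pharynx", "neurons", "seam_cells")
TREATMENTS = ("control", "bafa", "rab7_rnai")
VESICLES = ("AP", "AL")

#: Column order of the tidy count-record table shared across the package.
COUNT_COLUMNS = [
    "animal_id",
    "tissue",
    "day",
    "genotype",
    "treatment",
    "vesicle",
    "count",
]


class ConfigError(ValueError):
    """Raised when a generator configuration is incomplete or inconsistent."""


def default_mean_trajectories() -> dict[tuple[str, str, str], dict[int, float]]:
    """Default expected counts per (genotype, tissue, vesicle) over adult days.

    Configuration data, not assertions: wild-type pools grow with age (muscle
    APs about nine-fold from Day 1 to Day 10), ALs exceed APs in every tissue,
    daf-2 pools start elevated, and glp-1 neurons start AP-rich / AL-poor.
    """
    days = DAYS

    def traj(vals: Sequence[float]) -> dict[int, float]:
        return dict(zip(days, [float(v) for v in vals]))

    t: dict[tuple[str, str, str], dict[int, float]] = {}
    # wild type
    t[("WT", "intestine", "AP")] = traj([4, 5, 7, 8, 10])
    t[("WT", "intestine", "AL")] = traj([8, 10, 13, 16, 20])
    t[("WT", "muscle", "AP")] = traj([1, 2.5, 4, 6, 9])
    t[("WT", "muscle", "AL")] = traj([3, 5, 7, 9, 12])
    t[("WT", "pharynx", "AP")] = traj([3, 4, 5, 6, 7])
    t[("WT", "pharynx", "AL")] = traj([6, 8, 9, 11, 13])
    t[("WT", "neurons", "AP")] = traj([2, 3, 4, 4.5, 5])
    t[("WT", "neurons", "AL")] = traj([5.5, 5.5, 5, 4.5, 4])
    # daf-2: elevated early, AL keeps climbing in intestine
    t[("daf-2", "intestine", "AP")] = traj([6, 7, 7.5, 8, 8])
    t[("daf-2", "intestine", "AL")] = traj([12, 15, 18, 21, 24])
    t[("daf-2", "muscle", "AP")] = traj([3, 4, 5, 5.5, 6])
    t[("daf-2", "muscle", "AL")] = traj([5, 8, 9, 9, 9.5])
    t[("daf-2", "pharynx", "AP")] = traj([3, 4, 4.5, 5, 5.5])
    t[("daf-2", "pharynx", "AL")] = traj([9, 10, 10, 11, 11])
    t[("daf-2", "neurons", "AP")] = traj([3.5, 4, 4.5, 5, 5])
    t[("daf-2", "neurons", "AL")] = traj([6, 6.5, 6.5, 6, 6])
    # glp-1: AP-rich, AL-poor neurons when young; ALs stay flat
    t[("glp-1", "intestine", "AP")] = traj([5, 6, 7, 8, 9])
    t[("glp-1", "intestine", "AL")] = traj([10, 12, 14, 16, 18])
    t[("glp-1", "muscle", "AP")] = traj([2, 3, 4.5, 6, 8])
    t[("glp-1", "muscle", "AL")] = traj([4, 6, 8, 10, 11])
    t[("glp-1", "pharynx", "AP")] = traj([3, 4, 5, 5.5, 6])
    t[("glp-1", "pharynx", "AL")] = traj([7, 8, 9, 10, 12])
    t[("glp-1", "neurons", "AP")] = traj([4, 4.5, 4.5, 5, 5])
    t[("glp-1", "neurons", "AL")] = traj([3, 3.5, 4, 4, 4])
    return t


def _default_perturbations() -> dict[str, Perturbation]:
    # BafA: threefold beta / twofold gamma reduction (the worked fold-change
    # example); rab-7 RNAi blocks AP->AL fusion only.
    return {
        "bafa": Perturbation(f_beta=1 / 3, f_gamma=1 / 2),
        "rab7_rnai": Perturbation(f_beta=0.2, f_gamma=1.0),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to draw a reproducible synthetic count dataset.

    Parameters
    ----------
    mean_trajectories
        Map (genotype, tissue, vesicle) -> {adult day: expected control count}.
    perturbation_effects
        Map treatment name -> multiplicative (f_beta, f_gamma) perturbation.
    n_animals_per_cell
        Animals per design cell; default 30, the study's typical per-time-point
        sample size.
    coloc_fractions
        Simplex (mCherry with GFP, mCherry with LysoTracker, mCherry with
        neither); default (0.10, 0.75, 0.15) as scored in the Day 1 wild-type
        intestine.
    baseline_flux
        Flux assumed when converting control means into implied kinetic
        parameters for treated arms (the treated steady state does not depend
        on this choice, only the implied rate constants do).
    nb_dispersion
        If set, counts are negative binomial with this shape parameter
        (variance mu + mu^2/k); None (default) means pure Poisson.
    drop_day7_neurons
        Omit the Day 7 neuron cells from generated designs, mirroring the
        study's missing neuron time point.
    """

    mean_trajectories: Mapping[tuple[str, str, str], Mapping[int, float]] = field(
        default_factory=default_mean_trajectories
    )
    perturbation_effects: Mapping[str, Perturbation] = field(
        default_factory=_default_perturbations
    )
    n_animals_per_cell: int = 30
    coloc_fractions: tuple[float, float, float] = (0.10, 0.75, 0.15)
    seed: int = 0
    baseline_flux: float = 12.0
    nb_dispersion: float | None = None
    drop_day7_neurons: bool = False

    def __post_init__(self) -> None:
        if self.n_animals_per_cell < 1:
            raise ConfigError("n_animals_per_cell must be >= 1")
        fr = np.asarray(self.coloc_fractions, dtype=float)
        if fr.shape != (3,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"coloc_fractions must be a 3-simplex, got {self.coloc_fractions}"
            )
        for key, traj in self.mean_trajectories.items():
            if any(m < 0 for m in traj.values()):
                raise ConfigError(f"negative mean in trajectory for cell {key}")
        if self.baseline_flux <= 0:
            raise ConfigError("baseline_flux must be > 0")
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0 when set")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mean_trajectories": {
                "|".join(k): {str(d): v for d, v in traj.items()}
                for k, traj in self.mean_trajectories.items()
            },
            "perturbation_effects": {
                name: {"f_beta": p.f_beta, "f_gamma": p.f_gamma}
                for name, p in self.perturbation_effects.items()
            },
            "n_animals_per_cell": self.n_animals_per_cell,
            "coloc_fractions": list(self.coloc_fractions),
            "seed": self.seed,
            "baseline_flux": self.baseline_flux,
            "nb_dispersion": self.nb_dispersion,
            "drop_day7_neurons": self.drop_day7_neurons,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        kwargs = dict(d)
        if "mean_trajectories" in kwargs:
            kwargs["mean_trajectories"] = {
                tuple(k.split("|")): {int(day): float(v) for day, v in traj.items()}
                for k, traj in kwargs["mean_trajectories"].items()
            }
        if "perturbation_effects" in kwargs:
            kwargs["perturbation_effects"] = {
                name: Perturbation(**p)
                for name, p in kwargs["perturbation_effects"].items()
            }
        if "coloc_fractions" in kwargs:
            kwargs["coloc_fractions"] = tuple(kwargs["coloc_fractions"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(**overrides) -> GeneratorConfig:
    """The study-shaped default configuration (3 genotypes x 4 tissues x
    5 days x 2 vesicle types, 30 animals per cell)."""
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


def _control_mean(config: GeneratorConfig, genotype, tissue, vesicle, day) -> float:
    key = (genotype, tissue, vesicle)
    traj = config.mean_trajectories.get(key)
    if traj is None or day not in traj:
        raise ConfigError(
            f"no mean trajectory configured for design cell "
            f"(genotype={genotype!r}, tissue={tissue!r}, vesicle={vesicle!r}, "
            f"day={day})"
        )
    return float(traj[day])


def _treated_pools(
    config: GeneratorConfig, control: PoolState, treatment: str
) -> PoolState:
    """New steady-state pools after applying the treatment's perturbation to
    the kinetic parameters implied by the control pools."""
    pert = config.perturbation_effects.get(treatment)
    if pert is None:
        raise ConfigError(f"no perturbation effect configured for {treatment!r}")
    scen = rates_from_pools(control, config.baseline_flux)
    params = KineticParameters(
        influx_J=scen.assumed_flux, beta=scen.beta, gamma=scen.gamma
    )
    return steady_state_pools(apply_perturbation(params, pert))


def _draw_counts(rng: np.random.Generator, mean: float, n: int, config) -> np.ndarray:
    if mean == 0:
        return np.zeros(n, dtype=int)
    if config.nb_dispersion is None:
        return rng.poisson(mean, size=n)
    k = config.nb_dispersion
    return rng.negative_binomial(k, k / (k + mean), size=n)


def generate_count_dataset(
    config: GeneratorConfig,
    treatments: Sequence[str] = ("control",),
    days: Sequence[int] = DAYS,
) -> pd.DataFrame:
    """Draw a full design's worth of animal-level puncta counts.

    One row per animal x vesicle type for every (genotype, tissue) cell with a
    configured mean trajectory, each requested day and treatment.  Counts are
    independent Poisson (or negative binomial when the dispersion knob is set)
    around the control mean, or around the kinetically implied treated steady
    state for perturbed arms.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    bad_day = set(days) - set(DAYS)
    if bad_day:
        raise ConfigError(f"days outside the study design: {sorted(bad_day)}")
    cells = sorted({(g, t) for (g, t, _v) in config.mean_trajectories})
    rows: list[dict] = []
    for genotype, tissue in cells:
        for day in days:
            if (
                config.drop_day7_neurons
                and tissue == "neurons"
                and day == 7
            ):
                continue
            control = PoolState(
                ap=_control_mean(config, genotype, tissue, "AP", day),
                al=_control_mean(config, genotype, tissue, "AL", day),
            )
            for treatment in treatments:
                if treatment == "control":
                    means = {"AP": control.ap, "AL": control.al}
                else:
                    pools = _treated_pools(config, control, treatment)
                    means = {"AP": pools.ap, "AL": pools.al}
                n = config.n_animals_per_cell
                ids = [
                    f"{genotype}|{tissue}|d{day}|{treatment}|a{i:03d}"
                    for i in range(n)
                ]
                for vesicle in VESICLES:
                    drawn = _draw_counts(rng, means[vesicle], n, config)
                    for animal, c in zip(ids, drawn):
                        rows.append(
                            {
                                "animal_id": animal,
                                "tissue": tissue,
                                "day": day,
                                "genotype": genotype,
                                "treatment": treatment,
                                "vesicle": vesicle,
                                "count": int(c),
                            }
                        )
    if not rows:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    return pd.DataFrame(rows)[COUNT_COLUMNS]


def generate_flux_assay(
    config: GeneratorConfig,
    genotype: str,
    tissue: str,
    day: int,
    treatment: str = "bafa",
) -> tuple[pd.DataFrame, Perturbation]:
    """Paired control/treated counts for one design cell, with ground truth.

    The control arm is drawn around the baseline steady state, the treated arm
    around the post-perturbation steady state; the applied
    :class:`~autoflux.bafa.Perturbation` is returned alongside so recovery can
    be checked against truth.
    """
    if treatment not in config.perturbation_effects:
        raise ConfigError(f"no perturbation effect configured for {treatment!r}")
    sub = replace(
        config,
        mean_trajectories={
            k: v
            for k, v in config.mean_trajectories.items()
            if k[0] == genotype and k[1] == tissue
        },
    )
    if not sub.mean_trajectories:
        raise ConfigError(
            f"no mean trajectory configured for (genotype={genotype!r}, "
            f"tissue={tissue!r})"
        )
    df = generate_count_dataset(sub, treatments=("control", treatment), days=[day])
    return df, config.perturbation_effects[treatment]


def generate_colocalization(
    n_punctae: int, config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[int, int, int]:
    """Multinomial split of mCherry-positive punctae into (with GFP, with
    LysoTracker, with neither) according to ``config.coloc_fractions``."""
    if n_punctae < 0:
        raise ValueError(f"n_punctae must be >= 0, got {n_punctae}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    draw = rng.multinomial(n_punctae, config.coloc_fractions)
    return int(draw[0]), int(draw[1]), int(draw[2])
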