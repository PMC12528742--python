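"""Synthetic rearing datasets with the structure the mixture model assumes.

Each simulated individual draws a latent component population, a rearing
temperature from the experimental design, a thermal budget
K ~ Weibull(shape, scale), a development time D = K / (T - t0), a body
length from the component's normal size distribution (truncated at zero)
and a sex. Two presets reproduce the published two-component fits for the
carrion beetles Creophilus maxillosus and Necrodes littoralis, including
their rearing-temperature designs, so every stage of the pipeline is
testable without access to the original (restricted) datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import Dataset, DevelopmentRecord
from .weibull_mix import MixtureModel


@dataclass(frozen=True)
class ComponentDesign:
    """Generating parameters for one component population."""

    weight: float
    shape: float
    scale: float
    t0: float
    mean_length: float = 18.0  # mm
    sd_length: float = 0.8  # mm


@dataclass(frozen=True)
class SimulationDesign:
    """Full generating design: components, temperature design, cohort size.

    Temperatures are sampled with the given proportions (uniform by
    default — real per-temperature cohort sizes are unpublished).
    """

    components: tuple[ComponentDesign, ...]
    temperatures: tuple[float, ...]
    n: int = 1000
    sex_ratio: float = 0.5
    seed: int = 0
    temperature_proportions: tuple[float, ...] | None = None
    species_label: str = ""

    def __post_init__(self) -> None:
        w = sum(c.weight for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {w}")
        t0_max = max(c.t0 for c in self.components)
        if min(self.temperatures) <= t0_max:
            raise ValueError(
                f"every temperature must exceed every threshold (min temp "
                f"{min(self.temperatures)} <= t0 {t0_max})"
            )
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0 <= self.sex_ratio <= 1):
            raise ValueError("sex_ratio must be a probability")
        if self.temperature_proportions is not None:
            if len(self.temperature_proportions) != len(self.temperatures):
                raise ValueError("temperature_proportions length mismatch")
            if abs(sum(self.temperature_proportions) - 1.0) > 1e-9:
                raise ValueError("temperature_proportions must sum to 1")


#: Published two-component fits and rearing designs for the two species.
_PRESETS: dict[str, SimulationDesign] = {
    "creophilus_maxillosus": SimulationDesign(
        components=(
            ComponentDesign(0.87, 14.03, 442.74, 11.25, mean_length=19.57),
            ComponentDesign(0.13, 6.72, 556.66, 11.15, mean_length=19.21),
        ),
        # three extreme design temperatures (10, 12.5, 32.5 °C) saw total
        # mortality and are excluded
        temperatures=(15.0, 17.5, 20.0, 22.5, 25.0, 27.5, 30.0),
        species_label="Creophilus maxillosus",
    ),
    "necrodes_littoralis": SimulationDesign(
        components=(
            ComponentDesign(0.41, 14.57, 394.44, 9.52, mean_length=17.75),
            ComponentDesign(0.59, 13.67, 423.95, 10.21, mean_length=16.96),
        ),
        temperatures=(14.0, 15.0, 16.0, 17.0, 18.0, 19.0, 20.0, 22.0, 26.0, 30.0),
        species_label="Necrodes littoralis",
    ),
}


def species_preset(name: str, n: int = 1000, seed: int = 0) -> SimulationDesign:
    """Return the generating design for a studied species.

    Known names: ``creophilus_maxillosus``, ``necrodes_littoralis``.
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(_PRESETS))}"
        )
    base = _PRESETS[name]
    return SimulationDesign(
        components=base.components,
        temperatures=base.temperatures,
        n=n,
        sex_ratio=base.sex_ratio,
        seed=seed,
        species_label=base.species_label,
    )


def preset_model(name: str) -> MixtureModel:
    """The published fitted mixture for a species preset, as a MixtureModel.

    Components are ordered by expected K ascending, matching the model
    invariant (the dominant/large component of both species has the
    smaller mean thermal budget).
    """
    from .weibull_mix import WeibullComponent

    design = species_preset(name)
    comps = [
        WeibullComponent(weight=c.weight, shape=c.shape, scale=c.scale, t0=c.t0)
        for c in design.components
    ]
    model = MixtureModel(components=comps).sorted_by_mean_k()
    model.validate()
    return model


def sample_dataset(design: SimulationDesign, return_assignment: bool = False):
    """Draw a dataset from a simulation design, fully reproducible from seed.

    With ``return_assignment=True`` also returns the true component index
    of every record (useful for recovery and labeling tests).
    """
    rng = np.random.default_rng(design.seed)
    n = design.n
    weights = np.array([c.weight for c in design.components])
    comp_idx = rng.choice(len(weights), size=n, p=weights)
    props = design.temperature_proportions
    temps = rng.choice(np.asarray(design.temperatures), size=n, p=props)

    shapes = np.array([c.shape for c in design.components])[comp_idx]
    scales = np.array([c.scale for c in design.components])[comp_idx]
    t0s = np.array([c.t0 for c in design.components])[comp_idx]
    k = scales * rng.weibull(shapes)
    dev_time = k / (temps - t0s)

    mu = np.array([c.mean_length for c in design.components])[comp_idx]
    sd = np.array([c.sd_length for c in design.components])[comp_idx]
    length = rng.normal(mu, sd)
    while np.any(length <= 0):  # truncate at zero by redrawing
        bad = length <= 0
        length[bad] = rng.normal(mu[bad], sd[bad])
    sex = np.where(rng.random(n) < design.sex_ratio, "M", "F")

    records = [
        DevelopmentRecord(float(d), float(t), str(s), float(l))
        for d, t, s, l in zip(dev_time, temps, sex, length)
    ]
    ds = Dataset(records, species_label=design.species_label)
    if return_assignment:
        return ds, comp_idx
    return ds


def sample_from_model(model: MixtureModel, temps: np.ndarray, seed: int = 0) -> Dataset:
    """Simulate development times from a fitted mixture at given temperatures.

    Used by the parametric bootstrap: keeps the observed temperature design
    (one simulated individual per supplied temperature) and draws component
    membership and K from the fitted model. No size/sex covariates.
    """
    rng = np.random.default_rng(seed)
    temps = np.asarray(temps, dtype=float)
    n = len(temps)
    comp_idx = rng.choice(model.n_components, size=n, p=model.weights)
    shapes = np.array([c.shape for c in model.components])[comp_idx]
    scales = np.array([c.scale for c in model.components])[comp_idx]
    t0s = np.array([c.t0 for c in model.components])[comp_idx]
    k = scales * rng.weibull(shapes)
    dev_time = k / (temps - t0s)
    records = [DevelopmentRecord(float(d), float(t)) for d, t in zip(dev_time, temps)]
    return Dataset(records)
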