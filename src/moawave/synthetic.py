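"""Synthetic labeled TCRC datasets for exercising the full pipeline.

Each chemical is simulated as logistic negative-control growth multiplied
by a concentration- and time-dependent survival term: the kill rate follows
a Hill function of concentration and acts after an onset lag, optionally
saturating (recovery) or preceded by a transient stimulation bump
(hormetic-like shapes). Cluster archetypes fix the parameter centres;
individual compounds jitter around them, and measurement noise is
multiplicative log-normal plus a small additive term.

The generator's only contracts with the experimental design are the hourly
0-72 h grid, the 11-concentration 1:3 dilution series, the negative
control, and the imbalanced cluster sizes of the default preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .preprocess import DEFAULT_GRID, N_CONCENTRATIONS, TCRC, TCRCSet


@dataclass(frozen=True)
class MOAArchetype:
    """Parameter centre of one mode-of-action cluster."""

    label: str
    k_max: float  # maximal kill rate, 1/h
    ec50: float  # concentration of half-maximal kill, same unit as top_conc
    hill: float = 2.0  # Hill coefficient of the concentration response
    lag: float = 0.0  # onset delay of the kill term, h
    stim_amp: float = 0.0  # transient stimulation amplitude (0 = none)
    stim_tau: float = 6.0  # time-to-peak of the stimulation bump, h
    recovery: bool = False
    recovery_cap: float = 24.0  # max effective kill exposure when recovering, h

    def __post_init__(self) -> None:
        if self.k_max < 0 or self.ec50 <= 0 or self.hill <= 0:
            raise ConfigError("rates must be >= 0, ec50 and hill > 0")


@dataclass(frozen=True)
class GrowthParams:
    """Negative-control logistic growth; g(0) = 1 by construction."""

    plateau: float = 6.0  # asymptotic fold change G
    rate: float = 0.08  # 1/h
    t_half: float = 30.0  # h


@dataclass(frozen=True)
class GeneratorConfig:
    archetypes: tuple[MOAArchetype, ...] = ()
    counts: tuple[int, ...] = ()
    top_conc: float = 100.0
    dilution: float = 3.0
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    growth: GrowthParams = GrowthParams()
    noise_mult_sigma: float = 0.05
    noise_add_sigma: float = 0.01
    jitter_sigma: float = 0.15  # log-scale jitter of per-compound parameters

    def __post_init__(self) -> None:
        if len(self.archetypes) != len(self.counts):
            raise ConfigError("archetypes and counts must align")
        if any(c < 1 for c in self.counts):
            raise ConfigError("cluster counts must be >= 1")
        if self.dilution <= 1:
            raise ConfigError("dilution factor must be > 1")
        if self.top_conc <= 0:
            raise ConfigError("top concentration must be > 0")

    @property
    def concentrations(self) -> np.ndarray:
        return self.top_conc / self.dilution ** np.arange(N_CONCENTRATIONS)


def growth_curve(t: np.ndarray, params: GrowthParams | None = None) -> np.ndarray:
    """Deterministic negative-control NCI trajectory, anchored at g(0) = 1."""
    params = params or GrowthParams()
    t = np.asarray(t, dtype=float)
    rise = 1.0 - np.exp(-params.rate * t)  # 0 at t = 0, so g(0) = 1 exactly
    gate = 1.0 + np.exp(-params.rate * (t - params.t_half))
    return 1.0 + (params.plateau - 1.0) * rise / gate


def survival_factor(
    t: np.ndarray, concentration: float, arch: MOAArchetype
) -> np.ndarray:
    """Closed-form survival multiplier s(t, c) of the kill model."""
    t = np.asarray(t, dtype=float)
    if concentration <= 0:
        return np.ones_like(t)
    hill_frac = concentration ** arch.hill / (
        concentration ** arch.hill + arch.ec50 ** arch.hill
    )
    exposure = np.maximum(0.0, t - arch.lag)
    if arch.recovery:
        exposure = np.minimum(exposure, arch.recovery_cap)
    s = np.exp(-arch.k_max * hill_frac * exposure)
    if arch.stim_amp > 0:
        bump = (t / arch.stim_tau) * np.exp(1.0 - t / arch.stim_tau)
        s = s * (1.0 + arch.stim_amp * hill_frac * bump)
    return s


def _jittered(arch: MOAArchetype, sigma: float, rng: np.random.Generator) -> MOAArchetype:
    if sigma <= 0:
        return arch
    factor = lambda: float(np.exp(rng.normal(0.0, sigma)))  # noqa: E731
    return replace(
        arch,
        k_max=arch.k_max * factor(),
        ec50=arch.ec50 * factor(),
        hill=arch.hill * factor(),
        lag=arch.lag * factor(),
        stim_amp=arch.stim_amp * factor(),
    )


def generate_tcrc_set(
    archetype: MOAArchetype,
    config: GeneratorConfig,
    seed: int | np.random.Generator = 0,
    chemical_id: str = "chem",
    jitter: bool = True,
) -> TCRCSet:
    """Simulate one chemical: 11 treated curves plus the negative control.

    With noise sigmas set to 0 the negative control equals the growth curve
    exactly and every treated curve is the closed-form product
    ``g(t) * s(t, c)``. NCI at t = 0 is pinned to exactly 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = _jittered(archetype, config.jitter_sigma, rng) if jitter else archetype
    t = config.grid
    base_growth = growth_curve(t, config.growth)

    def observe(clean: np.ndarray) -> np.ndarray:
        noisy = clean
        if config.noise_mult_sigma > 0:
            noisy = noisy * np.exp(rng.normal(0.0, config.noise_mult_sigma, size=t.size))
        if config.noise_add_sigma > 0:
            noisy = noisy + rng.normal(0.0, config.noise_add_sigma, size=t.size)
        noisy = noisy.copy()
        noisy[0] = 1.0  # normalization anchor
        return noisy

    curves = []
    for conc in config.concentrations:
        clean = base_growth * survival_factor(t, float(conc), params)
        curves.append(
            TCRC(times=t, nci=observe(clean), concentration=float(conc),
                 chemical_id=chemical_id)
        )
    nc = TCRC(times=t, nci=observe(base_growth), concentration=None,
              chemical_id=chemical_id)
    return TCRCSet(
        chemical_id=chemical_id,
        curves=curves,
        negative_control=nc,
        label=archetype.label,
        meta={"archetype": archetype.label},
    )


def generate_dataset(config: GeneratorConfig, seed: int = 0) -> list[TCRCSet]:
    """Simulate a labeled dataset honouring the per-cluster compound counts."""
    rng = np.random.default_rng(seed)
    sets = []
    for arch, count in zip(config.archetypes, config.counts):
        for i in range(count):
            sets.append(
                generate_tcrc_set(
                    arch, config, seed=rng, chemical_id=f"{arch.label}-{i + 1:02d}"
                )
            )
    return sets


# ---------------------------------------------------------------------------
# Presets


def default_preset(**overrides) -> GeneratorConfig:
    """Seven separable clusters with the imbalanced sizes 20/5/4/5/6/10/13."""
    archetypes = (
        MOAArchetype("C1", k_max=0.12, ec50=8.0, hill=2.0, lag=4.0),
        MOAArchetype("C2", k_max=0.05, ec50=30.0, hill=1.2, lag=0.0, stim_amp=0.8),
        MOAArchetype("C3", k_max=0.20, ec50=3.0, hill=3.0, lag=0.0),
        MOAArchetype("C4", k_max=0.08, ec50=15.0, hill=1.5, lag=24.0),
        MOAArchetype("C6", k_max=0.06, ec50=50.0, hill=1.0, lag=8.0, recovery=True,
                     recovery_cap=20.0),
        MOAArchetype("C8", k_max=0.15, ec50=5.0, hill=2.5, lag=12.0, stim_amp=0.4),
        MOAArchetype("C10", k_max=0.10, ec50=60.0, hill=4.0, lag=36.0),
    )
    counts = (20, 5, 4, 5, 6, 10, 13)
    return GeneratorConfig(archetypes=archetypes, counts=counts, **overrides)


def null_preset(**overrides) -> GeneratorConfig:
    """Identical dynamics in every cluster: labels carry no signal."""
    base = MOAArchetype("C1", k_max=0.10, ec50=10.0, hill=2.0, lag=6.0)
    archetypes = tuple(
        replace(base, label=label) for label in ("C1", "C2", "C3", "C4", "C6", "C8", "C10")
    )
    counts = (20, 5, 4, 5, 6, 10, 13)
    return GeneratorConfig(archetypes=archetypes, counts=counts, **overrides)


def onset_preset(onset_hour: float = 36.0, **overrides) -> GeneratorConfig:
    """Two clusters indistinguishable before ``onset_hour``.

    Cluster A starts killing only after the onset; cluster B never responds,
    so every discriminating feature lives in the late window.
    """
    archetypes = (
        MOAArchetype("A", k_max=0.15, ec50=10.0, hill=2.0, lag=onset_hour),
        MOAArchetype("B", k_max=0.0, ec50=10.0, hill=2.0),
    )
    counts = (12, 12)
    return GeneratorConfig(archetypes=archetypes, counts=counts, **overrides)


PRESETS = {
    "default": default_preset,
    "null": null_preset,
    "onset": onset_preset,
}
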