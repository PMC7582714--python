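"""Synthetic fluorogenic-substrate assay generator.

Emulates the initial-rate structure of a 20S proteasome chymotrypsin-like
activity assay: 2 nM enzyme, fluorogenic substrate between 5 and 100 µM,
modulator between 0 and 10 µM, at least three replicates per point, 37 °C.
Velocities follow the two-state forward model, optionally with an
uncompetitive substrate-inhibition term (so that loss of double-reciprocal
linearity above the substrate cutoff is exercisable) and multiplicative
Gaussian noise.

Three anchored parameter presets are provided. Their allosteric constants
and binding-constant ratios reproduce printed free-energy values
(32.7 / 26.1 / 8.3 kJ/mol gaps; 21.4 and 23.9 kJ/mol per binding step,
i.e. an about 4000-fold affinity ratio in the substrate-free form); the
remaining absolute scales and turnover numbers are fixture choices, chosen
so activation completes by roughly 3 µM (human-like) or 1 µM (yeast-like)
modulator, and recorded as such on each scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model
from ._constants import DEFAULT_TEMPERATURE_K, rt
from .rates import VelocityDataset
from .scheme import ModulatorScheme

__all__ = [
    "AssayDesign",
    "NoiseOptions",
    "FIXTURE_NAMES",
    "fixture_scheme",
    "default_design",
    "generate_dataset",
    "model_profile",
]

FIXTURE_NAMES = ("H20S_LIKE", "Y20S_LIKE", "A3DN_LIKE")


@dataclass(frozen=True)
class AssayDesign:
    """Experimental design of the simulated assay.

    The default substrate grid covers the fitted range (5–25 µM); setting
    ``include_high_substrate`` appends the 50 and 100 µM points used only
    for linearity diagnostics.
    """

    enzyme_nM: float = 2.0
    substrate_uM: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0)
    modulator_uM: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5, 1.0, 2.0, 3.0, 5.0, 10.0)
    replicates: int = 3
    temperature_K: float = DEFAULT_TEMPERATURE_K
    include_high_substrate: bool = False

    def __post_init__(self) -> None:
        if self.enzyme_nM <= 0:
            raise ValueError("enzyme_nM must be > 0")
        if any(s <= 0 for s in self.substrate_uM):
            raise ValueError("substrate grid must be strictly positive")
        if any(l < 0 for l in self.modulator_uM):
            raise ValueError("modulator grid must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def substrate_grid(self) -> tuple[float, ...]:
        if self.include_high_substrate:
            return tuple(self.substrate_uM) + (50.0, 100.0)
        return tuple(self.substrate_uM)


@dataclass(frozen=True)
class NoiseOptions:
    """Stochastic options of the generator.

    ``cv`` is the relative standard deviation of multiplicative Gaussian
    velocity noise (0 disables noise); ``seed`` is mandatory whenever
    cv > 0. ``substrate_inhibition_Ksi`` (µM) switches on the uncompetitive
    substrate-inhibition term; None leaves it off.
    """

    cv: float = 0.05
    seed: int | None = None
    substrate_inhibition_Ksi: float | None = None

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.substrate_inhibition_Ksi is not None and self.substrate_inhibition_Ksi <= 0:
            raise ValueError("substrate_inhibition_Ksi must be > 0 when present")
        if self.cv > 0 and self.seed is None:
            raise ValueError("a seed is required for noisy output")


def default_design() -> AssayDesign:
    """The default assay design (2 nM enzyme, 5–25 µM substrate fitted grid,
    0–10 µM modulator, 3 replicates, 310.15 K)."""
    return AssayDesign()


def _anchored(kJ_per_mol: float, temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Equilibrium constant whose A->B free energy is the given magnitude
    with A favored: L = exp(-dG/RT)."""
    return math.exp(-kJ_per_mol / rt(temperature_K))


def fixture_scheme(name: str) -> ModulatorScheme:
    """Anchored parameter presets.

    ``H20S_LIKE``
        Human-like: n = 3 activating sites, no inhibitory site. Allosteric
        constants anchored to 32.7 (substrate-free) and 26.1 kJ/mol
        (substrate-bound) A/B gaps; K_BU/K_AU = 4000 exactly and
        K_BL/K_AL = exp(23.9 kJ/mol / RT).
    ``Y20S_LIKE``
        Yeast-like: n = 2, m = 1 with K_BI = 2 µM^-1; same anchored
        energies, binding scales chosen so activation completes by ~1 µM.
    ``A3DN_LIKE``
        Gate-disrupted mutant: n = 2, m = 1, a small 8.3 kJ/mol
        substrate-free gap, equal turnover numbers for the two
        conformations, Michaelis constants above wild-type, and the
        yeast-like modulator binding constants carried over.
    """
    T = DEFAULT_TEMPERATURE_K
    if name == "H20S_LIKE":
        delta = math.exp(23.9 / rt(T))
        return ModulatorScheme(
            kcat_A=1.0,
            kcat_B=0.5,
            km_0=60.0,
            km_A=60.0,
            km_B=10.0,
            K_AU=0.01,
            K_BU=0.01 * 4000.0,
            K_AL=0.005,
            K_BL=0.005 * delta,
            L_U=_anchored(32.7, T),
            L_L=_anchored(26.1, T),
            n=3,
            m=0,
            temperature_K=T,
            fixture_choices=("kcat_A", "kcat_B", "km_0", "km_A", "km_B", "K_AU", "K_AL"),
        )
    if name == "Y20S_LIKE":
        delta = math.exp(23.9 / rt(T))
        return ModulatorScheme(
            kcat_A=0.8,
            kcat_B=0.4,
            km_0=40.0,
            km_A=40.0,
            km_B=8.0,
            K_AU=0.15,
            K_BU=0.15 * 4000.0,
            K_AL=0.08,
            K_BL=0.08 * delta,
            K_BI=2.0,
            L_U=_anchored(32.7, T),
            L_L=_anchored(26.1, T),
            n=2,
            m=1,
            temperature_K=T,
            fixture_choices=(
                "kcat_A", "kcat_B", "km_0", "km_A", "km_B", "K_AU", "K_AL", "K_BI",
            ),
        )
    if name == "A3DN_LIKE":
        delta = math.exp(23.9 / rt(T))
        return ModulatorScheme(
            kcat_A=1.5,
            kcat_B=1.5,
            km_0=80.0,
            km_A=80.0,
            km_B=30.0,
            K_AU=0.15,
            K_BU=0.15 * 4000.0,
            K_AL=0.08,
            K_BL=0.08 * delta,
            K_BI=2.0,
            L_U=_anchored(8.3, T),
            L_L=_anchored(4.15, T),
            n=2,
            m=1,
            temperature_K=T,
            fixture_choices=(
                "kcat_A", "kcat_B", "km_0", "km_A", "km_B", "K_AU", "K_AL",
                "K_BI", "L_L",
            ),
        )
    raise ValueError(f"unknown fixture name {name!r}; choose from {FIXTURE_NAMES}")


def model_profile(
    scheme: ModulatorScheme,
    modulator_uM=None,
    efficiency: str = "eq3",
) -> pd.DataFrame:
    """Noiseless catalytic profile straight from the forward model.

    The kcat and Km columns are the observed-parameter curves; the
    efficiency column is either the printed population-weighted specificity
    constant (``efficiency='eq3'``, the observable the staged fit targets
    by default) or the plain ratio kcat_obs/km_obs (``'ratio'``, which is
    what a profile estimated from velocity data necessarily contains).
    """
    if efficiency not in ("eq3", "ratio"):
        raise ValueError("efficiency must be 'eq3' or 'ratio'")
    L = np.asarray(
        default_design().modulator_uM if modulator_uM is None else modulator_uM,
        dtype=float,
    )
    kcat = np.asarray(model.observed_kcat(scheme, L))
    km = np.asarray(model.observed_km(scheme, L))
    if efficiency == "eq3":
        eff = np.asarray(model.observed_efficiency(scheme, L))
    else:
        eff = kcat / km
    return pd.DataFrame(
        {
            "modulator_uM": L,
            "kcat_obs_per_s": kcat,
            "km_obs_uM": km,
            "eff_obs": eff,
        }
    )


def generate_dataset(
    scheme: ModulatorScheme,
    design: AssayDesign | None = None,
    noise: NoiseOptions | None = None,
) -> VelocityDataset:
    """Simulate a replicate-level velocity dataset under the scheme.

    Each row's velocity is the forward-model value (with the
    substrate-inhibition term when Ksi is set), multiplied by
    ``1 + N(0, cv)``; negative draws are truncated at zero and logged in
    the metadata. Byte-identical output for identical inputs and seed.
    """
    design = design or default_design()
    noise = noise or NoiseOptions(cv=0.0)
    rows = []
    for L in design.modulator_uM:
        for S in design.substrate_grid:
            v = model.velocity(
                scheme,
                design.enzyme_nM,
                S,
                L,
                Ksi=noise.substrate_inhibition_Ksi,
            )
            for rep in range(1, design.replicates + 1):
                rows.append((S, L, rep, v, design.enzyme_nM))
    frame = pd.DataFrame(
        rows,
        columns=[
            "substrate_uM",
            "modulator_uM",
            "replicate",
            "velocity_nM_per_s",
            "enzyme_nM",
        ],
    )
    truncated = 0
    if noise.cv > 0:
        rng = np.random.default_rng(noise.seed)
        factors = 1.0 + rng.normal(0.0, noise.cv, len(frame))
        noisy = frame["velocity_nM_per_s"].to_numpy() * factors
        truncated = int(np.sum(noisy < 0))
        frame["velocity_nM_per_s"] = np.maximum(noisy, 0.0)
    metadata = {
        "generator": "allokin.synth.generate_dataset",
        "enzyme_nM": design.enzyme_nM,
        "temperature_K": design.temperature_K,
        "replicates": design.replicates,
        "noise_cv": noise.cv,
        "seed": noise.seed,
        "substrate_inhibition_Ksi_uM": noise.substrate_inhibition_Ksi,
        "n_truncated_velocities": truncated,
    }
    return VelocityDataset(data=frame, metadata=metadata)
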