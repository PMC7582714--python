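"""Free-energy and linkage analysis of a fitted modulation scheme.

Converts the allosteric constants and modulator-binding ratios into an
occupancy-resolved ladder of A<->B free energies. Sign convention: the
reported value is ΔG(A→B) = −RT·ln(L_eff), so a positive value means
conformation A is favored; every output carries an explicit favored-state
label because sign conventions for conformational equilibria are a common
source of ambiguity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._constants import R_KJ_PER_MOL_K
from .scheme import ModulatorScheme

__all__ = [
    "gibbs_free_energy",
    "interaction_ratios",
    "energy_ladder",
    "InteractionRatios",
    "EnergyLadder",
]


def gibbs_free_energy(K_eq: float, T: float) -> float:
    """Standard Gibbs free energy ΔG⁰ = −RT·ln(K_eq), kJ/mol.

    Parameters
    ----------
    K_eq : dimensionless equilibrium constant, > 0.
    T : absolute temperature, kelvin.
    """
    if K_eq <= 0:
        raise ValueError(f"equilibrium constant must be > 0, got {K_eq}")
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    return -R_KJ_PER_MOL_K * T * math.log(K_eq)


@dataclass(frozen=True)
class InteractionRatios:
    """Dimensionless ratios of the four modulator association constants.

    alpha = K_AU/K_AL and beta = K_BU/K_BL quantify substrate linkage within
    each conformation; gamma = K_BU/K_AU and delta = K_BL/K_AL quantify the
    conformational preference of the modulator. The identity
    alpha/beta = delta/gamma holds by construction.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float


def interaction_ratios(scheme: ModulatorScheme) -> InteractionRatios:
    """Compute (alpha, beta, gamma, delta) from the four association
    constants; all four must be strictly positive."""
    for name in ("K_AU", "K_BU", "K_AL", "K_BL"):
        if getattr(scheme, name) <= 0:
            raise ValueError(
                f"{name} must be > 0 to form interaction ratios "
                f"(got {getattr(scheme, name)})"
            )
    return InteractionRatios(
        alpha=scheme.K_AU / scheme.K_AL,
        beta=scheme.K_BU / scheme.K_BL,
        gamma=scheme.K_BU / scheme.K_AU,
        delta=scheme.K_BL / scheme.K_AL,
    )


@dataclass(frozen=True)
class EnergyLadder:
    """Occupancy-resolved A<->B free energies, kJ/mol.

    For modulator occupancy ``i`` the effective allosteric constant is
    ``L_U·gamma^i`` (substrate-free) or ``L_L·delta^i`` (substrate-bound),
    so the ladder is exactly arithmetic in i:

        dG_unbound_i = dG_unbound_0 − i·RT·ln(gamma)
        dG_bound_i   = dG_bound_0 − i·RT·ln(delta)

    Positive values mean A is favored.
    """

    occupancy: tuple[int, ...]
    dG_unbound: tuple[float, ...]
    dG_bound: tuple[float, ...]
    temperature_K: float

    def favored_state(self, dG: float) -> str:
        return "A" if dG > 0 else ("B" if dG < 0 else "none")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "occupancy": list(self.occupancy),
                "dG_unbound_kJmol": list(self.dG_unbound),
                "dG_bound_kJmol": list(self.dG_bound),
                "favored_state_unbound": [
                    self.favored_state(g) for g in self.dG_unbound
                ],
                "favored_state_bound": [self.favored_state(g) for g in self.dG_bound],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "temperature_K": self.temperature_K,
            "units": "kJ/mol",
            "sign_convention": "dG(A->B) = -RT ln L; positive favors A",
            "rows": self.to_dataframe().to_dict(orient="records"),
        }
        text = json.dumps(doc, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def energy_ladder(scheme: ModulatorScheme, i_max: int | None = None) -> EnergyLadder:
    """Free-energy ladder of the A<->B transition for modulator occupancies
    ``0..i_max`` (default ``n``), substrate-free and substrate-bound.

    The occupancy scaling uses exact (unrounded) gamma and delta from the
    scheme's association constants; rounding happens only at report time.
    """
    if i_max is None:
        i_max = scheme.n
    if i_max > scheme.n:
        raise ValueError(f"i_max={i_max} exceeds the number of sites n={scheme.n}")
    ratios = interaction_ratios(scheme)
    rt = scheme.rt
    dG_u0 = -rt * math.log(scheme.L_U)
    dG_b0 = -rt * math.log(scheme.L_L)
    occ = np.arange(i_max + 1)
    dG_u = dG_u0 - occ * rt * math.log(ratios.gamma)
    dG_b = dG_b0 - occ * rt * math.log(ratios.delta)
    return EnergyLadder(
        occupancy=tuple(int(i) for i in occ),
        dG_unbound=tuple(float(g) for g in dG_u),
        dG_bound=tuple(float(g) for g in dG_b),
        temperature_K=scheme.temperature_K,
    )
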