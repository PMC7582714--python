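"""Parameter set of the two-state concerted allosteric scheme.

The enzyme is assumed to pre-exist in two conformations, A and B, in fast
equilibrium. A cationic modulator binds ``n`` activating sites concertedly
(all sites switch state together, as in the canonical two-state model) and,
optionally, ``m`` competitive inhibitory sites that are effective only in the
B conformation. Each conformation has its own Michaelis–Menten parameters;
the modulator has four association constants distinguishing conformation
(A/B) and substrate occupancy (unbound/substrate-bound).
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from ._constants import DEFAULT_TEMPERATURE_K

__all__ = ["ModulatorScheme", "ObservedParameters", "SchemaError"]


class SchemaError(ValueError):
    """Raised when a scheme JSON document violates the expected schema."""


#: Unit strings required in serialized schemes, keyed by field name.
_UNITS = {
    "kcat_A": "1/s",
    "kcat_B": "1/s",
    "km_0": "uM",
    "km_A": "uM",
    "km_B": "uM",
    "K_AU": "1/uM",
    "K_BU": "1/uM",
    "K_AL": "1/uM",
    "K_BL": "1/uM",
    "K_BI": "1/uM",
    "K_AI": "1/uM",
    "L_U": "dimensionless",
    "L_L": "dimensionless",
    "n": "sites",
    "m": "sites",
    "sigma_A": "dimensionless",
    "sigma_B": "dimensionless",
    "temperature_K": "K",
}


@dataclass
class ModulatorScheme:
    """Full parameter set of the two-state modulation scheme.

    Parameters
    ----------
    kcat_A, kcat_B
        Turnover numbers of conformations A and B, s^-1.
    km_0
        Michaelis constant in the absence of modulator, µM.
    km_A, km_B
        Michaelis constants of the two conformations, µM.
    K_AU, K_BU
        Modulator association constants for substrate-free A and B, µM^-1.
    K_AL, K_BL
        Modulator association constants for substrate-bound A and B, µM^-1.
    K_BI
        Association constant of the competitive inhibitory site on B, µM^-1.
    K_AI
        Inhibitory association constant on A; fixed at 0 by model assumption
        (the inhibitory site is effective only in the B conformation).
    L_U, L_L
        Allosteric constants [B]/[A] for substrate-free and substrate-bound
        enzyme. Values << 1 mean conformation A is favored.
    n
        Number of concerted activating modulator sites (>= 1).
    m
        Number of competitive inhibitory sites (>= 0).
    sigma_A, sigma_B
        Multipliers of kcat upon modulator binding; fixed at 1 by model
        assumption (binding does not alter the rate-limiting step).
    temperature_K
        Assay temperature, kelvin.
    fixture_choices
        Names of fields whose values are package fixture choices rather than
        externally anchored quantities (bookkeeping for presets).
    """

    kcat_A: float
    kcat_B: float
    km_0: float
    km_A: float
    km_B: float
    K_AU: float
    K_BU: float
    K_AL: float
    K_BL: float
    L_U: float
    L_L: float
    n: int
    m: int = 0
    K_BI: float = 0.0
    K_AI: float = 0.0
    sigma_A: float = 1.0
    sigma_B: float = 1.0
    temperature_K: float = DEFAULT_TEMPERATURE_K
    fixture_choices: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        for name in (
            "kcat_A", "kcat_B", "km_0", "km_A", "km_B",
            "K_AU", "K_BU", "K_AL", "K_BL", "K_BI", "K_AI",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.L_U <= 0 or self.L_L <= 0:
            raise ValueError("allosteric constants L_U and L_L must be > 0")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n}")
        if int(self.m) != self.m or self.m < 0:
            raise ValueError(f"m must be a non-negative integer, got {self.m}")
        self.n = int(self.n)
        self.m = int(self.m)
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be > 0")
        if self.K_AI != 0.0:
            warnings.warn(
                "K_AI != 0 overrides the model assumption that the inhibitory "
                "site is silent in conformation A",
                stacklevel=2,
            )
        if self.sigma_A != 1.0 or self.sigma_B != 1.0:
            warnings.warn(
                "sigma_A/sigma_B != 1 overrides the assumption that modulator "
                "binding leaves kcat unchanged",
                stacklevel=2,
            )

    # -- derived quantities -------------------------------------------------

    @property
    def rt(self) -> float:
        """RT in kJ/mol at the scheme temperature."""
        from ._constants import R_KJ_PER_MOL_K

        return R_KJ_PER_MOL_K * self.temperature_K

    def replace(self, **changes) -> "ModulatorScheme":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-ready dict: each parameter carries an explicit unit string."""
        out = {}
        for name, unit in _UNITS.items():
            value = getattr(self, name)
            out[name] = {"value": value, "unit": unit}
        if self.fixture_choices:
            out["fixture_choices"] = list(self.fixture_choices)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, doc: dict) -> "ModulatorScheme":
        if not isinstance(doc, dict):
            raise SchemaError("scheme document must be a JSON object")
        unknown = set(doc) - set(_UNITS) - {"fixture_choices"}
        if unknown:
            raise SchemaError(f"unknown keys in scheme JSON: {sorted(unknown)}")
        missing = set(_UNITS) - set(doc)
        if missing:
            raise SchemaError(f"scheme JSON missing fields: {sorted(missing)}")
        kwargs = {}
        for name, unit in _UNITS.items():
            entry = doc[name]
            if not isinstance(entry, dict) or set(entry) != {"value", "unit"}:
                raise SchemaError(
                    f"field {name!r} must be an object with 'value' and 'unit'"
                )
            if entry["unit"] != unit:
                raise SchemaError(
                    f"field {name!r} has unit {entry['unit']!r}, expected {unit!r}"
                )
            kwargs[name] = entry["value"]
        kwargs["fixture_choices"] = tuple(doc.get("fixture_choices", ()))
        return cls(**kwargs)

    @classmethod
    def from_json(cls, source: str | Path) -> "ModulatorScheme":
        """Load a scheme from a JSON file path or a JSON string."""
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"invalid JSON: {exc}") from exc
        return cls.from_dict(doc)


@dataclass(frozen=True)
class ObservedParameters:
    """Observed catalytic parameters at one modulator concentration."""

    modulator_uM: float
    kcat_obs: float  # s^-1
    km_obs: float  # µM
    efficiency_obs: float  # s^-1 µM^-1

    def __post_init__(self) -> None:
        if self.km_obs <= 0:
            raise ValueError("km_obs must be > 0")
        if not math.isfinite(self.kcat_obs):
            raise ValueError("kcat_obs must be finite")
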