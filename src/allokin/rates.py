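"""Extraction of observed (kcat, Km) per modulator concentration.

The classical initial-rate workflow: for each modulator concentration,
replicate velocities are averaged per substrate level, the double-reciprocal
(Lineweaver–Burk) regression provides the linearity diagnostic and starting
values, and a direct nonlinear Michaelis–Menten fit provides the primary
estimates. Rows above the substrate cutoff (default 25 µM, where
substrate-linked inhibition breaks double-reciprocal linearity) are excluded
before fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import LineweaverBurkRegressor, MichaelisMentenRegressor

__all__ = [
    "VelocityDataset",
    "double_reciprocal_fit",
    "michaelis_menten_fit",
    "linearity_partition",
    "catalytic_profile",
    "DEFAULT_S_CUT",
    "LINEARITY_R2_THRESHOLD",
    "PROFILE_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Substrate cutoff above which double-reciprocal linearity is not assumed, µM.
DEFAULT_S_CUT = 25.0

#: r² threshold on the double-reciprocal regression below which a group is
#: flagged non-linear. Clean Michaelis–Menten data sit essentially at 1;
#: the substrate-inhibited regime falls well below.
LINEARITY_R2_THRESHOLD = 0.98

DATASET_COLUMNS = [
    "substrate_uM",
    "modulator_uM",
    "replicate",
    "velocity_nM_per_s",
    "enzyme_nM",
]

PROFILE_COLUMNS = [
    "modulator_uM",
    "kcat_obs_per_s",
    "km_obs_uM",
    "eff_obs",
    "r_squared",
    "n_replicates",
    "linearity_flag",
]


@dataclass
class VelocityDataset:
    """Replicate-level initial-rate observations over a (substrate ×
    modulator) design.

    ``data`` holds one row per measurement with columns
    ``substrate_uM, modulator_uM, replicate, velocity_nM_per_s, enzyme_nM``.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"velocity dataset missing columns: {missing}")
        if (self.data["velocity_nM_per_s"] < 0).any():
            raise ValueError("velocities must be >= 0")
        self.data = self.data[DATASET_COLUMNS].reset_index(drop=True)

    @property
    def enzyme_nM(self) -> float:
        values = self.data["enzyme_nM"].unique()
        if len(values) != 1:
            raise ValueError("dataset mixes enzyme concentrations")
        return float(values[0])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in self.metadata.items():
                fh.write(f"# {key}: {value}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "VelocityDataset":
        path = Path(path)
        metadata = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    metadata[key.strip()] = value.strip()
                body_start = i + 1
            else:
                break
        from io import StringIO

        frame = pd.read_csv(StringIO("".join(lines[body_start:])))
        missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(
                f"velocity dataset CSV missing columns: {missing} "
                f"(found {list(frame.columns)})"
            )
        return cls(data=frame, metadata=metadata)


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (S_uM, v_nM_per_s)")
    return arr[:, 0], arr[:, 1]


def double_reciprocal_fit(points, E0: float) -> tuple[float, float, float]:
    """Lineweaver–Burk estimate of (kcat, km, r_squared) from (S, v) points.

    Ordinary least squares of E0/v on 1/S; kcat = 1/intercept,
    km = slope/intercept. A non-positive intercept yields non-physical
    values, which are returned with a warning rather than suppressed.
    """
    S, v = _as_points(points)
    if np.any(v == 0):
        raise ValueError("zero-velocity points cannot enter a double-reciprocal fit")
    reg = LineweaverBurkRegressor(enzyme_nM=E0).fit(S.reshape(-1, 1), v)
    if reg.nonphysical_:
        warnings.warn(
            "double-reciprocal intercept <= 0: non-physical kcat/km returned",
            stacklevel=2,
        )
    return reg.kcat_, reg.km_, reg.r_squared_


def michaelis_menten_fit(points, E0: float) -> tuple[float, float, float]:
    """Nonlinear least-squares (kcat, km, r_squared) on v = E0·kcat·S/(Km+S),
    initialized from the double-reciprocal estimate."""
    S, v = _as_points(points)
    reg = MichaelisMentenRegressor(enzyme_nM=E0).fit(S.reshape(-1, 1), v)
    return reg.kcat_, reg.km_, reg.r_squared_


def linearity_partition(
    points,
    E0: float,
    S_cut: float = DEFAULT_S_CUT,
    r2_threshold: float = LINEARITY_R2_THRESHOLD,
):
    """Partition (S, v) points at the substrate cutoff and diagnose loss of
    double-reciprocal linearity.

    Returns ``(retained, excluded, flag)`` where ``retained`` holds rows
    with S <= S_cut, and ``flag`` is True when the full-range regression
    falls below the r² threshold while the retained range does not —
    the signature of substrate-linked inhibition at high substrate.
    """
    if S_cut <= 0:
        raise ValueError("S_cut must be > 0")
    S, v = _as_points(points)
    keep = S <= S_cut
    retained = np.column_stack([S[keep], v[keep]])
    excluded = np.column_stack([S[~keep], v[~keep]])
    if retained.shape[0] == 0:
        raise ValueError(f"no points at S <= {S_cut} µM")
    flag = False
    if excluded.shape[0] > 0 and np.unique(S).size >= 3:
        _, _, r2_full = double_reciprocal_fit(np.column_stack([S, v]), E0)
        _, _, r2_kept = double_reciprocal_fit(retained, E0)
        flag = bool(r2_full < r2_threshold <= r2_kept)
    return retained, excluded, flag


def catalytic_profile(
    dataset: VelocityDataset | pd.DataFrame,
    S_cut: float = DEFAULT_S_CUT,
    r2_threshold: float = LINEARITY_R2_THRESHOLD,
    average_replicates: bool = True,
    nonlinear_primary: bool = True,
) -> pd.DataFrame:
    """Per-modulator-concentration estimates of observed kcat, Km and
    kcat/Km (the catalytic profile).

    For every modulator concentration, replicates are averaged per
    substrate level (the plotted mean points), the data are restricted to
    S <= S_cut, and (kcat, km) are estimated — by the nonlinear
    Michaelis–Menten fit initialized from the double-reciprocal regression
    (default) or by the double-reciprocal regression alone. ``r_squared`` is
    always the double-reciprocal (linearity) statistic. ``eff_obs`` is
    kcat_obs/km_obs. Groups that cannot be fitted (fewer than two distinct
    positive-velocity substrate levels) are skipped and logged.
    """
    if isinstance(dataset, pd.DataFrame):
        dataset = VelocityDataset(data=dataset)
    E0 = dataset.enzyme_nM
    rows = []
    for L, group in dataset.data.groupby("modulator_uM", sort=True):
        n_replicates = int(group["replicate"].nunique())
        if average_replicates:
            cells = (
                group.groupby("substrate_uM", sort=True)["velocity_nM_per_s"]
                .mean()
                .reset_index()
            )
        else:
            cells = group[["substrate_uM", "velocity_nM_per_s"]]
        cells = cells[cells["velocity_nM_per_s"] > 0]
        points = cells[["substrate_uM", "velocity_nM_per_s"]].to_numpy(float)
        if points.shape[0] < 2 or np.unique(points[:, 0]).size < 2:
            logger.warning(
                "skipping modulator %.4g µM: fewer than 2 usable substrate levels", L
            )
            continue
        try:
            retained, _, flag = linearity_partition(
                points, E0, S_cut=S_cut, r2_threshold=r2_threshold
            )
            _, _, r2 = double_reciprocal_fit(retained, E0)
            if nonlinear_primary and retained.shape[0] >= 3:
                kcat, km, _ = michaelis_menten_fit(retained, E0)
            else:
                kcat, km, _ = double_reciprocal_fit(retained, E0)
        except (ValueError, RuntimeError) as exc:
            logger.warning("skipping modulator %.4g µM: %s", L, exc)
            continue
        rows.append(
            {
                "modulator_uM": float(L),
                "kcat_obs_per_s": kcat,
                "km_obs_uM": km,
                "eff_obs": kcat / km,
                "r_squared": r2,
                "n_replicates": n_replicates,
                "linearity_flag": flag,
            }
        )
    if not rows:
        raise ValueError("no modulator group could be fitted")
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)
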