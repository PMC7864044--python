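"""Flat-arrangement maximum diameters and DLS size comparison.

Both building blocks are roughly cylindrical: the hexameric core is
5-6 nm across and each cytochrome unit about 2.5 nm.  If the chains of
a star model lie flat in the core's plane, the largest possible span
runs through the core and along the two longest chains on opposite
sides:

    d_max = d_core + (l(1) + l(2)) * d_unit,

with ``l(1) >= l(2)`` the two longest chain lengths (``l(2) = 0`` for a
single-chain model).  Heights are ignored: the span is an in-plane
measurement.  Comparing ``d_max`` with the number-weighted hydrodynamic
diameter from dynamic light scattering classifies the solution
conformation: an observed diameter well below the flat-arrangement
maximum indicates a flexible, non-flat arrangement of the chains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Tuple, Union

import numpy as np

from .stoichiometry import StarModel

__all__ = [
    "GeometryParams",
    "DlsDistribution",
    "DlsSummary",
    "SizeComparison",
    "max_flat_diameter",
    "dls_summary",
    "compare_size",
    "read_dls_csv",
    "write_dls_csv",
]


@dataclass(frozen=True)
class GeometryParams:
    """Building-block dimensions in nm.

    Defaults: core 6 nm (upper end of the 5-6 nm range, the value the
    flat-arrangement sums use) and 2.5 nm per cytochrome unit.
    """

    d_core: float = 6.0
    d_unit: float = 2.5

    def __post_init__(self) -> None:
        if self.d_core <= 0 or self.d_unit <= 0:
            raise ValueError("geometry parameters must be positive")


@dataclass(frozen=True)
class DlsDistribution:
    """Number-weighted hydrodynamic diameter distribution."""

    diameters: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        f = np.asarray(self.frequencies, dtype=float)
        if d.ndim != 1 or f.ndim != 1 or d.size != f.size:
            raise ValueError("diameters and frequencies must be equal-length 1-D arrays")
        if d.size < 1:
            raise ValueError("distribution is empty")
        if np.any(np.diff(d) <= 0):
            raise ValueError("diameters must be strictly increasing")
        if np.any(f < 0):
            raise ValueError("frequencies must be non-negative")
        if float(f.sum()) <= 0:
            raise ValueError("frequencies are all zero; distribution is unnormalizable")
        d.setflags(write=False)
        f.setflags(write=False)
        object.__setattr__(self, "diameters", d)
        object.__setattr__(self, "frequencies", f)


@dataclass(frozen=True)
class DlsSummary:
    """Mode and number-weighted mean diameter (nm)."""

    mode: float
    mean: float


@dataclass(frozen=True)
class SizeComparison:
    """Observed vs maximum flat-arrangement diameter.

    ``compactness = d_obs / d_max``.  Verdicts: ``flat-consistent``
    when the observation matches the flat maximum within the tolerance
    fraction; ``flexible/compact`` when the particle is markedly
    smaller (chains folded out of plane); ``larger-than-model`` when it
    exceeds the model's maximum.
    """

    d_max: float
    d_obs: float
    compactness: float
    verdict: str

    def __post_init__(self) -> None:
        if self.compactness <= 0:
            raise ValueError("compactness must be positive")
        if self.verdict not in ("flat-consistent", "flexible/compact", "larger-than-model"):
            raise ValueError(f"unknown verdict {self.verdict!r}")

    def to_dict(self) -> dict:
        return {
            "d_max_nm": self.d_max,
            "d_obs_nm": self.d_obs,
            "compactness": self.compactness,
            "verdict": self.verdict,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def max_flat_diameter(model: StarModel, params: GeometryParams = GeometryParams()) -> float:
    """Maximum in-plane diameter of a star model (nm)."""
    longest = model.chains[0]
    second = model.chains[1] if model.n_chains > 1 else 0
    return params.d_core + (longest + second) * params.d_unit


def dls_summary(dist: DlsDistribution) -> DlsSummary:
    """Mode (ties -> smallest diameter) and number-weighted mean."""
    idx = int(np.argmax(dist.frequencies))  # argmax returns the first maximum
    mean = float(np.dot(dist.diameters, dist.frequencies) / dist.frequencies.sum())
    return DlsSummary(mode=float(dist.diameters[idx]), mean=mean)


def compare_size(
    model: StarModel,
    d_obs: float,
    params: GeometryParams = GeometryParams(),
    tol_fraction: float = 0.15,
) -> SizeComparison:
    """Classify an observed hydrodynamic diameter against the flat model."""
    if d_obs <= 0:
        raise ValueError("d_obs must be positive")
    d_max = max_flat_diameter(model, params)
    if abs(d_obs - d_max) <= tol_fraction * d_max:
        verdict = "flat-consistent"
    elif d_obs < (1.0 - tol_fraction) * d_max:
        verdict = "flexible/compact"
    else:
        verdict = "larger-than-model"
    return SizeComparison(
        d_max=d_max, d_obs=d_obs, compactness=d_obs / d_max, verdict=verdict
    )


def read_dls_csv(path: Union[str, Path]) -> DlsDistribution:
    """Read a (diameter_nm, number_frequency) CSV."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    if {"diameter_nm", "number_frequency"}.issubset(df.columns):
        d, f = df["diameter_nm"], df["number_frequency"]
    elif len(cols) >= 2:
        d, f = df[cols[0]], df[cols[1]]
    else:
        raise ValueError(f"{path}: expected columns diameter_nm, number_frequency")
    return DlsDistribution(diameters=d.to_numpy(float), frequencies=f.to_numpy(float))


def write_dls_csv(dist: DlsDistribution, path: Union[str, Path]) -> None:
    import pandas as pd

    pd.DataFrame(
        {"diameter_nm": dist.diameters, "number_frequency": dist.frequencies}
    ).to_csv(path, index=False)
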