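"""Star-model stoichiometry: unit ratios, heme-location fractions, and
enumeration of chain multisets on a hexameric core.

The assembly is modelled as a "star": linear chains of heme-tethered
cytochrome units radiate from the heme-binding sites of a ring-shaped
homohexameric core.  A star model is the multiset of chain lengths
``{l_1, ..., l_k}`` with ``1 <= k <= n_sites`` occupied sites.

Heme accounting: every unit carries one surface-tethered heme.  The
terminal exposed heme of each chain occupies one core binding site, so
a chain of length ``l`` places 1 heme in a core site and ``l - 1``
hemes in cytochrome pockets, the distal unit's own pocket remaining
vacant (which is what terminates the chain).  For total units
``U = sum(l_i)`` and ``k`` chains the heme-location fractions are
therefore exactly

    f_core = k / U        f_cyt = (U - k) / U.

These fractions depend only on the totals ``(U, k)``; within a fixed
``(U, k)`` family only geometry, not heme location, can discriminate
between partitions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, List, Optional, Sequence, Tuple

__all__ = [
    "MonomerQuant",
    "StarModel",
    "HemeLocationFractions",
    "UnitRatio",
    "ModelFit",
    "EnumerationResult",
    "Tolerances",
    "units_per_hexamer",
    "heme_location_fractions",
    "partitions_exact",
    "enumerate_star_models",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves rounded up: 0.5 -> 1."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class MonomerQuant:
    """Paired monomer concentrations (uM +/- sd) of the two species.

    ``label`` names the preparation, e.g. "1/1" or "3/1" for the molar
    equivalence of cytochrome units toward core heme-binding sites at
    mixing time.
    """

    c_cyt: float
    sd_cyt: float
    c_hthp: float
    sd_hthp: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.c_cyt <= 0 or self.c_hthp <= 0:
            raise ValueError("monomer concentrations must be positive")
        if self.sd_cyt < 0 or self.sd_hthp < 0:
            raise ValueError("standard deviations must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "MonomerQuant":
        return cls(
            c_cyt=d["c_cyt"],
            sd_cyt=d.get("sd_cyt", 0.0),
            c_hthp=d["c_hthp"],
            sd_hthp=d.get("sd_hthp", 0.0),
            label=d.get("label", ""),
        )


@dataclass(frozen=True)
class StarModel:
    """Multiset of chain lengths attached to an ``n_sites``-site core."""

    chains: Tuple[int, ...]
    n_sites: int = 6

    def __post_init__(self) -> None:
        chains = tuple(sorted((int(c) for c in self.chains), reverse=True))
        if not chains:
            raise ValueError("a star model needs at least one chain")
        if any(c < 1 for c in chains):
            raise ValueError("every chain length must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if len(chains) > self.n_sites:
            raise ValueError(
                f"{len(chains)} chains exceed the {self.n_sites} core binding sites"
            )
        object.__setattr__(self, "chains", chains)

    @property
    def total_units(self) -> int:
        """U: total cytochrome units across all chains."""
        return sum(self.chains)

    @property
    def n_chains(self) -> int:
        """k: number of chains = number of occupied core sites."""
        return len(self.chains)

    @property
    def vacant_sites(self) -> int:
        return self.n_sites - self.n_chains

    def __str__(self) -> str:
        return "{" + ",".join(str(c) for c in self.chains) + "}"


@dataclass(frozen=True)
class HemeLocationFractions:
    """Exact heme-location fractions of a star model."""

    f_cyt: Fraction
    f_hthp: Fraction

    def __post_init__(self) -> None:
        if self.f_cyt + self.f_hthp != 1:
            raise ValueError("fractions must sum to 1 exactly")

    @property
    def f_cyt_float(self) -> float:
        return float(self.f_cyt)

    @property
    def f_hthp_float(self) -> float:
        return float(self.f_hthp)

    def to_dict(self) -> dict:
        return {
            "f_cyt": str(self.f_cyt),
            "f_hthp": str(self.f_hthp),
            "f_cyt_decimal": float(self.f_cyt),
            "f_hthp_decimal": float(self.f_hthp),
        }


def heme_location_fractions(model: StarModel) -> HemeLocationFractions:
    """Exact heme-location fractions ``((U-k)/U, k/U)`` of a model.

    Each chain terminates in one core-bound heme; the remaining hemes
    of its units sit in cytochrome pockets.
    """
    U = model.total_units
    k = model.n_chains
    return HemeLocationFractions(f_cyt=Fraction(U - k, U), f_hthp=Fraction(k, U))


@dataclass(frozen=True)
class UnitRatio:
    """Cytochrome units per core hexamer, with propagated sd."""

    value: float
    sd: float

    @property
    def rounded(self) -> int:
        """Round-half-up integer unit count (the unrounded value is kept)."""
        return round_half_up(self.value)

    def to_dict(self) -> dict:
        return {"value": self.value, "sd": self.sd, "rounded": self.rounded}


def units_per_hexamer(q: MonomerQuant, n_sites: int = 6) -> UnitRatio:
    """Observed units per hexamer: ``n_sites * c_cyt / c_hthp``.

    The core protein always assembles as a hexamer, so the monomer
    concentration ratio times the site count gives the average number
    of cytochrome units conjugated per core.  The sd follows first-order
    (delta-method) propagation of the two relative errors.
    """
    ratio = n_sites * q.c_cyt / q.c_hthp
    rel = math.sqrt((q.sd_cyt / q.c_cyt) ** 2 + (q.sd_hthp / q.c_hthp) ** 2)
    return UnitRatio(value=ratio, sd=ratio * rel)


def partitions_exact(U: int, k: int) -> List[Tuple[int, ...]]:
    """All partitions of ``U`` into exactly ``k`` positive parts.

    Parts are returned in canonical non-increasing order without
    duplicates; ``U < k`` yields an empty list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if U < k:
        return []

    def rec(remaining: int, parts_left: int, max_part: int) -> Iterator[Tuple[int, ...]]:
        if parts_left == 1:
            if remaining <= max_part:
                yield (remaining,)
            return
        # first part at most max_part, and must leave >= 1 per later part
        hi = min(max_part, remaining - (parts_left - 1))
        # first part at least ceil(remaining / parts_left) keeps non-increasing order
        lo = -(-remaining // parts_left)
        for first in range(hi, lo - 1, -1):
            for rest in rec(remaining - first, parts_left - 1, first):
                yield (first,) + rest

    return list(rec(U, k, U))


@dataclass(frozen=True)
class ModelFit:
    """A candidate star model scored against the observations."""

    model: StarModel
    U: int
    k: int
    f_cyt: Fraction
    f_hthp: Fraction
    score: float

    def to_dict(self) -> dict:
        return {
            "chains": list(self.model.chains),
            "n_sites": self.model.n_sites,
            "U": self.U,
            "k": self.k,
            "vacant_sites": self.model.vacant_sites,
            "f_cyt": str(self.f_cyt),
            "f_hthp": str(self.f_hthp),
            "f_cyt_decimal": float(self.f_cyt),
            "f_hthp_decimal": float(self.f_hthp),
            "score": self.score,
        }


@dataclass(frozen=True)
class Tolerances:
    """Score weights for model enumeration.

    ``sigma_U``/``sigma_f`` override the automatic weights.  By default
    the weights follow the observations' own uncertainties
    (chi-square weighting): ``sigma_U = max(sd_U, 0.5)`` and, when a
    finite sd accompanies the observed fraction,
    ``sigma_f = max(sd_f, 1e-3)``; without one, a conservative flat
    ``sigma_f = 0.05`` is used.
    """

    sigma_U: Optional[float] = None
    sigma_f: Optional[float] = None
    f_sigma_floor: float = 1e-3
    f_sigma_default: float = 0.05


class EnumerationResult(Sequence):
    """Ranked list of :class:`ModelFit`, possibly empty with diagnostic."""

    def __init__(self, models: List[ModelFit], diagnostic: Optional[str] = None):
        self.models = models
        self.diagnostic = diagnostic

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, i):
        return self.models[i]

    def __iter__(self):
        return iter(self.models)

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "diagnostic": self.diagnostic,
                "models": [m.to_dict() for m in self.models],
            },
            **kwargs,
        )


def enumerate_star_models(
    U_obs: float,
    f_cyt_obs: float,
    sd_U: float = 0.0,
    sd_f: Optional[float] = None,
    n_sites: int = 6,
    tolerances: Optional[Tolerances] = None,
    k_range: Optional[Tuple[int, int]] = None,
) -> EnumerationResult:
    """Enumerate and rank star models against observed (U, f_cyt).

    Candidates are every partition of ``U`` into ``k`` positive parts
    for ``k`` in 1..n_sites and ``U`` within ``round(U_obs +/- span)``
    where ``span = max(2 * sd_U, 2)``.  Each candidate is scored by

        score = ((U - U_obs) / sigma_U)**2 + ((f_cyt - f_cyt_obs) / sigma_f)**2

    (see :class:`Tolerances` for the weights) and the list is sorted by
    score, ties broken by smaller U, then larger k, then lexicographic
    chain multiset.  ``k_range`` restricts the chain count, e.g. to
    force a fully occupied core.
    """
    if U_obs <= 0:
        raise ValueError("U_obs must be positive")
    if not (0.0 <= f_cyt_obs <= 1.0):
        raise ValueError("f_cyt_obs must lie in [0, 1]")
    if sd_U < 0:
        raise ValueError("sd_U must be non-negative")
    tol = tolerances or Tolerances()
    sigma_U = tol.sigma_U if tol.sigma_U is not None else max(sd_U, 0.5)
    if tol.sigma_f is not None:
        sigma_f = tol.sigma_f
    elif sd_f is not None and math.isfinite(sd_f) and sd_f >= 0:
        sigma_f = max(sd_f, tol.f_sigma_floor)
    else:
        sigma_f = tol.f_sigma_default

    span = max(2.0 * sd_U, 2.0)
    U_lo = max(1, round_half_up(U_obs - span))
    U_hi = round_half_up(U_obs + span)
    k_lo, k_hi = (1, n_sites) if k_range is None else k_range
    if not (1 <= k_lo <= k_hi <= n_sites):
        raise ValueError(f"invalid k_range {k_range} for n_sites={n_sites}")

    fits: List[ModelFit] = []
    for U in range(U_lo, U_hi + 1):
        for k in range(k_lo, min(k_hi, U) + 1):
            f_cyt = Fraction(U - k, U)
            score = ((U - U_obs) / sigma_U) ** 2 + (
                (float(f_cyt) - f_cyt_obs) / sigma_f
            ) ** 2
            for chains in partitions_exact(U, k):
                model = StarModel(chains=chains, n_sites=n_sites)
                fits.append(
                    ModelFit(
                        model=model,
                        U=U,
                        k=k,
                        f_cyt=f_cyt,
                        f_hthp=Fraction(k, U),
                        score=score,
                    )
                )
    if not fits:
        return EnumerationResult(
            [],
            diagnostic=(
                f"no feasible chain multisets for U in [{U_lo}, {U_hi}] and "
                f"k in [{k_lo}, {k_hi}] on a {n_sites}-site core"
            ),
        )
    fits.sort(key=lambda m: (m.score, m.U, -m.k, m.model.chains))
    return EnumerationResult(fits)
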