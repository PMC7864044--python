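"""Synthetic data generators with known ground truth.

Every input the analysis consumes can be generated here: two-host basis
absorption spectra and noisy mixtures, Coomassie-stained gel images
with calibration ladders, and number-weighted DLS distributions.  Each
generator is a pure function of its parameters and seed and returns a
:class:`SyntheticTruth` record alongside the data, so recovery can be
checked end to end.

The emulation is statistical, not photophysical: spectra are sums of
Gaussian bands at the literature peak positions (heights are free
parameters chosen so the 623-630 nm region is diagnostic of the
tyrosine-coordinated host), gel bands are Gaussian in migration
distance with protein-specific staining coefficients and multiplicative
(CV-based) area noise matching the 10-20 % scatter typical of stained
band areas, and DLS number distributions are binned log-normal samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .densitometry import BandWindow, LaneProfile, LaneRect, extract_lane_profiles
from .geometry import DlsDistribution
from .spectra import (
    DEFAULT_FIT_WINDOW,
    AbsorbanceSpectrum,
    BasisPair,
    normalize,
)
from .stoichiometry import StarModel

__all__ = [
    "BandSpec",
    "SyntheticTruth",
    "GelLayout",
    "GelDataset",
    "ScenarioData",
    "DEFAULT_CYT_BANDS",
    "DEFAULT_HTHP_BANDS",
    "DEFAULT_STAINING_COEFFS",
    "HTHP_LADDER_UM",
    "CYT_LADDER_UM",
    "make_basis_spectra",
    "make_mixture",
    "make_gel",
    "make_dls",
    "make_scenario",
]


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: center (nm), sigma (nm), height."""

    center: float
    width_sigma: float
    relative_height: float

    def __post_init__(self) -> None:
        if self.width_sigma <= 0:
            raise ValueError("width_sigma must be positive")
        if self.relative_height <= 0:
            raise ValueError("relative_height must be positive")


#: Cytochrome-type host: Soret at 417 nm, Q bands at 532/562 nm.
DEFAULT_CYT_BANDS: Tuple[BandSpec, ...] = (
    BandSpec(417.0, 10.0, 1.0),
    BandSpec(532.0, 12.0, 0.08),
    BandSpec(562.0, 10.0, 0.09),
)

#: Hexameric tyrosine-coordinated host: Soret at 402 nm, bands at
#: 500/534.5 nm and the diagnostic charge-transfer band at 623 nm.
DEFAULT_HTHP_BANDS: Tuple[BandSpec, ...] = (
    BandSpec(402.0, 10.0, 1.0),
    BandSpec(500.0, 12.0, 0.08),
    BandSpec(534.5, 12.0, 0.06),
    BandSpec(623.0, 14.0, 0.08),
)

#: Gel band depth (intensity units) per uM, per protein.  Staining
#: response is protein-specific, hence distinct coefficients.
DEFAULT_STAINING_COEFFS: Dict[str, float] = {"cyt": 0.018, "hthp": 0.045}

#: Calibration ladder concentrations (uM): hexamer monomer 2-10 uM,
#: cytochrome unit 2-30 uM.
HTHP_LADDER_UM: Tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0)
CYT_LADDER_UM: Tuple[float, ...] = (2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying one generated dataset."""

    seed: int
    true_f_cyt: Optional[float] = None
    true_concentrations: Optional[Dict[str, Dict[str, float]]] = None
    true_chains: Optional[StarModel] = None
    true_dls_median: Optional[float] = None
    noise: Dict[str, float] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "true_f_cyt": self.true_f_cyt,
            "true_concentrations": self.true_concentrations,
            "true_chains": list(self.true_chains.chains) if self.true_chains else None,
            "true_dls_median": self.true_dls_median,
            "noise": self.noise,
            "warnings": self.warnings,
        }


def _band_sum(grid: np.ndarray, bands: Sequence[BandSpec]) -> np.ndarray:
    y = np.zeros_like(grid)
    for b in bands:
        y += b.relative_height * np.exp(-((grid - b.center) ** 2) / (2 * b.width_sigma**2))
    return y


def make_basis_spectra(
    cyt_bands: Sequence[BandSpec] = DEFAULT_CYT_BANDS,
    hthp_bands: Sequence[BandSpec] = DEFAULT_HTHP_BANDS,
    grid: Optional[Sequence[float]] = None,
    window: Tuple[float, float] = DEFAULT_FIT_WINDOW,
) -> BasisPair:
    """Gaussian-band basis spectra, unit-area normalized on ``window``."""
    if not cyt_bands or not hthp_bands:
        raise ValueError("band lists must be non-empty")
    g = np.arange(250.0, 800.0 + 0.5, 1.0) if grid is None else np.asarray(grid, float)
    for name, bands in (("cyt", cyt_bands), ("hthp", hthp_bands)):
        for b in bands:
            if not (g[0] <= b.center <= g[-1]):
                raise ValueError(f"{name} band at {b.center} nm lies outside the grid")
    a = AbsorbanceSpectrum(g, _band_sum(g, cyt_bands), label="cyt-like basis")
    b = AbsorbanceSpectrum(g, _band_sum(g, hthp_bands), label="hthp-like basis")
    a = normalize(a, "unit-area", window=window)
    b = normalize(b, "unit-area", window=window)
    return BasisPair(basis_a=a, basis_b=b, grid=g)


def make_mixture(
    basis: BasisPair,
    f_cyt: float,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> Tuple[AbsorbanceSpectrum, SyntheticTruth]:
    """Noisy convex combination ``f*a + (1-f)*b`` of the basis spectra.

    ``noise_sd`` is the additive Gaussian noise level expressed as a
    fraction of the noise-free mixture's Soret maximum.
    """
    if not (0.0 <= f_cyt <= 1.0):
        raise ValueError("f_cyt must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    clean = f_cyt * basis.basis_a.absorbances + (1.0 - f_cyt) * basis.basis_b.absorbances
    scale = noise_sd * float(clean.max())
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, scale, size=clean.size) if scale > 0 else clean
    mix = AbsorbanceSpectrum(
        basis.grid,
        noisy,
        label=f"synthetic mixture f_cyt={f_cyt:g}",
        normalization=basis.basis_a.normalization,
    )
    truth = SyntheticTruth(
        seed=seed, true_f_cyt=f_cyt, noise={"spectrum_noise_sd": noise_sd}
    )
    return mix, truth


# ---------------------------------------------------------------------------
# Gel images


@dataclass(frozen=True)
class GelLayout:
    """Geometry of a synthetic gel image.

    Migration runs down the rows.  Apparent masses are mapped to rows
    by a fixed log-linear rule ``row = offset + slope * log10(mass_ref
    / mass)``; only the relative band separation matters downstream.
    """

    n_lanes: int
    height: int = 240
    lane_width: int = 20
    lane_gap: int = 8
    margin: int = 10
    band_sigma: float = 4.0
    apparent_masses_kda: Tuple[float, float] = (12.0, 6.0)  # (cyt, hthp)

    def __post_init__(self) -> None:
        if self.n_lanes < 1:
            raise ValueError("need at least one lane")

    @property
    def width(self) -> int:
        return 2 * self.margin + self.n_lanes * self.lane_width + (
            self.n_lanes - 1
        ) * self.lane_gap

    def lane_rects(self) -> List[LaneRect]:
        return [
            LaneRect(
                row0=0,
                col0=self.margin + i * (self.lane_width + self.lane_gap),
                height=self.height,
                width=self.lane_width,
            )
            for i in range(self.n_lanes)
        ]

    def band_row(self, mass_kda: float) -> float:
        # anchor: 12 kDa at 35 % of the height; slope spans half the
        # gel per mass decade
        slope = 1.16 * self.height
        return 0.35 * self.height + slope * (math.log10(12.0) - math.log10(mass_kda))

    def band_windows(self) -> Dict[str, BandWindow]:
        """Band windows centered on the two expected apparent masses."""
        half = 3.5 * self.band_sigma
        out = {}
        for species, mass in zip(("cyt", "hthp"), self.apparent_masses_kda):
            r = self.band_row(mass)
            out[species] = BandWindow(start=r - half, end=r + half, flank_width=5)
        return out


@dataclass
class GelDataset:
    """A rendered gel with its extracted profiles and ground truth."""

    image: np.ndarray
    profiles: List[LaneProfile]
    lane_rects: List[LaneRect]
    band_windows: Dict[str, BandWindow]
    lane_ids: List[str]
    truth: SyntheticTruth


def make_gel(
    truth_concs: Sequence[Dict[str, float]],
    staining_coeffs: Optional[Dict[str, float]] = None,
    layout: Optional[GelLayout] = None,
    baseline_drift: float = 0.05,
    noise_cv: float = 0.15,
    seed: int = 0,
    lane_ids: Optional[Sequence[str]] = None,
) -> GelDataset:
    """Render a synthetic stained gel.

    ``truth_concs`` holds one dict per lane mapping species ("cyt",
    "hthp") to loaded monomer concentration in uM.  Band amplitude is
    concentration times the species' staining coefficient, perturbed by
    multiplicative Gaussian noise of coefficient of variation
    ``noise_cv`` (the 10-20 % area scatter of stained bands).  A linear
    background drift down the migration axis and faint pixel noise are
    added.  Bands closer than 3 sigma trigger a warning in the truth
    record rather than an error.
    """
    coeffs = dict(DEFAULT_STAINING_COEFFS if staining_coeffs is None else staining_coeffs)
    if any(v <= 0 for v in coeffs.values()):
        raise ValueError("staining coefficients must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if not truth_concs:
        raise ValueError("need at least one lane")
    layout = layout or GelLayout(n_lanes=len(truth_concs))
    if layout.n_lanes != len(truth_concs):
        raise ValueError(
            f"layout has {layout.n_lanes} lanes but {len(truth_concs)} were specified"
        )
    if lane_ids is None:
        lane_ids = [f"lane{i + 1:02d}" for i in range(layout.n_lanes)]
    rng = np.random.default_rng(seed)

    rows = np.arange(layout.height, dtype=float)
    background = 0.85 - baseline_drift * rows / layout.height
    image = np.tile(background[:, None], (1, layout.width))

    truth = SyntheticTruth(
        seed=seed,
        true_concentrations={},
        noise={"noise_cv": noise_cv, "baseline_drift": baseline_drift},
    )
    mass_by_species = dict(zip(("cyt", "hthp"), layout.apparent_masses_kda))
    band_rows = {sp: layout.band_row(m) for sp, m in mass_by_species.items()}
    centers = sorted(band_rows.values())
    for lo, hi in zip(centers, centers[1:]):
        if hi - lo < 3 * layout.band_sigma:
            truth.warnings.append(
                f"bands at rows {lo:.1f} and {hi:.1f} are closer than 3 sigma "
                f"({3 * layout.band_sigma:.1f} rows); areas may overlap"
            )

    rects = layout.lane_rects()
    for rect, lane_id, concs in zip(rects, lane_ids, truth_concs):
        truth.true_concentrations[lane_id] = dict(concs)
        for species, conc in concs.items():
            if species not in coeffs:
                raise ValueError(f"no staining coefficient for species {species!r}")
            if conc < 0:
                raise ValueError("concentrations must be non-negative")
            if conc == 0:
                continue
            mult = max(1.0 + rng.normal(0.0, noise_cv), 0.0) if noise_cv > 0 else 1.0
            amp = conc * coeffs[species] * mult
            band = amp * np.exp(
                -((rows - band_rows[species]) ** 2) / (2 * layout.band_sigma**2)
            )
            image[:, rect.col_slice] -= band[:, None]
    image += rng.normal(0.0, 0.002, size=image.shape)
    np.clip(image, 0.0, None, out=image)

    profiles = extract_lane_profiles(image, rects, lane_ids=list(lane_ids))
    return GelDataset(
        image=image,
        profiles=profiles,
        lane_rects=rects,
        band_windows=layout.band_windows(),
        lane_ids=list(lane_ids),
        truth=truth,
    )


def make_dls(
    median_nm: float = 8.3,
    sigma_log: float = 0.2,
    n_particles: int = 10_000,
    bins: int = 64,
    seed: int = 0,
) -> Tuple[DlsDistribution, SyntheticTruth]:
    """Binned log-normal number-weighted diameter distribution."""
    if median_nm <= 0:
        raise ValueError("median_nm must be positive")
    if sigma_log <= 0:
        raise ValueError("sigma_log must be positive")
    if bins < 3:
        raise ValueError("need at least 3 bins")
    rng = np.random.default_rng(seed)
    sample = rng.lognormal(mean=math.log(median_nm), sigma=sigma_log, size=n_particles)
    counts, edges = np.histogram(sample, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dist = DlsDistribution(diameters=centers, frequencies=counts.astype(float))
    truth = SyntheticTruth(
        seed=seed,
        true_dls_median=median_nm,
        noise={"sigma_log": sigma_log, "n_particles": float(n_particles)},
    )
    return dist, truth


# ---------------------------------------------------------------------------
# Full scenario: spectra + gel + DLS for one assembly preparation


@dataclass
class ScenarioData:
    """Everything one fractionated-assembly analysis consumes."""

    basis: BasisPair
    mixture: AbsorbanceSpectrum
    gel: GelDataset
    sample_lane_ids: List[str]
    calibration_lanes: Dict[str, Dict[str, float]]  # species -> lane_id -> uM
    dls: DlsDistribution
    truth: SyntheticTruth


def make_scenario(
    chains: Sequence[int] = (2, 2, 2, 2, 2, 1),
    c_hthp: float = 2.6,
    n_sample_lanes: int = 2,
    spectrum_noise_sd: float = 0.01,
    gel_noise_cv: float = 0.15,
    dls_median_nm: float = 8.3,
    seed: int = 0,
) -> ScenarioData:
    """Generate a complete synthetic assembly experiment.

    The true star model fixes the heme-location fraction
    ``f_cyt = (U-k)/U`` of the mixture spectrum and, together with the
    core monomer concentration ``c_hthp``, the cytochrome concentration
    ``c_cyt = (U/6) * c_hthp``.  The gel carries the fractionated
    sample in ``n_sample_lanes`` replicate lanes plus both calibration
    ladders, mirroring a single-gel quantification with standards.
    """
    model = StarModel(chains=tuple(chains))
    U, k = model.total_units, model.n_chains
    f_cyt = (U - k) / U
    c_cyt = U / model.n_sites * c_hthp

    basis = make_basis_spectra()
    mixture, _ = make_mixture(basis, f_cyt, noise_sd=spectrum_noise_sd, seed=seed)

    sample_ids = [f"sample{i + 1}" for i in range(n_sample_lanes)]
    lanes: List[Dict[str, float]] = [
        {"cyt": c_cyt, "hthp": c_hthp} for _ in sample_ids
    ]
    lane_ids = list(sample_ids)
    calibration: Dict[str, Dict[str, float]] = {"hthp": {}, "cyt": {}}
    for i, conc in enumerate(HTHP_LADDER_UM):
        lid = f"hthp_std{i + 1}"
        lanes.append({"hthp": conc})
        lane_ids.append(lid)
        calibration["hthp"][lid] = conc
    for i, conc in enumerate(CYT_LADDER_UM):
        lid = f"cyt_std{i + 1}"
        lanes.append({"cyt": conc})
        lane_ids.append(lid)
        calibration["cyt"][lid] = conc

    gel = make_gel(
        lanes,
        noise_cv=gel_noise_cv,
        seed=seed + 1,
        lane_ids=lane_ids,
        layout=GelLayout(n_lanes=len(lanes)),
    )
    dls, _ = make_dls(median_nm=dls_median_nm, seed=seed + 2)

    truth = SyntheticTruth(
        seed=seed,
        true_f_cyt=f_cyt,
        true_concentrations=gel.truth.true_concentrations,
        true_chains=model,
        true_dls_median=dls_median_nm,
        noise={
            "spectrum_noise_sd": spectrum_noise_sd,
            "gel_noise_cv": gel_noise_cv,
        },
        warnings=list(gel.truth.warnings),
    )
    return ScenarioData(
        basis=basis,
        mixture=mixture,
        gel=gel,
        sample_lane_ids=sample_ids,
        calibration_lanes=calibration,
        dls=dls,
        truth=truth,
    )
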