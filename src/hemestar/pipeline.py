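"""End-to-end orchestration: config, stages, report, SEC plumbing.

The pipeline composes the analysis stages for each fractionated
assembly sample:

1. constrained two-basis unmixing of the mixture spectrum gives the
   heme-location fraction ``f_cyt`` with a delta-method sd;
2. gel densitometry gives monomer concentrations (uM +/- sd) of the
   two species from calibration ladders run on the same gel;
3. the concentration ratio gives units-per-hexamer ``U`` with
   propagated sd, and candidate star models are enumerated and ranked
   against ``(U, f_cyt)``;
4. the top model's flat-arrangement maximum diameter is compared with
   the number-weighted DLS summary to classify the solution shape.

SEC calibration (log-linear molecular mass vs elution volume) is
included as minor plumbing for apparent-mass estimates; elution
volumes themselves are never predicted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml
from scipy import stats

from . import densitometry as dens
from . import geometry as geom
from . import spectra as spec
from . import stoichiometry as stoi

__all__ = [
    "ConfigError",
    "RunConfig",
    "SecCalibration",
    "ApparentMass",
    "fit_sec_calibration",
    "apparent_mass",
    "run_pipeline",
    "analyze_sample",
    "default_config_dict",
]

log = logging.getLogger("hemestar.pipeline")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


# ---------------------------------------------------------------------------
# SEC calibration


@dataclass(frozen=True)
class SecCalibration:
    """Log-linear SEC column calibration: log10(mass/kDa) vs volume/mL."""

    standards: Tuple[Tuple[float, float], ...]  # (elution volume mL, mass kDa)
    slope: float
    intercept: float
    volume_range: Tuple[float, float]


@dataclass(frozen=True)
class ApparentMass:
    """Apparent molecular mass (kDa) from an elution volume."""

    mass_kda: float
    volume_ml: float
    extrapolated: bool


def fit_sec_calibration(standards: Sequence[Tuple[float, float]]) -> SecCalibration:
    """Least-squares fit of log10(mass) on elution volume (>= 3 standards)."""
    if len(standards) < 3:
        raise ValueError(f"SEC calibration needs >= 3 standards, got {len(standards)}")
    vols = np.array([s[0] for s in standards], dtype=float)
    masses = np.array([s[1] for s in standards], dtype=float)
    if np.unique(vols).size != vols.size:
        raise ValueError("standard elution volumes must be distinct")
    if np.any(masses <= 0):
        raise ValueError("standard masses must be positive")
    fit = stats.linregress(vols, np.log10(masses))
    return SecCalibration(
        standards=tuple((float(v), float(m)) for v, m in standards),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        volume_range=(float(vols.min()), float(vols.max())),
    )


def apparent_mass(cal: SecCalibration, volume_ml: float) -> ApparentMass:
    """Invert the SEC calibration at one elution volume."""
    mass = 10.0 ** (cal.intercept + cal.slope * volume_ml)
    lo, hi = cal.volume_range
    return ApparentMass(
        mass_kda=float(mass),
        volume_ml=float(volume_ml),
        extrapolated=not (lo <= volume_ml <= hi),
    )


# ---------------------------------------------------------------------------
# Run configuration


def _require(d: dict, key: str, ctx: str):
    if key not in d:
        raise ConfigError(f"missing required config key {ctx}.{key}")
    return d[key]


def _band_window(d: dict, ctx: str) -> dens.BandWindow:
    try:
        return dens.BandWindow(
            start=float(_require(d, "start", ctx)),
            end=float(_require(d, "end", ctx)),
            flank_width=int(d.get("flank_width", 5)),
        )
    except ValueError as e:
        raise ConfigError(f"{ctx}: {e}") from e


@dataclass
class SampleConfig:
    name: str
    mixture: Path
    lanes: List[str]
    dls: Optional[Path] = None


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Built from a YAML mapping via :meth:`from_yaml`; all paths are
    resolved relative to the config file's directory and must exist.
    """

    basis_cyt: Path
    basis_hthp: Path
    window: Tuple[float, float]
    gel_profiles: Path
    band_windows: Dict[str, dens.BandWindow]
    calibration: Dict[str, Dict[str, float]]
    samples: List[SampleConfig]
    n_sites: int = 6
    tolerances: stoi.Tolerances = field(default_factory=stoi.Tolerances)
    geometry: geom.GeometryParams = field(default_factory=geom.GeometryParams)
    tol_fraction: float = 0.15
    dls_statistic: str = "mode"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as e:
            raise ConfigError(f"{path}: invalid YAML: {e}") from e
        if not isinstance(raw, dict) or not raw:
            raise ConfigError(f"{path}: empty or non-mapping config")
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Union[str, Path] = ".") -> "RunConfig":
        base = Path(base_dir)

        def resolve(p, ctx) -> Path:
            q = base / str(p)
            if not q.exists():
                raise ConfigError(f"{ctx}: path {q} does not exist")
            return q

        basis = _require(raw, "basis", "")
        gel = _require(raw, "gel", "")
        window = tuple(float(x) for x in raw.get("window", spec.DEFAULT_FIT_WINDOW))
        if len(window) != 2 or not (200 <= window[0] < window[1] <= 1000):
            raise ConfigError(f"window must be [lo, hi] within 200-1000 nm, got {window}")

        band_windows = {
            sp: _band_window(w, f"gel.band_windows.{sp}")
            for sp, w in _require(gel, "band_windows", "gel").items()
        }
        calibration = {
            sp: {str(k): float(v) for k, v in lanes.items()}
            for sp, lanes in _require(gel, "calibration", "gel").items()
        }
        for sp in ("cyt", "hthp"):
            if sp not in band_windows:
                raise ConfigError(f"gel.band_windows must define {sp!r}")
            if sp not in calibration or len(calibration[sp]) < 3:
                raise ConfigError(f"gel.calibration.{sp} needs >= 3 ladder lanes")

        samples = []
        for i, s in enumerate(_require(raw, "samples", "")):
            samples.append(
                SampleConfig(
                    name=str(s.get("name", f"sample{i + 1}")),
                    mixture=resolve(_require(s, "mixture", f"samples[{i}]"), f"samples[{i}].mixture"),
                    lanes=[str(x) for x in _require(s, "lanes", f"samples[{i}]")],
                    dls=resolve(s["dls"], f"samples[{i}].dls") if s.get("dls") else None,
                )
            )
        if not samples:
            raise ConfigError("samples list is empty")

        enum_cfg = raw.get("enumeration", {})
        geo_cfg = raw.get("geometry", {})
        n_sites = int(enum_cfg.get("n_sites", 6))
        if n_sites < 1:
            raise ConfigError("enumeration.n_sites must be >= 1")
        tol_fraction = float(geo_cfg.get("tol_fraction", 0.15))
        if not (0 < tol_fraction < 1):
            raise ConfigError("geometry.tol_fraction must lie in (0, 1)")
        dls_statistic = str(raw.get("dls_statistic", "mode"))
        if dls_statistic not in ("mode", "mean"):
            raise ConfigError("dls_statistic must be 'mode' or 'mean'")

        return cls(
            basis_cyt=resolve(_require(basis, "cyt", "basis"), "basis.cyt"),
            basis_hthp=resolve(_require(basis, "hthp", "basis"), "basis.hthp"),
            window=window,
            gel_profiles=resolve(_require(gel, "profiles", "gel"), "gel.profiles"),
            band_windows=band_windows,
            calibration=calibration,
            samples=samples,
            n_sites=n_sites,
            tolerances=stoi.Tolerances(
                sigma_U=enum_cfg.get("sigma_U"), sigma_f=enum_cfg.get("sigma_f")
            ),
            geometry=geom.GeometryParams(
                d_core=float(geo_cfg.get("d_core", 6.0)),
                d_unit=float(geo_cfg.get("d_unit", 2.5)),
            ),
            tol_fraction=tol_fraction,
            dls_statistic=dls_statistic,
            seed=int(raw.get("seed", 0)),
        )


def default_config_dict() -> dict:
    """Template configuration with all defaults spelled out."""
    return {
        "window": [350.0, 700.0],
        "basis": {"cyt": "basis_cyt.csv", "hthp": "basis_hthp.csv"},
        "gel": {
            "profiles": "lane_profiles.csv",
            "band_windows": {
                "cyt": {"start": 70.0, "end": 98.0, "flank_width": 5},
                "hthp": {"start": 154.0, "end": 182.0, "flank_width": 5},
            },
            "calibration": {
                "hthp": {"hthp_std1": 2.0, "hthp_std2": 4.0, "hthp_std3": 6.0,
                         "hthp_std4": 8.0, "hthp_std5": 10.0},
                "cyt": {"cyt_std1": 2.0, "cyt_std2": 5.0, "cyt_std3": 10.0,
                        "cyt_std4": 15.0, "cyt_std5": 20.0, "cyt_std6": 25.0,
                        "cyt_std7": 30.0},
            },
        },
        "samples": [
            {"name": "1/1", "mixture": "mixture.csv",
             "lanes": ["sample1", "sample2"], "dls": "dls.csv"}
        ],
        "enumeration": {"n_sites": 6, "sigma_U": None, "sigma_f": None},
        "geometry": {"d_core": 6.0, "d_unit": 2.5, "tol_fraction": 0.15},
        "dls_statistic": "mode",
        "seed": 0,
    }


# ---------------------------------------------------------------------------
# Pipeline


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _quantify_species(
    profiles: Dict[str, dens.LaneProfile],
    species: str,
    band_window: dens.BandWindow,
    ladder: Dict[str, float],
    sample_lanes: Sequence[str],
) -> Tuple[dens.CalibrationCurve, dens.ConcentrationEstimate, List[float]]:
    """Fit one species' calibration and estimate the sample concentration.

    Replicate sample lanes are averaged at the area level and the
    replicate count enters the inverse-prediction standard error.
    """
    concs, areas = [], []
    for lane_id, conc in ladder.items():
        if lane_id not in profiles:
            raise ValueError(f"calibration lane {lane_id!r} missing from profiles")
        concs.append(conc)
        areas.append(dens.peak_area(profiles[lane_id], band_window))
    curve = dens.fit_calibration(concs, areas)
    sample_areas = []
    for lane_id in sample_lanes:
        if lane_id not in profiles:
            raise ValueError(f"sample lane {lane_id!r} missing from profiles")
        sample_areas.append(dens.peak_area(profiles[lane_id], band_window))
    estimate = dens.estimate_concentration(
        curve, float(np.mean(sample_areas)), n_replicates=len(sample_areas)
    )
    log.info(
        "densitometry[%s]: r2=%.4f slope=%.4g; sample areas %s -> %.3g +/- %.2g uM",
        species, curve.r_squared, curve.slope,
        [round(a, 3) for a in sample_areas], estimate.value, estimate.sd,
    )
    return curve, estimate, sample_areas


def analyze_sample(
    name: str,
    mixture: spec.AbsorbanceSpectrum,
    basis: spec.BasisPair,
    window: Tuple[float, float],
    profiles: Dict[str, dens.LaneProfile],
    band_windows: Dict[str, dens.BandWindow],
    calibration: Dict[str, Dict[str, float]],
    sample_lanes: Sequence[str],
    dls_dist: Optional[geom.DlsDistribution] = None,
    n_sites: int = 6,
    tolerances: Optional[stoi.Tolerances] = None,
    geometry_params: geom.GeometryParams = geom.GeometryParams(),
    tol_fraction: float = 0.15,
    dls_statistic: str = "mode",
    top_n: int = 10,
) -> dict:
    """Run all stages for one sample and return the report section."""
    unmix = spec.unmix_two_component(mixture, basis, window=window)
    log.info("unmix[%s]: f_cyt=%.4f +/- %.4f (sse=%.3g, n=%d)",
             name, unmix.f_a, unmix.f_sd, unmix.sse, unmix.n_points)

    curves, estimates = {}, {}
    for species in ("cyt", "hthp"):
        curves[species], estimates[species], _ = _quantify_species(
            profiles, species, band_windows[species], calibration[species], sample_lanes
        )
    quant = stoi.MonomerQuant(
        c_cyt=estimates["cyt"].value,
        sd_cyt=estimates["cyt"].sd,
        c_hthp=estimates["hthp"].value,
        sd_hthp=estimates["hthp"].sd,
        label=name,
    )
    ratio = stoi.units_per_hexamer(quant, n_sites=n_sites)
    log.info("stoichiometry[%s]: U = %.2f +/- %.2f (rounded %d)",
             name, ratio.value, ratio.sd, ratio.rounded)

    ranked = stoi.enumerate_star_models(
        U_obs=ratio.value,
        f_cyt_obs=unmix.f_a,
        sd_U=ratio.sd,
        sd_f=unmix.f_sd,
        n_sites=n_sites,
        tolerances=tolerances,
    )
    report: dict = {
        "sample": name,
        "unmixing": unmix.to_dict(),
        "calibration": {sp: curves[sp].to_dict() for sp in curves},
        "concentrations_uM": {sp: estimates[sp].to_dict() for sp in estimates},
        "units_per_hexamer": ratio.to_dict(),
        "models": [m.to_dict() for m in ranked[:top_n]],
        "enumeration_diagnostic": ranked.diagnostic,
    }
    if len(ranked):
        top = ranked[0]
        d_max = geom.max_flat_diameter(top.model, geometry_params)
        report["top_model"] = top.to_dict()
        report["d_max_nm"] = d_max
        if dls_dist is not None:
            summary = geom.dls_summary(dls_dist)
            d_obs = summary.mode if dls_statistic == "mode" else summary.mean
            comparison = geom.compare_size(
                top.model, d_obs, geometry_params, tol_fraction=tol_fraction
            )
            report["dls"] = {"mode_nm": summary.mode, "mean_nm": summary.mean,
                             "statistic": dls_statistic}
            report["size_comparison"] = comparison.to_dict()
            log.info("geometry[%s]: d_max=%.1f nm, d_obs=%.1f nm -> %s",
                     name, d_max, d_obs, comparison.verdict)
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for every configured sample.

    Deterministic for fixed inputs: the report carries input digests
    but no timestamps.  Stage failures raise with the stage name.
    """
    digests = {
        "basis_cyt": _digest(config.basis_cyt),
        "basis_hthp": _digest(config.basis_hthp),
        "gel_profiles": _digest(config.gel_profiles),
    }
    log.info("inputs: %s", digests)

    def stage(label, fn, /, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ValueError, OSError) as e:
            raise RuntimeError(f"stage {label!r} failed: {e}") from e

    basis_a = stage("read-basis", spec.read_spectrum, config.basis_cyt, label="cyt basis")
    basis_b = stage("read-basis", spec.read_spectrum, config.basis_hthp, label="hthp basis")
    basis_a = stage("normalize", spec.normalize, basis_a, "unit-area", window=config.window)
    basis_b = stage("normalize", spec.normalize, basis_b, "unit-area", window=config.window)
    basis = stage("basis-pair", spec.BasisPair.from_spectra, basis_a, basis_b)

    profile_list = stage("read-profiles", dens.read_lane_profiles_csv, config.gel_profiles)
    profiles = {p.lane_id: p for p in profile_list}

    sample_reports = []
    for s in config.samples:
        mixture = stage("read-mixture", spec.read_spectrum, s.mixture)
        dls_dist = stage("read-dls", geom.read_dls_csv, s.dls) if s.dls else None
        sample_reports.append(
            stage(
                f"analyze[{s.name}]",
                analyze_sample,
                s.name,
                mixture,
                basis,
                config.window,
                profiles,
                config.band_windows,
                config.calibration,
                s.lanes,
                dls_dist=dls_dist,
                n_sites=config.n_sites,
                tolerances=config.tolerances,
                geometry_params=config.geometry,
                tol_fraction=config.tol_fraction,
                dls_statistic=config.dls_statistic,
            )
        )
    return {
        "inputs": digests,
        "window_nm": list(config.window),
        "n_sites": config.n_sites,
        "samples": sample_reports,
    }


def write_report(report: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
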