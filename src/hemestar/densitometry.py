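"""Gel densitometry: lane profiles, baseline-corrected band areas, and
linear calibration to monomer concentrations.

The quantification procedure mirrors standard SDS-PAGE image analysis:
identical rectangular regions of interest are placed over each lane,
intensity is summed across the lane width to give a band-density
profile against migration distance, each band's peak area is measured
after subtracting a linear baseline anchored on flanking points, and a
linear calibration curve (peak area vs known loaded concentration)
converts sample areas into monomer concentrations with an
inverse-prediction standard error.

Staining response (Coomassie Brilliant Blue) is protein-specific, so a
separate calibration curve is required per protein species.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

__all__ = [
    "LaneProfile",
    "LaneRect",
    "BandWindow",
    "CalibrationCurve",
    "ConcentrationEstimate",
    "extract_lane_profiles",
    "subtract_linear_baseline",
    "peak_area",
    "fit_calibration",
    "estimate_concentration",
    "read_lane_profiles_csv",
    "write_lane_profiles_csv",
]


@dataclass(frozen=True)
class LaneProfile:
    """Band-density profile of one gel lane.

    ``positions`` are migration distances (arbitrary units, strictly
    increasing, >= 20 points); ``intensities`` are band densities with
    dark bands mapped to positive peaks.  Baseline-corrected profiles
    may contain negative values.
    """

    positions: np.ndarray
    intensities: np.ndarray
    lane_id: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or inten.ndim != 1 or pos.size != inten.size:
            raise ValueError("positions and intensities must be equal-length 1-D arrays")
        if pos.size < 20:
            raise ValueError(f"profile needs at least 20 points, got {pos.size}")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(inten))):
            raise ValueError("profile contains non-finite values")
        pos.setflags(write=False)
        inten.setflags(write=False)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class LaneRect:
    """Rectangular lane region of interest: rows are the migration axis."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("lane rectangle must have positive height and width")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("lane rectangle origin must be non-negative")

    @property
    def col_slice(self) -> slice:
        return slice(self.col0, self.col0 + self.width)

    @property
    def row_slice(self) -> slice:
        return slice(self.row0, self.row0 + self.height)


@dataclass(frozen=True)
class BandWindow:
    """Positions bracketing one band, plus baseline anchor width.

    ``flank_width`` points immediately outside each edge of the window
    serve as baseline anchors.
    """

    start: float
    end: float
    flank_width: int = 5

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window start ({self.start}) must precede end ({self.end})")
        if self.flank_width < 3:
            raise ValueError("flank_width must be at least 3")


def extract_lane_profiles(
    image: np.ndarray,
    lane_layout: Sequence[LaneRect],
    lane_ids: Optional[Sequence[str]] = None,
) -> List[LaneProfile]:
    """Extract one band-density profile per lane rectangle.

    All rectangles must be identical in size (the procedure mandates
    identical regions so band areas are comparable across lanes), lie
    within the image, and not overlap.  Raw grayscale is inverted
    (image maximum minus pixel) so dark bands become positive peaks;
    intensity at each migration row is the sum across the lane width.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"image must be 2-D grayscale, got shape {img.shape}")
    if not lane_layout:
        raise ValueError("lane_layout is empty")
    h0, w0 = lane_layout[0].height, lane_layout[0].width
    for i, r in enumerate(lane_layout):
        if (r.height, r.width) != (h0, w0):
            raise ValueError(
                f"lane rectangle {i} has size {(r.height, r.width)}; all rectangles "
                f"must equal the first lane's size {(h0, w0)}"
            )
        if r.row0 + r.height > img.shape[0] or r.col0 + r.width > img.shape[1]:
            raise ValueError(f"lane rectangle {i} extends beyond the image bounds")
    for i, r in enumerate(lane_layout):
        for j, s in enumerate(lane_layout[:i]):
            if (
                r.row0 < s.row0 + s.height
                and s.row0 < r.row0 + r.height
                and r.col0 < s.col0 + s.width
                and s.col0 < r.col0 + r.width
            ):
                raise ValueError(f"lane rectangles {j} and {i} overlap")
    if lane_ids is None:
        lane_ids = [f"lane{i + 1:02d}" for i in range(len(lane_layout))]
    elif len(lane_ids) != len(lane_layout):
        raise ValueError("lane_ids length must match lane_layout length")
    inverted = float(img.max()) - img
    profiles = []
    for rect, lane_id in zip(lane_layout, lane_ids):
        block = inverted[rect.row_slice, rect.col_slice]
        profiles.append(
            LaneProfile(
                positions=np.arange(rect.row0, rect.row0 + rect.height, dtype=float),
                intensities=block.sum(axis=1),
                lane_id=lane_id,
            )
        )
    return profiles


def _anchor_indices(
    profile: LaneProfile, window: BandWindow
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    pos = profile.positions
    if window.start < pos[0] or window.end > pos[-1]:
        raise ValueError(
            f"band window [{window.start}, {window.end}] lies outside the profile "
            f"range [{pos[0]}, {pos[-1]}]"
        )
    inside = np.nonzero((pos >= window.start) & (pos <= window.end))[0]
    if inside.size < 2:
        raise ValueError("band window contains fewer than 2 profile points")
    left = np.arange(inside[0] - window.flank_width, inside[0])
    right = np.arange(inside[-1] + 1, inside[-1] + 1 + window.flank_width)
    if left[0] < 0 or right[-1] >= pos.size:
        raise ValueError(
            f"window leaves fewer than flank_width={window.flank_width} baseline "
            "anchor points on one side; enlarge the profile or shrink the window"
        )
    return inside, left, right


def subtract_linear_baseline(profile: LaneProfile, window: BandWindow) -> LaneProfile:
    """Subtract a straight baseline through the flanking anchor medians.

    The line passes through (median position, median intensity) of the
    ``flank_width`` anchor points on each side and is subtracted from
    the anchors through the window; points outside are untouched.  On a
    profile that is itself a straight line the corrected window is
    identically zero.
    """
    inside, left, right = _anchor_indices(profile, window)
    pos, inten = profile.positions, profile.intensities
    x1 = float(np.median(pos[left]))
    y1 = float(np.median(inten[left]))
    x2 = float(np.median(pos[right]))
    y2 = float(np.median(inten[right]))
    slope = (y2 - y1) / (x2 - x1)
    corrected = inten.copy()
    span = np.arange(left[0], right[-1] + 1)
    corrected[span] = inten[span] - (y1 + slope * (pos[span] - x1))
    return replace(profile, intensities=corrected)


def peak_area(profile: LaneProfile, window: BandWindow) -> float:
    """Baseline-corrected trapezoidal peak area over the band window.

    Negative corrected values are clipped to zero before integration:
    band density cannot be negative, and clipping prevents baseline
    noise from cancelling signal.
    """
    corrected = subtract_linear_baseline(profile, window)
    inside, _, _ = _anchor_indices(profile, window)
    y = np.clip(corrected.intensities[inside], 0.0, None)
    return float(np.trapezoid(y, corrected.positions[inside]))


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map between band peak area and monomer concentration.

    ``area = slope * concentration + intercept``.  ``conc_mean`` and
    ``conc_ss`` (sum of squared concentration deviations) record the
    calibration design for inverse-prediction standard errors.
    """

    slope: float
    intercept: float
    residual_sd: float
    r_squared: float
    conc_range: Tuple[float, float]
    n_points: int
    conc_mean: float
    conc_ss: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope:g}")
        if not self.conc_range[0] < self.conc_range[1]:
            raise ValueError("conc_range min must be below max")
        if self.n_points < 3:
            raise ValueError("calibration needs at least 3 points")

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "residual_sd": self.residual_sd,
            "r_squared": self.r_squared,
            "conc_range": list(self.conc_range),
            "n_points": self.n_points,
            "conc_mean": self.conc_mean,
            "conc_ss": self.conc_ss,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        d = dict(d)
        d["conc_range"] = tuple(d["conc_range"])
        return cls(**d)


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Monomer concentration (uM) with inverse-prediction sd."""

    value: float
    sd: float
    extrapolated: bool

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.value < 0 and not self.extrapolated:
            raise ValueError("negative concentration must carry the extrapolated flag")

    def to_dict(self) -> dict:
        return {"value": self.value, "sd": self.sd, "extrapolated": self.extrapolated}


def fit_calibration(
    concentrations: Sequence[float], areas: Sequence[float]
) -> CalibrationCurve:
    """Ordinary least squares of peak area on concentration.

    Requires at least 3 points with non-zero concentration spread; the
    fit includes an intercept because background staining produces a
    nonzero blank signal.
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(areas, dtype=float)
    if c.size != a.size:
        raise ValueError("concentrations and areas must have equal length")
    if c.size < 3:
        raise ValueError(f"calibration needs at least 3 points, got {c.size}")
    if np.ptp(c) <= 0:
        raise ValueError("concentrations have zero spread; cannot fit a line")
    fit = stats.linregress(c, a)
    resid = a - (fit.intercept + fit.slope * c)
    residual_sd = math.sqrt(float(np.dot(resid, resid)) / (c.size - 2))
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_sd=residual_sd,
        r_squared=float(fit.rvalue) ** 2,
        conc_range=(float(c.min()), float(c.max())),
        n_points=int(c.size),
        conc_mean=float(c.mean()),
        conc_ss=float(np.dot(c - c.mean(), c - c.mean())),
    )


def estimate_concentration(
    curve: CalibrationCurve, area: float, n_replicates: int = 1
) -> ConcentrationEstimate:
    """Invert the calibration curve for a measured peak area.

    The point estimate is ``(area - intercept) / slope``.  The standard
    error follows first-order inverse prediction,

        sd = (s / slope) * sqrt(1/m + 1/n + (x0 - xbar)^2 / Sxx),

    with ``s`` the calibration residual sd, ``m`` the number of
    replicate sample measurements averaged into ``area``, ``n`` the
    number of calibration points, and ``Sxx`` the concentration sum of
    squares.  Estimates outside the calibrated concentration range are
    flagged as extrapolated.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    x0 = (area - curve.intercept) / curve.slope
    sd = (curve.residual_sd / curve.slope) * math.sqrt(
        1.0 / n_replicates
        + 1.0 / curve.n_points
        + (x0 - curve.conc_mean) ** 2 / curve.conc_ss
    )
    extrapolated = not (curve.conc_range[0] <= x0 <= curve.conc_range[1])
    return ConcentrationEstimate(value=float(x0), sd=float(sd), extrapolated=extrapolated)


# ---------------------------------------------------------------------------
# CSV IO


def write_lane_profiles_csv(
    profiles: Sequence[LaneProfile], path: Union[str, Path]
) -> None:
    """Write lane profiles as long-form CSV (position, intensity, lane_id)."""
    import pandas as pd

    frames = [
        pd.DataFrame(
            {"position": p.positions, "intensity": p.intensities, "lane_id": p.lane_id}
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_lane_profiles_csv(path: Union[str, Path]) -> List[LaneProfile]:
    """Read lane profiles from long-form CSV (position, intensity, lane_id)."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    required = {"position", "intensity", "lane_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    profiles = []
    for lane_id, grp in df.groupby("lane_id", sort=False):
        grp = grp.sort_values("position")
        profiles.append(
            LaneProfile(
                positions=grp["position"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                lane_id=str(lane_id),
            )
        )
    return profiles
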