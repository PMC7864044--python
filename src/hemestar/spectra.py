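"""UV-Vis absorbance spectra and constrained two-component unmixing.

Hemoproteins with distinct axial heme coordination show distinct
absorption spectra: a low-spin bis-His/Met cytochrome-type host has its
Soret band near 417 nm with Q bands at 532/562 nm, while a high-spin
tyrosine-coordinated host absorbs at 402 nm with charge-transfer
character near 623 nm.  A mixture spectrum is therefore modelled as a
convex combination of the two reference ("basis") spectra,

    m(lambda) = f * a(lambda) + (1 - f) * b(lambda),

with a single free fraction ``f`` constrained to [0, 1] (the two
coefficients sum to one).  Fitting ``f`` over the heme absorption region
yields the fraction of heme moieties residing in each host environment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "AbsorbanceSpectrum",
    "BasisPair",
    "UnmixResult",
    "HemeTransferReport",
    "DegenerateBasisError",
    "DEFAULT_FIT_WINDOW",
    "resample_to_grid",
    "normalize",
    "common_grid",
    "unmix_two_component",
    "unmix_grid_search",
    "heme_transfer_evidence",
    "read_spectrum",
    "write_spectrum",
]

#: Default fit window (nm) covering the Soret and Q/CT bands of both
#: host environments while excluding the 280 nm protein band.
DEFAULT_FIT_WINDOW: Tuple[float, float] = (350.0, 700.0)

NORMALIZATION_MODES = ("raw", "per-heme-extinction", "unit-area")


class DegenerateBasisError(ValueError):
    """The two basis spectra are identical on the fit window."""


def _as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """A wavelength-indexed absorbance trace.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelengths in nm, all within 200-1000 nm,
        at least 10 points.
    absorbances
        Absorbance values on the scale declared by ``normalization``
        (raw AU, extinction in M^-1 cm^-1, or unit-area).  Small
        negative values are tolerated: measured baselines carry noise.
    """

    wavelengths: np.ndarray
    absorbances: np.ndarray
    label: str = ""
    normalization: str = "raw"

    def __post_init__(self) -> None:
        wl = _as_float_array(self.wavelengths, "wavelengths")
        ab = _as_float_array(self.absorbances, "absorbances")
        if wl.size != ab.size:
            raise ValueError(
                f"wavelengths ({wl.size}) and absorbances ({ab.size}) differ in length"
            )
        if wl.size < 10:
            raise ValueError(f"spectrum needs at least 10 points, got {wl.size}")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < 200.0 or wl[-1] > 1000.0:
            raise ValueError(
                f"wavelengths must lie within 200-1000 nm, got span "
                f"[{wl[0]:g}, {wl[-1]:g}]"
            )
        if self.normalization not in NORMALIZATION_MODES:
            raise ValueError(
                f"unknown normalization {self.normalization!r}; "
                f"expected one of {NORMALIZATION_MODES}"
            )
        wl.setflags(write=False)
        ab.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbances", ab)

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def span(self) -> Tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def restrict(self, window: Tuple[float, float]) -> "AbsorbanceSpectrum":
        """Return the spectrum restricted to ``window`` (inclusive)."""
        lo, hi = window
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if mask.sum() < 10:
            raise ValueError(
                f"window {window} leaves only {int(mask.sum())} points (need >= 10)"
            )
        return replace(
            self, wavelengths=self.wavelengths[mask], absorbances=self.absorbances[mask]
        )


def resample_to_grid(
    spectrum: AbsorbanceSpectrum, grid: Sequence[float]
) -> AbsorbanceSpectrum:
    """Linearly interpolate ``spectrum`` onto ``grid``.

    The grid must lie within the spectrum's wavelength span;
    extrapolation is refused.
    """
    g = _as_float_array(grid, "grid")
    lo, hi = spectrum.span
    if g[0] < lo or g[-1] > hi:
        raise ValueError(
            f"grid [{g[0]:g}, {g[-1]:g}] nm extends beyond the spectrum span "
            f"[{lo:g}, {hi:g}] nm; refusing to extrapolate"
        )
    values = np.interp(g, spectrum.wavelengths, spectrum.absorbances)
    return replace(spectrum, wavelengths=g, absorbances=values)


def normalize(
    spectrum: AbsorbanceSpectrum,
    mode: str,
    extinction_at_peak: Optional[float] = None,
    window: Optional[Tuple[float, float]] = None,
) -> AbsorbanceSpectrum:
    """Rescale a spectrum to a declared normalization.

    ``unit-area`` scales so the trapezoidal integral over ``window``
    (default: the full span) equals 1.  ``per-heme-extinction`` scales
    so the global maximum equals ``extinction_at_peak`` (M^-1 cm^-1),
    i.e. the trace reads as a per-heme extinction spectrum.
    """
    if mode == "raw":
        return replace(spectrum, normalization="raw")
    if mode == "unit-area":
        target = spectrum if window is None else spectrum.restrict(window)
        area = float(np.trapezoid(target.absorbances, target.wavelengths))
        if area <= 0.0 or not math.isfinite(area):
            raise ValueError(
                "cannot unit-area normalize: integral over the window is "
                f"{area:g} (all-zero or negative spectrum?)"
            )
        return replace(
            spectrum, absorbances=spectrum.absorbances / area, normalization="unit-area"
        )
    if mode == "per-heme-extinction":
        if extinction_at_peak is None or extinction_at_peak <= 0:
            raise ValueError("per-heme-extinction mode requires extinction_at_peak > 0")
        peak = float(np.max(spectrum.absorbances))
        if peak <= 0.0:
            raise ValueError("cannot normalize an all-zero (or negative) spectrum")
        scale = extinction_at_peak / peak
        return replace(
            spectrum,
            absorbances=spectrum.absorbances * scale,
            normalization="per-heme-extinction",
        )
    raise ValueError(f"unknown normalization mode {mode!r}")


def common_grid(*spectra: AbsorbanceSpectrum) -> np.ndarray:
    """Coarsest common wavelength grid of several spectra.

    The grid covers the overlap of all spans, stepped at the largest
    median step among the inputs, so that no spectrum is implicitly
    extrapolated or over-resolved.
    """
    lo = max(s.span[0] for s in spectra)
    hi = min(s.span[1] for s in spectra)
    if hi <= lo:
        raise ValueError("spectra have no overlapping wavelength range")
    step = max(float(np.median(np.diff(s.wavelengths))) for s in spectra)
    n = int(math.floor((hi - lo) / step)) + 1
    if n < 10:
        raise ValueError(
            f"overlap [{lo:g}, {hi:g}] nm at step {step:g} nm leaves only {n} points"
        )
    return lo + step * np.arange(n)


@dataclass(frozen=True)
class BasisPair:
    """Two reference spectra resampled onto one grid.

    ``basis_a`` is the cytochrome-type reference (Soret 417 nm),
    ``basis_b`` the hexameric-host reference (Soret 402 nm).
    """

    basis_a: AbsorbanceSpectrum
    basis_b: AbsorbanceSpectrum
    grid: np.ndarray

    def __post_init__(self) -> None:
        g = _as_float_array(self.grid, "grid")
        g.setflags(write=False)
        object.__setattr__(self, "grid", g)
        for name, s in (("basis_a", self.basis_a), ("basis_b", self.basis_b)):
            if s.wavelengths.size != g.size or not np.allclose(s.wavelengths, g):
                raise ValueError(f"{name} is not sampled on the shared grid")
        if self.basis_a.normalization != self.basis_b.normalization:
            raise ValueError(
                "basis spectra must share one normalization mode, got "
                f"{self.basis_a.normalization!r} and {self.basis_b.normalization!r}"
            )

    @classmethod
    def from_spectra(
        cls,
        basis_a: AbsorbanceSpectrum,
        basis_b: AbsorbanceSpectrum,
        grid: Optional[Sequence[float]] = None,
    ) -> "BasisPair":
        g = common_grid(basis_a, basis_b) if grid is None else np.asarray(grid, float)
        return cls(resample_to_grid(basis_a, g), resample_to_grid(basis_b, g), g)


@dataclass(frozen=True)
class UnmixResult:
    """Outcome of a constrained two-component fit.

    ``f_a + f_b == 1`` holds exactly by construction.  ``f_sd`` is the
    delta-method standard error of ``f_a`` derived from the fit
    residuals (NaN when fewer than 4 points).  ``clipped`` is set when
    the unconstrained optimum fell outside [0, 1].
    """

    f_a: float
    f_b: float
    sse: float
    window: Tuple[float, float]
    n_points: int
    clipped: bool = False
    f_sd: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_a <= 1.0):
            raise ValueError(f"f_a must be in [0, 1], got {self.f_a}")
        if abs(self.f_a + self.f_b - 1.0) > 1e-12:
            raise ValueError("f_a + f_b must equal 1 exactly")
        if self.sse < 0:
            raise ValueError("sse must be non-negative")

    def to_dict(self) -> dict:
        return {
            "f_a": self.f_a,
            "f_b": self.f_b,
            "sse": self.sse,
            "window": list(self.window),
            "n_points": self.n_points,
            "clipped": self.clipped,
            "f_sd": None if math.isnan(self.f_sd) else self.f_sd,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "UnmixResult":
        return cls(
            f_a=d["f_a"],
            f_b=d["f_b"],
            sse=d["sse"],
            window=tuple(d["window"]),
            n_points=d["n_points"],
            clipped=d.get("clipped", False),
            f_sd=float("nan") if d.get("f_sd") is None else d["f_sd"],
        )


def _window_arrays(
    mix: AbsorbanceSpectrum, basis: BasisPair, window: Tuple[float, float]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"empty window {window}")
    mask = (basis.grid >= lo) & (basis.grid <= hi)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"window {window} contains only {int(mask.sum())} grid points (need >= 3)"
        )
    grid_w = basis.grid[mask]
    m = resample_to_grid(mix, grid_w).absorbances
    a = basis.basis_a.absorbances[mask]
    b = basis.basis_b.absorbances[mask]
    return m, a, b


def unmix_two_component(
    mix: AbsorbanceSpectrum,
    basis: BasisPair,
    window: Tuple[float, float] = DEFAULT_FIT_WINDOW,
) -> UnmixResult:
    """Fit ``mix = f*a + (1-f)*b`` by constrained least squares.

    The optimum has the closed form
    ``f* = sum((m-b)*(a-b)) / sum((a-b)**2)``, clipped to [0, 1]; the
    clipping is recorded in the result.  Raises
    :class:`DegenerateBasisError` when the bases coincide on the window.
    """
    m, a, b = _window_arrays(mix, basis, window)
    d = a - b
    denom = float(np.dot(d, d))
    scale = max(float(np.dot(a, a)), float(np.dot(b, b)), 1.0)
    if denom <= 1e-14 * scale:
        raise DegenerateBasisError(
            f"basis spectra are identical on window {window}; the fraction "
            "is unidentifiable"
        )
    f_raw = float(np.dot(m - b, d)) / denom
    clipped = not (0.0 <= f_raw <= 1.0)
    f = min(1.0, max(0.0, f_raw))
    resid = m - (f * a + (1.0 - f) * b)
    sse = float(np.dot(resid, resid))
    n = m.size
    f_sd = math.sqrt(sse / (n - 1) / denom) if n >= 4 else float("nan")
    return UnmixResult(
        f_a=f,
        f_b=1.0 - f,
        sse=sse,
        window=(float(window[0]), float(window[1])),
        n_points=n,
        clipped=clipped,
        f_sd=f_sd,
    )


def unmix_grid_search(
    mix: AbsorbanceSpectrum,
    basis: BasisPair,
    window: Tuple[float, float] = DEFAULT_FIT_WINDOW,
    step: float = 0.001,
) -> float:
    """Exhaustive search for the best fraction on a fixed grid of ``f``.

    Slow but assumption-free; serves as an independent check of the
    closed-form solution.
    """
    m, a, b = _window_arrays(mix, basis, window)
    fs = np.arange(0.0, 1.0 + step / 2, step)
    models = fs[:, None] * a[None, :] + (1.0 - fs)[:, None] * b[None, :]
    sses = np.sum((models - m[None, :]) ** 2, axis=1)
    return float(fs[int(np.argmin(sses))])


@dataclass(frozen=True)
class HemeTransferReport:
    """Change in the hexameric-host heme fraction between two fits."""

    delta_f_b: float
    transfer: bool
    threshold: float
    before: UnmixResult
    after: UnmixResult


def heme_transfer_evidence(
    before: UnmixResult, after: UnmixResult, threshold: float = 0.05
) -> HemeTransferReport:
    """Flag heme transfer into the hexameric host.

    An increase of ``f_b`` beyond ``threshold`` between two fits against
    the same basis pair and window indicates migration of heme from the
    cytochrome-type environment into the hexamer's binding sites.
    """
    if tuple(before.window) != tuple(after.window):
        raise ValueError(
            f"results were fitted on different windows: {before.window} vs {after.window}"
        )
    delta = after.f_b - before.f_b
    return HemeTransferReport(
        delta_f_b=delta,
        transfer=delta > threshold,
        threshold=threshold,
        before=before,
        after=after,
    )


# ---------------------------------------------------------------------------
# File IO: two-column delimited text (wavelength_nm, absorbance), '#' comments


def read_spectrum(
    path: Union[str, Path], label: Optional[str] = None, normalization: str = "raw"
) -> AbsorbanceSpectrum:
    """Read a two-column (wavelength_nm, absorbance) text/CSV file."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {body!r}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1 or not rows:
                    continue  # header line
                raise ValueError(f"{path}:{lineno}: non-numeric data {body!r}")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    wl, ab = zip(*rows)
    return AbsorbanceSpectrum(
        wavelengths=np.array(wl),
        absorbances=np.array(ab),
        label=label if label is not None else path.stem,
        normalization=normalization,
    )


def write_spectrum(spectrum: AbsorbanceSpectrum, path: Union[str, Path]) -> None:
    """Write a spectrum in the same two-column format the reader accepts."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# label: {spectrum.label}\n")
        fh.write(f"# normalization: {spectrum.normalization}\n")
        fh.write("wavelength_nm,absorbance\n")
        for wl, ab in zip(spectrum.wavelengths, spectrum.absorbances):
            fh.write(f"{wl:.6g},{ab:.10g}\n")
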