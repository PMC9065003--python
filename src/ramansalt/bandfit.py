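"""Band component analysis: sub-peak counting and multi-Gaussian deconvolution.

Broad Raman features — the Amide I envelope around 1600–1700 cm^-1 in
particular — are superpositions of overlapping sub-bands.  The workflow here
follows the classic curve-resolution recipe: count the sub-peaks from the
negative lobes of a Savitzky–Golay second derivative, then least-squares fit a
sum of Gaussian line shapes

    g(nu) = h * exp(-4 ln2 (nu - c)^2 / w^2)

parameterized by height h, center c and full width at half maximum w, and
report center/height/width/area per component.  The Gaussian area is
h * w * sqrt(pi / (4 ln 2)).

Trend extraction (`band_trends`) aggregates per-band peak intensities by
(week, concentration) group and, for center shifts, fits the group mean
spectrum — single-spectrum fits at realistic noise are too unstable to chart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import argrelmin, savgol_filter

from .errors import InputError, ParameterError
from .spectio import Spectrum, SpectrumSet

__all__ = [
    "GAUSS_AREA_FACTOR",
    "AMIDE_WINDOW",
    "BandComponent",
    "BandFitResult",
    "gaussian_band",
    "second_derivative",
    "count_subpeaks",
    "fit_gaussian_bands",
    "band_intensity",
    "band_trends",
]

#: area = height * fwhm * GAUSS_AREA_FACTOR for a Gaussian line
GAUSS_AREA_FACTOR = float(np.sqrt(np.pi / (4.0 * np.log(2.0))))


def band_assignments() -> pd.DataFrame:
    """Static table of tentative biochemical assignments for the leaf bands."""
    from importlib.resources import files

    with (files("ramansalt") / "data" / "band_assignments.csv").open() as fh:
        return pd.read_csv(fh)

#: default Amide I fitting window, wide enough for the 1619–1686 cm^-1 components
AMIDE_WINDOW = (1590.0, 1720.0)

_FOUR_LN2 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class BandComponent:
    """One fitted Gaussian line: center (cm^-1), height, FWHM (cm^-1), area."""

    center: float
    height: float
    fwhm: float

    @property
    def area(self) -> float:
        return self.height * self.fwhm * GAUSS_AREA_FACTOR


@dataclass(frozen=True)
class BandFitResult:
    """Multi-Gaussian decomposition of one spectral window."""

    window: tuple[float, float]
    components: tuple[BandComponent, ...]
    residual_rms: float
    n_iterations: int
    converged: bool


def gaussian_band(shift: np.ndarray, height: float, center: float, fwhm: float) -> np.ndarray:
    """FWHM-parameterized Gaussian line shape."""
    return height * np.exp(-_FOUR_LN2 * (shift - center) ** 2 / fwhm**2)


def _uniform_step(shift: np.ndarray) -> float:
    steps = np.diff(shift)
    step = float(steps.mean())
    if not np.allclose(steps, step, rtol=1e-6, atol=1e-9):
        raise ParameterError("second derivative requires a uniform shift axis; resample first")
    return step


def second_derivative(spectrum: Spectrum, sg_window: int = 21, sg_order: int = 3) -> np.ndarray:
    """Savitzky–Golay second derivative with respect to shift (cm^-1)."""
    if sg_window % 2 == 0 or sg_window <= sg_order or sg_order < 2:
        raise ParameterError(
            f"need odd sg_window > sg_order >= 2, got window={sg_window} order={sg_order}"
        )
    if sg_window > spectrum.n_points:
        raise ParameterError(f"sg_window {sg_window} exceeds spectrum length {spectrum.n_points}")
    step = _uniform_step(spectrum.shift)
    return savgol_filter(spectrum.intensity, sg_window, sg_order, deriv=2, delta=step)


def _window_slice(shift: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo >= hi:
        raise ParameterError(f"empty window ({lo}, {hi})")
    mask = (shift >= lo) & (shift <= hi)
    if not mask.any():
        raise ParameterError(f"window ({lo}, {hi}) contains no axis points")
    return mask

def count_subpeaks(
    spectrum: Spectrum,
    window: tuple[float, float],
    prominence_frac: float = 0.1,
    sg_window: int = 21,
    sg_order: int = 3,
) -> tuple[int, np.ndarray]:
    """Count sub-peaks from negative second-derivative lobes inside a window.

    Each underlying peak produces a negative lobe in the second derivative;
    lobes whose depth is at least ``prominence_frac`` of the deepest lobe are
    counted.  Returns the count and the shift values of the lobe minima, which
    serve as initial centers for :func:`fit_gaussian_bands`.
    """
    d2 = second_derivative(spectrum, sg_window, sg_order)
    mask = _window_slice(spectrum.shift, window)
    idx = np.nonzero(mask)[0]
    d2_w = d2[idx]
    minima = argrelmin(d2_w, order=1)[0]
    minima = minima[d2_w[minima] < 0]
    if minima.size == 0:
        return 0, np.array([])
    depths = -d2_w[minima]
    keep = depths >= prominence_frac * depths.max()
    centers = spectrum.shift[idx[minima[keep]]]
    return int(keep.sum()), centers


def fit_gaussian_bands(
    spectrum: Spectrum,
    window: tuple[float, float],
    n_bands: int,
    init_centers: np.ndarray | None = None,
    max_iterations: int = 500,
    tol: float = 1e-10,
) -> BandFitResult:
    """Least-squares fit of ``n_bands`` Gaussian components inside a window.

    Iterates until the relative cost change drops below ``tol`` or
    ``max_iterations`` residual evaluations are spent; a failed convergence is
    reported through the ``converged`` flag, never silently.  Components come
    back sorted by center.
    """
    if n_bands < 1:
        raise ParameterError("n_bands must be >= 1")
    lo, hi = window
    mask = _window_slice(spectrum.shift, window)
    x = spectrum.shift[mask]
    y = spectrum.intensity[mask]
    if x.size < 3 * n_bands:
        raise ParameterError(f"window holds {x.size} points, too few for {n_bands} bands")

    if init_centers is None:
        init_centers = np.linspace(lo, hi, n_bands + 2)[1:-1]
    init_centers = np.asarray(init_centers, dtype=float)
    if init_centers.size != n_bands:
        raise ParameterError(f"{init_centers.size} initial centers for {n_bands} bands")
    if np.any(init_centers < lo) or np.any(init_centers > hi):
        raise ParameterError("initial centers must lie inside the window")

    span = hi - lo
    init_h = np.clip(np.interp(init_centers, x, y), 1e-6 * max(y.max(), 1e-30), None)
    init_w = np.full(n_bands, max(span / (2.0 * n_bands), 2.0 * float(np.diff(x).mean())))
    p0 = np.concatenate([init_h, init_centers, init_w])

    grid_step = float(np.diff(x).mean())
    lower = np.concatenate([np.zeros(n_bands), np.full(n_bands, lo), np.full(n_bands, grid_step / 2)])
    upper = np.concatenate(
        [np.full(n_bands, np.inf), np.full(n_bands, hi), np.full(n_bands, 4.0 * span)]
    )

    def model(p: np.ndarray) -> np.ndarray:
        h, c, w = p[:n_bands], p[n_bands : 2 * n_bands], p[2 * n_bands :]
        return gaussian_band(x[:, None], h, c, w).sum(axis=1)

    res = least_squares(
        lambda p: model(p) - y,
        p0,
        bounds=(lower, upper),
        ftol=tol,
        xtol=tol,
        gtol=tol,
        max_nfev=max_iterations,
    )

    h, c, w = res.x[:n_bands], res.x[n_bands : 2 * n_bands], res.x[2 * n_bands :]
    order = np.argsort(c)
    h, c, w = h[order], c[order], w[order]
    if n_bands > 1 and np.any(np.diff(c) < grid_step):
        warnings.warn(
            "two fitted band centers collapsed within one grid step; "
            "the decomposition is degenerate",
            stacklevel=2,
        )
    components = tuple(
        BandComponent(center=float(ci), height=float(hi_), fwhm=float(wi))
        for hi_, ci, wi in zip(h, c, w)
    )
    residual_rms = float(np.sqrt(np.mean((model(res.x) - y) ** 2)))
    return BandFitResult(
        window=(float(lo), float(hi)),
        components=components,
        residual_rms=residual_rms,
        n_iterations=int(res.nfev),
        converged=bool(res.status > 0),
    )


def band_intensity(sset: SpectrumSet, shift_cm1: float, half_window: float) -> np.ndarray:
    """Per-spectrum maximum intensity within ±half_window of a target band.

    With ``half_window == 0`` this is the intensity at the nearest grid point.
    """
    if half_window < 0:
        raise ParameterError("half_window must be >= 0")
    if shift_cm1 < sset.shift[0] or shift_cm1 > sset.shift[-1]:
        raise ParameterError(f"band position {shift_cm1} cm^-1 lies off the shift axis")
    if half_window == 0:
        j = int(np.argmin(np.abs(sset.shift - shift_cm1)))
        return sset.intensities[:, j].copy()
    mask = _window_slice(sset.shift, (shift_cm1 - half_window, shift_cm1 + half_window))
    return sset.intensities[:, mask].max(axis=1)


def _iqr(values: np.ndarray) -> float:
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return float(q3 - q1)


def band_trends(
    sset: SpectrumSet,
    bands: list[tuple[str, float, float]],
    mode: str = "intensity",
    fit_window: tuple[float, float] = AMIDE_WINDOW,
    prominence_frac: float = 0.1,
) -> pd.DataFrame:
    """Per-(week, concentration) band trends.

    mode="intensity": groupwise mean and interquartile range of
    :func:`band_intensity` for every (label, shift, half_window) in ``bands``.

    mode="center": the group mean spectrum is decomposed over ``fit_window``
    (sub-peak count from the second derivative, then a multi-Gaussian fit) and
    each requested band is matched to the fitted component nearest in center,
    using the lowest-concentration group of each week as the reference.
    """
    if sset.meta is None:
        raise InputError("band_trends requires attached metadata")
    if mode not in ("intensity", "center"):
        raise ParameterError(f"unknown mode {mode!r}")

    rows: list[dict] = []
    grouped = sset.meta.groupby(["week", "concentration_mM"], sort=True).indices
    if mode == "intensity":
        values = {label: band_intensity(sset, shift, hw) for label, shift, hw in bands}
        for (week, conc), idx in grouped.items():
            idx = np.asarray(idx)
            if idx.size == 0:
                continue
            for label, _, _ in bands:
                v = values[label][idx]
                rows.append(
                    {
                        "week": week,
                        "concentration_mM": conc,
                        "band_label": label,
                        "mean_intensity": float(v.mean()),
                        "iqr": _iqr(v),
                    }
                )
        return pd.DataFrame(rows)

    for (week, conc), idx in grouped.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            warnings.warn(f"group (week={week}, conc={conc}) has no spectra; omitted", stacklevel=2)
            continue
        mean_spec = Spectrum(sset.shift, sset.intensities[idx].mean(axis=0))
        n, centers = count_subpeaks(mean_spec, fit_window, prominence_frac)
        if n == 0:
            warnings.warn(f"no sub-peaks found for group (week={week}, conc={conc})", stacklevel=2)
            continue
        fit = fit_gaussian_bands(mean_spec, fit_window, n, centers)
        fitted_centers = np.array([c.center for c in fit.components])
        for label, shift, _ in bands:
            j = int(np.argmin(np.abs(fitted_centers - shift)))
            comp = fit.components[j]
            rows.append(
                {
                    "week": week,
                    "concentration_mM": conc,
                    "band_label": label,
                    "center_cm1": comp.center,
                    "height": comp.height,
                    "fwhm_cm1": comp.fwhm,
                    "area": comp.area,
                    "residual_rms": fit.residual_rms,
                }
            )
    return pd.DataFrame(rows)
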