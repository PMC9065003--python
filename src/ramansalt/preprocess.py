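"""Spectral preprocessing chain for leaf Raman maps.

The chain mirrors how the raw maps were conditioned before any chemometrics:

1. boxcar (moving-mean) denoising, window 3 by default;
2. fluorescence-baseline estimation by connecting consecutive local minima of
   the spectrum with straight lines in shift (cm^-1) coordinates, and
   subtraction of that piecewise-linear profile;
3. L2 (vector) normalization, so every spectrum has unit Euclidean norm;
4. outlier elimination by keeping spectra whose per-spectrum scalar score lies
   between two sample quantiles (0.5% / 99.5% by default).

Local minima are defined as a strict decrease from the left and a non-strict
increase to the right, which resolves plateaus deterministically; the first
and last points are always anchors so the baseline covers the full axis.
Corrected intensities may be negative (noise below the baseline) and are not
clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (
    ExtrapolationError,
    InputError,
    NormalizationError,
    ParameterError,
)
from .spectio import Spectrum, SpectrumSet

__all__ = [
    "BaselineResult",
    "QuantileFilterReport",
    "PreprocessConfig",
    "boxcar_smooth",
    "find_baseline_anchors",
    "baseline_correct",
    "l2_normalize",
    "quantile_filter",
    "resample_to_grid",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)

SCORE_FUNCTIONS = {
    "total_intensity": lambda mat: mat.sum(axis=1),
    "l2_norm_raw": lambda mat: np.linalg.norm(mat, axis=1),
}


@dataclass(frozen=True)
class BaselineResult:
    """Piecewise-linear fluorescence baseline and the corrected spectrum."""

    baseline: np.ndarray
    corrected: np.ndarray
    anchor_indices: np.ndarray


@dataclass(frozen=True)
class QuantileFilterReport:
    """Which spectra survived quantile elimination and under what convention."""

    kept_ids: tuple[str, ...]
    removed_ids: tuple[str, ...]
    lower_q: float
    upper_q: float
    score_name: str
    per_group: bool = False
    # sample-quantile convention recorded for reproducibility
    quantile_method: str = "linear"


@dataclass(frozen=True)
class PreprocessConfig:
    """Stage toggles and parameters for :func:`preprocess_pipeline`."""

    boxcar_window: int | None = 3
    baseline: bool = True
    normalize: bool = True
    quantile_filter: bool = True
    lower_q: float = 0.005
    upper_q: float = 0.995
    score: str = "total_intensity"
    per_group: bool = False


def _smooth_values(y: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window)
    # truncated-window mean at the edges: divide by the number of real points
    return np.convolve(y, kernel, mode="same") / np.convolve(np.ones_like(y), kernel, mode="same")


def boxcar_smooth(spectrum: Spectrum, window: int) -> Spectrum:
    """Moving-mean smoothing; edge points average over the truncated window."""
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"boxcar window must be odd and >= 1, got {window}")
    if window > spectrum.n_points:
        raise ParameterError(
            f"boxcar window {window} exceeds spectrum length {spectrum.n_points}"
        )
    if window == 1:
        return spectrum
    return spectrum.with_intensity(_smooth_values(spectrum.intensity, window))


def find_baseline_anchors(spectrum: Spectrum) -> np.ndarray:
    """Indices of interior local minima plus both endpoints, sorted and unique.

    A point i is a local minimum when intensity[i] < intensity[i-1] and
    intensity[i] <= intensity[i+1].
    """
    y = spectrum.intensity
    if y.size < 3:
        raise ParameterError("baseline anchors require >= 3 points")
    interior = np.nonzero((y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:]))[0] + 1
    return np.unique(np.concatenate(([0], interior, [y.size - 1])))


def baseline_correct(spectrum: Spectrum) -> BaselineResult:
    """Estimate the fluorescence profile and subtract it.

    The baseline linearly interpolates the intensity between consecutive
    anchors in shift coordinates; corrected + baseline reconstructs the input
    exactly and the corrected value is exactly zero at every anchor.
    """
    anchors = find_baseline_anchors(spectrum)
    baseline = np.interp(spectrum.shift, spectrum.shift[anchors], spectrum.intensity[anchors])
    # np.interp returns node values exactly at nodes, so anchors subtract to 0.0
    return BaselineResult(baseline=baseline, corrected=spectrum.intensity - baseline, anchor_indices=anchors)


def l2_normalize(spectrum: Spectrum) -> Spectrum:
    """Divide the spectrum by its Euclidean norm (vector normalization)."""
    norm = float(np.linalg.norm(spectrum.intensity))
    if norm <= 0.0 or not np.isfinite(norm):
        raise NormalizationError(f"cannot normalize spectrum {spectrum.id!r}: zero or invalid norm")
    return spectrum.with_intensity(spectrum.intensity / norm)


def _score_matrix(sset: SpectrumSet, score: str) -> np.ndarray:
    try:
        return SCORE_FUNCTIONS[score](sset.intensities)
    except KeyError:
        raise ParameterError(
            f"unknown score {score!r}; choose from {sorted(SCORE_FUNCTIONS)}"
        ) from None


def quantile_filter(
    sset: SpectrumSet,
    lower_q: float = 0.005,
    upper_q: float = 0.995,
    score: str = "total_intensity",
    per_group: bool = False,
) -> tuple[SpectrumSet, QuantileFilterReport]:
    """Keep spectra whose score lies inside [Q(lower_q), Q(upper_q)].

    Quantiles use the linear-interpolation convention between order
    statistics.  With ``per_group`` the quantiles are computed within each
    (week, concentration_mM) group, which requires attached metadata.
    """
    if not (0.0 <= lower_q < upper_q <= 1.0):
        raise ParameterError(f"need 0 <= lower_q < upper_q <= 1, got ({lower_q}, {upper_q})")
    if sset.n_spectra == 0:
        raise InputError("cannot quantile-filter an empty SpectrumSet")
    scores = _score_matrix(sset, score)

    keep = np.zeros(sset.n_spectra, dtype=bool)
    if per_group:
        if sset.meta is None:
            raise InputError("per_group filtering requires attached metadata")
        groups = sset.meta.groupby(["week", "concentration_mM"], sort=False).indices.values()
    else:
        groups = [np.arange(sset.n_spectra)]
    for idx in groups:
        idx = np.asarray(idx)
        lo, hi = np.quantile(scores[idx], [lower_q, upper_q], method="linear")
        keep[idx] = (scores[idx] >= lo) & (scores[idx] <= hi)

    kept_idx = np.nonzero(keep)[0]
    removed_ids = tuple(sset.ids[i] for i in np.nonzero(~keep)[0])
    report = QuantileFilterReport(
        kept_ids=tuple(sset.ids[i] for i in kept_idx),
        removed_ids=removed_ids,
        lower_q=lower_q,
        upper_q=upper_q,
        score_name=score,
        per_group=per_group,
    )
    return sset.subset(kept_idx), report


def resample_to_grid(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a new shift grid (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    if grid.min() < spectrum.shift[0] or grid.max() > spectrum.shift[-1]:
        raise ExtrapolationError(
            f"target grid [{grid.min()}, {grid.max()}] extends beyond measured range "
            f"[{spectrum.shift[0]}, {spectrum.shift[-1]}]"
        )
    return Spectrum(grid, np.interp(grid, spectrum.shift, spectrum.intensity), spectrum.id)


def _log_group_counts(sset: SpectrumSet, stage: str) -> None:
    if sset.meta is None:
        logger.info("[%s] %d spectra (no metadata)", stage, sset.n_spectra)
        return
    counts = (
        sset.meta.groupby(["week", "concentration_mM"]).size().rename("n_spectra").reset_index()
    )
    logger.info("[%s] per-group spectrum counts:\n%s", stage, counts.to_string(index=False))


def preprocess_pipeline(
    sset: SpectrumSet, config: PreprocessConfig = PreprocessConfig()
) -> tuple[SpectrumSet, QuantileFilterReport | None]:
    """Run boxcar -> baseline correction -> L2 normalization -> quantile filter.

    Stages can be disabled individually through the config; with everything
    disabled this is the identity.  Per-group spectrum counts are logged after
    filtering.
    """
    mat = sset.intensities.copy()
    if config.boxcar_window is not None and config.boxcar_window > 1:
        if config.boxcar_window % 2 == 0:
            raise ParameterError("boxcar window must be odd")
        mat = np.apply_along_axis(_smooth_values, 1, mat, config.boxcar_window)
    if config.baseline:
        for i in range(mat.shape[0]):
            mat[i] = baseline_correct(Spectrum(sset.shift, mat[i])).corrected
    if config.normalize:
        norms = np.linalg.norm(mat, axis=1)
        bad = np.nonzero(norms <= 0)[0]
        if bad.size:
            raise NormalizationError(
                f"zero-norm spectra after correction: {[sset.ids[i] for i in bad]}"
            )
        mat = mat / norms[:, None]
    out = sset.with_intensities(mat)
    report = None
    if config.quantile_filter:
        out, report = quantile_filter(
            out, config.lower_q, config.upper_q, config.score, config.per_group
        )
        _log_group_counts(out, "quantile_filter")
    return out, report
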