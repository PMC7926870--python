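"""Spectral preprocessing: resampling, baseline correction, vector
normalization, Savitzky–Golay smoothing/derivatives, group averaging.

The default pipeline order is resample → baseline → normalize; derivative
spectra are computed on demand from the preprocessed traces.  Defaults
mirror routine serum ATR-FTIR practice: analysis range 800–3500 cm⁻¹ at
2 cm⁻¹ steps, rubberband (lower convex hull) baseline, unit Euclidean
norm, and Savitzky–Golay differentiation with a 21-point window and
polynomial order 7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .core import CohortSet, Spectrum, ValidationError, average_replicates

__all__ = [
    "PreprocessConfig",
    "resample_to_grid",
    "baseline_correct",
    "vector_normalize",
    "sg_derivative",
    "group_average",
    "preprocess_spectrum",
    "preprocess_cohort",
]


@dataclass(frozen=True)
class PreprocessConfig:
    grid_start: float = 800.0
    grid_stop: float = 3500.0
    grid_step: float = 2.0
    baseline_method: str = "rubberband"  # rubberband | polynomial | none
    baseline_poly_degree: int = 2
    normalize: bool = True
    sg_window: int = 21
    sg_polyorder: int = 7

    def __post_init__(self) -> None:
        if not self.grid_start < self.grid_stop:
            raise ValidationError("grid_start must be < grid_stop")
        if self.grid_step <= 0:
            raise ValidationError("grid_step must be positive")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValidationError("sg_window must be odd and > sg_polyorder")
        if self.baseline_method not in ("rubberband", "polynomial", "none"):
            raise ValidationError(f"unknown baseline method {self.baseline_method!r}")

    @property
    def grid(self) -> np.ndarray:
        n = int(np.floor((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


def resample_to_grid(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Linear interpolation onto the uniform analysis grid."""
    grid = cfg.grid
    lo, hi = s.wavenumbers[0], s.wavenumbers[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise ValidationError(
            f"requested grid [{grid[0]}, {grid[-1]}] exceeds data span [{lo}, {hi}]"
        )
    if grid.size == len(s) and np.allclose(grid, s.wavenumbers):
        return s
    return s.with_grid(grid, np.interp(grid, s.wavenumbers, s.absorbance))


def _lower_hull(k: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Lower convex hull of the points (k, a), evaluated on k (rubberband)."""
    hull: list[int] = []
    for i in range(len(k)):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            # pop i1 if it lies on/above the chord i0 -> i
            cross = (k[i1] - k[i0]) * (a[i] - a[i0]) - (a[i1] - a[i0]) * (k[i] - k[i0])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(k, k[hull], a[hull])


def baseline_correct(s: Spectrum, method: str = "rubberband", poly_degree: int = 2) -> Spectrum:
    """Subtract a baseline estimate.

    ``rubberband`` subtracts the lower convex hull of (k, A); the result is
    non-negative and the operation is idempotent.  ``polynomial`` fits a
    least-squares polynomial through automatically selected local minima
    and subtracts it.  ``none`` returns the input.
    """
    if method == "none":
        return s
    k, a = s.wavenumbers, s.absorbance
    if method == "rubberband":
        base = _lower_hull(k, a)
    elif method == "polynomial":
        # anchor on local minima (plus endpoints) to avoid fitting the peaks
        interior = np.nonzero((a[1:-1] <= a[:-2]) & (a[1:-1] <= a[2:]))[0] + 1
        anchors = np.unique(np.r_[0, interior, len(k) - 1])
        kc = k - k.mean()  # center for conditioning
        coef = np.polyfit(kc[anchors], a[anchors], poly_degree)
        base = np.polyval(coef, kc)
    else:
        raise ValidationError(f"unknown baseline method {method!r}")
    return s.with_absorbance(a - base)


def vector_normalize(s: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm (removes film-thickness factors)."""
    norm = float(np.linalg.norm(s.absorbance))
    if norm == 0.0:
        raise ValidationError(f"sample {s.sample_id!r}: all-zero spectrum")
    return s.with_absorbance(s.absorbance / norm)


def _check_uniform(k: np.ndarray) -> float:
    dk = np.diff(k)
    if not np.allclose(dk, dk[0], rtol=1e-8, atol=1e-10):
        raise ValidationError("Savitzky–Golay differentiation requires a uniform grid")
    return float(dk[0])


def sg_derivative(s: Spectrum, order: int, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Savitzky–Golay derivative (order 1 or 2) with respect to wavenumber.

    Units are A.U./cm⁻¹ (order 1) or A.U./cm⁻² (order 2).  Exact on
    polynomials of degree ≤ ``sg_polyorder`` at interior points.
    """
    cfg = cfg or PreprocessConfig()
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if len(s) < cfg.sg_window:
        raise ValidationError(
            f"spectrum length {len(s)} shorter than SG window {cfg.sg_window}"
        )
    dk = _check_uniform(s.wavenumbers)
    d = savgol_filter(
        s.absorbance, cfg.sg_window, cfg.sg_polyorder, deriv=order, delta=dk, mode="interp"
    )
    return s.with_absorbance(d)


def group_average(cohort: CohortSet, group: str, average_reps: bool = True) -> Spectrum:
    """Pointwise mean spectrum of a group's (replicate-averaged) samples."""
    sub = cohort.subset(group)
    if len(sub) == 0:
        raise ValidationError(f"no samples in group {group!r}")
    if average_reps:
        sub = average_replicates(sub)
    k0 = sub.spectra[0].wavenumbers
    for s in sub:
        if len(s) != len(sub.spectra[0]) or not np.array_equal(s.wavenumbers, k0):
            raise ValidationError("group_average requires a common grid; resample first")
    mean_a = np.mean([s.absorbance for s in sub], axis=0)
    return Spectrum(
        sample_id=f"{group}_average",
        group=group,
        wavenumbers=k0,
        absorbance=mean_a,
    )


def preprocess_spectrum(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """resample → baseline → (optional) vector normalization."""
    cfg = cfg or PreprocessConfig()
    out = resample_to_grid(s, cfg)
    out = baseline_correct(out, cfg.baseline_method, cfg.baseline_poly_degree)
    if cfg.normalize:
        out = vector_normalize(out)
    return out


def preprocess_cohort(
    cohort: CohortSet, cfg: PreprocessConfig | None = None, average_reps: bool = True
) -> CohortSet:
    """Preprocess every spectrum; optionally average replicates per subject."""
    cfg = cfg or PreprocessConfig()
    out = CohortSet([preprocess_spectrum(s, cfg) for s in cohort], grid=cfg.grid)
    if average_reps:
        out = average_replicates(out)
        out = CohortSet(
            [vector_normalize(s) if cfg.normalize else s for s in out], grid=cfg.grid
        )
    return out
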