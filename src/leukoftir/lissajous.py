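"""Lissajous phase-shift classification of first-derivative spectra.

A control-average first-derivative spectrum serves as the reference.
Plotting (ref′(k), sample′(k)) over a narrow wavenumber window traces a
Lissajous figure: in-phase (covariant) samples fall on a positive-slope
line — phase shift 0 — while anti-phase (contravariant) samples fall on a
negative-slope line — phase shift π.  The decision statistic is the
Pearson correlation of the two derivative segments; its sign gives the
phase, with an ambiguity band |r| ≤ τ.  A window scan ranks candidate
regions by how differently the two cohort groups classify, and a
concordance check compares phases against the clinical WBC/blast-count
rule (phase 0 ⇔ WBC > 9.0 and blasts > 1.0, both 10³/µL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CohortSet, Spectrum, ValidationError
from .preprocess import PreprocessConfig, group_average, sg_derivative

__all__ = [
    "DEFAULT_WINDOW",
    "RefDeriv",
    "PhaseResult",
    "WindowScan",
    "build_reference",
    "lissajous_points",
    "classify_phase",
    "classify_cohort",
    "scan_windows",
    "phase_count_concordance",
]

DEFAULT_WINDOW = (1042.0, 1050.0)
DEFAULT_TAU = 0.2

PHASE_ZERO = "0"
PHASE_PI = "pi"
PHASE_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class RefDeriv:
    """First-derivative reference built from control spectra only."""

    grid: np.ndarray
    values: np.ndarray
    n_controls: int


@dataclass(frozen=True)
class PhaseResult:
    sample_id: str
    window: tuple[float, float]
    phase: str  # "0" | "pi" | "ambiguous"
    statistic: float  # Pearson correlation in [-1, 1]; NaN if undefined
    curve: np.ndarray  # (n, 2) array of (ref', sample') points


@dataclass(frozen=True)
class WindowScan:
    windows: list[tuple[float, float]]
    scores: np.ndarray  # separation score per window, in [0, 1]

    def ranked(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"k1": [w[0] for w in self.windows],
             "k2": [w[1] for w in self.windows],
             "separation_score": self.scores}
        )
        return df.sort_values("separation_score", ascending=False, kind="stable")


def build_reference(
    cohort: CohortSet, cfg: PreprocessConfig | None = None, exclude: str | None = None
) -> RefDeriv:
    """SG first derivative of the control-group average spectrum.

    ``exclude`` drops one control subject first (leave-one-out mode for
    classifying controls against a reference that does not contain them).
    """
    cfg = cfg or PreprocessConfig()
    controls = cohort.subset("control")
    if exclude is not None:
        controls = CohortSet(
            [s for s in controls if s.sample_id != exclude], grid=controls.grid
        )
    if len(controls) == 0:
        raise ValidationError("no control samples to build a reference from")
    avg = group_average(controls, "control")
    deriv = sg_derivative(avg, 1, cfg)
    return RefDeriv(
        grid=deriv.wavenumbers, values=deriv.absorbance,
        n_controls=len(controls.sample_ids),
    )


def _window_slice(grid: np.ndarray, window: tuple[float, float]) -> slice:
    k1, k2 = window
    if k1 >= k2:
        raise ValidationError("window must satisfy k1 < k2")
    if k1 < grid[0] or k2 > grid[-1]:
        raise ValidationError(f"window {window} outside grid [{grid[0]}, {grid[-1]}]")
    sl = slice(
        int(np.searchsorted(grid, k1, side="left")),
        int(np.searchsorted(grid, k2, side="right")),
    )
    if sl.stop - sl.start < 3:
        raise ValidationError(
            f"window {window} holds fewer than 3 grid points; widen it or "
            "interpolate to a finer grid"
        )
    return sl


def lissajous_points(
    ref: RefDeriv,
    s: Spectrum,
    window: tuple[float, float] = DEFAULT_WINDOW,
    cfg: PreprocessConfig | None = None,
) -> np.ndarray:
    """Ordered (ref′(k), sample′(k)) pairs over the window."""
    cfg = cfg or PreprocessConfig()
    if len(s) != ref.grid.size or not np.array_equal(s.wavenumbers, ref.grid):
        raise ValidationError("sample and reference must share a grid; resample first")
    deriv = sg_derivative(s, 1, cfg)
    sl = _window_slice(ref.grid, window)
    return np.column_stack([ref.values[sl], deriv.absorbance[sl]])


def classify_phase(
    ref: RefDeriv,
    s: Spectrum,
    window: tuple[float, float] = DEFAULT_WINDOW,
    tau: float = DEFAULT_TAU,
    cfg: PreprocessConfig | None = None,
) -> PhaseResult:
    """Phase 0 vs π from the sign of the windowed derivative correlation."""
    curve = lissajous_points(ref, s, window, cfg)
    x, y = curve[:, 0], curve[:, 1]
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return PhaseResult(s.sample_id, window, PHASE_AMBIGUOUS, float("nan"), curve)
    r = float(np.corrcoef(x, y)[0, 1])
    if r > tau:
        phase = PHASE_ZERO
    elif r < -tau:
        phase = PHASE_PI
    else:
        phase = PHASE_AMBIGUOUS
    return PhaseResult(s.sample_id, window, phase, r, curve)


def classify_cohort(
    cohort: CohortSet,
    ref: RefDeriv | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    tau: float = DEFAULT_TAU,
    cfg: PreprocessConfig | None = None,
    leave_one_out: bool = False,
) -> list[PhaseResult]:
    """Classify every sample; optionally rebuild the reference without the
    control being classified (honest-evaluation mode)."""
    cfg = cfg or PreprocessConfig()
    results = []
    for s in cohort:
        if leave_one_out and s.group == "control":
            r = build_reference(cohort, cfg, exclude=s.sample_id)
        else:
            r = ref if ref is not None else build_reference(cohort, cfg)
        results.append(classify_phase(r, s, window, tau, cfg))
    return results


def scan_windows(
    cohort: CohortSet,
    ref: RefDeriv,
    delta: float = 8.0,
    step: float = 2.0,
    k_range: tuple[float, float] | None = None,
    tau: float = DEFAULT_TAU,
    cfg: PreprocessConfig | None = None,
) -> WindowScan:
    """Slide a width-Δ window and score group separation of phase labels.

    The score is |P(phase 0 | disease) − P(phase 0 | control)| ∈ [0, 1].
    """
    cfg = cfg or PreprocessConfig()
    grid = ref.grid
    if delta < 2 * cfg.grid_step:
        raise ValidationError("delta must span at least 2 grid steps")
    lo, hi = k_range if k_range is not None else (grid[0], grid[-1])
    labels = cohort.labels()
    if not {"control", "bcp_all"} <= set(labels):
        raise ValidationError("window scan needs both labeled groups")
    # precompute derivatives once; windows reuse the slices
    derivs = {s.sample_id: sg_derivative(s, 1, cfg).absorbance for s in cohort}
    windows, scores = [], []
    k1 = lo
    while k1 + delta <= hi:
        window = (k1, k1 + delta)
        sl = _window_slice(grid, window)
        x = ref.values[sl]
        zero_frac = {"control": [], "bcp_all": []}
        for s in cohort:
            y = derivs[s.sample_id][sl]
            if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if s.group in zero_frac:
                zero_frac[s.group].append(1.0 if r > tau else 0.0)
        if zero_frac["control"] and zero_frac["bcp_all"]:
            score = abs(np.mean(zero_frac["bcp_all"]) - np.mean(zero_frac["control"]))
        else:
            score = 0.0
        windows.append(window)
        scores.append(score)
        k1 += step
    return WindowScan(windows=windows, scores=np.array(scores))


def phase_count_concordance(
    results: list[PhaseResult],
    counts: pd.DataFrame,
    wbc_thr: float = 9.0,
    blast_thr: float = 1.0,
) -> pd.DataFrame:
    """Agreement between observed phases and the WBC/blast-count rule.

    ``counts`` must be indexed by sample_id with ``wbc`` and ``blasts``
    columns (10³/µL).  Predicted phase is 0 when both counts exceed their
    thresholds, π otherwise.  Samples with missing counts are excluded
    and flagged in the ``excluded`` column.
    """
    rows = []
    for res in results:
        if res.sample_id not in counts.index:
            rows.append({"sample_id": res.sample_id, "excluded": True})
            continue
        wbc = counts.loc[res.sample_id, "wbc"]
        blasts = counts.loc[res.sample_id, "blasts"]
        if pd.isna(wbc) or pd.isna(blasts):
            rows.append({"sample_id": res.sample_id, "excluded": True})
            continue
        predicted = PHASE_ZERO if (blasts > blast_thr and wbc > wbc_thr) else PHASE_PI
        rows.append(
            {"sample_id": res.sample_id, "excluded": False,
             "wbc": float(wbc), "blasts": float(blasts),
             "observed_phase": res.phase, "predicted_phase": predicted,
             "agree": res.phase == predicted}
        )
    df = pd.DataFrame(rows)
    df.attrs["concordance"] = (
        float(df.loc[~df["excluded"], "agree"].mean()) if (~df["excluded"]).any() else float("nan")
    )
    return df
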