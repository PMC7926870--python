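"""Peak location, integration and ratio biomarkers with group testing.

Ratios of band areas (or heights) are classic serum-IR biomarkers because
they cancel film thickness.  Windows are band-level: each window spans a
band's visible support, and per-sample maxima are located inside it, so a
few cm⁻¹ of disease-related peak drift needs no per-group window table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CohortSet, Spectrum, ValidationError

__all__ = [
    "PeakWindow",
    "RatioResult",
    "DEFAULT_WINDOWS",
    "CH3_WINDOW",
    "AMIDE_I_WINDOW",
    "locate_peak",
    "integrate_peak",
    "ratio_feature",
    "cohort_ratio_table",
    "group_ratio_test",
]


@dataclass(frozen=True)
class PeakWindow:
    label: str
    lo: float  # cm⁻¹
    hi: float  # cm⁻¹

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError(f"window {self.label!r}: lo must be < hi")


# Band-level integration windows around the principal serum bands,
# roughly symmetric about each band maximum and covering its support.
DEFAULT_WINDOWS: dict[str, PeakWindow] = {
    w.label: w
    for w in [
        PeakWindow("894", 870, 915),
        PeakWindow("931", 915, 955),
        PeakWindow("1071", 1040, 1100),
        PeakWindow("1166", 1140, 1190),
        PeakWindow("1241", 1210, 1270),
        PeakWindow("1311", 1290, 1330),
        PeakWindow("1340", 1330, 1365),
        PeakWindow("1396", 1365, 1425),
        PeakWindow("1455", 1425, 1490),
        PeakWindow("1538", 1500, 1580),
        PeakWindow("1645", 1600, 1700),
        PeakWindow("2924", 2900, 2945),
        PeakWindow("2965", 2945, 2985),
        PeakWindow("3278", 3150, 3400),
    ]
}
CH3_WINDOW = DEFAULT_WINDOWS["2965"]
AMIDE_I_WINDOW = DEFAULT_WINDOWS["1645"]


def _window_slice(s: Spectrum, w: PeakWindow) -> slice:
    k = s.wavenumbers
    if w.lo < k[0] or w.hi > k[-1]:
        raise ValidationError(
            f"window {w.label!r} [{w.lo}, {w.hi}] outside grid [{k[0]}, {k[-1]}]"
        )
    i0 = int(np.searchsorted(k, w.lo, side="left"))
    i1 = int(np.searchsorted(k, w.hi, side="right"))
    if i1 - i0 < 3:
        raise ValidationError(f"window {w.label!r} contains fewer than 3 grid points")
    return slice(i0, i1)


def locate_peak(s: Spectrum, w: PeakWindow) -> tuple[float, float]:
    """(position, height) of the maximal absorbance in the window.

    Ties break toward the lower wavenumber.
    """
    sl = _window_slice(s, w)
    a = s.absorbance[sl]
    i = int(np.argmax(a))  # argmax returns the first (lowest-k) maximum
    return float(s.wavenumbers[sl][i]), float(a[i])


def integrate_peak(s: Spectrum, w: PeakWindow, local_baseline: bool = False) -> float:
    """Trapezoidal band area over the window, in A.U.·cm⁻¹.

    With ``local_baseline`` the chord joining the window endpoints is
    subtracted first, making the area invariant to any linear background
    on the window.
    """
    sl = _window_slice(s, w)
    k = s.wavenumbers[sl]
    a = s.absorbance[sl].copy()
    if local_baseline:
        a -= a[0] + (a[-1] - a[0]) * (k - k[0]) / (k[-1] - k[0])
    return float(np.trapezoid(a, k))


def ratio_feature(
    s: Spectrum,
    num: PeakWindow,
    den: PeakWindow,
    mode: str = "area",
    local_baseline: bool = False,
) -> float:
    """Numerator/denominator band ratio, area (default) or height mode."""
    if mode == "area":
        n = integrate_peak(s, num, local_baseline)
        d = integrate_peak(s, den, local_baseline)
    elif mode == "height":
        n = locate_peak(s, num)[1]
        d = locate_peak(s, den)[1]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if d <= 0:
        raise ValidationError(
            f"sample {s.sample_id!r}: nonpositive denominator in window {den.label!r}"
        )
    return n / d


def cohort_ratio_table(
    cohort: CohortSet,
    pairs: list[tuple[str, str]] | None = None,
    mode: str = "area",
    local_baseline: bool = False,
    windows: dict[str, PeakWindow] | None = None,
) -> pd.DataFrame:
    """Per-sample ratio features for a list of (numerator, denominator) labels."""
    windows = windows or DEFAULT_WINDOWS
    pairs = pairs or [("2965", "1645")]
    rows = []
    for s in cohort:
        row: dict = {"sample_id": s.sample_id, "group": s.group}
        for nlab, dlab in pairs:
            row[f"{nlab}/{dlab}"] = ratio_feature(
                s, windows[nlab], windows[dlab], mode=mode, local_baseline=local_baseline
            )
        rows.append(row)
    return pd.DataFrame(rows)


_VAR_FLOOR = 1e-12  # zero-variance guard for the t statistic


@dataclass(frozen=True)
class RatioResult:
    test_name: str
    p_value: float
    statistic: float
    control_median: float
    case_median: float
    control_range: tuple[float, float]
    case_range: tuple[float, float]


def group_ratio_test(
    control_vals: np.ndarray, case_vals: np.ndarray, test: str = "welch_t"
) -> RatioResult:
    """Two-sided group comparison of a per-sample feature.

    ``welch_t`` is Welch's unequal-variance t test (with an ε variance
    floor so zero-variance groups stay finite); ``mann_whitney`` is the
    exact-on-small-n Mann–Whitney U test.
    """
    c = np.asarray(control_vals, dtype=float)
    x = np.asarray(case_vals, dtype=float)
    if c.size < 2 or x.size < 2:
        raise ValidationError("need at least 2 values per group")
    if test == "welch_t":
        vc = max(c.var(ddof=1), _VAR_FLOOR)
        vx = max(x.var(ddof=1), _VAR_FLOOR)
        se2 = vc / c.size + vx / x.size
        t = (c.mean() - x.mean()) / np.sqrt(se2)
        df = se2**2 / (
            (vc / c.size) ** 2 / (c.size - 1) + (vx / x.size) ** 2 / (x.size - 1)
        )
        p = 2.0 * stats.t.sf(abs(t), df)
        stat = float(t)
    elif test == "mann_whitney":
        res = stats.mannwhitneyu(c, x, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return RatioResult(
        test_name=test,
        p_value=float(min(p, 1.0)),
        statistic=stat,
        control_median=float(np.median(c)),
        case_median=float(np.median(x)),
        control_range=(float(c.min()), float(c.max())),
        case_range=(float(x.min()), float(x.max())),
    )
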