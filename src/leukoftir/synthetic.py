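"""Seeded synthetic serum FTIR cohort generator.

Each synthetic serum spectrum is a sum of Gaussian absorption bands at the
positions and heights of the principal serum bands (nucleic-acid,
phospholipid, protein and lipid vibrations plus the amide I/II envelope),
an amide-I composite whose eight sub-band areas are proportional to the
planted protein secondary-structure fractions, a weak odd-symmetric
"phase marker" in the carbohydrate region whose sign encodes the planted
covariant (phase 0) / contravariant (phase π) class, a smooth baseline
drift, a log-normal film-thickness factor, and i.i.d. Gaussian noise.

Every planted quantity the downstream pipeline estimates — structure
fractions, the CH₃/amide-I area ratio, the phase class, WBC and blast
counts — is emitted in a ground-truth table so recovery can be verified
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CohortSet, Spectrum
from .preprocess import PreprocessConfig, preprocess_spectrum

__all__ = [
    "BandSpec",
    "GroupModel",
    "SyntheticConfig",
    "AMIDE_SUBBAND_CENTERS",
    "AMIDE_ASSIGNMENTS",
    "default_group_models",
    "generate_sample",
    "generate_cohort",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# canonical amide-I sub-band centers (cm⁻¹) and their secondary-structure
# assignments; three β-sheet lines, two β-turn lines, one each for α-helix,
# intermolecular β-sheet and amino-acid side chains
AMIDE_SUBBAND_CENTERS = (1607.0, 1614.0, 1623.0, 1633.0, 1649.0, 1672.0, 1685.0, 1694.0)
AMIDE_ASSIGNMENTS = {
    1607.0: "side_chain",
    1614.0: "intermolecular",
    1623.0: "beta_sheet",
    1633.0: "beta_sheet",
    1649.0: "alpha",
    1672.0: "beta_turn",
    1685.0: "beta_turn",
    1694.0: "beta_sheet",
}
# how each structure's planted area is split across its sub-bands
AMIDE_SPLITS = {
    "side_chain": {1607.0: 1.0},
    "intermolecular": {1614.0: 1.0},
    "beta_sheet": {1623.0: 0.45, 1633.0: 0.45, 1694.0: 0.10},
    "alpha": {1649.0: 1.0},
    "beta_turn": {1672.0: 0.6, 1685.0: 0.4},
}
AMIDE_SUBBAND_FWHM = 18.0  # cm⁻¹


@dataclass(frozen=True)
class BandSpec:
    center: float  # cm⁻¹
    height: float  # A.U.
    fwhm: float  # cm⁻¹
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.height < 0 or self.fwhm <= 0:
            raise ValueError("band height must be >= 0 and fwhm > 0")

    @property
    def sigma(self) -> float:
        return self.fwhm * FWHM_TO_SIGMA

    @property
    def area(self) -> float:
        return self.height * self.sigma * np.sqrt(2.0 * np.pi)

    def evaluate(self, k: np.ndarray) -> np.ndarray:
        return self.height * np.exp(-0.5 * ((k - self.center) / self.sigma) ** 2)


@dataclass(frozen=True)
class GroupModel:
    """Generative model of one cohort group."""

    bands: tuple[BandSpec, ...]  # all bands except the amide I composite
    amide_fractions: dict  # structure -> fraction, sums to 1
    amide_total_area: float  # A.U.·cm⁻¹
    ch3_scale: float  # multiplier on the ~2965 cm⁻¹ CH₃ band
    phase_class_prob: float  # P(sample is covariant / phase 0)

    def __post_init__(self) -> None:
        total = sum(self.amide_fractions.values())
        if any(f < 0 for f in self.amide_fractions.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError("amide fractions must be >= 0 and sum to 1")
        if not 0.0 <= self.phase_class_prob <= 1.0:
            raise ValueError("phase_class_prob must be in [0, 1]")

    def amide_subband_areas(self, fractions: dict | None = None) -> dict:
        """Sub-band center -> area for given (default: model) fractions."""
        fractions = fractions if fractions is not None else self.amide_fractions
        areas: dict[float, float] = {}
        for structure, frac in fractions.items():
            for center, w in AMIDE_SPLITS[structure].items():
                areas[center] = areas.get(center, 0.0) + self.amide_total_area * frac * w
        return areas

    def evaluate(
        self,
        k: np.ndarray,
        fractions: dict | None = None,
        ch3_height_factor: float = 1.0,
        marker_coeff: float = 0.0,
        marker_center: float = 1046.0,
        marker_width: float = 2.5,
    ) -> np.ndarray:
        """Noise-free band composite at unit thickness, zero baseline."""
        a = np.zeros_like(k, dtype=float)
        for band in self.bands:
            scale = self.ch3_scale * ch3_height_factor if 2940.0 < band.center < 2990.0 else 1.0
            a += scale * band.evaluate(k)
        sigma = AMIDE_SUBBAND_FWHM * FWHM_TO_SIGMA
        for center, area in self.amide_subband_areas(fractions).items():
            height = area / (sigma * np.sqrt(2.0 * np.pi))
            a += height * np.exp(-0.5 * ((k - center) / sigma) ** 2)
        if marker_coeff != 0.0:
            a += marker_coeff * _odd_marker(k, marker_center, marker_width)
        return a


def _odd_marker(k: np.ndarray, center: float, width: float) -> np.ndarray:
    """Odd-symmetric unit bump: max |value| = exp(-1/2) at center ± width."""
    u = (k - center) / width
    return u * np.exp(-0.5 * u * u)


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generation settings (defaults are the study conditions)."""

    n_control: int = 10
    n_bcp_all: int = 10
    replicates: int = 3
    grid_start: float = 400.0
    grid_stop: float = 4000.0
    grid_step: float = 2.0
    noise_sd: float = 0.002  # A.U., per point
    baseline_coeffs_sd: float = 0.005  # A.U., quadratic drift coefficients
    thickness_sd: float = 0.1  # log-scale
    marker_window: tuple[float, float] = (1042.0, 1050.0)
    marker_amplitude: float = 0.02  # A.U.; class term is ± this value
    marker_width: float = 4.0  # cm⁻¹
    fraction_kappa: float = 400.0  # Dirichlet-like concentration of fractions
    band_jitter_sd: float = 0.05  # log-scale jitter of band heights
    ch3_jitter_sd: float = 0.3  # log-scale jitter of the CH₃ band height
    amide_area_jitter_sd: float = 0.1  # log-scale jitter of total amide area
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_bcp_all < 1 or self.replicates < 1:
            raise ValueError("counts and replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.marker_window[0] < self.marker_window[1]:
            raise ValueError("marker window must satisfy k1 < k2")

    @property
    def grid(self) -> np.ndarray:
        n = int(np.floor((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)

    @property
    def marker_center(self) -> float:
        return 0.5 * (self.marker_window[0] + self.marker_window[1])


# Principal serum band positions (cm⁻¹) and maxima (A.U.) per group; the
# amide I line itself is synthesized from the eight sub-bands instead.
# Widths: 25 cm⁻¹ for fingerprint bands, 45 cm⁻¹ for C–H stretches, 80 cm⁻¹
# for the broad N–H/O–H stretch, plus a 40 cm⁻¹ carbohydrate-region pedestal
# at 1046 cm⁻¹.  The pedestal keeps the phase-marker region physically
# non-negative, and its right-flank slope balances the neighboring
# 1070/1071 cm⁻¹ band's tail so the window's background derivative is
# locally flat — the regime in which in-phase/anti-phase polarity shows up
# as clean ±slope Lissajous lines.
_CONTROL_BANDS = [
    (894.0, 0.002, 25.0), (931.0, 0.001, 25.0), (1046.0, 0.025, 40.0),
    (1071.0, 0.039, 25.0), (1166.0, 0.013, 25.0), (1241.0, 0.027, 25.0),
    (1311.0, 0.022, 25.0), (1340.0, 0.020, 25.0), (1396.0, 0.041, 25.0),
    (1455.0, 0.034, 25.0), (1538.0, 0.066, 25.0),
    (2924.0, 0.028, 45.0), (2965.0, 0.027, 45.0), (3278.0, 0.028, 80.0),
]
_BCP_ALL_BANDS = [
    (893.0, 0.001, 25.0), (932.0, 0.001, 25.0), (1046.0, 0.025, 40.0),
    (1070.0, 0.029, 25.0), (1163.0, 0.012, 25.0), (1239.0, 0.025, 25.0),
    (1311.0, 0.022, 25.0), (1340.0, 0.020, 25.0), (1396.0, 0.037, 25.0),
    (1454.0, 0.033, 25.0), (1537.0, 0.064, 25.0),
    (2926.0, 0.020, 45.0), (2962.0, 0.019, 45.0), (3277.0, 0.034, 80.0),
]

_CONTROL_FRACTIONS = {
    "alpha": 0.51, "beta_sheet": 0.25, "beta_turn": 0.175,
    "intermolecular": 0.06, "side_chain": 0.005,
}
_BCP_ALL_FRACTIONS = {
    "alpha": 0.40, "beta_sheet": 0.34, "beta_turn": 0.23,
    "intermolecular": 0.03, "side_chain": 0.0,
}

AMIDE_TOTAL_AREA = 2.2  # A.U.·cm⁻¹; composite maximum ≈ 0.07 A.U.
RATIO_TARGETS = {"control": 1.595, "bcp_all": 0.54}  # expected 2965/1645 area ratio


def _measured_ratio(spectrum: Spectrum) -> float:
    """CH₃/amide-I windowed area ratio under the pipeline's conventions.

    Rubberband-corrected, trapezoid over the default (2945, 2985) and
    (1600, 1700) cm⁻¹ windows; this is the noise-free limit of what the
    feature pipeline measures, and defines the planted "true ratio".
    """
    from .peaks import AMIDE_I_WINDOW, CH3_WINDOW, integrate_peak

    cfg = PreprocessConfig(normalize=False)
    pre = preprocess_spectrum(spectrum, cfg)
    num = integrate_peak(pre, CH3_WINDOW)
    den = integrate_peak(pre, AMIDE_I_WINDOW)
    return num / den


def _spectrum_from_model(model: GroupModel, cfg: SyntheticConfig, **kw) -> Spectrum:
    k = cfg.grid
    return Spectrum(
        sample_id="model", wavenumbers=k, absorbance=model.evaluate(k, **kw)
    )


def _tune_ch3_scale(model: GroupModel, target: float, cfg: SyntheticConfig) -> GroupModel:
    """Fixed-point solve for the CH₃ multiplier hitting the target ratio."""
    from dataclasses import replace as dreplace

    m = model
    for _ in range(8):
        r = _measured_ratio(_spectrum_from_model(m, cfg))
        if abs(r - target) < 1e-10 * target:
            break
        m = dreplace(m, ch3_scale=m.ch3_scale * target / r)
    return m


def default_group_models(cfg: SyntheticConfig | None = None) -> tuple[GroupModel, GroupModel]:
    """Control and BCP-ALL group models with tuned CH₃ multipliers.

    The control model carries ~51% α-helix, 25% β-sheet, 17.5% β-turn, 6%
    intermolecular β-sheet and the small side-chain remainder; the disease
    model shifts mass from α-helix to β structures.  CH₃ multipliers are
    solved so the expected CH₃/amide-I area ratio is ≈ 1.6 (control) vs
    ≈ 0.54 (disease).
    """
    cfg = cfg or SyntheticConfig()
    control = GroupModel(
        bands=tuple(BandSpec(c, h, w) for c, h, w in _CONTROL_BANDS),
        amide_fractions=dict(_CONTROL_FRACTIONS),
        amide_total_area=AMIDE_TOTAL_AREA,
        ch3_scale=1.0,
        phase_class_prob=0.4,
    )
    bcp_all = GroupModel(
        bands=tuple(BandSpec(c, h, w) for c, h, w in _BCP_ALL_BANDS),
        amide_fractions=dict(_BCP_ALL_FRACTIONS),
        amide_total_area=AMIDE_TOTAL_AREA,
        ch3_scale=1.0,
        phase_class_prob=0.4,
    )
    control = _tune_ch3_scale(control, RATIO_TARGETS["control"], cfg)
    bcp_all = _tune_ch3_scale(bcp_all, RATIO_TARGETS["bcp_all"], cfg)
    return control, bcp_all


def _draw_fractions(model: GroupModel, cfg: SyntheticConfig, rng: np.random.Generator) -> dict:
    """Dirichlet-like per-sample fractions around the group composition."""
    names = list(model.amide_fractions)
    shapes = np.array([cfg.fraction_kappa * model.amide_fractions[n] for n in names])
    draws = np.array([rng.gamma(s) if s > 0 else 0.0 for s in shapes])
    draws = draws / draws.sum()
    return dict(zip(names, draws))


def _draw_counts(
    phase: str, group: str, rng: np.random.Generator
) -> tuple[float, float]:
    """WBC and blast counts (10³/µL) consistent with the phase-class rule.

    Disease samples obey the rule by construction: covariant (phase 0)
    samples have WBC > 9.0 and blasts > 1.0; contravariant samples fall
    below at least one threshold.  Control counts are rule-independent.
    """
    if group == "control":
        wbc = float(np.exp(rng.normal(np.log(6.0), 0.35)))
        return wbc, 0.0
    if phase == "0":
        wbc = 0.0
        while wbc <= 9.0:
            wbc = float(np.exp(rng.normal(np.log(20.0), 0.8)))
        blasts = wbc * rng.uniform(0.3, 0.9)
    else:
        wbc = float(rng.uniform(0.1, 9.0))
        blasts = min(wbc * rng.uniform(0.0, 0.15), 1.0)
    return wbc, float(blasts)


def generate_sample(
    model: GroupModel,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    sample_id: str,
    group: str,
    marker_sign: int,
    phase: str,
) -> tuple[list[Spectrum], dict]:
    """One subject: ``cfg.replicates`` spectra plus its ground-truth row.

    ``marker_sign`` (±1) sets the sample's marker polarity; ``phase`` is
    the planted class label ("0" when the sign matches the control-cohort
    majority orientation, "pi" otherwise — see :func:`generate_cohort`).
    """
    fractions = _draw_fractions(model, cfg, rng)
    ch3_factor = float(np.exp(rng.normal(0.0, cfg.ch3_jitter_sd)))
    amide_factor = float(np.exp(rng.normal(0.0, cfg.amide_area_jitter_sd)))
    band_factors = np.exp(rng.normal(0.0, cfg.band_jitter_sd, size=len(model.bands)))
    marker_coeff = marker_sign * cfg.marker_amplitude
    wbc, blasts = _draw_counts(phase, group, rng)

    from dataclasses import replace as dreplace

    sample_model = dreplace(
        model,
        bands=tuple(
            dreplace(b, height=b.height * f) for b, f in zip(model.bands, band_factors)
        ),
        amide_total_area=model.amide_total_area * amide_factor,
    )
    k = cfg.grid
    clean = sample_model.evaluate(
        k,
        fractions=fractions,
        ch3_height_factor=ch3_factor,
        marker_coeff=marker_coeff,
        marker_center=cfg.marker_center,
        marker_width=cfg.marker_width,
    )
    meta = {"wbc": wbc} if group == "control" else {"wbc": wbc, "blasts": blasts}
    true_ratio = _measured_ratio(
        Spectrum(sample_id=sample_id, wavenumbers=k, absorbance=clean)
    )

    x = (k - k.mean()) / (0.5 * (k[-1] - k[0]))  # in [-1, 1]
    replicates = []
    for r in range(1, cfg.replicates + 1):
        coeffs = rng.normal(0.0, cfg.baseline_coeffs_sd, size=3)
        drift = coeffs[0] + coeffs[1] * x + coeffs[2] * x * x
        drift = drift - drift.min()  # keep the pre-noise trace non-negative
        thickness = float(np.exp(rng.normal(0.0, cfg.thickness_sd)))
        noise = rng.normal(0.0, cfg.noise_sd, size=k.size) if cfg.noise_sd > 0 else 0.0
        replicates.append(
            Spectrum(
                sample_id=sample_id,
                group=group,
                replicate=r,
                wavenumbers=k,
                absorbance=thickness * (clean + drift) + noise,
                meta=dict(meta),
            )
        )
    truth = {
        "sample_id": sample_id,
        "group": group,
        "frac_alpha": fractions["alpha"],
        "frac_beta_sheet": fractions["beta_sheet"],
        "frac_beta_turn": fractions["beta_turn"],
        "frac_intermolecular": fractions["intermolecular"],
        "frac_side_chain": fractions["side_chain"],
        "ratio_2965_1645": true_ratio,
        "phase": phase,
        "wbc": wbc,
        "blasts": blasts,
    }
    return replicates, truth


def _draw_marker_signs(
    cfg: SyntheticConfig,
    models: tuple[GroupModel, GroupModel],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Marker polarities for both groups plus the cohort orientation.

    The phase labels are relational: a sample is covariant (phase 0) when
    its marker polarity matches the control-group majority, because the
    classifier's reference is the control average and carries the majority
    direction.  An exactly tied control group leaves the reference with no
    marker direction, so tied sign vectors are re-drawn.
    """
    p_ctrl, p_all = models[0].phase_class_prob, models[1].phase_class_prob
    for _ in range(200):
        ctrl = np.where(rng.uniform(size=cfg.n_control) < p_ctrl, 1, -1)
        if ctrl.sum() != 0:
            break
    else:  # pragma: no cover - (2/3)^200 is never reached in practice
        ctrl[-1] = -ctrl[-1]
    disease = np.where(rng.uniform(size=cfg.n_bcp_all) < p_all, 1, -1)
    orientation = 1 if ctrl.sum() > 0 else -1
    return ctrl, disease, orientation


def generate_cohort(
    cfg: SyntheticConfig | None = None,
    models: tuple[GroupModel, GroupModel] | None = None,
) -> tuple[CohortSet, pd.DataFrame]:
    """Full seeded cohort: spectra plus the aligned ground-truth table."""
    cfg = cfg or SyntheticConfig()
    control_model, bcp_all_model = models or default_group_models(cfg)
    rng = np.random.default_rng(cfg.seed)
    ctrl_signs, all_signs, orientation = _draw_marker_signs(
        cfg, (control_model, bcp_all_model), rng
    )
    spectra: list[Spectrum] = []
    rows: list[dict] = []
    for i in range(cfg.n_control):
        sign = int(ctrl_signs[i])
        reps, truth = generate_sample(
            control_model, cfg, rng, f"CTRL{i + 1:03d}", "control",
            marker_sign=sign, phase="0" if sign == orientation else "pi",
        )
        spectra.extend(reps)
        rows.append(truth)
    for i in range(cfg.n_bcp_all):
        sign = int(all_signs[i])
        reps, truth = generate_sample(
            bcp_all_model, cfg, rng, f"ALL{i + 1:03d}", "bcp_all",
            marker_sign=sign, phase="0" if sign == orientation else "pi",
        )
        spectra.extend(reps)
        rows.append(truth)
    return CohortSet(spectra, grid=cfg.grid), pd.DataFrame(rows)
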