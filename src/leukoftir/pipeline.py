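"""One-command orchestration: cohort in → preprocessing → ratio, structure
and phase biomarkers → evaluation → machine-readable report.

The report is deterministic for a fixed seed (no timestamps; JSON with
sorted keys) and embeds the fully resolved configuration, so a run can be
reproduced from its own report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amide import cohort_structure_table
from .core import CohortSet, ValidationError, load_cohort
from .evaluate import bootstrap_auc_ci, loocv_adaboost, roc_youden
from .lissajous import (
    DEFAULT_WINDOW,
    build_reference,
    classify_cohort,
    phase_count_concordance,
)
from .peaks import cohort_ratio_table, group_ratio_test
from .preprocess import PreprocessConfig, preprocess_cohort, sg_derivative
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    manifest: str | None = None  # exactly one of manifest / synthetic
    synthetic: SyntheticConfig | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    ratio_pairs: tuple[tuple[str, str], ...] = (("2965", "1645"),)
    marker_window: tuple[float, float] = DEFAULT_WINDOW
    tau: float = 0.2
    leave_one_out_reference: bool = False
    run_ml_baseline: bool = True
    seed: int = 0
    output_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.synthetic is None):
            raise ValidationError("exactly one of manifest/synthetic must be set")

    def to_dict(self) -> dict:
        # output_dir is environmental (like a timestamp): it is excluded so
        # reports from different directories stay byte-identical
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        return d


def _load_input(cfg: PipelineConfig) -> tuple[CohortSet, pd.DataFrame | None]:
    if cfg.synthetic is not None:
        synth = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        return generate_cohort(synth)
    return load_cohort(cfg.manifest), None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the report files under output_dir."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, truth = _load_input(cfg)

    pre = preprocess_cohort(cohort, cfg.preprocess)
    labels = pre.labels()
    have_groups = {"control", "bcp_all"} <= set(labels)

    # --- stage 1: peak-ratio biomarkers
    features = cohort_ratio_table(pre, pairs=list(cfg.ratio_pairs))
    features.to_csv(out / "features.csv", index=False)
    ratio_tests = {}
    if have_groups:
        for nlab, dlab in cfg.ratio_pairs:
            col = f"{nlab}/{dlab}"
            res = group_ratio_test(
                features.loc[features.group == "control", col].to_numpy(),
                features.loc[features.group == "bcp_all", col].to_numpy(),
            )
            ratio_tests[col] = {
                "p_value": res.p_value,
                "control_median": res.control_median,
                "case_median": res.case_median,
            }

    # --- stage 2: amide I secondary structure + ROC on %βs+βt
    structure, group_means, avg_mode = cohort_structure_table(pre, cfg.preprocess)
    structure.to_csv(out / "structure.csv", index=False)
    roc_block = None
    if have_groups:
        ok = structure.dropna(subset=["pct_beta_total"])
        scores = ok["pct_beta_total"].to_numpy()
        y = (ok["group"] == "bcp_all").to_numpy().astype(int)
        direction = (
            "lower_is_case"
            if scores[y == 1].mean() < scores[y == 0].mean()
            else "higher_is_case"
        )
        roc = roc_youden(scores, y, direction)
        ci = bootstrap_auc_ci(scores, y, seed=cfg.seed, direction=direction)
        roc_block = {
            "biomarker": "pct_beta_total",
            "auc": roc.auc, "cutoff": roc.cutoff,
            "sensitivity": roc.sensitivity, "specificity": roc.specificity,
            "accuracy": roc.accuracy, "direction": roc.direction,
            "auc_ci95": list(ci),
        }
        with open(out / "roc.json", "w") as fh:
            json.dump(roc_block, fh, indent=2, sort_keys=True)

    # --- stage 3: Lissajous phase classification + count concordance
    ref = build_reference(pre, cfg.preprocess)
    phases = classify_cohort(
        pre, ref, cfg.marker_window, cfg.tau, cfg.preprocess,
        leave_one_out=cfg.leave_one_out_reference,
    )
    phase_df = pd.DataFrame(
        [{"sample_id": r.sample_id, "group": labels[r.sample_id],
          "phase": r.phase, "statistic": r.statistic} for r in phases]
    )
    phase_df.to_csv(out / "phases.csv", index=False)
    counts = pre.counts()
    disease_ids = set(labels[labels == "bcp_all"].index)
    disease_results = [r for r in phases if r.sample_id in disease_ids]
    concord = phase_count_concordance(disease_results, counts)
    concordance = concord.attrs["concordance"] if len(concord) else float("nan")

    # --- stage 4: ML baseline on first-derivative spectra
    ml_block = None
    if cfg.run_ml_baseline and have_groups:
        X = np.vstack([sg_derivative(s, 1, cfg.preprocess).absorbance for s in pre])
        y = np.array([1 if s.group == "bcp_all" else 0 for s in pre])
        cm = loocv_adaboost(X, y, seed=cfg.seed)
        ml_block = {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                    "accuracy": cm.accuracy}

    resolved = cfg.to_dict()
    report = {
        "version": __version__,
        "seed": cfg.seed,
        "config": resolved,
        "config_hash": hashlib.sha256(
            json.dumps(resolved, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_samples": len(labels),
        "n_spectra": len(cohort),
        "ratio_tests": ratio_tests,
        "structure_group_means": {
            g: group_means.loc[g].to_dict() for g in group_means.index
        },
        "structure_average_spectrum_mode": {
            g: {"pct_alpha": ss.pct_alpha, "pct_beta_total": ss.pct_beta_total,
                "pct_other": ss.pct_other}
            for g, ss in avg_mode.items()
        },
        "roc": roc_block,
        "phase_concordance_bcp_all": concordance,
        "ml_baseline": ml_block,
    }
    if truth is not None:
        truth.to_csv(out / "ground_truth.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
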