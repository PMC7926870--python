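"""Small bundled example datasets.

``clinical_example_counts`` is the published worked example this package
ships for the WBC/blast-count concordance rule: per-subject white blood
cell and circulating blast counts (10³/µL) with the Lissajous phase label
each subject received.  For the ten leukemia subjects the rule
(phase 0 ⇔ WBC > 9.0 and blasts > 1.0) matches the labels 10/10; for the
ten controls the labels show no relationship with WBC, which is the
point of the contrast.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["clinical_example_counts", "rule_predicted_phase"]

_BCP_ALL_ROWS = [
    # (sample_id, phase, wbc, blasts)
    ("BCAx076ALL", "0", 205.8, 183.16),
    ("BCAx077ALL", "0", 21.08, 11.80),
    ("BCAx079ALL", "pi", 1.7, 0.24),
    ("BCAx083ALL", "0", 9.08, 2.81),
    ("BCAx084ALL", "pi", 3.33, 0.66),
    ("BCAx094ALL", "pi", 2.22, 0.0),
    ("BCAx103ALL", "pi", 0.13, 0.0),
    ("BCAx113ALL", "pi", 1.62, 0.19),
    ("BCAx146ALL", "pi", 4.15, 0.33),
    ("BCAx167ALL", "0", 22.43, 10.99),
]
_CONTROL_ROWS = [
    # controls carry no blast counts
    ("BCAx099KAll", "0", 3.98, None),
    ("BCAx101KAll", "pi", 7.38, None),
    ("BCAx102KAll", "0", 4.86, None),
    ("BCAx105KAll", "pi", 5.37, None),
    ("BCAx106KAll", "0", 10.63, None),
    ("BCAx109KAll", "pi", 5.61, None),
    ("BCAx119KAll", "0", 10.50, None),
    ("BCAx127KAll", "pi", 7.99, None),
    ("BCAx130KAll", "pi", 3.6, None),
    ("BCAx131KAll", "pi", 5.24, None),
]


def clinical_example_counts(group: str = "bcp_all") -> pd.DataFrame:
    """Worked-example counts table, indexed by sample_id.

    ``group`` selects ``bcp_all`` (WBC, blasts, phase) or ``control``
    (WBC, phase; blasts NaN).
    """
    if group == "bcp_all":
        rows = _BCP_ALL_ROWS
    elif group == "control":
        rows = _CONTROL_ROWS
    else:
        raise ValueError(f"unknown group {group!r}")
    df = pd.DataFrame(rows, columns=["sample_id", "phase", "wbc", "blasts"])
    return df.set_index("sample_id")


def rule_predicted_phase(
    wbc: float, blasts: float, wbc_thr: float = 9.0, blast_thr: float = 1.0
) -> str:
    """Phase predicted from counts: "0" iff both thresholds are exceeded."""
    return "0" if (blasts > blast_thr and wbc > wbc_thr) else "pi"
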