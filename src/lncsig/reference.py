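"""Reference summary statistics of the 28-probe plasma lncRNA IPMN panel.

Fixed published-style inputs used for arithmetic cross-checks of the
pipeline's summary conventions: per-probe group means on the log2 scale for
the malignant (n = 30) vs benign (n = 21) IPMN contrast, the reported
two-sided p-values, BH false discovery rates and mean-ratio fold changes;
plus the cohort bookkeeping (pre-QC sample counts, QC exclusions and the
pathology-grade mix of the retained cases).  These are inputs, not outputs:
the package recomputes the derived columns (overall mean, fold change, FDR,
selection set) from the group means and p-values.
"""

from __future__ import annotations

import pandas as pd

N_BENIGN = 21
N_MALIGNANT = 30
N_CONTROLS = 22

#: Pre-QC cohort and exclusion bookkeeping.
PRE_QC_CASES = 57
PRE_QC_CONTROLS = 24
AMPLIFICATION_FAILURES_CASES = 1
BINDING_DENSITY_FAILURES_CASES = 5
BINDING_DENSITY_FAILURES_CONTROLS = 2
RETAINED_CASES = 51
RETAINED_CONTROLS = 22

#: Pathology-grade counts of the retained IPMN cases.
GRADE_COUNTS = {"low": 6, "moderate": 15, "high": 12, "invasive": 18}
GRADE_PERCENTAGES = {"low": 12, "moderate": 29, "high": 24, "invasive": 35}

#: probe -> (overall mean, benign mean, malignant mean, p, FDR, fold change),
#: log2 units for the means; fold change is malignant mean / benign mean.
_PANEL_ROWS = {
    "GLIS3-AS1":  (11.7, 10.6, 12.4, 0.005, 0.120, 1.2),
    "ANRIL":      (11.7, 10.7, 12.3, 0.009, 0.120, 1.2),
    "PANDA":      (8.4, 7.0, 9.3, 0.016, 0.141, 1.3),
    "MEG3":       (10.3, 9.4, 10.9, 0.022, 0.141, 1.2),
    "PVT1":       (12.2, 11.6, 12.6, 0.037, 0.141, 1.1),
    "ADARB2-AS1": (10.4, 9.8, 10.8, 0.039, 0.141, 1.1),
    "LINC00472":  (10.4, 9.6, 10.9, 0.039, 0.141, 1.1),
    "UCA1":       (12.1, 11.4, 12.6, 0.041, 0.141, 1.1),
    "PPP3CB":     (13.5, 13.1, 13.8, 0.058, 0.176, 1.1),
    "LINC00469":  (9.6, 8.7, 10.3, 0.099, 0.277, 1.2),
    "LINC00491":  (9.9, 9.2, 10.5, 0.133, 0.337, 1.1),
    "TERC":       (9.2, 8.7, 9.5, 0.153, 0.355, 1.1),
    "AS1DHRS4":   (13.4, 13.0, 13.7, 0.183, 0.365, 1.0),
    "MALAT1":     (10.7, 10.4, 11.0, 0.198, 0.365, 1.1),
    "H19":        (15.0, 14.6, 15.2, 0.206, 0.365, 1.0),
    "PTENP1":     (6.5, 5.8, 6.9, 0.209, 0.365, 1.2),
    "GAS5":       (15.2, 14.9, 15.4, 0.240, 0.379, 1.0),
    "HOXD-AS1":   (7.1, 6.6, 7.4, 0.245, 0.379, 1.1),
    "BCYRN1":     (0.2, 0.4, 0.1, 0.336, 0.506, 0.1),
    "HULC":       (2.1, 1.5, 2.5, 0.395, 0.531, 1.6),
    "HOTAIR":     (6.5, 6.3, 6.7, 0.400, 0.531, 1.1),
    "XIST":       (0.9, 0.7, 1.1, 0.537, 0.683, 1.6),
    "LINC00244":  (0.9, 0.7, 1.0, 0.594, 0.690, 1.4),
    "SRA":        (5.5, 5.4, 5.6, 0.624, 0.690, 1.0),
    "DDX6P":      (2.9, 2.6, 3.1, 0.632, 0.690, 1.2),
    "lncRNA-p21": (5.9, 5.7, 6.0, 0.642, 0.690, 1.0),
    "HOTTIP":     (5.8, 5.6, 6.0, 0.668, 0.693, 1.1),
    "aHIF":       (9.6, 9.6, 9.5, 0.849, 0.849, 1.0),
}

#: The eight lncRNAs forming the malignancy risk signature (raw p < 0.05).
SIGNATURE_PROBES = ("GLIS3-AS1", "ANRIL", "PANDA", "MEG3", "PVT1",
                    "ADARB2-AS1", "LINC00472", "UCA1")


def panel_summary() -> pd.DataFrame:
    """The reference per-probe summary as a DataFrame (probe-indexed)."""
    return pd.DataFrame.from_dict(
        _PANEL_ROWS, orient="index",
        columns=["overall_mean", "benign_mean", "malignant_mean",
                 "p", "fdr", "fold_change"],
    ).rename_axis("probe")


__all__ = [
    "panel_summary", "SIGNATURE_PROBES", "GRADE_COUNTS", "GRADE_PERCENTAGES",
    "N_BENIGN", "N_MALIGNANT", "N_CONTROLS", "PRE_QC_CASES",
    "PRE_QC_CONTROLS", "AMPLIFICATION_FAILURES_CASES",
    "BINDING_DENSITY_FAILURES_CASES", "BINDING_DENSITY_FAILURES_CONTROLS",
    "RETAINED_CASES", "RETAINED_CONTROLS",
]
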