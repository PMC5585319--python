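"""Sample-level quality gates for plasma nCounter panels.

Implements the pre-normalization gates: spectrophotometric hemolysis
detection (any of A414/A541/A576 strictly above 0.2), qPCR-targeted dilution
factors for the multiplexed target enrichment (MTE) product, the
binding-density acceptance window, erythrocyte/WBC contamination comparison
between cohorts, and the sample-exclusion bookkeeping.  Hemolysis is
*recorded*, never excluding by itself: exclusion happens only for
amplification failure or out-of-window binding density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CountDataset

HEMOLYSIS_ABSORBANCE_THRESHOLD = 0.2
BINDING_DENSITY_LO = 0.05
BINDING_DENSITY_HI = 2.25
#: Post-dilution target Cq values for the MTE QC genes.
CQ_TARGETS = {"GNAS": 16.0, "VIM": 19.0}


def detect_hemolysis(a414: float, a541: float, a576: float) -> bool | None:
    """True iff any absorbance strictly exceeds 0.2; ``None`` (not
    assessable) when any reading is missing — never silently passed."""
    vals = (a414, a541, a576)
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
        return None
    return any(float(v) > HEMOLYSIS_ABSORBANCE_THRESHOLD for v in vals)


def compute_dilution_factor(cq_gnas: float, cq_vim: float) -> float:
    """Dilution factor bringing each QC gene to its target Cq, assuming 100%
    PCR efficiency (one cycle = factor 2); samples already above target are
    not diluted and the higher candidate factor wins (to avoid cartridge
    overloading).  Always >= 1."""
    if not (math.isfinite(cq_gnas) and math.isfinite(cq_vim)):
        raise ValueError("Cq values must be finite")
    d_gnas = 2.0 ** (CQ_TARGETS["GNAS"] - cq_gnas) if cq_gnas < CQ_TARGETS["GNAS"] else 1.0
    d_vim = 2.0 ** (CQ_TARGETS["VIM"] - cq_vim) if cq_vim < CQ_TARGETS["VIM"] else 1.0
    return max(d_gnas, d_vim)


def check_binding_density(
    density: float,
    lo: float = BINDING_DENSITY_LO,
    hi: float = BINDING_DENSITY_HI,
) -> bool | None:
    """Pass iff ``lo <= density <= hi`` (inclusive bounds); ``None`` when the
    density is missing."""
    if density is None or (isinstance(density, float) and math.isnan(density)):
        return None
    return lo <= float(density) <= hi


@dataclass
class QCReport:
    """Per-sample QC flags plus retained/excluded bookkeeping by cohort."""

    table: pd.DataFrame           # hemolysis, bd_pass, dilution_factor, exclusion_reason
    retained_by_cohort: dict = field(default_factory=dict)
    excluded_by_cohort: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return sum(self.retained_by_cohort.values())

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded_by_cohort.values())

    def to_dict(self) -> dict:
        return {
            "retained_by_cohort": dict(self.retained_by_cohort),
            "excluded_by_cohort": dict(self.excluded_by_cohort),
            "samples": self.table.reset_index().to_dict(orient="records"),
        }


def exclude_samples(dataset: CountDataset) -> tuple[CountDataset, QCReport]:
    """Drop samples failing amplification or the binding-density window.

    Hemolysis and contamination are recorded in the report but never exclude
    (contamination is instead compared between cohorts, see
    :func:`compare_contamination`).  Raises when nothing would remain.
    """
    md = dataset.metadata
    rows = []
    for sid, rec in md.iterrows():
        hemo = detect_hemolysis(
            rec.get("absorbance_414", np.nan),
            rec.get("absorbance_541", np.nan),
            rec.get("absorbance_576", np.nan),
        )
        bd_pass = check_binding_density(rec.get("binding_density", np.nan))
        try:
            dil = compute_dilution_factor(rec.get("cq_gnas", np.nan),
                                          rec.get("cq_vim", np.nan))
        except ValueError:
            dil = np.nan
        if bool(rec.get("amplification_failed", False)):
            reason = "amplification_failure"
        elif bd_pass is False:
            reason = "binding_density"
        else:
            reason = "none"
        rows.append({"sample_id": sid, "cohort": rec.get("cohort", "case"),
                     "hemolysis": hemo, "bd_pass": bd_pass,
                     "dilution_factor": dil, "exclusion_reason": reason})
    table = pd.DataFrame(rows).set_index("sample_id")

    keep = table["exclusion_reason"] == "none"
    if not keep.any():
        raise ValueError("all samples excluded by QC; nothing to analyze")
    retained = table.loc[keep, "cohort"].value_counts().to_dict()
    excluded = table.loc[~keep, "cohort"].value_counts().to_dict()
    report = QCReport(table=table, retained_by_cohort=retained,
                      excluded_by_cohort=excluded)
    assert report.n_retained + report.n_excluded == len(md)
    return dataset.subset(table.index[keep]), report


def compare_contamination(
    dataset: CountDataset,
    groups: pd.Series | None = None,
) -> dict:
    """Compare erythrocyte contamination between two cohorts.

    Frequency: two-sided Fisher exact test on the hemolysis flag.
    Amount: two-sided Wilcoxon rank-sum (Mann-Whitney) test on log2 of the
    summed hemolysis + WBC marker counts.  Returns both statistics/p-values.
    """
    md = dataset.metadata
    if groups is None:
        groups = md["cohort"]
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    in_a = np.asarray(groups == labels[0])
    if in_a.all() or not in_a.any():
        raise ValueError("one group is empty")

    hemo = np.array([
        detect_hemolysis(r.get("absorbance_414", np.nan),
                         r.get("absorbance_541", np.nan),
                         r.get("absorbance_576", np.nan))
        for _, r in md.iterrows()
    ])
    assessable = np.array([h is not None for h in hemo])
    flags = np.array([bool(h) for h in np.where(assessable, hemo, False)])
    a_flag, a_n = int(flags[in_a & assessable].sum()), int((in_a & assessable).sum())
    b_flag, b_n = int(flags[~in_a & assessable].sum()), int((~in_a & assessable).sum())
    _, freq_p = stats.fisher_exact(
        [[a_flag, a_n - a_flag], [b_flag, b_n - b_flag]])

    markers = dataset.panel.hemolysis_markers + dataset.panel.wbc_markers
    missing = [m for m in markers if m not in dataset.counts.columns]
    if missing:
        raise ValueError(f"contamination marker probes missing: {missing}")
    amount = np.log2(dataset.counts[markers].sum(axis=1).to_numpy() + 1.0)
    stat, amount_p = stats.mannwhitneyu(
        amount[in_a], amount[~in_a], alternative="two-sided")
    return {
        "frequency_table": [[a_flag, a_n - a_flag], [b_flag, b_n - b_flag]],
        "frequency_p": float(freq_p),
        "amount_statistic": float(stat),
        "amount_p": float(amount_p),
        "groups": [str(labels[0]), str(labels[1])],
    }


def grade_distribution(grade_counts: dict) -> dict:
    """Percentages (rounded to integers) of each pathology grade."""
    total = sum(grade_counts.values())
    if total <= 0:
        raise ValueError("no graded samples")
    return {g: round(100.0 * c / total) for g, c in grade_counts.items()}


__all__ = [
    "detect_hemolysis", "compute_dilution_factor", "check_binding_density",
    "exclude_samples", "compare_contamination", "grade_distribution",
    "QCReport", "CQ_TARGETS", "BINDING_DENSITY_LO", "BINDING_DENSITY_HI",
    "HEMOLYSIS_ABSORBANCE_THRESHOLD",
]
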