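"""Synthetic nCounter-style panel datasets with known ground truth.

The generator emulates the structure of a pre-operative plasma lncRNA study:
a 28-probe endogenous panel measured on benign IPMN cases, malignant IPMN
cases and non-diseased controls, with housekeeping genes, negative/positive
controls, spike-ins, hemolysis and WBC contamination markers, per-sample
absorbances, binding densities, qPCR Cq values, clinical covariates and
precomputed external (miRNA / radiomic) signature scores.

Count model: endogenous abundance is log-normal on the log2 scale — each
count is ``round(2 ** (baseline + delta * malignant + N(0, sd)))`` — so the
log2 analysis scale used downstream is exact and the binormal AUC of any
linear score has a closed form (:func:`expected_signature_auc`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from . import panel as _panel
from .datasets import CountDataset

#: The eight malignancy-associated lncRNAs planted by default, at a
#: +1 log2-unit shift in malignant samples.
DEFAULT_PLANTED = {
    "ADARB2-AS1": 1.0, "ANRIL": 1.0, "GLIS3-AS1": 1.0, "LINC00472": 1.0,
    "MEG3": 1.0, "PANDA": 1.0, "PVT1": 1.0, "UCA1": 1.0,
}

#: Per-covariate (benign, malignant) prevalences; binary flags sampled
#: independently given class.  Controls are sampled at the benign rate.
DEFAULT_COVARIATE_PREVALENCES = {
    "jaundice": (0.05, 0.27),
    "main_duct": (0.22, 0.30),
    "mural_nodule": (0.14, 0.27),
    "gender_male": (0.38, 0.63),
    "hrs": (0.05, 0.73),
    "wf": (0.48, 0.54),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulated panel experiment.

    Defaults are the study conditions emulated throughout the test suite:
    21 benign / 30 malignant IPMN cases and 22 controls, a 28-probe panel
    with eight planted malignancy probes at delta = 1.0 log2 units, and
    within-group SD of 1.0 log2 units.
    """

    n_benign: int = 21
    n_malignant: int = 30
    n_controls: int = 22
    n_endogenous_probes: int = 28
    planted_probes: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED))
    within_group_sd: float = 1.0
    baseline_log2_mean: dict | float | None = None
    housekeeping_level: float = 2000.0
    negative_control_mean: float = 15.0
    negative_control_sd: float = 5.0
    hemolysis_probability: float = 0.10
    covariate_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    external_score_auc: dict = field(
        default_factory=lambda: {"mirna_score": 0.73, "radiomic_score": 0.77}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_benign", "n_malignant", "n_controls",
                     "n_endogenous_probes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.within_group_sd <= 0:
            raise ValueError("within_group_sd must be > 0")
        if not 0.0 <= self.hemolysis_probability <= 1.0:
            raise ValueError("hemolysis_probability must be in [0, 1]")
        for cov, (pb, pm) in self.covariate_prevalences.items():
            if not (0.0 <= pb <= 1.0 and 0.0 <= pm <= 1.0):
                raise ValueError(f"prevalences for {cov!r} must be in [0, 1]")
        for score, auc in self.external_score_auc.items():
            if not 0.0 < auc < 1.0:
                raise ValueError(f"external_score_auc[{score!r}] must be in (0, 1)")
        if self.negative_control_mean < 0 or self.negative_control_sd <= 0:
            raise ValueError("negative-control mean must be >= 0 and sd > 0")
        if self.housekeeping_level <= 0:
            raise ValueError("housekeeping_level must be > 0")

    def endogenous_names(self) -> list[str]:
        base = list(_panel.DEFAULT_LNCRNAS)
        if self.n_endogenous_probes <= len(base):
            return base[: self.n_endogenous_probes]
        extra = [f"LNC{k:04d}" for k in range(self.n_endogenous_probes - len(base))]
        return base + extra

    def baselines(self) -> np.ndarray:
        """Per-probe baseline log2 means (benign level)."""
        names = self.endogenous_names()
        if self.baseline_log2_mean is None:
            # evenly spread over the abundance range typical of the panel
            return np.linspace(6.0, 13.0, len(names))
        if np.isscalar(self.baseline_log2_mean):
            return np.full(len(names), float(self.baseline_log2_mean))
        return np.asarray([self.baseline_log2_mean[n] for n in names], dtype=float)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """What the generator planted: per-probe true log2 shifts, per-sample
    true class and contamination flags.  Deltas are zero off the planted set."""

    true_delta: pd.Series
    true_class: pd.Series          # benign | malignant | control
    contamination: pd.Series       # hemolysis flag per sample

    @property
    def planted_probes(self) -> list[str]:
        return list(self.true_delta.index[self.true_delta != 0.0])


def expected_signature_auc(k: int, delta: float, sd: float) -> float:
    """Binormal AUC of an equally-weighted sum of ``k`` independent probes,
    each shifted by ``delta`` between groups with common SD ``sd``:
    ``Phi(sqrt(k) * delta / (sd * sqrt(2)))``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return float(ndtr(np.sqrt(k) * delta / (sd * np.sqrt(2.0))))


def _binary(rng: np.random.Generator, p: np.ndarray) -> np.ndarray:
    return (rng.random(len(p)) < p).astype(int)


def generate_dataset(config: SimConfig) -> tuple[CountDataset, GroundTruth]:
    """Draw one complete dataset; identical config (incl. seed) gives
    bit-identical output."""
    endog = config.endogenous_names()
    unknown = [p for p in config.planted_probes if p not in endog]
    if unknown:
        raise ValueError(f"planted probes not in panel: {unknown}")

    rng = np.random.default_rng(config.seed)
    pan = _panel.default_panel(tuple(endog))

    n_b, n_m, n_c = config.n_benign, config.n_malignant, config.n_controls
    n = n_b + n_m + n_c
    classes = np.array(["benign"] * n_b + ["malignant"] * n_m + ["control"] * n_c)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    malignant = (classes == "malignant").astype(float)

    baselines = config.baselines()
    delta = np.array([config.planted_probes.get(p, 0.0) for p in endog])

    # endogenous counts: log-normal on log2 scale, rounded
    log2_expr = (
        baselines[None, :]
        + np.outer(malignant, delta)
        + rng.normal(0.0, config.within_group_sd, size=(n, len(endog)))
    )
    counts = {p: np.rint(2.0 ** log2_expr[:, j]).astype(int)
              for j, p in enumerate(endog)}

    # housekeeping: stable, zero planted shift, small technical noise
    hk_log2 = np.log2(config.housekeeping_level)
    for p in _panel.DEFAULT_HOUSEKEEPING:
        counts[p] = np.rint(2.0 ** (hk_log2 + rng.normal(0, 0.05, n))).astype(int)
    # spike-ins: carried through, somewhat more variable than housekeeping
    for p in _panel.DEFAULT_SPIKE_INS:
        counts[p] = np.rint(2.0 ** (hk_log2 - 1.0 + rng.normal(0, 0.3, n))).astype(int)

    # contamination: hemolysis flag independent of class; flagged samples get
    # elevated erythrocyte markers and an absorbance peak above 0.2
    hemolysed = rng.random(n) < config.hemolysis_probability
    for p in _panel.DEFAULT_HEMOLYSIS_MARKERS:
        lvl = 6.0 + 3.0 * hemolysed
        counts[p] = np.rint(2.0 ** (lvl + rng.normal(0, 0.5, n))).astype(int)
    for p in _panel.DEFAULT_WBC_MARKERS:
        counts[p] = np.rint(2.0 ** (5.0 + rng.normal(0, 0.5, n))).astype(int)

    # negative controls: truncated normal (>= 0), independent of class
    for p in _panel.DEFAULT_NEGATIVES:
        draws = rng.normal(config.negative_control_mean,
                           config.negative_control_sd, n)
        counts[p] = np.rint(np.clip(draws, 0.0, None)).astype(int)
    # positive controls: fixed geometric ladder (plumbing only)
    for p, level in zip(_panel.DEFAULT_POSITIVES, _panel.POSITIVE_LADDER):
        counts[p] = np.full(n, int(level))

    counts_df = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"))

    # ---- metadata ---------------------------------------------------------
    md = pd.DataFrame(index=counts_df.index)
    md["cohort"] = np.where(classes == "control", "control", "case")
    grade = np.full(n, "none", dtype=object)
    # benign cases split low:moderate 6:15 and malignant high:invasive 12:18,
    # matching the cohort's printed grade mix
    grade[classes == "benign"] = rng.choice(
        ["low", "moderate"], size=n_b, p=[6 / 21, 15 / 21])
    grade[classes == "malignant"] = rng.choice(
        ["high", "invasive"], size=n_m, p=[12 / 30, 18 / 30])
    md["grade"] = grade

    clean = rng.uniform(0.02, 0.15, size=(n, 3))
    peak = np.column_stack([
        rng.uniform(0.25, 0.80, n),
        rng.uniform(0.05, 0.40, n),
        rng.uniform(0.05, 0.40, n),
    ])
    absorb = np.where(hemolysed[:, None], peak, clean)
    md["absorbance_414"] = absorb[:, 0]
    md["absorbance_541"] = absorb[:, 1]
    md["absorbance_576"] = absorb[:, 2]
    md["binding_density"] = rng.uniform(0.1, 1.8, n)
    md["cq_gnas"] = rng.normal(15.0, 1.5, n)
    md["cq_vim"] = rng.normal(18.0, 1.5, n)
    md["amplification_failed"] = False

    prev_of = {"benign": 0, "malignant": 1, "control": 0}
    for cov, pair in config.covariate_prevalences.items():
        p = np.array([pair[prev_of[c]] for c in classes])
        md[cov] = _binary(rng, p)

    # continuous clinical covariates (cases only; controls NaN where
    # disease-specific): cyst size larger and albumin lower in malignant
    cyst = np.where(malignant == 1,
                    rng.normal(3.5, 1.0, n), rng.normal(2.8, 1.0, n))
    md["cyst_size_cm"] = np.where(classes == "control", np.nan,
                                  np.clip(cyst, 0.5, None))
    ca199 = np.exp(np.where(malignant == 1,
                            rng.normal(4.5, 1.5, n), rng.normal(3.0, 1.5, n)))
    md["ca19_9"] = np.where(classes == "control", np.nan, ca199)
    alb = np.where(malignant == 1,
                   rng.normal(3.9, 0.66, n), rng.normal(4.4, 0.98, n))
    md["albumin"] = np.where(classes == "control", np.nan, alb)

    # external scores: class-conditional normals calibrated so the
    # malignant-vs-benign binormal AUC hits the configured target
    for score, auc in config.external_score_auc.items():
        mu = np.sqrt(2.0) * ndtri(auc)
        md[score] = rng.normal(mu * malignant, 1.0, n)

    dataset = CountDataset(counts=counts_df, metadata=md, panel=pan)
    truth = GroundTruth(
        true_delta=pd.Series(delta, index=endog, name="true_delta"),
        true_class=pd.Series(classes, index=counts_df.index, name="true_class"),
        contamination=pd.Series(hemolysed, index=counts_df.index,
                                name="contamination"),
    )
    return dataset, truth


__all__ = ["SimConfig", "GroundTruth", "generate_dataset",
           "expected_signature_auc", "DEFAULT_PLANTED",
           "DEFAULT_COVARIATE_PREVALENCES"]
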