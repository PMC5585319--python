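"""End-to-end orchestration: signature discovery, the multimodal model grid
and clinical correlation reporting.

Two contrasts are supported: ``case_control`` (IPMN cases vs non-diseased
controls) and ``malignant_benign`` (cases with high-grade/invasive pathology
vs cases with low/moderate-grade dysplasia).  Discovery = moderated-t
screen at raw p < alpha, PC1 risk-score fit on the selected probes, ROC /
Youden / confusion evaluation.  The model grid fits one logistic model per
covariate combination (clinical flags plus lncRNA / miRNA / radiomic
scores), evaluates each at its Youden threshold, BH-adjusts the AUC-vs-0.5
p-values across the grid and reports the IDI of every augmented model
against the clinical-only base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .datasets import CountDataset, MALIGNANT_GRADES
from .diffexpr import DEResult, ModeratedTTest, bh_fdr, differential_abundance, select_candidates
from .metrics import (DiagnosticReport, evaluate_scores, fit_logistic, idi,
                      spearman_assoc, youden_threshold)
from .normalize import normalize_dataset
from .signature import Signature, fit_pc1, score_samples

logger = logging.getLogger("lncsig")

CONTRASTS = ("case_control", "malignant_benign")

#: Covariate combinations of the multimodal grid (clinical flags and the
#: three signature score channels).
DEFAULT_MODEL_GRID = (
    ("gender_male",),
    ("jaundice",),
    ("hrs",),
    ("wf",),
    ("lnc_score",),
    ("mirna_score",),
    ("radiomic_score",),
    ("mirna_score", "radiomic_score"),
    ("lnc_score", "radiomic_score"),
    ("lnc_score", "mirna_score"),
    ("lnc_score", "mirna_score", "radiomic_score"),
    ("hrs", "wf", "lnc_score"),
    ("hrs", "wf", "lnc_score", "mirna_score", "radiomic_score"),
    ("wf", "lnc_score"),
    ("wf", "lnc_score", "mirna_score", "radiomic_score"),
    ("wf", "gender_male", "jaundice", "lnc_score", "mirna_score",
     "radiomic_score"),
)


@dataclass
class AnalysisConfig:
    """Settings of one analysis run."""

    contrast: str = "malignant_benign"
    alpha: float = 0.05
    prior_df: float | None = None
    standardize: bool = False
    cv_folds: int = 10
    cv_reps: int = 1000
    seed: int = 0
    model_grid: tuple = DEFAULT_MODEL_GRID
    base_model: tuple = ("wf", "gender_male", "jaundice")

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"contrast must be one of {CONTRASTS}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def contrast_labels(dataset: CountDataset, contrast: str) -> pd.Series:
    """Boolean outcome for the requested contrast, restricted to the samples
    it involves (all samples for case_control; cases only for
    malignant_benign, with benign = low/moderate, malignant =
    high/invasive)."""
    md = dataset.metadata
    if contrast == "case_control":
        return md["cohort"].eq("case")
    if contrast == "malignant_benign":
        cases = md[md["cohort"] == "case"]
        return cases["grade"].isin(MALIGNANT_GRADES)
    raise ValueError(f"unknown contrast: {contrast!r}")


class SignatureDiscovery(BaseEstimator, ClassifierMixin):
    """Full discovery procedure as one scikit-learn classifier.

    ``fit(X, y)`` re-runs the moderated-t screen at raw p < ``alpha``, fits
    the PC1 risk score on the selected probes, orients it, and picks the
    Youden threshold on the training scores; ``decision_function`` returns
    risk scores for new samples against the training centering, and
    ``predict`` applies the training threshold.  With no probe passing the
    screen the signature is empty and all scores are zero (chance-level
    prediction) — the condition is recorded in ``warning_``.

    Used directly inside repeated cross-validation so that selection,
    signature fitting and thresholding all happen inside each training fold.
    """

    def __init__(self, alpha: float = 0.05, prior_df: float | None = None,
                 standardize: bool = False):
        self.alpha = alpha
        self.prior_df = prior_df
        self.standardize = standardize

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(bool)
        self.classes_ = np.array([False, True])
        self.selector_ = ModeratedTTest(alpha=self.alpha,
                                        prior_df=self.prior_df).fit(X, y)
        self.selected_probes_ = list(self.selector_.selected_probes_)
        self.warning_ = None
        if not self.selected_probes_:
            self.signature_ = None
            self.threshold_ = 0.0
            self.warning_ = ("no probe passed the selection threshold; "
                             "empty signature, chance-level scores")
            return self
        self.signature_ = fit_pc1(X[self.selected_probes_],
                                  standardize=self.standardize)
        scores = self.signature_.scores.to_numpy()
        yd = youden_threshold(scores, y)
        thr = yd["threshold"]
        if not np.isfinite(thr):
            thr = scores.min() if thr == -np.inf else scores.max() + 1.0
        self.threshold_ = float(thr)
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "selector_"):
            raise ValueError("SignatureDiscovery is not fitted")
        X = pd.DataFrame(X)
        if self.signature_ is None:
            return np.zeros(len(X))
        return score_samples(self.signature_, X).to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.decision_function(X) >= self.threshold_


@dataclass
class DiscoveryResult:
    """Output of one discovery run on a normalized dataset."""

    de: DEResult
    signature: Signature | None
    report: DiagnosticReport | None
    scores: pd.Series | None
    selected_probes: list = field(default_factory=list)
    warning: str | None = None


def discover_signature(
    dataset: CountDataset,
    config: AnalysisConfig | None = None,
) -> DiscoveryResult:
    """Normalize, screen, build the PC1 risk score and evaluate it for the
    configured contrast.  Requires >= 2 samples per group."""
    config = config or AnalysisConfig()
    labels = contrast_labels(dataset, config.contrast)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    sub = dataset.subset(labels.index)
    norm = normalize_dataset(sub)
    matrix = norm.data
    y = labels.to_numpy()

    de = differential_abundance(matrix, y, prior_df=config.prior_df)
    selected = select_candidates(de, config.alpha)
    if not selected:
        logger.warning("no probe passed p < %.3g; empty signature", config.alpha)
        return DiscoveryResult(de=de, signature=None, report=None, scores=None,
                               selected_probes=[],
                               warning="no probe passed selection")
    sig = fit_pc1(matrix[selected], standardize=config.standardize)
    scores = sig.scores
    report = evaluate_scores(scores.to_numpy(), y, seed=config.seed)
    return DiscoveryResult(de=de, signature=sig, report=report, scores=scores,
                           selected_probes=selected)


def run_model_grid(
    samples: pd.DataFrame,
    outcome: str = "malignant",
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Fit one logistic model per covariate combination and evaluate it.

    ``samples`` holds the binary outcome column plus covariate columns;
    rows with any missing value across the union of grid covariates are
    dropped first (the complete-data multimodal subset), and the subset size
    is recorded in ``DataFrame.attrs['n']``.  Output: one row per model with
    AUC + DeLong CI, p vs chance, BH FDR across the grid, accuracy /
    sensitivity / specificity / PPV / NPV at the Youden threshold, the IDI
    against the clinical-only base model, and a separation flag.  Models
    referencing absent covariates are skipped with a log entry.
    """
    config = config or AnalysisConfig()
    grid = [tuple(m) for m in config.model_grid]
    usable = [m for m in grid
              if all(c in samples.columns for c in m)]
    for m in grid:
        if m not in usable:
            logger.warning("model %s skipped: missing covariates", m)
    cov_union = sorted({c for m in usable for c in m} | set(config.base_model
                       if all(c in samples.columns for c in config.base_model)
                       else ()))
    data = samples.dropna(subset=[outcome, *cov_union]).copy()
    y = data[outcome].astype(bool).to_numpy()

    base_probs = None
    if all(c in data.columns for c in config.base_model):
        base_probs = fit_logistic(y, data[list(config.base_model)]).fitted_probabilities

    rows = []
    for m in usable:
        fit = fit_logistic(y, data[list(m)])
        probs = fit.fitted_probabilities
        rep = evaluate_scores(probs, y)
        row = {
            "model": " + ".join(m),
            "n_terms": len(m),
            "auc": rep.auc, "auc_lo": rep.auc_ci[0], "auc_hi": rep.auc_ci[1],
            "p": rep.p_vs_chance,
            "accuracy": rep.accuracy, "sensitivity": rep.sensitivity,
            "specificity": rep.specificity, "ppv": rep.ppv, "npv": rep.npv,
            "separated": fit.separated,
        }
        if base_probs is not None and tuple(m) != tuple(config.base_model):
            row["idi_vs_base"] = idi(probs, base_probs, y).idi
        elif base_probs is not None:
            row["idi_vs_base"] = 0.0
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        p = out["p"].to_numpy()
        valid = np.isfinite(p)
        fdr = np.full(len(p), np.nan)
        if valid.any():
            fdr[valid] = bh_fdr(p[valid])
        out["fdr"] = fdr
    out.attrs["n"] = int(len(data))
    out.attrs["n_events"] = int(y.sum())
    return out


def correlate_signature_clinical(
    scores: pd.Series,
    clinical: pd.DataFrame,
    covariates: tuple = ("cyst_size_cm", "albumin", "ca19_9"),
) -> pd.DataFrame:
    """Spearman rho and p of the risk score against each continuous clinical
    covariate, on pairwise-complete observations."""
    rows = []
    for cov in covariates:
        if cov not in clinical.columns:
            continue
        paired = pd.concat([scores, clinical[cov]], axis=1).dropna()
        if len(paired) < 3:
            rows.append({"covariate": cov, "rho": np.nan, "p": np.nan,
                         "n": len(paired)})
            continue
        res = spearman_assoc(paired.iloc[:, 0], paired.iloc[:, 1])
        rows.append({"covariate": cov, "rho": res["rho"], "p": res["p"],
                     "n": len(paired)})
    return pd.DataFrame(rows).set_index("covariate")


__all__ = [
    "AnalysisConfig", "SignatureDiscovery", "DiscoveryResult",
    "discover_signature", "run_model_grid", "correlate_signature_clinical",
    "contrast_labels", "DEFAULT_MODEL_GRID", "CONTRASTS",
]
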