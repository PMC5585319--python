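"""Diagnostic-performance machinery.

ROC/AUC (Mann-Whitney concordance with half-credit for ties) with a DeLong
asymptotic confidence interval or a stratified bootstrap; Youden-index
operating thresholds; confusion-matrix metrics; multivariable logistic
models with Wald odds-ratio intervals and complete-separation detection;
Spearman rank association; the integrated discrimination improvement (IDI);
and repeated stratified k-fold cross-validation in which every model-fitting
step (probe selection, signature fit, thresholding) is re-run inside each
training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold


def _split_scores(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return s[y], s[~y]


def auc_mann_whitney(scores, labels) -> float:
    """AUC as normalized concordance: P(case > control) + 0.5 P(tie)."""
    cases, controls = _split_scores(scores, labels)
    m, n = len(cases), len(controls)
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance via midrank placements."""
    m, n = len(cases), len(controls)
    all_ranks = stats.rankdata(np.concatenate([cases, controls]))
    case_ranks = stats.rankdata(cases)
    control_ranks = stats.rankdata(controls)
    v10 = (all_ranks[:m] - case_ranks) / n            # placements of cases
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m   # placements of controls
    auc = float(v10.mean())
    if m > 1 and n > 1:
        var = float(v10.var(ddof=1) / m + v01.var(ddof=1) / n)
    else:
        var = float("nan")
    return auc, var


def roc_auc(
    scores,
    labels,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """AUC with confidence interval and a test against AUC = 0.5.

    ``ci_method`` is ``"delong"`` (asymptotic, default) or ``"bootstrap"``
    (stratified resampling of cases and controls).  CI bounds are clipped to
    [0, 1]; the p-value is the two-sided DeLong z-test against 0.5.
    """
    cases, controls = _split_scores(scores, labels)
    auc, var = _delong_variance(cases, controls)
    z = stats.norm.ppf(0.5 + level / 2.0)
    if ci_method == "delong":
        half = z * np.sqrt(var) if var == var else np.nan
        lo, hi = auc - half, auc + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bc = rng.choice(cases, size=len(cases), replace=True)
            bn = rng.choice(controls, size=len(controls), replace=True)
            boots[b], _ = _delong_variance(bc, bn)
        lo, hi = np.percentile(boots, [100 * (1 - level) / 2,
                                       100 * (1 + level) / 2])
    else:
        raise ValueError(f"unknown ci_method: {ci_method!r}")
    if var > 0:
        p = float(2.0 * stats.norm.sf(abs(auc - 0.5) / np.sqrt(var)))
    else:
        p = float("nan")
    return {
        "auc": auc,
        "ci": (float(max(0.0, min(lo, 1.0))), float(max(0.0, min(hi, 1.0)))),
        "ci_method": ci_method,
        "p_vs_chance": p,
        "variance": var,
    }


def youden_threshold(scores, labels) -> dict:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct sorted scores plus
    +/- infinity; predicted-positive means score >= threshold.  J-ties break
    toward higher specificity, then toward the larger threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate([[-np.inf], mids, [np.inf]])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    best = None
    for thr in candidates:
        pred = s >= thr
        sens = float((pred & y).sum() / n_pos)
        spec = float((~pred & ~y).sum() / n_neg)
        j = sens + spec - 1.0
        key = (j, spec, thr)
        if best is None or key > best[0]:
            best = (key, {"threshold": float(thr), "j": j,
                          "sensitivity": sens, "specificity": spec})
    return best[1]


@dataclass
class DiagnosticReport:
    """Confusion-derived diagnostics at an operating threshold, with AUC."""

    auc: float
    auc_ci: tuple
    ci_method: str
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    youden_j: float = float("nan")
    p_vs_chance: float = float("nan")

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


def diagnostic_metrics(scores, labels, threshold: float,
                       auc_result: dict | None = None) -> DiagnosticReport:
    """Classify score >= threshold as predicted-positive and derive rates."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pred = s >= threshold
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())

    def _rate(a, b):
        return float(a / b) if b > 0 else float("nan")

    if auc_result is None:
        auc_result = roc_auc(s, y)
    return DiagnosticReport(
        auc=auc_result["auc"], auc_ci=auc_result["ci"],
        ci_method=auc_result["ci_method"], threshold=float(threshold),
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_rate(tp, tp + fn), specificity=_rate(tn, tn + fp),
        ppv=_rate(tp, tp + fp), npv=_rate(tn, tn + fn),
        accuracy=_rate(tp + tn, tp + fp + tn + fn),
        youden_j=_rate(tp, tp + fn) + _rate(tn, tn + fp) - 1.0,
        p_vs_chance=auc_result.get("p_vs_chance", float("nan")),
    )


def evaluate_scores(scores, labels, ci_method: str = "delong",
                    seed: int = 0) -> DiagnosticReport:
    """ROC AUC + CI, Youden threshold and threshold metrics in one report."""
    auc_res = roc_auc(scores, labels, ci_method=ci_method, seed=seed)
    yd = youden_threshold(scores, labels)
    thr = yd["threshold"]
    if not np.isfinite(thr):
        # degenerate operating point (e.g. all scores tied): classify all
        # one way, consistent with score >= threshold
        s = np.asarray(scores, dtype=float)
        thr = s.min() if thr == -np.inf else s.max() + 1.0
    rep = diagnostic_metrics(scores, labels, thr, auc_result=auc_res)
    rep.youden_j = yd["j"]
    return rep


@dataclass
class LogisticModel:
    """Maximum-likelihood logistic fit with Wald odds-ratio intervals."""

    terms: list
    coefficients: np.ndarray
    odds_ratios: np.ndarray
    or_ci: np.ndarray              # (n_terms, 2)
    p_values: np.ndarray
    fitted_probabilities: np.ndarray
    separated: bool = False
    converged: bool = True

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coefficients,
            "odds_ratio": self.odds_ratios,
            "or_lo": self.or_ci[:, 0],
            "or_hi": self.or_ci[:, 1],
            "p": self.p_values,
        }, index=self.terms)


def fit_logistic(outcome, covariates: pd.DataFrame) -> LogisticModel:
    """Fit a multivariable logistic model with intercept.

    Raises on rank deficiency; detects complete separation (fitted
    probabilities collapsing to 0/1 or non-convergence) and flags it in the
    result instead of returning silently divergent estimates.
    """
    y = np.asarray(outcome).astype(float)
    X = pd.DataFrame(covariates).astype(float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    separated = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, design)
        try:
            res = model.fit(disp=0, maxiter=100)
        except Exception:
            res = model.fit(method="bfgs", disp=0, maxiter=500)
            separated = True
        converged = bool(getattr(res.mle_retvals, "get", lambda *_: True)("converged", True))
    probs = np.clip(res.predict(design), 1e-12, 1 - 1e-12)
    eps = 1e-8
    if ((probs[y == 1] > 1 - 1e-6).all() and (probs[y == 0] < 1e-6).all()) \
            or np.abs(res.params.to_numpy()).max() > 20:
        separated = True
    ci = res.conf_int()
    with np.errstate(over="ignore"):   # divergent Wald CI under separation
        or_ci = np.exp(ci.to_numpy())
    return LogisticModel(
        terms=list(design.columns),
        coefficients=res.params.to_numpy(),
        odds_ratios=np.exp(res.params.to_numpy()),
        or_ci=or_ci,
        p_values=res.pvalues.to_numpy(),
        fitted_probabilities=np.clip(probs, eps, 1 - eps),
        separated=separated,
        converged=converged,
    )


def spearman_assoc(x, y) -> dict:
    """Spearman rank correlation with midrank ties; p from the t
    approximation.  A constant input yields an explicitly undefined result."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": float("nan"), "p": float("nan"), "defined": False}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "defined": True}


@dataclass
class IdiResult:
    """Integrated discrimination improvement of a new risk model over an
    old one: the change in discrimination slope."""

    idi: float
    ci: tuple
    p: float
    slope_new: float
    slope_old: float


def idi(prob_new, prob_old, outcome, ci_method: str = "normal",
        n_boot: int = 2000, seed: int = 0) -> IdiResult:
    """IDI = [mean(new|events) - mean(new|non-events)]
           - [mean(old|events) - mean(old|non-events)].

    CI/p by the paired normal approximation on per-subject probability
    differences (default) or a bootstrap over subjects.
    """
    pn = np.asarray(prob_new, dtype=float)
    po = np.asarray(prob_old, dtype=float)
    y = np.asarray(outcome).astype(bool)
    if ((pn < 0) | (pn > 1) | (po < 0) | (po > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")

    def _slope(p):
        return float(p[y].mean() - p[~y].mean())

    slope_new, slope_old = _slope(pn), _slope(po)
    est = slope_new - slope_old
    d = pn - po
    ne, nn = int(y.sum()), int((~y).sum())
    se_sq = 0.0
    if ne > 1:
        se_sq += d[y].var(ddof=1) / ne
    if nn > 1:
        se_sq += d[~y].var(ddof=1) / nn
    se = float(np.sqrt(se_sq))
    if ci_method == "normal":
        if se > 0:
            z = est / se
            p = float(2.0 * stats.norm.sf(abs(z)))
            ci = (est - 1.96 * se, est + 1.96 * se)
        else:
            p = 1.0 if est == 0 else 0.0
            ci = (est, est)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx_e, idx_n = np.flatnonzero(y), np.flatnonzero(~y)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            be = rng.choice(idx_e, size=ne, replace=True)
            bn = rng.choice(idx_n, size=nn, replace=True)
            boots[b] = (pn[be].mean() - pn[bn].mean()) - (po[be].mean() - po[bn].mean())
        ci = tuple(np.percentile(boots, [2.5, 97.5]))
        p = float(2.0 * min((boots <= 0).mean(), (boots >= 0).mean()))
        p = min(1.0, max(p, 1.0 / n_boot))
    else:
        raise ValueError(f"unknown ci_method: {ci_method!r}")
    return IdiResult(idi=float(est), ci=(float(ci[0]), float(ci[1])),
                     p=p, slope_new=slope_new, slope_old=slope_old)


@dataclass
class CvResult:
    """Repetition-level metrics of repeated stratified k-fold CV."""

    per_repetition: pd.DataFrame
    k: int
    reps: int
    seed: int
    resampled_repetitions: int = 0
    summary: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(self.per_repetition["auc"].mean())

    def interval(self, metric: str = "auc") -> tuple:
        lo, hi = np.percentile(self.per_repetition[metric].dropna(), [2.5, 97.5])
        return (float(lo), float(hi))


def repeated_cv(
    X: pd.DataFrame,
    y,
    model,
    k: int = 10,
    reps: int = 1000,
    seed: int = 0,
) -> CvResult:
    """Repeated stratified k-fold cross-validation of a score-producing model.

    Per repetition: stratified random partition into ``k`` folds; the model
    (including any internal probe selection, signature fitting and
    threshold choice) is re-fit on each training set of k-1 folds; held-out
    decision scores are pooled to one AUC per repetition, and held-out class
    predictions (the model's own training-derived threshold) are pooled into
    accuracy/sensitivity/specificity/PPV/NPV.  A fold whose training set
    misses a class triggers a reshuffle of that repetition (counted).
    Summary: mean and 2.5/97.5 percentile interval across repetitions.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must be binary with both classes present")
    if len(y) < k:
        raise ValueError("need at least k samples")
    X = pd.DataFrame(X)
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(2 * reps) % (2**31 - 1)

    rows = []
    resampled = 0
    for r in range(reps):
        attempt, done = 0, False
        while not done:
            rs = int(rep_seeds[r] + attempt * 7919) % (2**31 - 1)
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
            splits = list(skf.split(X, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
                done = True
            else:
                attempt += 1
                resampled += 1
                if attempt > 50:
                    raise RuntimeError("cannot form folds with both classes")
        scores = np.empty(len(y))
        preds = np.empty(len(y), dtype=bool)
        for tr, te in splits:
            m = clone(model)
            m.fit(X.iloc[tr], y[tr])
            scores[te] = m.decision_function(X.iloc[te])
            preds[te] = np.asarray(m.predict(X.iloc[te])).astype(bool)
        auc = auc_mann_whitney(scores, y)
        yb = y.astype(bool)
        tp = int((preds & yb).sum()); fp = int((preds & ~yb).sum())
        tn = int((~preds & ~yb).sum()); fn = int((~preds & yb).sum())
        rows.append({
            "auc": auc,
            "accuracy": (tp + tn) / len(y),
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
            "ppv": tp / (tp + fp) if tp + fp else np.nan,
            "npv": tn / (tn + fn) if tn + fn else np.nan,
        })
    per_rep = pd.DataFrame(rows)
    summary = {}
    for col in per_rep.columns:
        vals = per_rep[col].dropna()
        lo, hi = np.percentile(vals, [2.5, 97.5]) if len(vals) else (np.nan, np.nan)
        summary[col] = {"mean": float(vals.mean()), "ci": (float(lo), float(hi))}
    return CvResult(per_repetition=per_rep, k=k, reps=reps, seed=seed,
                    resampled_repetitions=resampled, summary=summary)


__all__ = [
    "auc_mann_whitney", "roc_auc", "youden_threshold", "diagnostic_metrics",
    "evaluate_scores", "fit_logistic", "spearman_assoc", "idi", "repeated_cv",
    "DiagnosticReport", "LogisticModel", "IdiResult", "CvResult",
]
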