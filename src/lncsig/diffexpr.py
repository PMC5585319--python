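"""Two-group differential abundance with empirical-Bayes moderated t.

Per-probe residual variances are shrunk toward a common prior fitted by the
moment method on log s^2: with d = n1 + n2 - 2 residual df per probe, the
log variances (offset by digamma/log terms) have known mean and spread under
a scaled-F sampling model, and matching their empirical mean and variance
yields the prior df d0 and prior variance s0^2.  The moderated statistic

    t = (mean_2 - mean_1) / (s_post * sqrt(1/n1 + 1/n2)),
    s_post^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

is referred to a t distribution with d0 + d degrees of freedom.  Setting the
prior df to 0 recovers the ordinary pooled two-sample t; letting it grow
unboundedly pools all probes to the common prior variance.

Fold change convention: the summary table reports the *ratio of the group
means of log2-normalized abundance* (malignant mean / benign mean).  This
differs from the common 2^(difference) convention and is chosen because it
is the arithmetic that the panel's summary tables use (e.g. group means
7.0 and 9.3 print as fold change 1.3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator, TransformerMixin


def _trigamma(x):
    return special.polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of (d0, s0^2) from per-probe sample variances ``s2`` each
    with ``df`` degrees of freedom.  d0 may be ``inf`` (no excess spread in
    the observed log variances).  Zero variances are excluded from the fit;
    an all-zero input raises."""
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all probe variances are zero; prior fit impossible")
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = float(e.var(ddof=1)) - float(_trigamma(df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-probe moderated t, p and shared prior (d0, s0^2).

    Parameters
    ----------
    matrix
        samples x probes log2 abundance.
    labels
        Boolean/0-1 per-sample indicator; True marks group 2 (e.g.
        malignant), and the t statistic is oriented group2 - group1.
    prior_df
        ``None`` fits the prior from the data; ``0`` forces the ordinary
        pooled t; ``inf`` shrinks every variance fully to the prior.

    Returns a DataFrame indexed by probe with columns ``diff``, ``t``
    (ordinary), ``moderated_t``, ``p``, ``df_total`` and attrs ``d0``,
    ``s0_sq``.
    """
    y = np.asarray(labels).astype(bool)
    X = matrix.to_numpy(dtype=float)
    n2, n1 = int(y.sum()), int((~y).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples in each group")
    d = n1 + n2 - 2
    m1 = X[~y].mean(axis=0)
    m2 = X[y].mean(axis=0)
    diff = m2 - m1
    ss = X[~y].var(axis=0, ddof=1) * (n1 - 1) + X[y].var(axis=0, ddof=1) * (n2 - 1)
    s2 = ss / d
    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = diff / (np.sqrt(s2) * se_factor)

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, d)
    elif prior_df == 0:
        d0, s0_sq = 0.0, float("nan")
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(d)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = diff / (np.sqrt(s2_post) * se_factor)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.where(np.isnan(t_mod), 1.0, p)
    t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)

    out = pd.DataFrame(
        {"diff": diff, "t": t_ord, "moderated_t": t_mod, "p": p,
         "df_total": df_total},
        index=matrix.columns,
    )
    out.attrs["d0"] = float(d0)
    out.attrs["s0_sq"] = float(s0_sq)
    return out


def group_summary(
    matrix: pd.DataFrame,
    labels: np.ndarray,
) -> pd.DataFrame:
    """Per-probe benign/malignant/overall means (log2 units) and the
    mean-ratio fold change.  ``labels`` True marks malignant; the overall
    mean is the size-weighted pooled mean."""
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both groups must be nonempty")
    X = matrix.to_numpy(dtype=float)
    n1, n2 = int((~y).sum()), int(y.sum())
    benign = X[~y].mean(axis=0)
    malignant = X[y].mean(axis=0)
    overall = (n1 * benign + n2 * malignant) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = malignant / benign
    return pd.DataFrame(
        {"benign_mean": benign, "malignant_mean": malignant,
         "overall_mean": overall, "fold_change": fold},
        index=matrix.columns,
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a nonempty 1-D array")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DEResult:
    """Differential-abundance table plus shared shrinkage hyperparameters."""

    table: pd.DataFrame       # benign/malignant/overall means, fold, t, p, q
    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        q, p = self.table["q"].to_numpy(), self.table["p"].to_numpy()
        if (q + 1e-12 < p).any():
            raise ValueError("q must be >= p per probe")


def differential_abundance(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    prior_df: float | None = None,
) -> DEResult:
    """Full two-group analysis: group summaries, moderated t, BH FDR."""
    summary = group_summary(matrix, labels)
    tests = moderated_t(matrix, labels, prior_df=prior_df)
    table = summary.join(tests)
    table["q"] = bh_fdr(table["p"].to_numpy())
    return DEResult(table=table, d0=tests.attrs["d0"], s0_sq=tests.attrs["s0_sq"])


def select_candidates(de: DEResult, alpha: float = 0.05) -> list[str]:
    """Probes with unadjusted p < alpha (selection is on raw p; the FDR is
    reported alongside), sorted by p ascending."""
    tab = de.table[de.table["p"] < alpha].sort_values("p")
    return list(tab.index)


class ModeratedTTest(BaseEstimator, TransformerMixin):
    """Scikit-learn-style selector around the moderated-t screen.

    ``fit(X, y)`` computes the full differential-abundance table for the
    binary outcome ``y``; ``transform(X)`` keeps the columns with raw
    p < ``alpha``.

    Parameters
    ----------
    alpha : float, default 0.05
        Raw-p selection threshold.
    prior_df : float or None, default None
        Prior degrees of freedom; ``None`` fits them, ``0`` gives the
        ordinary pooled t.

    Attributes
    ----------
    results_ : DEResult
    p_values_, q_values_ : ndarray
    d0_, s0_sq_ : float
    selected_probes_ : list of str
    """

    def __init__(self, alpha: float = 0.05, prior_df: float | None = None):
        self.alpha = alpha
        self.prior_df = prior_df

    def fit(self, X: pd.DataFrame, y):
        self.results_ = differential_abundance(X, y, prior_df=self.prior_df)
        self.p_values_ = self.results_.table["p"].to_numpy()
        self.q_values_ = self.results_.table["q"].to_numpy()
        self.d0_ = self.results_.d0
        self.s0_sq_ = self.results_.s0_sq
        self.selected_probes_ = select_candidates(self.results_, self.alpha)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "selected_probes_"):
            raise ValueError("ModeratedTTest is not fitted")
        return X[self.selected_probes_]


__all__ = [
    "fit_variance_prior", "moderated_t", "group_summary", "bh_fdr",
    "differential_abundance", "select_candidates", "DEResult",
    "ModeratedTTest",
]
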