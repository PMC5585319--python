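"""First-principal-component composite risk score for a probe subset.

The risk score of a sample is the projection of its centered log2 expression
over the selected probes onto the leading eigenvector of their covariance
matrix: score = sum_i w_i (x_i - c_i) with sum_i w_i^2 = 1, where the w_i
maximize the score variance.  Probes are centered but not scaled by default
(the score is a weighted average of expression in log2 units); a
correlation-PCA mode standardizes columns first.  The eigenvector's sign is
fixed so the score correlates nonnegatively with the per-sample mean of the
selected probes — higher score means higher overall signature expression.
New samples are scored against the *training* centering offsets, making the
score a proper prospective predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class Signature:
    """Fitted PC1 risk signature."""

    probes: list[str]
    weights: np.ndarray            # unit norm
    offsets: np.ndarray            # per-probe centering, log2 units
    scale: np.ndarray | None       # per-probe SD when standardized, else None
    orientation: int               # +1/-1 sign applied to the raw eigenvector
    variance_explained: float      # leading eigenvalue / total variance
    scores: pd.Series = field(default=None)   # training scores

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if abs(float(w @ w) - 1.0) > 1e-9:
            raise ValueError("weights must have unit norm")
        if not 0.0 < self.variance_explained <= 1.0 + 1e-12:
            raise ValueError("variance_explained must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "probes": list(self.probes),
            "weights": [float(w) for w in self.weights],
            "offsets": [float(o) for o in self.offsets],
            "scale": None if self.scale is None else [float(s) for s in self.scale],
            "orientation": int(self.orientation),
            "variance_explained": float(self.variance_explained),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        return cls(
            probes=list(d["probes"]),
            weights=np.asarray(d["weights"], dtype=float),
            offsets=np.asarray(d["offsets"], dtype=float),
            scale=None if d.get("scale") is None else np.asarray(d["scale"], float),
            orientation=int(d["orientation"]),
            variance_explained=float(d["variance_explained"]),
        )


def _orient(w: np.ndarray) -> int:
    """Deterministic eigen-tie/sign helper: prefer the direction whose first
    nonzero weight is positive (lexicographically largest)."""
    for v in w:
        if v != 0.0:
            return 1 if v > 0 else -1
    return 1


def fit_pc1(
    matrix: pd.DataFrame,
    standardize: bool = False,
) -> Signature:
    """Fit the unit-norm direction maximizing score variance.

    ``matrix`` is samples x selected probes (log2).  Requires >= 2 samples,
    >= 1 probe and nonzero total variance.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 samples to fit a signature")
    if matrix.shape[1] < 1:
        raise ValueError("need >= 1 probe")
    X = matrix.to_numpy(dtype=float)
    offsets = X.mean(axis=0)
    Xc = X - offsets
    scale = None
    if standardize:
        scale = Xc.std(axis=0, ddof=1)
        if (scale == 0).any():
            raise ValueError("zero-variance probe; cannot standardize")
        Xc = Xc / scale
    cov = np.cov(Xc, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    total_var = float(np.trace(cov))
    if total_var <= 0:
        raise ValueError("zero total variance; no principal direction")
    eigvals, eigvecs = np.linalg.eigh(cov)
    lead = int(np.argmax(eigvals))
    w = eigvecs[:, lead]
    # deterministic representative under sign ambiguity / eigen-ties
    w = w * _orient(w)

    raw_scores = Xc @ w
    # orientation: nonnegative correlation with per-sample mean expression
    mean_expr = Xc.mean(axis=1)
    corr = float(raw_scores @ mean_expr)
    orientation = -1 if corr < 0 else 1
    w = w * orientation

    sig = Signature(
        probes=list(matrix.columns),
        weights=w,
        offsets=offsets,
        scale=scale,
        orientation=orientation,
        variance_explained=float(eigvals[lead]) / total_var,
    )
    sig.scores = pd.Series(Xc @ w, index=matrix.index, name="risk_score")
    return sig


def score_samples(sig: Signature, matrix: pd.DataFrame) -> pd.Series:
    """Risk score sum_i w_i (x_i - c_i) against training offsets; raises
    naming the first missing signature probe."""
    missing = [p for p in sig.probes if p not in matrix.columns]
    if missing:
        raise KeyError(f"signature probe missing from matrix: {missing[0]!r}")
    X = matrix[sig.probes].to_numpy(dtype=float) - sig.offsets
    if sig.scale is not None:
        X = X / sig.scale
    return pd.Series(X @ sig.weights, index=matrix.index, name="risk_score")


class PC1Signature(BaseEstimator, TransformerMixin):
    """Scikit-learn-style estimator for the PC1 risk score.

    Parameters
    ----------
    standardize : bool, default False
        Correlation-PCA mode: divide centered columns by their SD before
        extracting the leading direction.

    Attributes
    ----------
    signature_ : Signature
    weights_ : ndarray, unit norm
    variance_explained_ : float
    """

    def __init__(self, standardize: bool = False):
        self.standardize = standardize

    def fit(self, X: pd.DataFrame, y=None):
        self.signature_ = fit_pc1(X, standardize=self.standardize)
        self.weights_ = self.signature_.weights
        self.variance_explained_ = self.signature_.variance_explained
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "signature_"):
            raise ValueError("PC1Signature is not fitted")
        return score_samples(self.signature_, X).to_numpy()[:, None]

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return self.transform(X).ravel()


__all__ = ["Signature", "fit_pc1", "score_samples", "PC1Signature"]
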