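"""Background correction, detection filtering and housekeeping normalization.

The pipeline mirrors the standard digital-count workflow for plasma panels:

1. per-sample background cut-point = mean + 2 SD (n-1 denominator) of the
   negative-control probes; endogenous counts are background-subtracted and
   clipped at zero;
2. probes detected (raw count strictly above the per-sample cut-point) in
   fewer than 20% of samples are removed;
3. each sample is scaled so the geometric mean of the housekeeping genes
   (ACTB, PGK1, PPIB) equals the cohort reference (the arithmetic mean of the
   per-sample geometric means), then log2-transformed with a pseudocount
   of 1.

Housekeeping geometric means are computed on raw counts: the background
cut-point is an endogenous detection floor, and subtracting it from the
designated stable genes would destroy the scale they define.  Spike-in
probes are carried through and reported but never used for scaling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import CountDataset, NormalizedMatrix
from .panel import ProbePanel

DETECTION_FRACTION = 0.20


def background_cutpoints(counts: pd.DataFrame, panel: ProbePanel) -> pd.Series:
    """Per-sample negative-control cut-point: mean + 2 * sample SD."""
    negs = panel.negatives
    if len(negs) < 2:
        raise ValueError(
            f"need >= 2 negative-control probes (found {len(negs)}): "
            "the SD is undefined otherwise"
        )
    neg = counts[negs].to_numpy(dtype=float)
    return pd.Series(neg.mean(axis=1) + 2.0 * neg.std(axis=1, ddof=1),
                     index=counts.index, name="cutpoint")


def background_correct(
    dataset: CountDataset,
) -> tuple[pd.DataFrame, pd.Series]:
    """Subtract each sample's cut-point from its endogenous counts, clipping
    at zero.  Returns (corrected endogenous counts, per-sample cut-points)."""
    cut = background_cutpoints(dataset.counts, dataset.panel)
    endog = dataset.counts[dataset.panel.endogenous].astype(float)
    corrected = (endog.sub(cut, axis=0)).clip(lower=0.0)
    return corrected, cut


def filter_low_expression(
    raw_endogenous: pd.DataFrame,
    cutpoints: pd.Series,
    min_fraction: float = DETECTION_FRACTION,
) -> list[str]:
    """Probes detected (raw count strictly above the sample's cut-point) in at
    least ``min_fraction`` of samples; detection is judged on raw counts so
    the filter is independent of zero-clipping."""
    above = raw_endogenous.gt(cutpoints, axis=0)
    frac = above.mean(axis=0)
    return list(frac.index[frac >= min_fraction])


def normalize_housekeeping(
    corrected: pd.DataFrame,
    raw_counts: pd.DataFrame,
    panel: ProbePanel,
    cutpoints: pd.Series | None = None,
    retained_probes: list[str] | None = None,
) -> NormalizedMatrix:
    """Scale samples to a common housekeeping geometric mean and log2.

    ``corrected`` holds background-corrected endogenous counts; ``raw_counts``
    supplies the housekeeping columns.  Normalized value =
    ``log2(corrected * f_s + 1)`` with ``f_s = G / g_s``.
    """
    hk = panel.housekeeping
    missing = [h for h in hk if h not in raw_counts.columns]
    if missing:
        raise ValueError(f"housekeeping probes missing: {missing}")
    hk_counts = raw_counts[hk].to_numpy(dtype=float)
    bad = np.argwhere(hk_counts <= 0)
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"nonpositive housekeeping count for sample "
            f"{raw_counts.index[i]!r}, probe {hk[j]!r}"
        )
    g = np.exp(np.log(hk_counts).mean(axis=1))      # per-sample geometric mean
    reference = float(g.mean())                      # cohort arithmetic mean
    factors = pd.Series(reference / g, index=raw_counts.index,
                        name="scale_factor")

    cols = retained_probes if retained_probes is not None else list(corrected.columns)
    scaled = corrected[cols].mul(factors, axis=0)
    log2 = np.log2(scaled + 1.0)
    if cutpoints is None:
        cutpoints = pd.Series(np.nan, index=raw_counts.index, name="cutpoint")
    return NormalizedMatrix(
        data=log2,
        cutpoints=cutpoints,
        scale_factors=factors,
        reference_geomean=reference,
        retained_probes=list(cols),
    )


def normalize_dataset(dataset: CountDataset) -> NormalizedMatrix:
    """Full chain: background correction, 20% detection filter, housekeeping
    scaling, log2(x + 1)."""
    corrected, cut = background_correct(dataset)
    raw_endog = dataset.counts[dataset.panel.endogenous]
    retained = filter_low_expression(raw_endog, cut)
    return normalize_housekeeping(corrected, dataset.counts, dataset.panel,
                                  cutpoints=cut, retained_probes=retained)


class NCounterNormalizer(BaseEstimator, TransformerMixin):
    """Scikit-learn-style transformer wrapping the normalization chain.

    ``fit`` learns the detection-filtered probe list and the reference
    housekeeping geometric mean from the training cohort; ``transform``
    applies per-sample background correction and scaling to any dataset
    measured on the same panel and returns the log2 matrix (a DataFrame).

    Parameters
    ----------
    min_detection_fraction : float, default 0.20
        Minimum fraction of samples in which a probe must exceed the
        background cut-point to be retained.
    """

    def __init__(self, min_detection_fraction: float = DETECTION_FRACTION):
        self.min_detection_fraction = min_detection_fraction

    def fit(self, X: CountDataset, y=None):
        corrected, cut = background_correct(X)
        raw_endog = X.counts[X.panel.endogenous]
        self.retained_probes_ = filter_low_expression(
            raw_endog, cut, self.min_detection_fraction)
        norm = normalize_housekeeping(
            corrected, X.counts, X.panel, cutpoints=cut,
            retained_probes=self.retained_probes_)
        self.reference_geomean_ = norm.reference_geomean
        self.panel_ = X.panel
        return self

    def transform(self, X: CountDataset) -> pd.DataFrame:
        if not hasattr(self, "retained_probes_"):
            raise ValueError("NCounterNormalizer is not fitted")
        corrected, cut = background_correct(X)
        hk = X.counts[self.panel_.housekeeping].to_numpy(dtype=float)
        if (hk <= 0).any():
            raise ValueError("nonpositive housekeeping count in transform input")
        g = np.exp(np.log(hk).mean(axis=1))
        factors = self.reference_geomean_ / g
        scaled = corrected[self.retained_probes_].mul(
            pd.Series(factors, index=X.counts.index), axis=0)
        return np.log2(scaled + 1.0)


__all__ = [
    "background_cutpoints", "background_correct", "filter_low_expression",
    "normalize_housekeeping", "normalize_dataset", "NCounterNormalizer",
    "DETECTION_FRACTION",
]
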