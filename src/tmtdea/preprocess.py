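"""Completeness filtering and left-censored imputation of the ratio matrix.

Both steps follow the Perseus-style convention: proteins quantified in at
least a given fraction of samples are retained, and remaining missing values
are drawn from a per-sample Gaussian shifted into the left (low-abundance)
tail of that sample's observed distribution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .quant import RatioMatrix

logger = logging.getLogger(__name__)


class CompletenessFilter(BaseEstimator, TransformerMixin):
    """Drop proteins (features) observed in fewer than ``min_frac`` of samples.

    The boundary is inclusive: a protein finite in exactly ``min_frac`` of
    samples is retained. Operates on a samples x proteins matrix.
    """

    def __init__(self, min_frac: float = 0.70):
        self.min_frac = min_frac

    def fit(self, X, y=None):
        if not 0.0 < self.min_frac <= 1.0:
            raise ValueError("min_frac must be in (0, 1]")
        X = pd.DataFrame(X)
        frac = np.isfinite(X.to_numpy(dtype=float)).mean(axis=0)
        self.support_ = frac >= self.min_frac
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        return X.loc[:, self.support_]

    def get_support(self):
        return self.support_


class LeftCensoredImputer(BaseEstimator, TransformerMixin):
    """Impute missing values from a downshifted per-sample Gaussian.

    For each sample (row) with observed mean ``m`` and sd ``s``, missing
    entries are drawn from Normal(m - downshift*s, (width*s)^2). Defaults
    (downshift 1.8, width 0.3, in units of the sample sd) are the convention
    popularised by Perseus for left-censored label-free/TMT data. Stateless
    apart from validation; reproducible under ``random_state``.
    """

    def __init__(self, downshift: float = 1.8, width: float = 0.3,
                 random_state: int | None = None):
        self.downshift = downshift
        self.width = width
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.width <= 0:
            raise ValueError("width must be positive")
        X = pd.DataFrame(X)
        n_obs = np.isfinite(X.to_numpy(dtype=float)).sum(axis=1)
        if (n_obs < 2).any():
            bad = list(X.index[n_obs < 2])
            raise ValueError(f"samples with < 2 observed values: {bad}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        vals = X.to_numpy(dtype=float).copy()
        rng = np.random.default_rng(self.random_state)
        for i in range(vals.shape[0]):
            row = vals[i]
            miss = ~np.isfinite(row)
            if not miss.any():
                continue
            obs = row[~miss]
            m, s = obs.mean(), obs.std(ddof=1)
            row[miss] = rng.normal(m - self.downshift * s, self.width * s, miss.sum())
        return pd.DataFrame(vals, index=X.index, columns=X.columns)


def filter_completeness(matrix: RatioMatrix, min_frac: float = 0.70) -> RatioMatrix:
    """Retain proteins quantified in at least ``min_frac`` of samples."""
    f = CompletenessFilter(min_frac=min_frac).fit(matrix.X)
    kept = matrix.data.loc[f.support_]
    logger.info(
        "completeness filter (>= %.0f%%): %d -> %d proteins",
        100 * min_frac, matrix.data.shape[0], kept.shape[0],
    )
    return matrix.with_data(kept)


def impute_left_censored(
    matrix: RatioMatrix,
    downshift: float = 1.8,
    width: float = 0.3,
    seed: int | None = None,
) -> RatioMatrix:
    """Replace every missing value by a per-sample downshifted-Gaussian draw."""
    imp = LeftCensoredImputer(downshift=downshift, width=width, random_state=seed)
    Xc = imp.fit_transform(matrix.X)
    n_miss = int(matrix.data.isna().to_numpy().sum())
    logger.info("imputed %d missing values across %d proteins", n_miss, matrix.data.shape[0])
    return matrix.with_data(Xc.T)
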