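"""Inter-batch normalization methods and a quantitative batch-effect score.

Four normalizations commonly benchmarked for multi-batch TMT data are
implemented behind a common transformer interface:

* median-median — per-sample median centering alternated with per-batch block
  median centering, iterated to a fixed point;
* row-wise — per-protein median centering across samples;
* IRS (internal reference scaling) — per-protein scaling of each batch's
  linear intensities so the pooled reference channel equals its geometric
  mean across batches;
* median polish — Tukey's two-way additive fit; the fitted per-sample
  (column) effect is subtracted, leaving protein effects (biology) intact.

The batch-effect score is the mean per-protein eta-squared of a one-way
layout over batches: 0 means no batch structure, 1 means all variance is
between batches. It turns the usual boxplot-level comparison of methods into
a single ranking number.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .quant import RatioMatrix
from .simulate import REFERENCE_COL

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- median polish

@dataclass
class PolishFit:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iter: int
    converged: bool


def median_polish(values, tol: float = 1e-6, max_iter: int = 20) -> PolishFit:
    """Tukey two-way median polish of a complete rows x columns matrix.

    Alternately sweeps row medians into row effects and column medians into
    column effects until the largest sweep change is below ``tol`` or
    ``max_iter`` full sweeps are reached.
    """
    r = np.array(values, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("median polish requires a complete matrix")
    overall = 0.0
    row_eff = np.zeros(r.shape[0])
    col_eff = np.zeros(r.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        rm = np.median(r, axis=1)
        r -= rm[:, None]
        row_eff += rm
        delta = np.abs(rm).max() if rm.size else 0.0
        ce_m = np.median(col_eff)
        col_eff -= ce_m
        overall += ce_m

        cm = np.median(r, axis=0)
        r -= cm[None, :]
        col_eff += cm
        delta = max(delta, np.abs(cm).max() if cm.size else 0.0)
        re_m = np.median(row_eff)
        row_eff -= re_m
        overall += re_m
        if delta < tol:
            converged = True
            break
    return PolishFit(overall, row_eff, col_eff, r, n_iter, converged)


# ------------------------------------------------------------------ transformers

class RowwiseNormalizer(BaseEstimator, TransformerMixin):
    """Center each protein to zero median across samples (X: samples x proteins)."""

    def fit(self, X, y=None):
        self.n_features_in_ = pd.DataFrame(X).shape[1]
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        return X - X.median(axis=0)


class MedianMedianNormalizer(BaseEstimator, TransformerMixin):
    """Per-sample median centering alternated with per-batch block centering.

    A single pass of each step cannot zero both sets of medians (centering
    the batch blocks disturbs the sample medians), so the two sweeps are
    iterated to a joint fixed point; at convergence every sample median and
    every batch-block pooled median is below ``tol``.
    """

    def __init__(self, batches=None, tol: float = 1e-12, max_iter: int = 100):
        self.batches = batches
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        if self.batches is None:
            raise ValueError("batches mapping (sample -> batch) is required")
        self.n_features_in_ = pd.DataFrame(X).shape[1]
        return self

    def transform(self, X):
        X = pd.DataFrame(X).copy()
        batches = pd.Series(self.batches).loc[X.index]
        self.n_iter_ = 0
        for self.n_iter_ in range(1, self.max_iter + 1):
            col_med = X.median(axis=1)
            X = X.sub(col_med, axis=0)
            delta = col_med.abs().max()
            for _, idx in X.groupby(batches, sort=False).groups.items():
                block_med = np.median(X.loc[idx].to_numpy())
                X.loc[idx] -= block_med
                delta = max(delta, abs(block_med))
            if delta < self.tol:
                break
        return X


class MedianPolishNormalizer(BaseEstimator, TransformerMixin):
    """Subtract the median-polish per-sample effect from each sample.

    The two-way fit decomposes log2 values into overall + protein effect +
    sample effect + residual; only the sample effect (which absorbs loading
    and batch location shifts) is removed, so protein-level biology is
    retained. A final exact half-sweep recenters every sample median to zero
    (protein effects leave a small median offset per sample that the polish
    fixed point does not remove). ``sample_effects_``/``protein_effects_``
    are available after ``fit``.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 20):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        # rows of the polished matrix = proteins, columns = samples
        fit = median_polish(X.T.to_numpy(), tol=self.tol, max_iter=self.max_iter)
        if not fit.converged:
            warnings.warn(
                f"median polish did not converge in {fit.n_iter} sweeps",
                RuntimeWarning,
            )
        self.overall_ = fit.overall
        self.protein_effects_ = pd.Series(fit.row_effects, index=X.columns)
        sample_eff = pd.Series(fit.col_effects, index=X.index)
        # exact recentering half-sweep: zero the per-sample medians left by
        # the protein effects in the normalized matrix
        sample_eff = sample_eff + X.sub(sample_eff, axis=0).median(axis=1)
        self.sample_effects_ = sample_eff
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        return X.sub(self.sample_effects_.loc[X.index], axis=0)


# --------------------------------------------------------------------- functions

def normalize_rowwise(matrix: RatioMatrix) -> RatioMatrix:
    return matrix.with_data(RowwiseNormalizer().fit_transform(matrix.X).T)


def normalize_median_median(matrix: RatioMatrix, tol: float = 1e-12) -> RatioMatrix:
    t = MedianMedianNormalizer(batches=matrix.batches, tol=tol)
    return matrix.with_data(t.fit_transform(matrix.X).T)


def normalize_median_polish(
    matrix: RatioMatrix, tol: float = 1e-6, max_iter: int = 20
) -> tuple[RatioMatrix, MedianPolishNormalizer]:
    t = MedianPolishNormalizer(tol=tol, max_iter=max_iter)
    out = matrix.with_data(t.fit_transform(matrix.X).T)
    return out, t


def normalize_irs(
    tables: dict[int, pd.DataFrame], reference_label: str = REFERENCE_COL
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Internal reference scaling of per-batch linear intensity tables.

    For protein p and batch b, factor_{p,b} = geometric mean over batches of
    the reference intensities of p, divided by reference_{p,b}; all channels
    of batch b are multiplied by factor_{p,b}. Afterwards the reference values
    of each protein are equal across the batches where it was observed. A
    protein missing (or zero) its reference in a batch is left unscaled in
    that batch and flagged.

    Returns the corrected tables and a proteins x batches boolean frame of
    flags (True = left unscaled).
    """
    batches = sorted(tables)
    proteins = sorted(set().union(*(t.index for t in tables.values())))
    ref = pd.DataFrame(
        {b: tables[b][reference_label].reindex(proteins) for b in batches}
    )
    ref = ref.where(ref > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        geo = np.exp2(np.log2(ref).mean(axis=1, skipna=True))
    factors = geo.values[:, None] / ref.values
    flagged = pd.DataFrame(~np.isfinite(factors), index=proteins, columns=batches)
    if flagged.to_numpy().any():
        logger.warning(
            "IRS: %d (protein, batch) cells lack a reference value; left unscaled",
            int(flagged.to_numpy().sum()),
        )
    out = {}
    for j, b in enumerate(batches):
        f = pd.Series(factors[:, j], index=proteins).reindex(tables[b].index)
        f = f.where(np.isfinite(f), 1.0)
        out[b] = tables[b].mul(f, axis=0)
    return out, flagged


# ----------------------------------------------------------------- batch effect

def batch_effect_score(X, batches) -> float:
    """Mean over proteins of the between-batch eta-squared.

    ``X`` is samples x proteins (complete); ``batches`` maps samples to
    batches. For each protein, eta^2 = between-batch SS / total SS of the
    one-way layout over batches; proteins with zero total variance contribute
    0. Ranges from 0 (no batch effect) to 1 (pure batch effect).
    """
    X = pd.DataFrame(X)
    batches = pd.Series(batches).loc[X.index]
    if batches.nunique() < 2:
        raise ValueError("batch-effect score needs at least two batches")
    vals = X.to_numpy(dtype=float)
    grand = vals.mean(axis=0)
    sst = ((vals - grand) ** 2).sum(axis=0)
    ssb = np.zeros_like(grand)
    for _, idx in X.groupby(batches, sort=False).groups.items():
        sub = X.loc[idx].to_numpy(dtype=float)
        ssb += len(idx) * (sub.mean(axis=0) - grand) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        eta2 = np.where(sst > 0, ssb / sst, 0.0)
    return float(eta2.mean())


@dataclass
class NormalizationReport:
    """Outcome of one normalization method on one matrix."""

    method: str
    score_before: float
    score_after: float
    batch_medians_before: pd.Series
    batch_medians_after: pd.Series
    n_iter: int | None = None
    note: str = ""


def _batch_medians(matrix: RatioMatrix) -> pd.Series:
    by = matrix.X.groupby(matrix.batches, sort=True)
    return pd.Series({b: float(np.median(g.to_numpy())) for b, g in by})


def compare_normalizations(
    matrix: RatioMatrix,
    linear_tables: dict[int, pd.DataFrame] | None = None,
    cohort=None,
    tol: float = 1e-6,
    max_iter: int = 20,
) -> list[NormalizationReport]:
    """Run raw + all four methods and rank them by residual batch-effect score.

    ``linear_tables`` (the per-batch linear intensities including the
    reference channel) are needed for IRS; ``cohort`` maps their channels to
    samples. Without them the IRS entry is scored on the unscaled ratio
    matrix, which IRS leaves unchanged (ratio-to-reference already divides
    out the reference), and the report notes it.
    """
    score0 = batch_effect_score(matrix.X, matrix.batches)
    med0 = _batch_medians(matrix)
    reports = [NormalizationReport("raw", score0, score0, med0, med0)]

    mm = normalize_median_median(matrix)
    reports.append(
        NormalizationReport(
            "median-median", score0,
            batch_effect_score(mm.X, mm.batches), med0, _batch_medians(mm),
        )
    )
    rw = normalize_rowwise(matrix)
    reports.append(
        NormalizationReport(
            "row-wise", score0,
            batch_effect_score(rw.X, rw.batches), med0, _batch_medians(rw),
        )
    )
    if linear_tables is not None and cohort is not None:
        scaled, _ = normalize_irs(linear_tables)
        # score IRS on log2 absolute sample intensities (its native output)
        frames = []
        for r in cohort:
            col = scaled[r.batch_id][f"channel_{r.channel_id}"]
            frames.append(np.log2(col.where(col > 0)).rename(r.sample_id))
        irs_data = pd.concat(frames, axis=1).reindex(matrix.protein_ids).dropna(axis=0)
        irs_rm = RatioMatrix(irs_data, matrix.batches)
        reports.append(
            NormalizationReport(
                "irs", score0,
                batch_effect_score(irs_rm.X, irs_rm.batches),
                med0, _batch_medians(irs_rm),
            )
        )
    else:
        reports.append(
            NormalizationReport(
                "irs", score0, score0, med0, med0,
                note="no linear tables supplied; IRS leaves ratios unchanged",
            )
        )
    mp, t = normalize_median_polish(matrix, tol=tol, max_iter=max_iter)
    reports.append(
        NormalizationReport(
            "median-polish", score0,
            batch_effect_score(mp.X, mp.batches),
            med0, _batch_medians(mp), n_iter=t.n_iter_,
            note="" if t.converged_ else "did not converge",
        )
    )
    reports.sort(key=lambda r: r.score_after)
    return reports
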