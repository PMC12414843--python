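"""PSM filtering and rollup into a proteins x samples log2 ratio-to-reference matrix.

Reporter intensities are measured per PSM (peptide-spectrum match) in each TMT
batch. PSMs are filtered on precursor ion fraction (PIF), rolled up to protein
level as a reference-intensity-weighted mean of linear ratios to the pooled
reference channel, log2-transformed, and assembled across batches into a
single :class:`RatioMatrix` -- the central currency of the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import REFERENCE_COL, SampleRecord

logger = logging.getLogger(__name__)


@dataclass
class PsmRecord:
    """One PSM's reporter intensities across the channels of its batch."""

    psm_id: str
    protein_id: str
    batch_id: int
    intensities: np.ndarray  # linear scale, length = plex
    pif: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not 0.0 <= self.pif <= 1.0:
            raise ValueError(f"PIF must be in [0, 1], got {self.pif}")
        if (self.intensities < 0).any():
            raise ValueError("reporter intensities must be non-negative")


@dataclass
class RatioMatrix:
    """Proteins x samples log2(sample/reference) values; NaN marks missing.

    ``data`` is indexed by protein with one column per sample; ``batches``
    maps each sample to its TMT batch.
    """

    data: pd.DataFrame
    batches: pd.Series

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.batches.index)
        if missing:
            raise ValueError(f"samples without a batch assignment: {sorted(missing)}")
        self.batches = self.batches.loc[list(self.data.columns)]

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def X(self) -> pd.DataFrame:
        """Samples x proteins view (the estimator-facing orientation)."""
        return self.data.T

    def with_data(self, data: pd.DataFrame) -> "RatioMatrix":
        return RatioMatrix(data=data, batches=self.batches.loc[list(data.columns)])

    def completeness(self) -> pd.Series:
        """Fraction of finite values per protein."""
        return self.data.notna().mean(axis=1)


def filter_psms(psms: list[PsmRecord], pif_min: float = 0.75) -> list[PsmRecord]:
    """Retain PSMs with PIF strictly greater than ``pif_min``; order preserved.

    The boundary is exclusive: a PSM at exactly ``pif_min`` is removed.
    """
    if not 0.0 <= pif_min <= 1.0:
        raise ValueError("pif_min must be in [0, 1]")
    return [p for p in psms if p.pif > pif_min]


def rollup_protein_ratios(
    psms: list[PsmRecord], reference_channel: int
) -> dict[int, pd.DataFrame]:
    """Roll PSMs up to per-batch protein log2 ratios to the reference channel.

    For each protein and non-reference channel, the linear ratio is the
    weighted mean of per-PSM ratios with the PSM's reference-channel intensity
    as weight:

        ratio = sum_psm(ref_psm * s_psm/ref_psm) / sum_psm(ref_psm)
              = sum_psm(s_psm) / sum_psm(ref_psm)

    then log2-transformed. PSMs with zero reference intensity contribute
    nothing; a protein with no surviving PSM in a batch is missing there.
    ``reference_channel`` is 1-based.
    """
    sums: dict[int, dict[str, tuple[np.ndarray, float]]] = {}
    n_dropped = 0
    for p in psms:
        ref = p.intensities[reference_channel - 1]
        if ref <= 0:
            n_dropped += 1
            continue
        batch = sums.setdefault(p.batch_id, {})
        s, r = batch.get(p.protein_id, (np.zeros_like(p.intensities), 0.0))
        batch[p.protein_id] = (s + p.intensities, r + ref)
    if n_dropped:
        logger.info("rollup: dropped %d PSMs with zero reference intensity", n_dropped)
    tables = {}
    for b, by_prot in sums.items():
        plex = len(next(iter(by_prot.values()))[0])
        cols = [f"channel_{c}" for c in range(1, plex + 1) if c != reference_channel]
        rows = {}
        for prot, (s, r) in by_prot.items():
            ratios = np.delete(s, reference_channel - 1) / r
            with np.errstate(divide="ignore"):
                logr = np.log2(ratios)
            logr[np.isneginf(logr)] = np.nan  # zero-intensity channel: not quantified
            rows[prot] = logr
        tables[b] = pd.DataFrame.from_dict(rows, orient="index", columns=cols).sort_index()
    return tables


def batch_table_to_ratios(
    table: pd.DataFrame, reference_label: str = REFERENCE_COL
) -> pd.DataFrame:
    """Protein-level linear intensity table -> per-channel log2 ratio to reference.

    Accepts the generator's per-batch tables directly, bypassing PSM rollup for
    protein-level simulations. Channels where the reference is missing or zero
    become missing.
    """
    if reference_label not in table.columns:
        raise ValueError(f"reference column {reference_label!r} not in table")
    ref = table[reference_label].where(table[reference_label] > 0)
    samples = table.drop(columns=[reference_label])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(samples.div(ref, axis=0))
    return ratios.replace(-np.inf, np.nan)


def assemble_ratio_matrix(
    per_batch: dict[int, pd.DataFrame], cohort: list[SampleRecord]
) -> RatioMatrix:
    """Assemble per-batch ratio tables into one proteins x samples matrix.

    Proteins are the union over batches (sorted); a value is missing where a
    protein was not quantified in a sample's batch. Column order follows the
    cohort. Duplicate (batch, channel) claims raise.
    """
    if not per_batch:
        raise ValueError("no batch tables supplied")
    seen: dict[tuple[int, int], str] = {}
    for r in cohort:
        key = (r.batch_id, r.channel_id)
        if key in seen:
            raise ValueError(
                f"duplicate (batch, channel) {key}: {seen[key]} and {r.sample_id}"
            )
        seen[key] = r.sample_id
    proteins = sorted(set().union(*(t.index for t in per_batch.values())))
    cols = {}
    batches = {}
    for r in cohort:
        table = per_batch.get(r.batch_id)
        col = f"channel_{r.channel_id}"
        if table is None or col not in table.columns:
            cols[r.sample_id] = pd.Series(np.nan, index=proteins)
        else:
            cols[r.sample_id] = table[col].reindex(proteins)
        batches[r.sample_id] = r.batch_id
    data = pd.DataFrame(cols, index=proteins)
    return RatioMatrix(data=data, batches=pd.Series(batches))


def quantify_batches(
    tables: dict[int, pd.DataFrame],
    cohort: list[SampleRecord],
    reference_label: str = REFERENCE_COL,
) -> RatioMatrix:
    """Protein-level tables for all batches -> assembled :class:`RatioMatrix`."""
    ratios = {b: batch_table_to_ratios(t, reference_label) for b, t in tables.items()}
    return assemble_ratio_matrix(ratios, cohort)
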