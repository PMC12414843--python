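"""Synthetic cohorts, TMT batch designs, reporter-intensity data and linked survival data.

The generators emulate a multi-batch isobaric-labelling study of breast-cancer
core biopsies: 60 tumours in 12 TMT 6-plex batches, each batch carrying five
unique samples plus a pooled "supermix" reference channel; four IHC subtypes
(HR/HER2 combinations) with unbalanced group sizes; subtype-specific log2
effects for a subset of truly differential proteins; additive per-batch shifts;
left-censored (intensity-dependent) missingness; and exponential survival times
whose hazard depends on a gene-signature score.

Everything is seeded; a single global seed can be expanded into per-stage
substreams with :func:`spawn_seeds` so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

#: IHC subtype labels, in the order the clinical summary table lists them.
SUBTYPES = ("HR+/HER2-", "HR+/HER2+", "HR-/HER2-", "HR-/HER2+")

#: Default subtype proportions: 29/15/7/9 of 60 (the study cohort).
DEFAULT_SUBTYPE_COUNTS = (29, 15, 7, 9)
DEFAULT_SUBTYPE_PROBS = tuple(c / 60 for c in DEFAULT_SUBTYPE_COUNTS)

#: Default per-subtype log2 effect for differential proteins, keyed by subtype,
#: patterned on the THBS1-like profile: one subtype depressed by ~1 log2 unit,
#: the others near zero.
DEFAULT_EFFECT_PATTERN = {
    "HR+/HER2-": 0.05,
    "HR+/HER2+": 0.30,
    "HR-/HER2-": 0.33,
    "HR-/HER2+": -1.06,
}

REFERENCE_COL = "supermix"


def subtype_of(hr_positive: bool, her2_positive: bool) -> str:
    """IHC subtype as a pure function of HR and HER2 status."""
    return f"HR{'+' if hr_positive else '-'}/HER2{'+' if her2_positive else '-'}"


@dataclass
class SampleRecord:
    """One tumour sample with clinical status and (optional) TMT placement."""

    sample_id: str
    hr_status: bool
    her2_status: bool
    subtype: str
    batch_id: int | None = None
    channel_id: int | None = None

    def __post_init__(self) -> None:
        if self.subtype != subtype_of(self.hr_status, self.her2_status):
            raise ValueError(
                f"subtype {self.subtype!r} inconsistent with "
                f"HR={self.hr_status}, HER2={self.her2_status}"
            )


@dataclass(frozen=True)
class BatchDesign:
    """Layout of a multi-batch TMT experiment with one reference channel per batch."""

    n_batches: int
    plex: int = 6
    samples_per_batch: int = 5
    reference_label: str = REFERENCE_COL

    def __post_init__(self) -> None:
        if self.samples_per_batch != self.plex - 1:
            raise ValueError("samples_per_batch must equal plex - 1")

    @property
    def reference_channel(self) -> int:
        """The channel index reserved for the pooled reference (last channel)."""
        return self.plex

    @property
    def n_samples(self) -> int:
        return self.n_batches * self.samples_per_batch


@dataclass
class GroundTruth:
    """True generative parameters behind a simulated proteome.

    ``baseline`` is the per-protein true log2 abundance; ``effects`` holds the
    per-(protein, subtype) log2 delta (all-zero rows for non-differential
    proteins); ``batch_shift`` the additive per-batch log2 shift applied to
    sample channels; ``sigma`` the measurement noise sd.
    """

    baseline: pd.Series
    effects: pd.DataFrame
    batch_shift: pd.Series
    sigma: float
    ref_sigma: float = 0.15
    de_proteins: list[str] = field(default_factory=list)

    def reference_log2(self) -> pd.Series:
        """True reference-channel value: log2 of the linear-scale mean over samples.

        Requires sample weights implicitly equal (equal peptide amounts pooled),
        so it is computed from the subtype composition stored on ``effects.attrs``.
        """
        counts = self.effects.attrs["subtype_counts"]
        n = sum(counts.values())
        linear = np.zeros(len(self.baseline))
        for st, c in counts.items():
            linear += c * np.exp2(self.baseline.values + self.effects[st].values)
        return pd.Series(np.log2(linear / n), index=self.baseline.index)


@dataclass(frozen=True)
class SurvivalParams:
    """Exponential proportional-hazards generator parameters.

    ``baseline_hazard`` and ``censor_rate`` are per unit time (months by
    convention); ``coef`` is the log-hazard slope per unit of centered
    signature score; ``max_time`` the administrative follow-up cutoff.
    """

    baseline_hazard: float = 0.02
    coef: float = 0.8
    censor_rate: float = 0.01
    max_time: float = 120.0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0 or self.max_time <= 0:
            raise ValueError("baseline_hazard and max_time must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Expand one global seed into ``n`` independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def generate_cohort(
    n: int,
    subtype_probs: tuple[float, float, float, float] | None = None,
    seed: int | None = None,
    exact_counts: bool = False,
) -> list[SampleRecord]:
    """Draw ``n`` samples with IHC subtypes.

    With ``exact_counts`` the subtype counts are fixed to the largest-remainder
    apportionment of ``n * subtype_probs`` (for n=60 and the default
    proportions: 29, 15, 7, 9); otherwise assignment is multinomial. Sample
    order is randomly permuted either way.
    """
    if n < 4:
        raise ValueError("need n >= 4 samples (at least one per subtype slot)")
    probs = np.asarray(
        DEFAULT_SUBTYPE_PROBS if subtype_probs is None else subtype_probs, dtype=float
    )
    if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("subtype_probs must be 4 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    if exact_counts:
        raw = n * probs
        counts = np.floor(raw).astype(int)
        remainder = raw - counts
        for i in np.argsort(-remainder)[: n - counts.sum()]:
            counts[i] += 1
    else:
        counts = rng.multinomial(n, probs)
    labels = np.repeat(np.arange(4), counts)
    rng.shuffle(labels)
    records = []
    for i, lab in enumerate(labels, start=1):
        st = SUBTYPES[lab]
        records.append(
            SampleRecord(
                sample_id=f"SA{i:03d}",
                hr_status=st.startswith("HR+"),
                her2_status="HER2+" in st,
                subtype=st,
            )
        )
    return records


def assign_batches(
    samples: list[SampleRecord],
    plex: int = 6,
    seed: int | None = None,
) -> tuple[BatchDesign, list[SampleRecord]]:
    """Randomly place samples into TMT batches of ``plex - 1`` plus a reference.

    Sample channels are 1..plex-1; channel ``plex`` is reserved for the pooled
    reference in every batch. Raises if the cohort does not fill whole batches.
    """
    per_batch = plex - 1
    if len(samples) % per_batch != 0:
        raise ValueError(
            f"{len(samples)} samples cannot fill whole {plex}-plex batches "
            f"({per_batch} unique samples each)"
        )
    n_batches = len(samples) // per_batch
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    placed = []
    for pos, idx in enumerate(order):
        placed.append(
            replace(
                samples[idx],
                batch_id=pos // per_batch + 1,
                channel_id=pos % per_batch + 1,
            )
        )
    placed.sort(key=lambda r: r.sample_id)
    return BatchDesign(n_batches=n_batches, plex=plex, samples_per_batch=per_batch), placed


def generate_proteome(
    design: BatchDesign,
    cohort: list[SampleRecord],
    n_proteins: int = 1000,
    n_de: int = 50,
    effect_pattern: dict[str, float] | None = None,
    batch_sd: float = 0.5,
    sigma: float = 0.5,
    ref_sigma: float = 0.15,
    seed: int | None = None,
    baseline_mean: float = 20.0,
    baseline_sd: float = 2.0,
) -> tuple[dict[int, pd.DataFrame], GroundTruth]:
    """Simulate linear-scale reporter intensities for every batch.

    Per sample channel: log2 intensity = baseline + subtype delta + batch shift
    + Normal(0, sigma), where ``sigma`` combines biological and technical
    variation. The reference channel of each batch is the linear-scale mean of
    all samples' true abundances (the pooled supermix) plus independent
    Normal(0, ref_sigma) noise: the pool carries no between-tumour biological
    variance and its protein-level value averages many PSMs, so only a small
    technical component remains (default 0.15 log2 units, ~10% CV). The batch
    shift is a channel-specific artefact and is not applied to the reference.

    Returns ``{batch_id: DataFrame}`` with protein rows and columns
    ``channel_1..channel_{plex-1}`` plus ``supermix``, and the ground truth.
    """
    if n_de > n_proteins:
        raise ValueError("n_de cannot exceed n_proteins")
    if sigma < 0 or batch_sd < 0 or ref_sigma < 0:
        raise ValueError("sigma, ref_sigma and batch_sd must be non-negative")
    if len(cohort) != design.n_samples:
        raise ValueError("cohort size does not match design")
    pattern = dict(DEFAULT_EFFECT_PATTERN if effect_pattern is None else effect_pattern)
    rng = np.random.default_rng(seed)

    proteins = [f"P{i:05d}" for i in range(1, n_proteins + 1)]
    baseline = pd.Series(
        rng.normal(baseline_mean, baseline_sd, n_proteins), index=proteins
    )
    effects = pd.DataFrame(0.0, index=proteins, columns=list(SUBTYPES))
    de_proteins = list(rng.choice(proteins, size=n_de, replace=False))
    for st in SUBTYPES:
        effects.loc[de_proteins, st] = pattern[st]
    counts: dict[str, int] = {st: 0 for st in SUBTYPES}
    for r in cohort:
        counts[r.subtype] += 1
    effects.attrs["subtype_counts"] = counts
    batch_shift = pd.Series(
        rng.normal(0.0, batch_sd, design.n_batches),
        index=range(1, design.n_batches + 1),
    )
    truth = GroundTruth(baseline, effects, batch_shift, sigma,
                        ref_sigma=ref_sigma, de_proteins=de_proteins)

    ref_log2 = truth.reference_log2().values
    tables: dict[int, pd.DataFrame] = {}
    by_batch: dict[int, list[SampleRecord]] = {}
    for r in cohort:
        by_batch.setdefault(r.batch_id, []).append(r)
    for b in range(1, design.n_batches + 1):
        cols = {}
        for r in sorted(by_batch[b], key=lambda r: r.channel_id):
            log2v = (
                baseline.values
                + effects[r.subtype].values
                + batch_shift[b]
                + rng.normal(0.0, sigma, n_proteins)
            )
            cols[f"channel_{r.channel_id}"] = np.exp2(log2v)
        cols[design.reference_label] = np.exp2(
            ref_log2 + rng.normal(0.0, ref_sigma, n_proteins)
        )
        tables[b] = pd.DataFrame(cols, index=proteins)
    return tables, truth


def apply_missingness(
    tables: dict[int, pd.DataFrame],
    censor_midpoint: float = 17.0,
    censor_steepness: float = 0.8,
    seed: int | None = None,
    reference_label: str = REFERENCE_COL,
) -> dict[int, pd.DataFrame]:
    """Left-censor intensities: P(missing) = logistic((midpoint - log2 I) * steepness).

    Reference channels are never censored (the pooled supermix is abundant by
    construction). Returns new tables with missing entries as NaN.
    """
    if censor_steepness <= 0:
        raise ValueError("censor_steepness must be positive")
    rng = np.random.default_rng(seed)
    out = {}
    for b in sorted(tables):
        t = tables[b].copy()
        sample_cols = [c for c in t.columns if c != reference_label]
        vals = t[sample_cols].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            p_miss = expit((censor_midpoint - np.log2(vals)) * censor_steepness)
        mask = rng.random(vals.shape) < p_miss
        vals[mask] = np.nan
        t[sample_cols] = vals
        out[b] = t
    return out


def generate_survival(
    scores: pd.Series,
    params: SurvivalParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Exponential survival times with hazard baseline * exp(coef * centered score).

    Censoring is the minimum of an independent exponential (rate
    ``censor_rate``; none if 0) and the administrative cutoff ``max_time``.
    Returns a table with columns sample_id, time, event, score.
    """
    params = params or SurvivalParams()
    rng = np.random.default_rng(seed)
    centered = scores - scores.mean()
    hazard = params.baseline_hazard * np.exp(params.coef * centered.values)
    t_event = rng.exponential(1.0 / hazard)
    if params.censor_rate > 0:
        t_cens = rng.exponential(1.0 / params.censor_rate, len(scores))
    else:
        t_cens = np.full(len(scores), np.inf)
    t_cens = np.minimum(t_cens, params.max_time)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "sample_id": scores.index,
            "time": time,
            "event": event,
            "score": scores.values,
        }
    ).set_index("sample_id")


def generate_expression(
    n_samples: int,
    signature_genes: list[str],
    n_background: int = 20,
    latent_loading: float = 1.0,
    noise_sd: float = 0.3,
    seed: int | None = None,
) -> pd.DataFrame:
    """RSEM-like linear expression (genes x samples) with a shared latent factor.

    Signature genes co-vary through a per-sample Normal(0,1) latent factor
    scaled by ``latent_loading`` (emulating co-expression of an ECM programme);
    background genes are independent. Values are non-negative linear-scale
    estimates suitable for a log2(x+1) transform.
    """
    rng = np.random.default_rng(seed)
    samples = [f"PT{i:04d}" for i in range(1, n_samples + 1)]
    latent = rng.normal(0.0, 1.0, n_samples)
    rows = {}
    for g in signature_genes:
        mu = rng.uniform(4.0, 8.0)
        log2v = mu + latent_loading * latent + rng.normal(0.0, noise_sd, n_samples)
        rows[g] = np.exp2(log2v) - 1.0
    for i in range(1, n_background + 1):
        mu = rng.uniform(2.0, 8.0)
        log2v = mu + rng.normal(0.0, 1.0, n_samples)
        rows[f"BG{i:03d}"] = np.exp2(log2v) - 1.0
    expr = pd.DataFrame(rows, index=samples).T.clip(lower=0.0)
    expr.columns.name = "sample_id"
    return expr


def generate_ppi_edges(
    nodes: list[str],
    cluster_nodes: list[str],
    seed: int | None = None,
    cluster_score_range: tuple[int, int] = (880, 980),
    background_p: float = 0.15,
    background_score_range: tuple[int, int] = (150, 650),
) -> pd.DataFrame:
    """Synthetic STRING-style edge list: a high-score clique plus background edges.

    ``cluster_nodes`` form a complete clique with scores in
    ``cluster_score_range``; other node pairs get an edge with probability
    ``background_p`` and a score in ``background_score_range``. Edges between
    the cluster and the rest are kept below 400 so confidence-0.4 filtering
    isolates the clique.
    """
    rng = np.random.default_rng(seed)
    cluster = set(cluster_nodes)
    rows = []
    nodes = list(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if a in cluster and b in cluster:
                rows.append((a, b, int(rng.integers(*cluster_score_range))))
            elif rng.random() < background_p:
                score = int(rng.integers(*background_score_range))
                if (a in cluster) != (b in cluster):
                    score = min(score, 399)
                rows.append((a, b, score))
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
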