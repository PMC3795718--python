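"""Condition-specific feature selectors.

The centrepiece is the relative signal-to-noise ratio (rSNR).  For a target
experimental condition k, the training data are split into

* a **positive set** — the training samples of k itself, and
* a **negative set** — the training conditions whose factor sets are
  disjoint from k's (conditions sharing any factor with k are excluded
  from the calculation altogether).

Per gene g,

    SNR_pos = |mu_pos| / sigma_pos      over the pooled positive values,
    SNR_neg = |mu_neg| / sigma_neg      over per-condition mean expression
                                        across the negative conditions,
    rSNR    = SNR_pos / SNR_neg = CV_neg / CV_pos,

where CV = sigma / |mu| is the coefficient of variation.  Genes with low
variation within the condition of interest but high variation across
unrelated conditions score high.  Standard deviations use the sample
(n - 1) denominator throughout.

Baselines: the two-class signal-to-noise statistic
SNR_c = |mu1 - mu2| / (sigma1 + sigma2), Welch's t statistic
|mu1 - mu2| / sqrt(sigma1^2/n1 + sigma2^2/n2), uniform random selection,
and interaction-based (STRING-style) gene/link selection by confidence
cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import ConsistencyError, UndefinedScoreError
from .profiles import InteractionSet

__all__ = [
    "PositiveNegativeSplit",
    "GeneRanking",
    "build_split",
    "rsnr_scores",
    "rsnr_ranking",
    "snr_c_scores",
    "welch_t_scores",
    "random_selection",
    "string_gene_selection",
    "string_link_selection",
    "select_top",
    "select_section",
]

SNR_COMPONENT_COLUMNS = ("mu_pos", "sigma_pos", "mu_neg", "sigma_neg",
                         "snr_pos", "snr_neg", "rsnr")


@dataclass(frozen=True)
class PositiveNegativeSplit:
    """Training-data split underlying one condition's rSNR calculation."""

    target_condition: str
    positive_samples: tuple
    negative_conditions: tuple
    excluded_conditions: tuple
    negative_samples: dict = field(hash=False)


@dataclass
class GeneRanking:
    """Genes ordered by descending score; ties broken by gene id."""

    condition_id: str
    method: str
    genes: list
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ConsistencyError("ranking genes and scores differ in length")

    @classmethod
    def from_scores(cls, condition_id: str, method: str, gene_ids: Sequence,
                    scores: np.ndarray) -> "GeneRanking":
        scores = np.asarray(scores, dtype=float)
        gene_arr = np.asarray([str(g) for g in gene_ids], dtype=object)
        # descending score, gene-id lexicographic tie-break; -score sorts
        # +inf sentinels first
        order = np.lexsort((gene_arr, -scores))
        return cls(condition_id, method, [str(g) for g in gene_arr[order]],
                   scores[order])

    def __len__(self) -> int:
        return len(self.genes)

    def top(self, n: int) -> list:
        return select_top(self, n)

    def section(self, start_rank: int, n: int) -> list:
        return select_section(self, start_rank, n)


def build_split(ds: ExpressionDataset, training_samples: Sequence | None,
                target_condition: str) -> PositiveNegativeSplit:
    """Split the training data into positive/negative sets for one condition.

    The negative set contains every training condition whose factor set is
    disjoint from the target's; conditions sharing at least one factor are
    excluded from the rSNR calculation.  An empty negative set makes the
    rSNR undefined and raises :class:`UndefinedScoreError`.
    """
    if target_condition not in ds.conditions:
        raise ConsistencyError(f"unknown condition {target_condition!r}")
    tab = ds.samples if training_samples is None else ds.samples.loc[list(training_samples)]
    present = sorted(tab["condition_id"].unique())
    if target_condition not in present:
        raise ConsistencyError(
            f"condition {target_condition!r} has no samples in the training data"
        )
    target_factors = ds.conditions[target_condition].factors
    positive = tuple(tab.index[tab["condition_id"] == target_condition])
    negative, excluded = [], []
    for cid in present:
        if cid == target_condition:
            continue
        if ds.conditions[cid].factors & target_factors:
            excluded.append(cid)
        else:
            negative.append(cid)
    if not negative:
        raise UndefinedScoreError(
            f"rSNR undefined for condition {target_condition!r}: every other "
            "training condition shares an experimental factor with it, so the "
            "negative set is empty. Add conditions with disjoint factors."
        )
    neg_samples = {cid: tuple(tab.index[tab["condition_id"] == cid]) for cid in negative}
    return PositiveNegativeSplit(target_condition, positive, tuple(negative),
                                 tuple(excluded), neg_samples)


def _row_std(mat: np.ndarray) -> np.ndarray:
    """Sample standard deviation per row; exactly 0 for constant rows (axis-wise
    np.std can return ~1e-15 on constant input, which would defeat the
    documented zero-sigma sentinels)."""
    sd = mat.std(axis=1, ddof=1)
    constant = (mat == mat[:, :1]).all(axis=1)
    sd[constant] = 0.0
    return sd


def _pos_stats_pooled(ds, split):
    mat = ds.matrix(split.positive_samples)
    if mat.shape[1] < 2:
        raise ConsistencyError("positive set needs at least 2 values per gene")
    return mat.mean(axis=1), _row_std(mat)


def _pos_stats_per_timepoint(ds, split):
    tab = ds.samples.loc[list(split.positive_samples)]
    mus, sigmas = [], []
    for t in sorted(tab["time_point"].unique()):
        ids = list(tab.index[tab["time_point"] == t])
        if len(ids) < 2:
            raise ConsistencyError(
                "per-time-point aggregation needs >= 2 replicates at every "
                f"positive-set time point (time {t} has {len(ids)})"
            )
        m = ds.matrix(ids)
        mus.append(m.mean(axis=1))
        sigmas.append(_row_std(m))
    return np.mean(mus, axis=0), np.mean(sigmas, axis=0)


def _neg_stats_per_condition(ds, split):
    cond_means = [ds.matrix(ids).mean(axis=1) for ids in split.negative_samples.values()]
    if len(cond_means) < 2:
        raise ConsistencyError("negative set needs at least 2 conditions")
    stack = np.vstack(cond_means).T
    return stack.mean(axis=1), _row_std(stack)


def _neg_stats_per_timepoint(ds, split):
    ids = [s for v in split.negative_samples.values() for s in v]
    tab = ds.samples.loc[ids]
    tp_means = []
    for t in sorted(tab["time_point"].unique()):
        tids = list(tab.index[tab["time_point"] == t])
        tp_means.append(ds.matrix(tids).mean(axis=1))
    if len(tp_means) < 2:
        raise ConsistencyError("negative set needs >= 2 time points for "
                               "per-time-point aggregation")
    stack = np.vstack(tp_means).T
    return stack.mean(axis=1), _row_std(stack)


def rsnr_scores(ds: ExpressionDataset, split: PositiveNegativeSplit,
                aggregation: str = "pooled") -> pd.DataFrame:
    """Per-gene rSNR components for one condition's positive/negative split.

    Returns a DataFrame indexed by gene with columns ``mu_pos, sigma_pos,
    mu_neg, sigma_neg, snr_pos, snr_neg, rsnr``.

    ``aggregation='pooled'`` (default) pools all positive-set values per gene
    and aggregates the negative set over per-condition means.
    ``aggregation='per_timepoint'`` instead computes positive mean/sd per
    time point (averaged over time points) and negative per-time-point means.

    Degenerate cases are deterministic, never NaN: sigma_pos = 0 with
    cross-condition variation present gives +inf (ranked above all finite
    scores); sigma_neg = 0 gives 0 (no variation across conditions, gene
    uninformative); mu_pos = mu_neg = 0 gives 0 with a warning.
    """
    if aggregation == "pooled":
        mu_pos, sigma_pos = _pos_stats_pooled(ds, split)
        mu_neg, sigma_neg = _neg_stats_per_condition(ds, split)
    elif aggregation == "per_timepoint":
        mu_pos, sigma_pos = _pos_stats_per_timepoint(ds, split)
        mu_neg, sigma_neg = _neg_stats_per_timepoint(ds, split)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        snr_pos = np.abs(mu_pos) / sigma_pos
        snr_neg = np.abs(mu_neg) / sigma_neg
        rsnr = snr_pos / snr_neg

    # sigma_pos == 0 -> snr_pos = inf; sigma_neg == 0 -> snr_neg = inf -> 0
    rsnr = np.where(sigma_neg == 0, 0.0, rsnr)
    # mu_neg == 0 (snr_neg == 0): quotient is +inf unless mu_pos == 0 too
    both_zero_mu = (snr_neg == 0) & (snr_pos == 0) & (sigma_neg > 0)
    if both_zero_mu.any():
        warnings.warn(f"{int(both_zero_mu.sum())} gene(s) with zero mean in both "
                      "positive and negative sets scored 0")
    rsnr = np.where(both_zero_mu, 0.0, rsnr)
    rsnr = np.where((snr_neg == 0) & (snr_pos > 0) & (sigma_neg > 0), np.inf, rsnr)
    rsnr = np.nan_to_num(rsnr, nan=0.0, posinf=np.inf)

    return pd.DataFrame(
        {"mu_pos": mu_pos, "sigma_pos": sigma_pos, "mu_neg": mu_neg,
         "sigma_neg": sigma_neg, "snr_pos": snr_pos, "snr_neg": snr_neg,
         "rsnr": rsnr},
        index=pd.Index(ds.genes, name="gene_id"),
    )


def rsnr_ranking(ds: ExpressionDataset, target_condition: str,
                 training_samples: Sequence | None = None,
                 aggregation: str = "pooled") -> GeneRanking:
    """Convenience wrapper: split, score and rank in one call."""
    split = build_split(ds, training_samples, target_condition)
    comp = rsnr_scores(ds, split, aggregation=aggregation)
    return GeneRanking.from_scores(target_condition, "rsnr",
                                   list(comp.index), comp["rsnr"].to_numpy())


def _two_class_stats(ds, class1_samples, class2_samples):
    m1 = ds.matrix(list(class1_samples))
    m2 = ds.matrix(list(class2_samples))
    if m1.shape[1] < 2 or m2.shape[1] < 2:
        raise ConsistencyError("both classes need at least 2 samples")
    return (m1.mean(axis=1), _row_std(m1), m1.shape[1],
            m2.mean(axis=1), _row_std(m2), m2.shape[1])


def snr_c_scores(ds: ExpressionDataset, class1_samples: Sequence,
                 class2_samples: Sequence, condition_id: str = "global") -> GeneRanking:
    """Two-class signal-to-noise ranking, |mu1 - mu2| / (sigma1 + sigma2).

    Genes with identical class means score 0; a zero denominator with
    distinct means yields +inf, ranked above all finite scores.
    """
    mu1, s1, _, mu2, s2, _ = _two_class_stats(ds, class1_samples, class2_samples)
    num = np.abs(mu1 - mu2)
    denom = s1 + s2
    with np.errstate(divide="ignore", invalid="ignore"):
        score = num / denom
    score = np.where(denom == 0, np.where(num == 0, 0.0, np.inf), score)
    return GeneRanking.from_scores(condition_id, "snr_c", ds.genes, score)


def welch_t_scores(ds: ExpressionDataset, class1_samples: Sequence,
                   class2_samples: Sequence, condition_id: str = "global") -> GeneRanking:
    """Welch's unequal-variance t statistic (absolute value) as a ranking score."""
    mu1, s1, n1, mu2, s2, n2 = _two_class_stats(ds, class1_samples, class2_samples)
    num = np.abs(mu1 - mu2)
    denom = np.sqrt(s1 ** 2 / n1 + s2 ** 2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = num / denom
    score = np.where(denom == 0, np.where(num == 0, 0.0, np.inf), score)
    return GeneRanking.from_scores(condition_id, "welch_t", ds.genes, score)


def random_selection(genes: Sequence, n: int, seed) -> GeneRanking:
    """Uniform random control: n genes sampled without replacement.

    ``seed`` may be an int or a numpy Generator.  Scores are the arbitrary
    descending sequence n..1 so the result slots into ranking-based code.
    """
    genes = [str(g) for g in genes]
    if not 0 < n <= len(genes):
        raise ValueError(f"cannot sample {n} genes from {len(genes)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picked = list(rng.choice(np.asarray(genes, dtype=object), size=n, replace=False))
    return GeneRanking("global", "random", picked,
                       np.arange(n, 0, -1, dtype=float))


def string_gene_selection(genes: Sequence, links: InteractionSet, cutoff: int) -> list:
    """Genes on the array with at least one link above ``cutoff`` to another
    gene on the array ("linked genes dataset")."""
    if not 0 <= cutoff <= 1000:
        raise ValueError(f"cutoff {cutoff} outside [0, 1000]")
    kept_links = links.above(cutoff).restrict_to(genes)
    selected = sorted(kept_links.genes())
    if not selected:
        raise UndefinedScoreError(
            f"no gene has an interaction above cutoff {cutoff} within the array"
        )
    return selected


def string_link_selection(genes: Sequence, links: InteractionSet, cutoff: int) -> InteractionSet:
    """Links above ``cutoff`` between genes on the array ("link dataset").

    By construction its gene set equals :func:`string_gene_selection`'s at
    the same cutoff.
    """
    if not 0 <= cutoff <= 1000:
        raise ValueError(f"cutoff {cutoff} outside [0, 1000]")
    kept = links.above(cutoff).restrict_to(genes)
    if len(kept) == 0:
        raise UndefinedScoreError(
            f"no interaction above cutoff {cutoff} within the array"
        )
    return kept


def select_top(ranking: GeneRanking, n: int) -> list:
    """Top-n genes of a descending ranking."""
    return select_section(ranking, 1, n)


def select_section(ranking: GeneRanking, start_rank: int, n: int) -> list:
    """The n genes starting at 1-based ``start_rank`` of a descending ranking."""
    if n < 1:
        raise ValueError("section size must be >= 1")
    if start_rank < 1 or start_rank + n - 1 > len(ranking):
        raise ValueError(
            f"section [{start_rank}, {start_rank + n - 1}] outside ranking "
            f"of length {len(ranking)}"
        )
    return ranking.genes[start_rank - 1:start_rank - 1 + n]
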