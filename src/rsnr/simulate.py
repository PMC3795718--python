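"""Synthetic multi-condition expression time courses with planted markers.

The generator emulates the structure the rSNR method assumes: a factorial
design of experimental conditions (each condition a unique combination of
factor levels), an ordered time grid with replication, and a minority of
*planted* condition-specific genes.  A gene planted for condition k is

* tightly regulated within k — elevated mean, small within-condition
  standard deviation (low intrinsic coefficient of variation), and
* dispersed across the other conditions — each other condition receives
  its own mean shift drawn from a wide distribution (high extrinsic
  variation).

Background genes are i.i.d. Gaussian noise around a per-gene baseline and
carry no condition information.  Values live on an additive, log-like
scale.  The default effect sizes put the data in the regime the method is
meant for: the pooled within-condition variation of non-specific genes
(``noise_sd``, absorbing temporal dynamics and replicate noise) exceeds
the across-condition mean spread, so profile correlations over all genes
are noise-dominated and condition-specific selection is what makes the
markers count.  Presets mirror the shapes of the three study designs the
method targets: an 18-condition two-factor stress/tissue time course, a
6-condition toxicology course with ragged replication, and a 3-condition
static normal/diseased collection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import ConsistencyError
from .profiles import InteractionSet

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate",
    "generate_interactions",
    "permute_condition_labels",
    "default_config",
    "atgenexpress_config",
    "edge_config",
    "engreitz_config",
]

_AXIS_NAMES = ("trt", "tis", "dose", "ax4", "ax5")


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape and effect sizes of a synthetic dataset.

    ``factor_levels`` lists the number of levels per factor axis, e.g.
    ``(6,)`` for six single-factor conditions or ``(9, 2)`` for a 9x2
    two-factor design.  ``replicates`` is a scalar or a per-time-point
    tuple (ragged replication).  Effect sizes: planted genes sit
    ``planted_shift`` above baseline in their own condition with
    within-condition sd ``planted_within_sd``; every other condition gets a
    mean shift drawn from N(0, condition_spread_sd).  Background noise has
    sd ``noise_sd``.
    """

    n_genes: int = 1000
    factor_levels: tuple = (6,)
    factor_names: tuple | None = None
    n_timepoints: int = 8
    replicates: int | tuple = 2
    time_values: tuple | None = None
    n_planted_per_condition: int = 20
    planted_disjoint: bool = True
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    noise_sd: float = 2.0
    planted_shift: float = 2.0
    planted_within_sd: float = 0.4
    condition_spread_sd: float = 1.0
    link_p_signal: float = 0.5
    link_p_noise: float = 0.001
    link_score_range: tuple = (1, 1000)
    seed: int = 0

    def condition_factor_sets(self) -> dict:
        """Mapping condition_id -> frozenset of factor labels."""
        axes = []
        for a, n_levels in enumerate(self.factor_levels):
            if self.factor_names is not None and a < len(self.factor_names):
                labels = tuple(self.factor_names[a])
                if len(labels) != n_levels:
                    raise ConsistencyError(
                        f"factor axis {a}: {len(labels)} names for {n_levels} levels"
                    )
            else:
                labels = tuple(f"{_AXIS_NAMES[a]}{l + 1}" for l in range(n_levels))
            axes.append(labels)
        out = {}
        for combo in itertools.product(*axes):
            out["-".join(combo)] = frozenset(combo)
        return out

    @property
    def n_conditions(self) -> int:
        return int(np.prod(self.factor_levels))

    def replicate_counts(self) -> tuple:
        if isinstance(self.replicates, int):
            return (self.replicates,) * self.n_timepoints
        reps = tuple(int(r) for r in self.replicates)
        if len(reps) != self.n_timepoints:
            raise ConsistencyError("per-time-point replicate counts do not match "
                                   "n_timepoints")
        return reps

    def times(self) -> tuple:
        if self.time_values is not None:
            if len(self.time_values) != self.n_timepoints:
                raise ConsistencyError("time_values length must equal n_timepoints")
            return tuple(float(t) for t in self.time_values)
        return tuple(float(t) for t in range(self.n_timepoints))

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConsistencyError("n_genes must be >= 1")
        if self.n_planted_per_condition * self.n_conditions > self.n_genes and self.planted_disjoint:
            raise ConsistencyError("more planted genes requested than genes available")
        for name in ("baseline_sd", "noise_sd", "condition_spread_sd"):
            if getattr(self, name) <= 0:
                raise ConsistencyError(f"{name} must be > 0")
        if self.planted_within_sd < 0:
            raise ConsistencyError("planted_within_sd must be >= 0")
        fsets = self.condition_factor_sets()
        if all(
            all(fa & fb for cb, fb in fsets.items() if cb != ca)
            for ca, fa in fsets.items()
        ) and len(fsets) > 1:
            raise ConsistencyError(
                "every condition shares a factor with every other; no valid "
                "rSNR negative sets exist under this factor design"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    planted: dict                      # condition_id -> tuple of gene ids
    shifts: pd.DataFrame               # columns gene_id, condition_id, mean_shift
    genes: list = field(default_factory=list)

    def planted_set(self, condition_id: str) -> set:
        return set(self.planted.get(condition_id, ()))

    def all_planted(self) -> set:
        return {g for gs in self.planted.values() for g in gs}

    def to_frame(self) -> pd.DataFrame:
        rows = [(cid, g) for cid in sorted(self.planted) for g in self.planted[cid]]
        return pd.DataFrame(rows, columns=["condition_id", "gene_id"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SyntheticTruth":
        tab = pd.read_csv(path, sep="\t", dtype=str)
        planted = {cid: tuple(grp["gene_id"])
                   for cid, grp in tab.groupby("condition_id", sort=True)}
        return cls(planted=planted,
                   shifts=pd.DataFrame(columns=["gene_id", "condition_id", "mean_shift"]))


def _gene_ids(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def generate(config: GeneratorConfig) -> tuple:
    """Draw one dataset and its ground truth from the generator model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fsets = config.condition_factor_sets()
    conditions = sorted(fsets)
    times = config.times()
    reps = config.replicate_counts()
    genes = _gene_ids(config.n_genes)

    # sample metadata
    rows = []
    for cid in conditions:
        factors = ";".join(sorted(fsets[cid]))
        for t, r_count in zip(times, reps):
            for r in range(1, r_count + 1):
                rows.append((f"{cid}_t{t:g}_r{r}", cid, factors, t, r))
    meta = pd.DataFrame(rows, columns=["sample_id", "condition_id", "factors",
                                       "time_point", "replicate"]).set_index("sample_id")
    n_samples = len(meta)
    cond_of_col = meta["condition_id"].to_numpy()

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd,
                                            size=(config.n_genes, n_samples))

    # plant condition-specific genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    planted: dict[str, tuple] = {}
    shift_rows = []
    if config.n_planted_per_condition > 0:
        if config.planted_disjoint:
            pool = rng.choice(np.asarray(genes, dtype=object),
                              size=config.n_planted_per_condition * len(conditions),
                              replace=False)
            chunks = {cid: pool[i * config.n_planted_per_condition:
                                (i + 1) * config.n_planted_per_condition]
                      for i, cid in enumerate(conditions)}
        else:
            chunks = {cid: rng.choice(np.asarray(genes, dtype=object),
                                      size=config.n_planted_per_condition,
                                      replace=False)
                      for cid in conditions}
        for cid in conditions:
            planted[cid] = tuple(str(g) for g in chunks[cid])
            own_cols = np.flatnonzero(cond_of_col == cid)
            for g in planted[cid]:
                gi = gene_pos[g]
                own_mean = baseline[gi] + config.planted_shift
                values[gi, own_cols] = rng.normal(own_mean, config.planted_within_sd,
                                                  size=own_cols.size)
                shift_rows.append((g, cid, config.planted_shift))
                for other in conditions:
                    if other == cid:
                        continue
                    delta = rng.normal(0.0, config.condition_spread_sd)
                    cols = np.flatnonzero(cond_of_col == other)
                    values[gi, cols] = baseline[gi] + delta + rng.normal(
                        0.0, config.noise_sd, size=cols.size)
                    shift_rows.append((g, other, delta))

    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                         columns=meta.index)
    ds = ExpressionDataset(frame, meta, provenance=f"synthetic(seed={config.seed})")
    truth = SyntheticTruth(
        planted=planted,
        shifts=pd.DataFrame(shift_rows, columns=["gene_id", "condition_id", "mean_shift"]),
        genes=genes,
    )
    return ds, truth


def generate_interactions(truth: SyntheticTruth, config: GeneratorConfig,
                          seed=None) -> InteractionSet:
    """Scored links enriched among planted genes.

    Pairs within one condition's planted set link with probability
    ``link_p_signal``; every other pair links with probability
    ``link_p_noise``.  Scores are uniform integers over
    ``link_score_range``.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    genes = truth.genes
    if not genes:
        raise ConsistencyError("truth carries no gene list")
    lo, hi = config.link_score_range
    records = {}

    for cid in sorted(truth.planted):
        ps = sorted(truth.planted[cid])
        for i, a in enumerate(ps):
            for b in ps[i + 1:]:
                if rng.random() < config.link_p_signal:
                    records[(a, b)] = int(rng.integers(lo, hi + 1))

    if config.link_p_noise > 0:
        n = len(genes)
        n_pairs_target = int(config.link_p_noise * n * (n - 1) / 2)
        arr = np.asarray(genes, dtype=object)
        for _ in range(n_pairs_target):
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            a, b = (arr[i], arr[j]) if arr[i] < arr[j] else (arr[j], arr[i])
            if (a, b) not in records:
                records[(a, b)] = int(rng.integers(lo, hi + 1))

    return InteractionSet((a, b, s) for (a, b), s in sorted(records.items()))


def permute_condition_labels(ds: ExpressionDataset, seed) -> ExpressionDataset:
    """Null-model transform: shuffle condition labels within every
    (time_point, replicate) cell across conditions.

    Requires a uniform design (every condition sampled at every cell) so the
    condition/time/replicate grid is preserved exactly while the association
    between condition labels and expression values is destroyed.
    """
    rng = np.random.default_rng(seed)
    meta = ds.samples.copy()
    conditions = sorted(ds.conditions)
    factors_of = {cid: ds.conditions[cid].factors for cid in conditions}
    new_cond = pd.Series(index=meta.index, dtype=object)
    for (t, r), grp in meta.groupby(["time_point", "replicate"], sort=True):
        cells = sorted(grp.index, key=lambda s: meta.loc[s, "condition_id"])
        if len(cells) != len(conditions):
            raise ConsistencyError(
                "label permutation requires every condition to be present in "
                f"every (time_point, replicate) cell; cell ({t}, {r}) has "
                f"{len(cells)} of {len(conditions)}"
            )
        perm = rng.permutation(len(conditions))
        for s, k in zip(cells, perm):
            new_cond[s] = conditions[k]
    meta["condition_id"] = new_cond
    meta["factors"] = meta["condition_id"].map(factors_of)
    return ExpressionDataset(ds.values, meta, provenance=ds.provenance + "+permuted")


# -- presets -----------------------------------------------------------------


def default_config(**overrides) -> GeneratorConfig:
    """Six single-factor conditions, 8 time points, 2 replicates, G=1000,
    20 planted genes per condition."""
    return replace(GeneratorConfig(), **overrides)


def atgenexpress_config(**overrides) -> GeneratorConfig:
    """18 conditions = 9 stress treatments x 2 tissues, T=8, 2 replicates."""
    base = GeneratorConfig(
        n_genes=2074,
        factor_levels=(9, 2),
        factor_names=(("cold", "heat", "salt", "drought", "osmotic", "oxidative",
                       "uvb", "wounding", "genotoxic"),
                      ("root", "shoot")),
        n_timepoints=8,
        replicates=2,
        time_values=(0.25, 0.5, 1, 3, 6, 12, 24, 48),
        n_planted_per_condition=20,
    )
    return replace(base, **overrides)


def edge_config(**overrides) -> GeneratorConfig:
    """Six toxin/dose conditions, 12 time points, ragged replication."""
    base = GeneratorConfig(
        n_genes=1600,
        factor_levels=(3, 2),
        factor_names=(("toxA", "toxB", "toxC"), ("low", "high")),
        n_timepoints=12,
        replicates=(3, 3, 2, 2, 2, 2, 1, 1, 2, 1, 1, 2),
        time_values=(2, 4, 8, 12, 24, 36, 48, 72, 96, 120, 144, 192),
        n_planted_per_condition=20,
    )
    return replace(base, **overrides)


def engreitz_config(**overrides) -> GeneratorConfig:
    """Static collection: 3 disease conditions, pseudo-time {0: normal,
    1: diseased}, 9 experiments (replicates) per condition."""
    base = GeneratorConfig(
        n_genes=3378,
        factor_levels=(3,),
        factor_names=(("dmd", "brca", "hd"),),
        n_timepoints=2,
        replicates=9,
        time_values=(0.0, 1.0),
        n_planted_per_condition=20,
    )
    return replace(base, **overrides)
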