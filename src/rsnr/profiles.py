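"""Expression and transition profiles, and interaction-based link profiles.

A *transition profile* summarizes a pair of time points (t_x < t_y) of one
experimental condition as a single gene-indexed vector:

* DTP (differential transition profile): E(t_y) - E(t_x), the change in
  expression between the two time points;
* MTP (mean transition profile): (E(t_x) + E(t_y)) / 2, the mean expression
  across the two time points;
* TIMEPOINT: the raw single-time-point expression profile, kept as a pair
  of separate vectors so single-profile classification can be compared
  fairly with transition-profile classification.

A *link profile* re-indexes any of the above by scored gene-gene
interactions: the value of a link is the mean of its two genes' values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import ConsistencyError, FormatError

__all__ = [
    "TransitionProfile",
    "LinkProfile",
    "InteractionSet",
    "read_interactions",
    "write_interactions",
    "make_dtp",
    "make_mtp",
    "make_timepoint_profiles",
    "to_link_profile",
    "training_profiles",
]

DTP = "DTP"
MTP = "MTP"
TIMEPOINT = "TIMEPOINT"
PROFILE_KINDS = (DTP, MTP, TIMEPOINT)


@dataclass
class TransitionProfile:
    """A gene-indexed vector summarizing one or two time points of a condition.

    For ``kind == "TIMEPOINT"`` the vector carries a single time point
    (``time_point``) while ``time_pair`` records the enclosing test pair it
    belongs to.
    """

    condition_id: str
    kind: str
    time_pair: tuple
    gene_ids: Sequence
    values: np.ndarray
    replicate_tag: str = "averaged"
    time_point: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.gene_ids):
            raise ConsistencyError("profile values and gene_ids differ in length")
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.kind == TIMEPOINT and self.time_point is None:
            raise ConsistencyError("TIMEPOINT profiles must record their time point")

    @property
    def feature_ids(self) -> Sequence:
        return self.gene_ids

    def sort_key(self) -> tuple:
        tp = self.time_point if self.time_point is not None else float("nan")
        return (self.condition_id, self.time_pair, () if self.time_point is None else (tp,))


@dataclass
class LinkProfile:
    """A transition profile indexed by gene-gene links instead of genes.

    Each value is the mean of the two member genes' values in the
    underlying gene-level profile.
    """

    condition_id: str
    kind: str
    time_pair: tuple
    links: Sequence  # tuples (gene_a, gene_b), lexicographically ordered
    values: np.ndarray
    replicate_tag: str = "averaged"
    time_point: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.links):
            raise ConsistencyError("link profile values and links differ in length")

    @property
    def feature_ids(self) -> Sequence:
        return self.links

    def sort_key(self) -> tuple:
        return (self.condition_id, self.time_pair,
                () if self.time_point is None else (self.time_point,))


class InteractionSet:
    """Scored undirected gene-gene links (STRING detailed-links dialect).

    Scores are integers in [0, 1000]; self-links and duplicate pairs are
    rejected.  Pairs are stored with lexicographically ordered endpoints.
    """

    def __init__(self, records: Iterable):
        rows = []
        seen = set()
        for a, b, score in records:
            a, b = str(a), str(b)
            if a == b:
                raise ConsistencyError(f"self-link on gene {a!r}")
            pair = (a, b) if a < b else (b, a)
            if pair in seen:
                raise ConsistencyError(f"duplicate link {pair}")
            seen.add(pair)
            score = int(score)
            if not 0 <= score <= 1000:
                raise ConsistencyError(f"link score {score} outside [0, 1000]")
            rows.append((pair[0], pair[1], score))
        rows.sort()
        self.table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return iter(self.table.itertuples(index=False, name=None))

    @property
    def pairs(self) -> list:
        return list(zip(self.table["gene_a"], self.table["gene_b"]))

    @property
    def scores(self) -> np.ndarray:
        return self.table["combined_score"].to_numpy()

    def genes(self) -> set:
        return set(self.table["gene_a"]) | set(self.table["gene_b"])

    def above(self, cutoff: int) -> "InteractionSet":
        """Links with confidence score strictly greater than ``cutoff``."""
        sub = self.table[self.table["combined_score"] > cutoff]
        return InteractionSet(list(sub.itertuples(index=False, name=None)))

    def restrict_to(self, genes: Iterable) -> "InteractionSet":
        gset = set(genes)
        sub = self.table[self.table["gene_a"].isin(gset) & self.table["gene_b"].isin(gset)]
        return InteractionSet(list(sub.itertuples(index=False, name=None)))


def read_interactions(path, id_map_path=None) -> InteractionSet:
    """Read a TSV of scored links (columns gene_a, gene_b, combined_score).

    ``id_map_path`` optionally points to a two-column protein -> gene map
    applied to both endpoints before assembling the set.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    missing = {"gene_a", "gene_b", "combined_score"} - set(tab.columns)
    if missing:
        raise FormatError(f"interaction table {path} lacks columns {sorted(missing)}")
    if id_map_path is not None:
        m = pd.read_csv(id_map_path, sep="\t", header=None, dtype=str)
        mapping = dict(zip(m.iloc[:, 0], m.iloc[:, 1]))
        tab["gene_a"] = tab["gene_a"].map(lambda x: mapping.get(x, x))
        tab["gene_b"] = tab["gene_b"].map(lambda x: mapping.get(x, x))
    return InteractionSet(list(tab[["gene_a", "gene_b", "combined_score"]]
                               .itertuples(index=False, name=None)))


def write_interactions(links: InteractionSet, path) -> None:
    links.table.to_csv(path, sep="\t", index=False)


# -- profile construction ---------------------------------------------------


def _replicate_average(ds: ExpressionDataset, condition_id: str, time_point: float,
                       samples: Sequence | None) -> np.ndarray:
    ids = ds.samples_of(condition_id, time_point, within=samples)
    if not ids:
        raise ConsistencyError(
            f"condition {condition_id!r} has no sample at time point {time_point}"
        )
    return ds.matrix(ids).mean(axis=1)


def _check_pair(ds: ExpressionDataset, condition_id: str, t_x: float, t_y: float,
                samples: Sequence | None) -> None:
    if condition_id not in ds.conditions:
        raise ConsistencyError(f"unknown condition {condition_id!r}")
    if t_x == t_y:
        raise ValueError("transition profile needs two distinct time points")
    available = {ds.samples.loc[s, "time_point"]
                 for s in ds.samples_of(condition_id, within=samples)}
    for t in (t_x, t_y):
        if float(t) not in available:
            raise ConsistencyError(
                f"condition {condition_id!r} has no data at time point {t}"
            )


def make_dtp(ds: ExpressionDataset, condition_id: str, t_x: float, t_y: float,
             replicate_policy: str = "average", samples: Sequence | None = None):
    """Differential transition profile E(t_y) - E(t_x).

    ``replicate_policy='average'`` averages replicates within each time point
    and returns a single profile; ``'each'`` returns one profile per
    replicate combination (for sensitivity checks).
    """
    return _make_pair_profile(ds, condition_id, t_x, t_y, DTP, replicate_policy, samples)


def make_mtp(ds: ExpressionDataset, condition_id: str, t_x: float, t_y: float,
             replicate_policy: str = "average", samples: Sequence | None = None):
    """Mean transition profile (E(t_x) + E(t_y)) / 2."""
    return _make_pair_profile(ds, condition_id, t_x, t_y, MTP, replicate_policy, samples)


def _combine(kind: str, ex: np.ndarray, ey: np.ndarray) -> np.ndarray:
    return ey - ex if kind == DTP else (ex + ey) / 2.0


def _make_pair_profile(ds, condition_id, t_x, t_y, kind, replicate_policy, samples):
    if t_y < t_x:
        t_x, t_y = t_y, t_x
    _check_pair(ds, condition_id, t_x, t_y, samples)
    if replicate_policy == "average":
        ex = _replicate_average(ds, condition_id, t_x, samples)
        ey = _replicate_average(ds, condition_id, t_y, samples)
        return TransitionProfile(condition_id, kind, (float(t_x), float(t_y)),
                                 ds.genes, _combine(kind, ex, ey))
    if replicate_policy == "each":
        out = []
        ids_x = ds.samples_of(condition_id, t_x, within=samples)
        ids_y = ds.samples_of(condition_id, t_y, within=samples)
        for sx, sy in itertools.product(ids_x, ids_y):
            rx, ry = ds.sample_key(sx).replicate, ds.sample_key(sy).replicate
            vals = _combine(kind, ds.matrix([sx])[:, 0], ds.matrix([sy])[:, 0])
            out.append(TransitionProfile(condition_id, kind, (float(t_x), float(t_y)),
                                         ds.genes, vals, replicate_tag=f"r{rx}/r{ry}"))
        return out
    raise ValueError(f"unknown replicate_policy {replicate_policy!r}")


def make_timepoint_profiles(ds: ExpressionDataset, condition_id: str, t_x: float,
                            t_y: float, replicate_policy: str = "average",
                            samples: Sequence | None = None):
    """The two single-time-point expression profiles of a test pair."""
    if t_y < t_x:
        t_x, t_y = t_y, t_x
    _check_pair(ds, condition_id, t_x, t_y, samples)
    if replicate_policy != "average":
        raise ValueError("time-point profiles support replicate_policy='average' only")
    out = []
    for t in (t_x, t_y):
        vals = _replicate_average(ds, condition_id, t, samples)
        out.append(TransitionProfile(condition_id, TIMEPOINT, (float(t_x), float(t_y)),
                                     ds.genes, vals, time_point=float(t)))
    return tuple(out)


def to_link_profile(profile: TransitionProfile, links: InteractionSet) -> LinkProfile:
    """Re-index a gene-level profile by links; link value = mean of the two genes.

    Links whose genes are absent from the profile are dropped with a warning;
    an empty resulting link set is an error.
    """
    pos = {g: i for i, g in enumerate(profile.gene_ids)}
    kept_pairs, ia, ib = [], [], []
    dropped = 0
    for a, b in links.pairs:
        if a in pos and b in pos:
            kept_pairs.append((a, b))
            ia.append(pos[a])
            ib.append(pos[b])
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"{dropped} link(s) dropped: gene(s) absent from the profile")
    if not kept_pairs:
        raise ConsistencyError("no link has both genes present in the profile")
    vals = (profile.values[ia] + profile.values[ib]) / 2.0
    return LinkProfile(profile.condition_id, profile.kind, profile.time_pair,
                       kept_pairs, vals, replicate_tag=profile.replicate_tag,
                       time_point=profile.time_point)


def training_profiles(ds: ExpressionDataset, training_samples: Sequence | None,
                      kind: str = MTP, pair_mode: str = "all",
                      replicate_policy: str = "average") -> list:
    """All training profiles of every condition present in the training mask.

    For DTP/MTP, profiles are built from ordered pairs t_x < t_y of the
    condition's available time points — all pairs by default, or only
    consecutive pairs with ``pair_mode='consecutive'``.  For TIMEPOINT,
    one profile per available time point.  Profiles are returned sorted by
    (condition_id, time_pair) so downstream tie-breaking is deterministic.
    """
    if kind not in PROFILE_KINDS:
        raise ValueError(f"unknown profile kind {kind!r}")
    if pair_mode not in ("all", "consecutive"):
        raise ValueError(f"unknown pair_mode {pair_mode!r}")
    out: list[TransitionProfile] = []
    tab = ds.samples if training_samples is None else ds.samples.loc[list(training_samples)]
    for cid in sorted(tab["condition_id"].unique()):
        tps = sorted(tab.loc[tab["condition_id"] == cid, "time_point"].unique())
        if kind == TIMEPOINT:
            for t in tps:
                vals = _replicate_average(ds, cid, t, training_samples)
                out.append(TransitionProfile(cid, TIMEPOINT, (float(t), float(t)),
                                             ds.genes, vals, time_point=float(t)))
            continue
        if len(tps) < 2:
            warnings.warn(f"condition {cid!r} has < 2 training time points; skipped")
            continue
        means = {t: _replicate_average(ds, cid, t, training_samples) for t in tps}
        if pair_mode == "consecutive":
            pairs = list(zip(tps, tps[1:]))
        else:
            pairs = [(a, b) for i, a in enumerate(tps) for b in tps[i + 1:]]
        for t_x, t_y in pairs:
            out.append(TransitionProfile(cid, kind, (float(t_x), float(t_y)), ds.genes,
                                         _combine(kind, means[t_x], means[t_y])))
    out.sort(key=lambda p: p.sort_key())
    return out
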