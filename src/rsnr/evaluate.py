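"""Cross-validation scenarios, accuracy, query-vs-database ROC/AUC, and the
rank-structure experiments.

Two leave-out styles are implemented:

* **time-course CV** (random sub-sampling): a test unit is drawn from one
  condition by picking time points and one replicate per time point.  In
  scenario 1 the remaining replicates of the test time points stay in the
  training data; in scenario 2 the test unit is exactly two time points and
  *all* replicates of those time points are removed from training.  Ten
  test units per condition per repetition by default.
* **static CV**: each experiment (a normal/diseased pseudo-time pair) is
  left out exactly once.

Within every fold, feature selection is fitted on the training data only,
profiles are built, and the test unit is classified by Pearson 1NN with
majority voting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classify import classify_test_unit, classify_timepoint_mode, pearson_many
from .dataset import ExpressionDataset
from .errors import ConsistencyError
from .profiles import (DTP, MTP, TIMEPOINT, InteractionSet, TransitionProfile,
                       make_dtp, make_mtp, make_timepoint_profiles,
                       to_link_profile, training_profiles)
from .selection import (GeneRanking, build_split, random_selection, rsnr_scores,
                        select_section, select_top, snr_c_scores,
                        string_gene_selection, string_link_selection,
                        welch_t_scores)

__all__ = [
    "CVConfig",
    "SelectionSpec",
    "Fold",
    "CVResult",
    "ROCResult",
    "make_folds_timecourse",
    "make_folds_static",
    "run_cv",
    "run_cv_static",
    "accuracy",
    "auc_from_scores",
    "roc_auc_query",
    "rank_section_experiment",
    "stepwise_reduction_experiment",
]

RANKING_METHODS = ("rsnr", "snr_c", "welch_t")
SELECTOR_METHODS = ("all",) + RANKING_METHODS + ("random", "string_gene", "string_link")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings.

    Scenario 1 keeps sibling replicates of the test time points in the
    training data and draws a random number of test time points; scenario 2
    removes them and fixes the test unit to exactly 2 time points.
    Conditions with fewer than ``min_timepoints`` time points are excluded
    from testing under scenario 2.
    """

    scenario: int = 2
    profile_kind: str = MTP
    selector: str = "all"
    n_genes: int | None = None
    cutoff: int | None = None
    folds_per_condition: int = 10
    repetitions: int = 1
    seed: int = 0
    replicate_policy: str = "average"
    pair_mode: str = "all"           # training-pair enumeration: all | consecutive
    aggregation: str = "pooled"      # rSNR aggregation axis
    min_timepoints: int = 4

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")
        if self.profile_kind not in (DTP, MTP, TIMEPOINT):
            raise ValueError(f"unknown profile kind {self.profile_kind!r}")
        if self.selector not in SELECTOR_METHODS:
            raise ValueError(f"unknown selector {self.selector!r}")


@dataclass(frozen=True)
class SelectionSpec:
    """One feature-selection setting evaluated inside the CV.

    ``start_rank`` selects a section of the ranking instead of the top
    (1-based, into the descending list).  ``label`` names the setting in
    result tables.
    """

    method: str = "all"
    n_genes: int | None = None
    start_rank: int | None = None
    cutoff: int | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.method not in SELECTOR_METHODS:
            raise ValueError(f"unknown selector {self.method!r}")
        if self.label is None:
            bits = [self.method]
            if self.n_genes is not None:
                bits.append(f"n{self.n_genes}")
            if self.start_rank is not None:
                bits.append(f"from{self.start_rank}")
            if self.cutoff is not None:
                bits.append(f"cut{self.cutoff}")
            object.__setattr__(self, "label", "_".join(bits))


@dataclass
class Fold:
    """One test unit and its training mask."""

    test_condition: str
    test_time_points: list          # ascending
    test_samples: list              # list of lists, grouped per time point
    training_samples: list

    def flat_test_samples(self) -> list:
        return [s for grp in self.test_samples for s in grp]


@dataclass
class CVResult:
    """Per-fold records and accuracy summaries for one selection setting."""

    method_label: str
    records: pd.DataFrame
    accuracy_per_repetition: np.ndarray
    config: CVConfig | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(self.records["correct"].mean())

    @property
    def sd_over_repetitions(self) -> float:
        if len(self.accuracy_per_repetition) < 2:
            return float("nan")
        return float(np.std(self.accuracy_per_repetition, ddof=1))

    @property
    def sd_over_folds(self) -> float:
        c = self.records["correct"].to_numpy(dtype=float)
        if c.size < 2:
            return float("nan")
        return float(np.std(c, ddof=1))

    @property
    def n_folds(self) -> int:
        return len(self.records)


@dataclass
class ROCResult:
    """Per-query (score, label) lists, per-query AUCs and their mean."""

    per_query: pd.DataFrame          # query, condition, auc, n_pos, n_neg
    mean_auc: float
    n_undefined: int = 0


# -- fold construction -------------------------------------------------------


def make_folds_timecourse(ds: ExpressionDataset, config: CVConfig, rng) -> list:
    """Random sub-sampling folds for time-course data (scenarios 1 and 2)."""
    folds: list[Fold] = []
    all_samples = set(ds.sample_ids)
    for cid in sorted(ds.conditions):
        cond = ds.conditions[cid]
        tps = list(cond.time_points)
        if config.scenario == 2 and len(tps) < config.min_timepoints:
            warnings.warn(f"condition {cid!r} has {len(tps)} < "
                          f"{config.min_timepoints} time points; skipped as test source")
            continue
        if config.scenario == 1 and len(tps) < 2:
            warnings.warn(f"condition {cid!r} has < 2 time points; skipped")
            continue
        for _ in range(config.folds_per_condition):
            if config.scenario == 2:
                k = 2
            else:
                k = int(rng.integers(2, len(tps) + 1))
            chosen = sorted(rng.choice(tps, size=k, replace=False))
            test_groups = []
            removed = set()
            for t in chosen:
                ids = ds.samples_of(cid, t)
                pick = ids[int(rng.integers(0, len(ids)))]
                test_groups.append([pick])
                if config.scenario == 2:
                    removed.update(ids)      # all replicates of the test time point
                else:
                    removed.add(pick)        # only the test sample itself
            training = sorted(all_samples - removed)
            folds.append(Fold(cid, [float(t) for t in chosen], test_groups, training))
    if not folds:
        raise ConsistencyError("no condition is eligible as a test source")
    return folds


def experiments_of(ds: ExpressionDataset) -> list:
    """(condition_id, replicate) pairs present at every time point — the
    'experiments' of a static normal/diseased collection."""
    out = []
    for cid in sorted(ds.conditions):
        cond = ds.conditions[cid]
        reps_per_tp = [set(ds.samples.loc[ds.samples_of(cid, t), "replicate"])
                       for t in cond.time_points]
        common = set.intersection(*reps_per_tp) if reps_per_tp else set()
        out.extend((cid, r) for r in sorted(common))
    return out


def make_folds_static(ds: ExpressionDataset) -> list:
    """Leave-one-experiment-out folds; every experiment is test exactly once."""
    all_samples = set(ds.sample_ids)
    folds = []
    for cid, rep in experiments_of(ds):
        cond = ds.conditions[cid]
        test_groups = []
        for t in cond.time_points:
            ids = [s for s in ds.samples_of(cid, t)
                   if ds.samples.loc[s, "replicate"] == rep]
            test_groups.append(ids)
        test_flat = {s for grp in test_groups for s in grp}
        folds.append(Fold(cid, [float(t) for t in cond.time_points], test_groups,
                          sorted(all_samples - test_flat)))
    return folds


def assert_fold_hygiene(ds: ExpressionDataset, fold: Fold, scenario: int) -> None:
    """Scenario 2 invariant: no replicate of any test time point is in training."""
    if scenario != 2:
        return
    test_tps = set(fold.test_time_points)
    for s in fold.training_samples:
        key = ds.sample_key(s)
        if key.condition_id == fold.test_condition and key.time_point in test_tps:
            raise ConsistencyError(
                f"training sample {s!r} is a replicate of a test time point"
            )


# -- selection fitting --------------------------------------------------------


def _one_vs_rest_classes(ds, training, cid):
    c1 = ds.samples_of(cid, within=training)
    cset = set(c1)
    c2 = [s for s in training if s not in cset]
    return c1, c2


def _fit_rankings(ds, training, method, aggregation) -> dict:
    """Per-condition rankings of one ranking method, fitted on training only."""
    out = {}
    tab = ds.samples.loc[list(training)]
    for cid in sorted(tab["condition_id"].unique()):
        if method == "rsnr":
            split = build_split(ds, training, cid)
            comp = rsnr_scores(ds, split, aggregation=aggregation)
            out[cid] = GeneRanking.from_scores(cid, "rsnr", list(comp.index),
                                               comp["rsnr"].to_numpy())
        else:
            c1, c2 = _one_vs_rest_classes(ds, training, cid)
            score_fn = snr_c_scores if method == "snr_c" else welch_t_scores
            out[cid] = score_fn(ds, c1, c2, condition_id=cid)
    return out


class _FoldContext:
    """Caches per-fold work shared across selection settings."""

    def __init__(self, ds, fold, config, links, rng):
        self.ds = ds
        self.fold = fold
        self.config = config
        self.links = links
        self.rng = rng
        self._rankings: dict[str, dict] = {}
        self._gene_pos = {g: i for i, g in enumerate(ds.genes)}
        self.train_profiles = training_profiles(
            ds, fold.training_samples, kind=config.profile_kind,
            pair_mode=config.pair_mode, replicate_policy=config.replicate_policy)
        self.test_profiles = self._build_test_profiles()
        self._link_cache = None

    def _build_test_profiles(self):
        ds, fold, config = self.ds, self.fold, self.config
        tps = fold.test_time_points
        test_flat = fold.flat_test_samples()
        profiles = []
        if config.profile_kind == TIMEPOINT:
            for t_x, t_y in zip(tps, tps[1:]):
                profiles.append(make_timepoint_profiles(
                    ds, fold.test_condition, t_x, t_y, samples=test_flat))
            return profiles
        maker = make_dtp if config.profile_kind == DTP else make_mtp
        for t_x, t_y in zip(tps, tps[1:]):
            profiles.append(maker(ds, fold.test_condition, t_x, t_y,
                                  samples=test_flat))
        return profiles

    def rankings(self, method) -> dict:
        if method not in self._rankings:
            self._rankings[method] = _fit_rankings(
                self.ds, self.fold.training_samples, method, self.config.aggregation)
        return self._rankings[method]

    def selections(self, spec: SelectionSpec):
        """Per-condition feature positions for one spec, or None for all genes."""
        conds = sorted({p.condition_id for p in self.train_profiles})
        if spec.method == "all":
            return None
        if spec.method in RANKING_METHODS:
            rankings = self.rankings(spec.method)
            out = {}
            for cid in conds:
                ranking = rankings[cid]
                if spec.start_rank is not None:
                    genes = select_section(ranking, spec.start_rank, spec.n_genes)
                else:
                    genes = select_top(ranking, spec.n_genes or len(ranking))
                out[cid] = np.array([self._gene_pos[g] for g in genes], dtype=int)
            return out
        if spec.method == "random":
            picked = random_selection(self.ds.genes, spec.n_genes, self.rng)
            pos = np.array(sorted(self._gene_pos[g] for g in picked.genes), dtype=int)
            return {cid: pos for cid in conds}
        if spec.method == "string_gene":
            genes = string_gene_selection(self.ds.genes, self.links, spec.cutoff or 0)
            pos = np.array(sorted(self._gene_pos[g] for g in genes), dtype=int)
            return {cid: pos for cid in conds}
        raise ValueError(f"selections() does not handle {spec.method!r}")

    def link_profiles(self, cutoff):
        """Training/test profiles re-indexed by links above cutoff (cached)."""
        if self._link_cache is None or self._link_cache[0] != cutoff:
            kept = string_link_selection(self.ds.genes, self.links, cutoff or 0)
            train = [to_link_profile(p, kept) for p in self.train_profiles]
            if self.config.profile_kind == TIMEPOINT:
                test = [tuple(to_link_profile(q, kept) for q in pair)
                        for pair in self.test_profiles]
            else:
                test = [to_link_profile(p, kept) for p in self.test_profiles]
            self._link_cache = (cutoff, train, test)
        return self._link_cache[1], self._link_cache[2]

    def classify(self, spec: SelectionSpec, test_unit: str):
        if spec.method == "string_link":
            train, test = self.link_profiles(spec.cutoff)
            selections = None
        else:
            train, test = self.train_profiles, self.test_profiles
            selections = self.selections(spec)
        if self.config.profile_kind == TIMEPOINT:
            # one vote per consecutive test pair, each via global-max
            # comparison of the pair's two single-time-point profiles
            votes = []
            for pair in test:
                pred = classify_timepoint_mode(list(pair), train, selections,
                                               test_unit=test_unit)
                votes.append(pred)
            if len(votes) == 1:
                p = votes[0]
                return replace_true(p, self.fold.test_condition)
            from .classify import PairVote, _finalize
            pair_votes = [PairVote(v.predicted_condition,
                                   max(v.condition_sums.values()), -1, 0)
                          for v in votes]
            return _finalize(test_unit, pair_votes, self.fold.test_condition)
        return classify_test_unit(test, train, selections, test_unit=test_unit,
                                  true_condition=self.fold.test_condition)


def replace_true(pred, true_condition):
    pred.true_condition = true_condition
    return pred


def _spec_n_genes(spec: SelectionSpec, total: int) -> int:
    if spec.method == "all":
        return total
    return spec.n_genes if spec.n_genes is not None else total


def run_cv(ds: ExpressionDataset, config: CVConfig,
           specs: Sequence | SelectionSpec | None = None,
           links: InteractionSet | None = None):
    """Run the cross-validation for one or several selection settings.

    With ``specs=None`` a single setting is taken from ``config.selector``;
    a list of :class:`SelectionSpec` evaluates all settings on identical
    folds, fitted rankings and profiles (rankings are always fitted on
    training data only).  Returns a single :class:`CVResult` or a dict
    label -> CVResult.
    """
    single = False
    if specs is None:
        specs = [SelectionSpec(config.selector, config.n_genes, cutoff=config.cutoff)]
        single = True
    elif isinstance(specs, SelectionSpec):
        specs = [specs]
        single = True
    if any(s.method in ("string_gene", "string_link") for s in specs) and links is None:
        raise ConsistencyError("interaction-based selection requires a link set")

    rows: dict[str, list] = {s.label: [] for s in specs}
    rep_acc: dict[str, list] = {s.label: [] for s in specs}
    for rep in range(config.repetitions):
        rng = np.random.default_rng([config.seed, rep])
        folds = make_folds_timecourse(ds, config, rng)
        correct_count = {s.label: 0 for s in specs}
        for fi, fold in enumerate(folds):
            assert_fold_hygiene(ds, fold, config.scenario)
            ctx = _FoldContext(ds, fold, config, links, rng)
            unit = f"rep{rep}_fold{fi}_{fold.test_condition}"
            for spec in specs:
                pred = ctx.classify(spec, unit)
                ok = bool(pred.correct)
                correct_count[spec.label] += ok
                rows[spec.label].append(
                    (rep, fi, fold.test_condition, pred.predicted_condition,
                     ok, _spec_n_genes(spec, ds.n_genes), spec.label))
        for spec in specs:
            rep_acc[spec.label].append(correct_count[spec.label] / len(folds))

    out = {}
    for spec in specs:
        records = pd.DataFrame(
            rows[spec.label],
            columns=["repetition", "fold", "test_condition", "predicted_condition",
                     "correct", "n_genes", "method"])
        out[spec.label] = CVResult(spec.label, records,
                                   np.asarray(rep_acc[spec.label]), config=config)
    return out[specs[0].label] if single else out


def _experiment_profile(ds, cid, rep, kind, samples=None):
    cond = ds.conditions[cid]
    ids = [s for s in ds.samples_of(cid, within=samples)
           if ds.samples.loc[s, "replicate"] == rep]
    tps = sorted({ds.samples.loc[s, "time_point"] for s in ids})
    if len(tps) != 2:
        raise ConsistencyError(f"experiment ({cid}, {rep}) does not span 2 time points")
    return (make_dtp if kind == DTP else make_mtp)(ds, cid, tps[0], tps[1],
                                                   samples=ids)


def run_cv_static(ds: ExpressionDataset, config: CVConfig,
                  specs: Sequence | SelectionSpec | None = None,
                  links: InteractionSet | None = None):
    """Leave-one-experiment-out CV for static (normal/diseased) collections.

    Each experiment's two pseudo-time points form one MTP/DTP profile;
    training profiles are per-experiment (replicates are separate database
    entries, not averaged)."""
    single = False
    if specs is None:
        specs = [SelectionSpec(config.selector, config.n_genes, cutoff=config.cutoff)]
        single = True
    elif isinstance(specs, SelectionSpec):
        specs = [specs]
        single = True
    if config.profile_kind == TIMEPOINT:
        raise ValueError("static CV uses transition profiles (MTP or DTP)")

    gene_pos = {g: i for i, g in enumerate(ds.genes)}
    experiments = experiments_of(ds)
    rows: dict[str, list] = {s.label: [] for s in specs}
    rng = np.random.default_rng([config.seed, 0])
    for fi, (cid, rep) in enumerate(experiments):
        training = [s for s in ds.sample_ids
                    if not (ds.samples.loc[s, "condition_id"] == cid
                            and ds.samples.loc[s, "replicate"] == rep)]
        test_profile = _experiment_profile(ds, cid, rep, config.profile_kind)
        train_profiles = [
            _experiment_profile(ds, c2, r2, config.profile_kind, samples=training)
            for c2, r2 in experiments if not (c2 == cid and r2 == rep)]
        train_profiles.sort(key=lambda p: p.sort_key())
        conds = sorted({p.condition_id for p in train_profiles})
        for spec in specs:
            if spec.method == "all":
                selections = None
            elif spec.method in RANKING_METHODS:
                rankings = _fit_rankings(ds, training, spec.method, config.aggregation)
                selections = {
                    c: np.array([gene_pos[g] for g in
                                 (select_section(rankings[c], spec.start_rank, spec.n_genes)
                                  if spec.start_rank is not None else
                                  select_top(rankings[c], spec.n_genes or len(rankings[c])))],
                                dtype=int)
                    for c in conds}
            elif spec.method == "random":
                picked = random_selection(ds.genes, spec.n_genes, rng)
                pos = np.array(sorted(gene_pos[g] for g in picked.genes), dtype=int)
                selections = {c: pos for c in conds}
            elif spec.method == "string_gene":
                genes = string_gene_selection(ds.genes, links, spec.cutoff or 0)
                pos = np.array(sorted(gene_pos[g] for g in genes), dtype=int)
                selections = {c: pos for c in conds}
            else:
                raise ValueError(f"static CV does not support {spec.method!r}")
            pred = classify_test_unit([test_profile], train_profiles, selections,
                                      test_unit=f"{cid}_r{rep}", true_condition=cid)
            rows[spec.label].append((0, fi, cid, pred.predicted_condition,
                                     bool(pred.correct),
                                     _spec_n_genes(spec, ds.n_genes), spec.label))

    out = {}
    for spec in specs:
        records = pd.DataFrame(
            rows[spec.label],
            columns=["repetition", "fold", "test_condition", "predicted_condition",
                     "correct", "n_genes", "method"])
        acc = np.array([records["correct"].mean()])
        out[spec.label] = CVResult(spec.label, records, acc, config=config)
    return out[specs[0].label] if single else out


# -- metrics ------------------------------------------------------------------


def accuracy(predictions: Sequence) -> float:
    """Fraction of correct predictions (accepts Prediction objects or bools)."""
    vals = [p.correct if hasattr(p, "correct") else bool(p) for p in predictions]
    if not vals:
        raise ValueError("accuracy of an empty prediction list is undefined")
    return float(np.mean([bool(v) for v in vals]))


def auc_from_scores(scores: Sequence, labels: Sequence) -> float:
    """Area under the ROC curve via the rank-sum formulation (ties count 1/2).

    Equivalent to sweeping all score cutoffs and integrating TPR over FPR.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined without both positives and negatives")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc_query(ds: ExpressionDataset, config: CVConfig,
                  spec: SelectionSpec | None = None,
                  links: InteractionSet | None = None) -> ROCResult:
    """Query-vs-database ROC for a static collection.

    Every experiment queries the remaining experiments; scores are Pearson
    correlations of transition profiles, labels mark same-condition entries,
    and the per-query AUC is averaged over all queries.  When a selection is
    given, the correlation with a database entry of condition k uses k's
    selected genes (fitted on the database, i.e. excluding the query).
    Queries without both a positive and a negative database entry are
    excluded from the mean with a warning.
    """
    spec = spec or SelectionSpec("all")
    gene_pos = {g: i for i, g in enumerate(ds.genes)}
    experiments = experiments_of(ds)
    if len({c for c, _ in experiments}) < 2:
        raise ConsistencyError("query-vs-database ROC needs >= 2 conditions")
    rng = np.random.default_rng([config.seed, 1])
    rows = []
    n_undefined = 0
    for cid, rep in experiments:
        database = [(c2, r2) for c2, r2 in experiments if not (c2 == cid and r2 == rep)]
        training = [s for s in ds.sample_ids
                    if not (ds.samples.loc[s, "condition_id"] == cid
                            and ds.samples.loc[s, "replicate"] == rep)]
        query = _experiment_profile(ds, cid, rep, config.profile_kind)
        conds = sorted({c for c, _ in database})
        if spec.method == "all":
            selections = None
        elif spec.method in RANKING_METHODS:
            rankings = _fit_rankings(ds, training, spec.method, config.aggregation)
            selections = {c: np.array([gene_pos[g] for g in
                                       select_top(rankings[c], spec.n_genes or len(rankings[c]))],
                                      dtype=int)
                          for c in conds}
        elif spec.method == "random":
            picked = random_selection(ds.genes, spec.n_genes, rng)
            pos = np.array(sorted(gene_pos[g] for g in picked.genes), dtype=int)
            selections = {c: pos for c in conds}
        elif spec.method == "string_gene":
            genes = string_gene_selection(ds.genes, links, spec.cutoff or 0)
            pos = np.array(sorted(gene_pos[g] for g in genes), dtype=int)
            selections = {c: pos for c in conds}
        else:
            raise ValueError(f"roc_auc_query does not support {spec.method!r}")

        scores, labels = [], []
        for c2, r2 in database:
            entry = _experiment_profile(ds, c2, r2, config.profile_kind,
                                        samples=training)
            sel = None if selections is None else selections.get(c2)
            q = query.values if sel is None else query.values[sel]
            e = entry.values if sel is None else entry.values[sel]
            scores.append(float(pearson_many(q, e[None, :])[0]))
            labels.append(c2 == cid)
        labels_arr = np.asarray(labels)
        if labels_arr.all() or not labels_arr.any():
            warnings.warn(f"query ({cid}, {rep}) lacks positives or negatives; excluded")
            n_undefined += 1
            continue
        rows.append((f"{cid}_r{rep}", cid, auc_from_scores(scores, labels_arr),
                     int(labels_arr.sum()), int((~labels_arr).sum())))
    per_query = pd.DataFrame(rows, columns=["query", "condition", "auc",
                                            "n_pos", "n_neg"])
    if per_query.empty:
        raise ConsistencyError("no query had a defined AUC")
    return ROCResult(per_query, float(per_query["auc"].mean()), n_undefined)


# -- rank-structure experiments ----------------------------------------------


def rank_section_experiment(ds: ExpressionDataset, config: CVConfig,
                            section_size: int = 200,
                            include_random: bool = True) -> pd.DataFrame:
    """CV accuracy per section of the rSNR ranking (bottom to top).

    Sections of ``section_size`` genes tile the descending ranking from the
    top; the table reports them bottom-up together with an equal-size random
    control.  Columns: label, start_rank, mean_accuracy, sd_accuracy.
    """
    if ds.n_genes < section_size:
        raise ValueError("section size exceeds the number of genes")
    n_sections = ds.n_genes // section_size
    specs = [SelectionSpec("rsnr", section_size, start_rank=1 + j * section_size,
                           label=f"section_{j + 1}")
             for j in range(n_sections)]
    if include_random:
        specs.append(SelectionSpec("random", section_size, label="random"))
    results = run_cv(ds, config, specs)
    rows = []
    for spec in specs:
        res = results[spec.label]
        rows.append((spec.label, spec.start_rank if spec.start_rank else -1,
                     res.mean_accuracy, res.sd_over_folds))
    frame = pd.DataFrame(rows, columns=["label", "start_rank", "mean_accuracy",
                                        "sd_accuracy"])
    # bottom-up order: highest start_rank (worst section) first, random last
    sections = frame[frame["label"] != "random"].sort_values(
        "start_rank", ascending=False)
    rest = frame[frame["label"] == "random"]
    return pd.concat([sections, rest], ignore_index=True)


def stepwise_reduction_experiment(ds: ExpressionDataset, config: CVConfig,
                                  step: int = 200) -> pd.DataFrame:
    """Step-wise feature reduction: top-n rSNR vs equal-size random control.

    Sizes run G, G-step, ... down to the last size >= step.  At n = G both
    settings select every gene and coincide.  Columns: n_genes, method,
    mean_accuracy, sd_accuracy.
    """
    if not 0 < step < ds.n_genes:
        raise ValueError("step must be in (0, n_genes)")
    sizes = list(range(ds.n_genes, 0, -step))
    specs = []
    for n in sizes:
        specs.append(SelectionSpec("rsnr", n, label=f"rsnr_{n}"))
        specs.append(SelectionSpec("random", n, label=f"random_{n}"))
    results = run_cv(ds, config, specs)
    rows = []
    for n in sizes:
        for method in ("rsnr", "random"):
            res = results[f"{method}_{n}"]
            rows.append((n, method, res.mean_accuracy, res.sd_over_folds))
    return pd.DataFrame(rows, columns=["n_genes", "method", "mean_accuracy",
                                       "sd_accuracy"])
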