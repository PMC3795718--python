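"""Pearson-correlation 1-nearest-neighbor classification of profiles.

Each test transition profile is compared against every training profile;
when per-condition gene subsets are supplied, the correlation with a
training profile of condition k is computed on k's selected genes only.
A test unit with several transition profiles (one per consecutive pair of
its time points) is classified by majority voting over the per-pair
nearest-neighbor votes; vote ties are broken by the highest sum of winning
similarity scores.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConsistencyError

__all__ = [
    "UNDEFINED_SIMILARITY",
    "pearson",
    "pearson_many",
    "PairVote",
    "Prediction",
    "classify_pair",
    "classify_test_unit",
    "classify_timepoint_mode",
]

#: Sentinel returned for correlations with a zero-variance vector.  It
#: compares below -1, so a degenerate (constant) profile can never be the
#: nearest neighbor.
UNDEFINED_SIMILARITY = -2.0

MIN_COMMON_FEATURES = 3


def pearson(x: Sequence, y: Sequence) -> float:
    """Product-moment correlation; UNDEFINED_SIMILARITY if either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < MIN_COMMON_FEATURES:
        raise ValueError(f"need at least {MIN_COMMON_FEATURES} values, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0 or ny == 0:
        return UNDEFINED_SIMILARITY
    r = float((xc @ yc) / (nx * ny))
    return min(1.0, max(-1.0, r))


def pearson_many(x: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Correlation of vector ``x`` with every row of ``mat`` (rows x features)."""
    x = np.asarray(x, dtype=float)
    mat = np.asarray(mat, dtype=float)
    if mat.shape[1] != x.size:
        raise ValueError(f"length mismatch: {mat.shape[1]} vs {x.size}")
    xc = x - x.mean()
    nx = np.sqrt(xc @ xc)
    mc = mat - mat.mean(axis=1, keepdims=True)
    nm = np.sqrt((mc * mc).sum(axis=1))
    out = np.full(mat.shape[0], UNDEFINED_SIMILARITY)
    if nx == 0:
        return out
    ok = nm > 0
    out[ok] = np.clip((mc[ok] @ xc) / (nm[ok] * nx), -1.0, 1.0)
    return out


@dataclass
class PairVote:
    """Nearest-neighbor vote of one test profile."""

    condition_id: str
    similarity: float
    training_index: int
    n_features: int
    n_skipped: int = 0


@dataclass
class Prediction:
    """Final classification of one test unit."""

    test_unit: str
    predicted_condition: str
    votes: list
    condition_sums: dict
    tie_broken: bool = False
    true_condition: str | None = None

    @property
    def correct(self):
        if self.true_condition is None:
            return None
        return self.predicted_condition == self.true_condition


def _selection_indices(selections, condition_id, n_features):
    if selections is None:
        return None
    sel = selections.get(condition_id, None)
    if sel is None:
        return None
    return np.asarray(sel, dtype=int)


def classify_pair(test_profile, training_profiles: Sequence,
                  selections: Mapping | None = None) -> PairVote:
    """1NN vote of one test profile against all training profiles.

    ``selections`` maps condition_id to integer feature positions (into the
    profile vectors) or None for all features.  Training profiles whose
    selection leaves fewer than 3 features are skipped with a warning-level
    outcome; if every profile is skipped, a ConsistencyError is raised.
    Exact similarity ties go to the profile earliest in (condition_id,
    time_pair) order, which is how training profiles are sorted.
    """
    if not training_profiles:
        raise ConsistencyError("no training profiles")
    x = test_profile.values
    best_r = -np.inf
    best_idx = -1
    best_nfeat = 0
    n_skipped = 0

    # group contiguous runs of equal condition to vectorize correlation
    by_condition: dict[str, list[int]] = defaultdict(list)
    for i, p in enumerate(training_profiles):
        by_condition[p.condition_id].append(i)

    for cid in sorted(by_condition):
        idxs = by_condition[cid]
        sel = _selection_indices(selections, cid, x.size)
        if sel is not None and sel.size < MIN_COMMON_FEATURES:
            n_skipped += len(idxs)
            continue
        xv = x if sel is None else x[sel]
        mat = np.stack([training_profiles[i].values for i in idxs])
        if sel is not None:
            mat = mat[:, sel]
        rs = pearson_many(xv, mat)
        for local, i in enumerate(idxs):
            r = rs[local]
            if r > best_r:
                best_r = r
                best_idx = i
                best_nfeat = xv.size
    if best_idx < 0:
        raise ConsistencyError(
            "every training profile was skipped (selections below the "
            f"{MIN_COMMON_FEATURES}-feature minimum)"
        )
    return PairVote(training_profiles[best_idx].condition_id, float(best_r),
                    best_idx, best_nfeat, n_skipped)


def _finalize(test_unit, votes, true_condition) -> Prediction:
    counts: dict[str, int] = defaultdict(int)
    sums: dict[str, float] = defaultdict(float)
    for v in votes:
        counts[v.condition_id] += 1
        sums[v.condition_id] += v.similarity
    top = max(counts.values())
    tied = sorted(c for c, n in counts.items() if n == top)
    tie_broken = len(tied) > 1
    if tie_broken:
        # highest sum of winning similarity scores; residual ties go to the
        # lexicographically first condition id
        best = max(tied, key=lambda c: (sums[c], ))
        cand = [c for c in tied if sums[c] == sums[best]]
        winner = sorted(cand)[0]
    else:
        winner = tied[0]
    return Prediction(test_unit, winner, list(votes), dict(sums),
                      tie_broken=tie_broken, true_condition=true_condition)


def classify_test_unit(test_profiles: Sequence, training_profiles: Sequence,
                       selections: Mapping | None = None,
                       test_unit: str = "test",
                       true_condition: str | None = None) -> Prediction:
    """Majority voting over per-pair 1NN votes; ties by similarity sums."""
    if not test_profiles:
        raise ConsistencyError("test unit has no profiles")
    votes = [classify_pair(p, training_profiles, selections) for p in test_profiles]
    return _finalize(test_unit, votes, true_condition)


def classify_timepoint_mode(test_profiles: Sequence, training_profiles: Sequence,
                            selections: Mapping | None = None,
                            test_unit: str = "test",
                            true_condition: str | None = None) -> Prediction:
    """Single-time-point mode: the test pair's two expression profiles are
    compared with all training time-point profiles; the prediction is the
    condition of the globally most similar (test, training) pair."""
    if len(test_profiles) != 2:
        raise ConsistencyError("time-point mode requires exactly two test profiles")
    votes = [classify_pair(p, training_profiles, selections) for p in test_profiles]
    best = max(range(2), key=lambda i: (votes[i].similarity,))
    # deterministic on exact ties: first test profile wins via max() above
    winner = votes[best].condition_id
    sums = {winner: votes[best].similarity}
    return Prediction(test_unit, winner, votes, sums,
                      tie_broken=False, true_condition=true_condition)
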