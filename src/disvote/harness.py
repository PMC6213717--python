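"""Training and evaluation protocol for the meta-predictor.

Sequences (never individual residues) are split into an independent test
set (~20%) and five cross-validation folds over the remaining 80%, with
stratified rejection resampling so the disordered:structured residue
ratio of the test set tracks the training side.  Each cross-validation
rotation trains on three folds, monitors early stopping on a fourth, and
validates on the fifth; thresholds are re-derived from each rotation's
training folds only.  Reported summaries are mean +/- sd across the five
rotations.  Terminal-region experiments re-train the pipeline separately
on the first 25 N-terminal residues, the last 25 C-terminal residues and
the middle of every sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .estimators import DisorderMetaClassifier
from .metrics import MetricReport, evaluate, is_defined
from .score_io import Dataset, ScoreProfile

N_FOLDS = 5
TEST_FRACTION = 0.2

#: Residues within this distance of a terminus form the N/C regions.
REGION_WINDOW = 25


class Region(Enum):
    N_TER = "n_ter"
    MID = "mid"
    C_TER = "c_ter"


class SplitError(RuntimeError):
    """Raised when no split satisfies the class-ratio tolerance."""


class LeakageError(RuntimeError):
    """Raised when test sequences overlap cross-validation folds."""


@dataclass
class SplitPlan:
    """Sequence-level assignment to the test set and the five folds."""

    test_ids: tuple[str, ...]
    folds: tuple[tuple[str, ...], ...]
    seed: int

    def __post_init__(self) -> None:
        groups = [set(self.test_ids)] + [set(f) for f in self.folds]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split groups are not pairwise disjoint")

    @property
    def train_ids(self) -> tuple[str, ...]:
        return tuple(s for f in self.folds for s in f)

    def rotation(self, i: int) -> tuple[list[str], list[str], list[str]]:
        """(train_ids, stop_ids, val_ids) for rotation ``i``.

        Fold ``i`` validates, fold ``(i+1) mod 5`` is the early-stop set,
        the remaining three folds train.
        """
        val = list(self.folds[i])
        stop = list(self.folds[(i + 1) % N_FOLDS])
        train = [s for j, f in enumerate(self.folds)
                 if j not in (i, (i + 1) % N_FOLDS) for s in f]
        return train, stop, val

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"test_ids": list(self.test_ids),
                       "folds": [list(f) for f in self.folds],
                       "seed": self.seed}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(tuple(obj["test_ids"]),
                   tuple(tuple(f) for f in obj["folds"]), obj["seed"])


def _pos_neg_ratio(dataset: Dataset, ids) -> float:
    sub = dataset.subset(ids)
    _, y = sub.stacked()
    pos = int(y.sum())
    neg = y.size - pos
    if neg == 0:
        return np.inf
    return pos / neg


def make_split(dataset: Dataset, seed: int, ratio_tol: float = 0.10,
               max_attempts: int = 1000) -> SplitPlan:
    """Random sequence-level split into test set and five folds.

    Rejection-resamples the shuffle until the disordered:structured
    residue ratios of the test and training sides agree within
    ``ratio_tol`` relative difference.
    """
    if not dataset.is_labelled:
        raise ValueError("make_split requires a labelled dataset")
    ids = [p.seq_id for p in dataset.profiles]
    if len(ids) < 2 * N_FOLDS:
        raise ValueError(f"need at least {2 * N_FOLDS} sequences")
    n_test = int(round(TEST_FRACTION * len(ids)))
    rng = np.random.default_rng(seed)
    best = (np.inf, None)
    for _ in range(max_attempts):
        order = [ids[i] for i in rng.permutation(len(ids))]
        test, rest = order[:n_test], order[n_test:]
        r_test = _pos_neg_ratio(dataset, test)
        r_train = _pos_neg_ratio(dataset, rest)
        if not (np.isfinite(r_test) and np.isfinite(r_train)) or r_train == 0:
            continue
        rel = abs(r_test - r_train) / r_train
        if rel < best[0]:
            best = (rel, (test, rest))
        if rel <= ratio_tol:
            folds = tuple(tuple(f) for f in np.array_split(rest, N_FOLDS))
            return SplitPlan(tuple(test), folds, seed)
    raise SplitError(
        f"no split within ratio tolerance {ratio_tol} after {max_attempts} "
        f"attempts; best achieved relative difference {best[0]:.3f}"
    )


def region_mask(profile: ScoreProfile, region: Region) -> np.ndarray:
    """Boolean mask of the residues of ``profile`` belonging to a region.

    N_TER and C_TER are the 25 residues nearest each terminus; for
    sequences shorter than 50, positions claimed by both termini go to
    the nearer one (ties to N_TER).  The three regions partition every
    sequence exactly.
    """
    nd = profile.n_terminal_distance
    cd = profile.c_terminal_distance
    in_n = nd <= REGION_WINDOW
    in_c = cd <= REGION_WINDOW
    n_sel = in_n & (~in_c | (nd <= cd))
    c_sel = in_c & ~n_sel
    if region is Region.N_TER:
        return n_sel
    if region is Region.C_TER:
        return c_sel
    return ~n_sel & ~c_sel


def _stack_ids(dataset: Dataset, ids, mask_fn=None):
    return dataset.subset(ids).stacked(mask_fn)


def summarize(reports: list[MetricReport]) -> pd.DataFrame:
    """Mean +/- sd of each scalar metric across rotations.

    Undefined (nan-marked) values are excluded from aggregation; ``n``
    counts the rotations where the metric was defined.
    """
    rows = []
    names = reports[0].scalars().keys()
    for name in names:
        vals = [r.scalars()[name] for r in reports]
        ok = [v for v in vals if is_defined(v)]
        rows.append({
            "metric": name,
            "mean": float(np.mean(ok)) if ok else float("nan"),
            "sd": float(np.std(ok, ddof=1)) if len(ok) > 1 else 0.0,
            "n": len(ok),
        })
    return pd.DataFrame(rows)


def run_crossval(dataset: Dataset, plan: SplitPlan, params: dict | None = None,
                 mask_fn=None):
    """Five-rotation cross-validation of the meta-predictor.

    ``params`` are :class:`DisorderMetaClassifier` keyword arguments;
    ``mask_fn`` optionally restricts the residues used for both training
    and validation (used for region experiments).  Returns
    ``(models, reports, summary)``: the five fitted classifiers, their
    validation-fold metric reports, and the mean/sd summary table.
    """
    params = dict(params or {})
    models, reports = [], []
    for i in range(N_FOLDS):
        train_ids, stop_ids, val_ids = plan.rotation(i)
        X_tr, y_tr = _stack_ids(dataset, train_ids, mask_fn)
        X_st, y_st = _stack_ids(dataset, stop_ids, mask_fn)
        X_va, y_va = _stack_ids(dataset, val_ids, mask_fn)
        clf = DisorderMetaClassifier(**params).fit(X_tr, y_tr, X_st, y_st)
        probs = clf.predict_proba(X_va)[:, 1]
        reports.append(evaluate(y_va, probs, clf.call_cutoff))
        models.append(clf)
    return models, reports, summarize(reports)


def run_independent_test(models, dataset: Dataset, plan: SplitPlan):
    """Evaluate the five cross-validation models on the held-out test set."""
    overlap = set(plan.test_ids) & set(plan.train_ids)
    if overlap:
        raise LeakageError(f"test sequences also present in folds: {sorted(overlap)}")
    X, y = _stack_ids(dataset, plan.test_ids)
    reports = []
    for clf in models:
        probs = clf.predict_proba(X)[:, 1]
        reports.append(evaluate(y, probs, clf.call_cutoff))
    return reports, summarize(reports)


def run_region_experiment(dataset: Dataset, plan: SplitPlan,
                          params: dict | None = None,
                          rotations: int = N_FOLDS) -> dict:
    """Re-train and cross-validate the pipeline per terminal region.

    Returns ``{region: (models, reports, summary)}``; a region whose
    training data is degenerate (single class or empty) is reported as
    ``{region: error}`` without aborting the others.  ``rotations``
    limits the number of cross-validation rotations run per region.
    """
    out: dict[Region, object] = {}
    for region in Region:
        mask = lambda p, r=region: region_mask(p, r)
        try:
            models, reports = [], []
            for i in range(rotations):
                train_ids, stop_ids, val_ids = plan.rotation(i)
                X_tr, y_tr = _stack_ids(dataset, train_ids, mask)
                if X_tr.shape[0] == 0:
                    raise ValueError(f"region {region.value}: no residues")
                X_st, y_st = _stack_ids(dataset, stop_ids, mask)
                X_va, y_va = _stack_ids(dataset, val_ids, mask)
                clf = DisorderMetaClassifier(**dict(params or {})).fit(
                    X_tr, y_tr, X_st, y_st)
                probs = clf.predict_proba(X_va)[:, 1]
                reports.append(evaluate(y_va, probs, clf.call_cutoff))
                models.append(clf)
            out[region] = (models, reports, summarize(reports))
        except ValueError as exc:
            out[region] = exc
    return out


def terminal_balanced_accuracy(dataset: Dataset, ids, predict_fn) -> float:
    """Balanced accuracy over terminal residues (<= 25 of either end).

    ``predict_fn(profile) -> calls`` supplies per-residue binary calls;
    region-specific predictors can thus be stitched per residue.
    """
    from .metrics import confusion_metrics

    labels, calls = [], []
    for p in dataset.subset(ids):
        m = region_mask(p, Region.N_TER) | region_mask(p, Region.C_TER)
        labels.append(p.labels[m])
        calls.append(np.asarray(predict_fn(p))[m])
    rep = confusion_metrics(np.concatenate(labels), np.concatenate(calls))
    return rep.acc_b
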