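"""Dual-threshold two-step significance-voting encoder.

Each residue carries one score per component predictor.  A channel votes
TRUE (disorder) at step ``k`` when its score reaches that step's true
cutoff, FALSE (structure) when it falls to the false cutoff, and abstains
inside the band.  Step 1 uses the stringent cutoffs; a tie sends the
residue to the laxer step-2 cutoffs; a second tie is resolved by
significance voting, which compares the summed distances of the TRUE-side
scores above their cutoffs (d_T) against the FALSE-side scores below
theirs (d_F) instead of counting votes.

The tree does not emit a label.  It determines the branch taken and the
branch-dependent 10-dimensional encoding consumed by the network:
signed step-1 and step-2 score-to-threshold differences per channel
(a1, a2; zero for abstaining channels) plus d_T and d_F.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .score_io import CHANNELS
from .thresholds import ThresholdSet

TRUE, FALSE, ABSTAIN = 1, -1, 0  # per-channel call codes


class Branch(Enum):
    """Terminal branch of the voting tree for one residue."""

    TRUE_MAJ_1 = "true_majority_step1"
    FALSE_MAJ_1 = "false_majority_step1"
    TRUE_MAJ_2 = "true_majority_step2"
    FALSE_MAJ_2 = "false_majority_step2"
    SIG_TRUE = "significance_true"
    SIG_FALSE = "significance_false"
    SIG_TIE = "significance_tie"


@dataclass
class VoteState:
    """Vote counts, distances and branch for one residue."""

    step: int
    n_true: int
    n_false: int
    branch: Branch
    d_true: float
    d_false: float


@dataclass
class EncodedSample:
    """The 10 network inputs: a1 (4), a2 (4), d_true, d_false."""

    a1: np.ndarray
    a2: np.ndarray
    d_true: float
    d_false: float

    def vector(self) -> np.ndarray:
        return np.concatenate([self.a1, self.a2, [self.d_true, self.d_false]])


def step_votes(scores, thresholds: ThresholdSet, step: int):
    """Per-channel calls at one voting step.

    Returns ``(n_true, n_false, calls)`` where ``calls`` holds 1 (TRUE),
    -1 (FALSE) or 0 (ABSTAIN) per channel: TRUE iff score >= t_true,
    FALSE iff score <= t_false.
    """
    scores = np.asarray(scores, float)
    if scores.shape != (len(CHANNELS),):
        raise ValueError(f"expected {len(CHANNELS)} scores, got {scores.shape}")
    t_true, t_false = thresholds.arrays(step)
    calls = np.where(scores >= t_true, TRUE, np.where(scores <= t_false, FALSE, ABSTAIN))
    return int((calls == TRUE).sum()), int((calls == FALSE).sum()), calls


def significance_vote(scores, thresholds: ThresholdSet):
    """Distance-based tie-break using the step-2 cutoffs.

    d_true sums ``score - t2_true`` over channels calling TRUE at step 2;
    d_false sums ``t2_false - score`` over channels calling FALSE.  Both
    sums are non-negative and zero when no channel is on that side.
    """
    scores = np.asarray(scores, float)
    _, _, calls = step_votes(scores, thresholds, step=2)
    t_true, t_false = thresholds.arrays(2)
    d_true = float(((scores - t_true)[calls == TRUE]).sum())
    d_false = float(((t_false - scores)[calls == FALSE]).sum())
    if d_true > d_false:
        branch = Branch.SIG_TRUE
    elif d_false > d_true:
        branch = Branch.SIG_FALSE
    else:
        branch = Branch.SIG_TIE
    return d_true, d_false, branch


def _signed_diffs(scores: np.ndarray, calls: np.ndarray, t_true: np.ndarray,
                  t_false: np.ndarray) -> np.ndarray:
    """a-values: score minus the cutoff the channel crossed, 0 on abstain."""
    return np.where(
        calls == TRUE, scores - t_true, np.where(calls == FALSE, scores - t_false, 0.0)
    )


def encode_residue(scores, thresholds: ThresholdSet) -> tuple[EncodedSample, VoteState]:
    """Run the voting tree for one residue and build its 10-vector.

    Step-1 majority decides TRUE_MAJ_1/FALSE_MAJ_1; on a tie the step-2
    majority decides; on a second tie significance voting decides.  The
    a1/a2 components are the signed threshold differences of each step's
    calls (TRUE channels sit above their cutoff, FALSE channels below,
    abstainers contribute 0); d_true/d_false always come from the step-2
    calls so the network sees the distance evidence on every branch.
    """
    scores = np.asarray(scores, float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")

    n1_true, n1_false, calls1 = step_votes(scores, thresholds, step=1)
    n2_true, n2_false, calls2 = step_votes(scores, thresholds, step=2)
    t1t, t1f = thresholds.arrays(1)
    t2t, t2f = thresholds.arrays(2)
    a1 = _signed_diffs(scores, calls1, t1t, t1f)
    a2 = _signed_diffs(scores, calls2, t2t, t2f)
    d_true = float(((scores - t2t)[calls2 == TRUE]).sum())
    d_false = float(((t2f - scores)[calls2 == FALSE]).sum())

    if n1_true != n1_false:
        step = 1
        n_true, n_false = n1_true, n1_false
        branch = Branch.TRUE_MAJ_1 if n1_true > n1_false else Branch.FALSE_MAJ_1
    elif n2_true != n2_false:
        step = 2
        n_true, n_false = n2_true, n2_false
        branch = Branch.TRUE_MAJ_2 if n2_true > n2_false else Branch.FALSE_MAJ_2
    else:
        step = 2
        n_true, n_false = n2_true, n2_false
        if d_true > d_false:
            branch = Branch.SIG_TRUE
        elif d_false > d_true:
            branch = Branch.SIG_FALSE
        else:
            branch = Branch.SIG_TIE

    sample = EncodedSample(a1=a1, a2=a2, d_true=d_true, d_false=d_false)
    state = VoteState(step=step, n_true=n_true, n_false=n_false, branch=branch,
                      d_true=d_true, d_false=d_false)
    return sample, state


def encode_matrix(X, thresholds: ThresholdSet) -> tuple[np.ndarray, list[Branch]]:
    """Vectorised encoding of an ``(n, 4)`` score matrix.

    Returns the ``(n, 10)`` feature matrix and the branch per residue.
    Equivalent to :func:`encode_residue` row by row, but in array form.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] != len(CHANNELS):
        raise ValueError(f"expected (n, {len(CHANNELS)}) scores, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("scores must be finite")
    t1t, t1f = thresholds.arrays(1)
    t2t, t2f = thresholds.arrays(2)

    def calls_for(tt, tf):
        return np.where(X >= tt, TRUE, np.where(X <= tf, FALSE, ABSTAIN))

    c1, c2 = calls_for(t1t, t1f), calls_for(t2t, t2f)
    a1 = np.where(c1 == TRUE, X - t1t, np.where(c1 == FALSE, X - t1f, 0.0))
    a2 = np.where(c2 == TRUE, X - t2t, np.where(c2 == FALSE, X - t2f, 0.0))
    d_true = np.where(c2 == TRUE, X - t2t, 0.0).sum(axis=1)
    d_false = np.where(c2 == FALSE, t2f - X, 0.0).sum(axis=1)
    feats = np.hstack([a1, a2, d_true[:, None], d_false[:, None]])

    n1t, n1f = (c1 == TRUE).sum(1), (c1 == FALSE).sum(1)
    n2t, n2f = (c2 == TRUE).sum(1), (c2 == FALSE).sum(1)
    branches = []
    for i in range(X.shape[0]):
        if n1t[i] != n1f[i]:
            branches.append(Branch.TRUE_MAJ_1 if n1t[i] > n1f[i] else Branch.FALSE_MAJ_1)
        elif n2t[i] != n2f[i]:
            branches.append(Branch.TRUE_MAJ_2 if n2t[i] > n2f[i] else Branch.FALSE_MAJ_2)
        elif d_true[i] > d_false[i]:
            branches.append(Branch.SIG_TRUE)
        elif d_false[i] > d_true[i]:
            branches.append(Branch.SIG_FALSE)
        else:
            branches.append(Branch.SIG_TIE)
    return feats, branches
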