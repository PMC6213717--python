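"""The dual-threshold two-step significance-voting tree and its encoding."""

import itertools

import numpy as np
import pytest

from disvote.encoder import (ABSTAIN, FALSE, TRUE, Branch, encode_matrix,
                             encode_residue, significance_vote, step_votes)
from disvote.thresholds import ChannelThresholds, ThresholdSet


def straight_line_encode(scores, ts):
    """Independent re-implementation of the tree, one branch at a time.

    Deliberately scalar and explicit; kept free of any code shared with
    the production encoder.
    """
    quads = [ts.channels[c] for c in "DIVE"]

    def call(s, t_true, t_false):
        if s >= t_true:
            return "T"
        if s <= t_false:
            return "F"
        return "A"

    c1 = [call(s, q.t1_true, q.t1_false) for s, q in zip(scores, quads)]
    c2 = [call(s, q.t2_true, q.t2_false) for s, q in zip(scores, quads)]
    a1 = []
    for s, q, c in zip(scores, quads, c1):
        a1.append(s - q.t1_true if c == "T" else s - q.t1_false if c == "F" else 0.0)
    a2 = []
    for s, q, c in zip(scores, quads, c2):
        a2.append(s - q.t2_true if c == "T" else s - q.t2_false if c == "F" else 0.0)
    d_t = sum(s - q.t2_true for s, q, c in zip(scores, quads, c2) if c == "T")
    d_f = sum(q.t2_false - s for s, q, c in zip(scores, quads, c2) if c == "F")

    n1t, n1f = c1.count("T"), c1.count("F")
    n2t, n2f = c2.count("T"), c2.count("F")
    if n1t > n1f:
        branch = Branch.TRUE_MAJ_1
    elif n1f > n1t:
        branch = Branch.FALSE_MAJ_1
    elif n2t > n2f:
        branch = Branch.TRUE_MAJ_2
    elif n2f > n2t:
        branch = Branch.FALSE_MAJ_2
    elif d_t > d_f:
        branch = Branch.SIG_TRUE
    elif d_f > d_t:
        branch = Branch.SIG_FALSE
    else:
        branch = Branch.SIG_TIE
    return a1 + a2 + [d_t, d_f], branch


class TestStepVotes:
    def test_all_above_t1_true(self, symmetric_thresholds):
        n_t, n_f, calls = step_votes([0.9] * 4, symmetric_thresholds, 1)
        assert (n_t, n_f) == (4, 0) and (calls == TRUE).all()

    def test_all_inside_band_abstain(self, symmetric_thresholds):
        n_t, n_f, calls = step_votes([0.5, 0.45, 0.55, 0.5], symmetric_thresholds, 1)
        assert (n_t, n_f) == (0, 0) and (calls == ABSTAIN).all()

    def test_two_versus_two(self, symmetric_thresholds):
        n_t, n_f, calls = step_votes([0.95, 0.05, 0.95, 0.05], symmetric_thresholds, 1)
        assert (n_t, n_f) == (2, 2)
        assert list(calls) == [TRUE, FALSE, TRUE, FALSE]

    def test_boundary_scores_are_calls_not_abstentions(self, symmetric_thresholds):
        n_t, n_f, calls = step_votes([0.8, 0.2, 0.8, 0.2], symmetric_thresholds, 1)
        assert (n_t, n_f) == (2, 2)


class TestSignificanceVote:
    def test_distance_sums(self, symmetric_thresholds):
        # two TRUE channels 0.2 above t2_true, two FALSE 0.1 below t2_false
        d_t, d_f, branch = significance_vote([0.8, 0.3, 0.8, 0.3],
                                             symmetric_thresholds)
        assert d_t == pytest.approx(0.4)
        assert d_f == pytest.approx(0.2)
        assert branch is Branch.SIG_TRUE

    def test_symmetric_distances_tie(self, symmetric_thresholds):
        d_t, d_f, branch = significance_vote([0.9, 0.1, 0.9, 0.1],
                                             symmetric_thresholds)
        assert d_t == pytest.approx(d_f)
        assert branch is Branch.SIG_TIE

    def test_zero_zero_tie(self, symmetric_thresholds):
        d_t, d_f, branch = significance_vote([0.5] * 4, symmetric_thresholds)
        assert d_t == d_f == 0.0 and branch is Branch.SIG_TIE


class TestEncodeResidue:
    def test_unanimous_high_scores(self, symmetric_thresholds):
        sample, state = encode_residue([0.9, 0.95, 0.85, 0.9], symmetric_thresholds)
        assert state.branch is Branch.TRUE_MAJ_1
        assert (sample.a1 > 0).all() and sample.d_false == 0.0

    def test_all_abstain_encodes_to_zeros(self, symmetric_thresholds):
        sample, state = encode_residue([0.5] * 4, symmetric_thresholds)
        np.testing.assert_array_equal(sample.vector(), np.zeros(10))
        assert state.branch is Branch.SIG_TIE

    def test_two_two_configuration_full_vector(self, symmetric_thresholds):
        """2-2 tie at both steps, resolved by distances; hand-enumerated."""
        scores = [0.85, 0.15, 0.65, 0.35]
        sample, state = encode_residue(scores, symmetric_thresholds)
        # step 1: channels 0 (0.85>=0.8 TRUE) and 1 (0.15<=0.2 FALSE); 1-1 tie
        # step 2: 0,2 TRUE (>=0.6); 1,3 FALSE (<=0.4); 2-2 tie
        # d_t = (0.85-0.6)+(0.65-0.6)=0.30; d_f = (0.4-0.15)+(0.4-0.35)=0.30
        assert state.branch is Branch.SIG_TIE
        np.testing.assert_allclose(
            sample.vector(),
            [0.05, -0.05, 0.0, 0.0,
             0.25, -0.25, 0.05, -0.05,
             0.30, 0.30],
            atol=1e-12)

    def test_nan_score_rejected(self, symmetric_thresholds):
        with pytest.raises(ValueError, match="finite"):
            encode_residue([0.5, np.nan, 0.5, 0.5], symmetric_thresholds)


@pytest.fixture
def asymmetric_thresholds():
    return ThresholdSet({
        "D": ChannelThresholds(0.85, 0.60, 0.35, 0.10),
        "I": ChannelThresholds(0.80, 0.65, 0.40, 0.20),
        "V": ChannelThresholds(0.90, 0.70, 0.30, 0.15),
        "E": ChannelThresholds(0.75, 0.55, 0.45, 0.25),
    })


def test_exhaustive_grid_matches_straight_line_reimplementation(
        asymmetric_thresholds):
    """All 5^4 score combinations agree exactly with the independent
    scalar re-implementation of the tree."""
    grid = [0.0, 0.25, 0.5, 0.75, 1.0]
    combos = list(itertools.product(grid, repeat=4))
    X = np.array(combos)
    feats, branches = encode_matrix(X, asymmetric_thresholds)
    for i, scores in enumerate(combos):
        vec_o, branch_o = straight_line_encode(list(scores), asymmetric_thresholds)
        np.testing.assert_array_equal(feats[i], vec_o)
        assert branches[i] is branch_o
        sample, state = encode_residue(scores, asymmetric_thresholds)
        np.testing.assert_array_equal(sample.vector(), vec_o)
        assert state.branch is branch_o


def test_branch_partition_counts(asymmetric_thresholds):
    """Exactly one branch per residue over a random dataset."""
    rng = np.random.default_rng(9)
    X = rng.uniform(size=(5000, 4))
    _, branches = encode_matrix(X, asymmetric_thresholds)
    counts = {b: 0 for b in Branch}
    for b in branches:
        counts[b] += 1
    assert sum(counts.values()) == 5000


def test_monotonicity_in_single_channel(asymmetric_thresholds):
    """Raising one channel's score never decreases its a1/a2 or d_true,
    never increases d_false."""
    rng = np.random.default_rng(10)
    for _ in range(200):
        scores = rng.uniform(size=4)
        ch = int(rng.integers(4))
        bumped = scores.copy()
        bumped[ch] = min(1.0, bumped[ch] + rng.uniform(0, 0.5))
        lo, _ = encode_residue(scores, asymmetric_thresholds)
        hi, _ = encode_residue(bumped, asymmetric_thresholds)
        assert hi.a1[ch] >= lo.a1[ch] - 1e-12
        assert hi.a2[ch] >= lo.a2[ch] - 1e-12
        assert hi.d_true >= lo.d_true - 1e-12
        assert hi.d_false <= lo.d_false + 1e-12


def test_scaling_one_channel(asymmetric_thresholds):
    """Scaling a channel's scores and thresholds by c > 0 scales that
    channel's contributions by c (no hidden normalization)."""
    c = 3.7
    quads = dict(asymmetric_thresholds.channels)
    q = quads["V"]
    quads["V"] = ChannelThresholds(c * q.t1_true, c * q.t2_true,
                                   c * q.t2_false, c * q.t1_false)
    scaled_ts = ThresholdSet(quads)
    rng = np.random.default_rng(11)
    for _ in range(100):
        scores = rng.uniform(size=4)
        scaled = scores.copy()
        scaled[2] *= c
        base, _ = encode_residue(scores, asymmetric_thresholds)
        out, _ = encode_residue(scaled, scaled_ts)
        assert out.a1[2] == pytest.approx(c * base.a1[2], abs=1e-12)
        assert out.a2[2] == pytest.approx(c * base.a2[2], abs=1e-12)
        np.testing.assert_allclose(np.delete(out.a1, 2), np.delete(base.a1, 2))
        np.testing.assert_allclose(np.delete(out.a2, 2), np.delete(base.a2, 2))
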