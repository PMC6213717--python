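"""Information-gain curves and dual-threshold selection.

Each component-predictor channel scores disorder high, so a cutoff ``x``
splits residues into a putative-disorder group (score >= x) and a
putative-structure group (score < x).  The information gain of the split is
the reduction in label entropy (in bits):

    IG(x) = H(labels) - f_hi(x) H(labels | score >= x)
                      - f_lo(x) H(labels | score < x)

The IG curve over a score grid is single-peaked for a useful channel; the
peak location is the score that best partitions disordered from structured
residues and anchors the dual thresholds.  The step-``k`` true/false
cutoffs are the outermost grid points around the peak where
``IG >= step_k_frac * IG(peak)``: the right edge is the true-call
threshold, the left edge the false-call threshold.  Step 1 uses the
*lower* fraction, so its band is wider and its calls more stringent
(a TRUE call needs a score beyond the far edge of the high-IG region);
step 2 uses the higher fraction and is laxer.  Hence the ordering

    t1_true >= t2_true >= peak >= t2_false >= t1_false
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .score_io import CHANNELS, Dataset

#: Grid points where IG collapses below this are treated as flat (no signal).
FLAT_EPS = 1e-6


class DegenerateChannelError(ValueError):
    """Raised when a channel's IG curve carries no label signal."""


@dataclass
class InfoGainCurve:
    """Information gain as a function of score threshold for one channel."""

    channel: str
    grid: np.ndarray
    ig: np.ndarray
    p_pos: np.ndarray  # fraction of positive samples scoring >= x
    p_neg: np.ndarray  # fraction of negative samples scoring >= x

    @property
    def peak(self) -> float:
        """Grid score maximizing IG; ties broken toward the smaller score."""
        return float(self.grid[int(np.argmax(self.ig))])

    @property
    def peak_ig(self) -> float:
        return float(self.ig.max())


@dataclass
class ChannelThresholds:
    """Step-1 (stringent) and step-2 (lax) true/false cutoffs for a channel."""

    t1_true: float
    t2_true: float
    t2_false: float
    t1_false: float

    def __post_init__(self) -> None:
        if not (self.t1_true >= self.t2_true >= self.t2_false >= self.t1_false):
            raise ValueError(
                "threshold ordering violated: need "
                "t1_true >= t2_true >= t2_false >= t1_false, got "
                f"{self.t1_true}, {self.t2_true}, {self.t2_false}, {self.t1_false}"
            )

    def for_step(self, step: int) -> tuple[float, float]:
        """(true, false) cutoffs for voting step 1 or 2."""
        if step == 1:
            return self.t1_true, self.t1_false
        if step == 2:
            return self.t2_true, self.t2_false
        raise ValueError(f"step must be 1 or 2, got {step}")


@dataclass
class ThresholdSet:
    """Per-channel dual-threshold quadruples, in channel order."""

    channels: dict[str, ChannelThresholds]

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"thresholds missing for channels {missing}")

    def arrays(self, step: int) -> tuple[np.ndarray, np.ndarray]:
        """(t_true, t_false) 4-vectors for a step, channel order."""
        t = np.array([self.channels[c].for_step(step)[0] for c in CHANNELS])
        f = np.array([self.channels[c].for_step(step)[1] for c in CHANNELS])
        return t, f

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "channel": c,
                    "t1_true": self.channels[c].t1_true,
                    "t2_true": self.channels[c].t2_true,
                    "t2_false": self.channels[c].t2_false,
                    "t1_false": self.channels[c].t1_false,
                }
                for c in CHANNELS
            ]
        )

    @classmethod
    def from_frame(cls, df) -> "ThresholdSet":
        return cls(
            {
                row["channel"]: ChannelThresholds(
                    row["t1_true"], row["t2_true"], row["t2_false"], row["t1_false"]
                )
                for _, row in df.iterrows()
            }
        )


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector; 0 log 0 = 0."""
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def information_gain(labels, scores, x: float) -> float:
    """Information gain (bits) of splitting at ``score >= x``.

    Both classes must be present; an empty side of the split contributes
    zero weighted entropy, so ``x`` outside the score range gives IG = 0.
    """
    labels = np.asarray(labels, int)
    scores = np.asarray(scores, float)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    n_pos = int((labels == 1).sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("both classes required to define label entropy")

    parent = _entropy(np.array([n_pos, labels.size - n_pos]))
    hi = scores >= x
    ig = parent
    for side in (hi, ~hi):
        m = side.sum()
        if m:
            k = int((labels[side] == 1).sum())
            ig -= (m / labels.size) * _entropy(np.array([k, m - k]))
    # clip the tiny negative round-off that exact-zero gains can produce
    return max(ig, 0.0)


def ig_curve(dataset_or_labels, channel_or_scores=None, grid_size: int = 201,
             *, channel_name: str | None = None) -> InfoGainCurve:
    """Information-gain curve over an even score grid.

    Accepts either ``(dataset, channel_name)`` — using every labelled
    residue of that channel — or raw ``(labels, scores)`` arrays.  Also
    returns the fractions of positive and negative samples at or above
    each grid score (the sample-distribution curves IG is compared with).
    """
    if isinstance(dataset_or_labels, Dataset):
        ds = dataset_or_labels
        if not ds.is_labelled:
            raise ValueError("ig_curve requires a labelled dataset")
        ch = channel_or_scores
        idx = list(CHANNELS).index(ch)
        X, y = ds.stacked()
        scores, labels = X[:, idx], y
        name = ch
    else:
        labels = np.asarray(dataset_or_labels, int)
        scores = np.asarray(channel_or_scores, float)
        name = channel_name or "scores"
    if grid_size < 3:
        raise ValueError(f"grid_size must be >= 3, got {grid_size}")

    grid = np.linspace(scores.min(), scores.max(), grid_size)
    ig = np.array([information_gain(labels, scores, x) for x in grid])
    pos, neg = scores[labels == 1], scores[labels == 0]
    p_pos = np.array([(pos >= x).mean() for x in grid])
    p_neg = np.array([(neg >= x).mean() for x in grid])
    return InfoGainCurve(name, grid, ig, p_pos, p_neg)


def select_thresholds(curve: InfoGainCurve, step1_frac: float = 0.6,
                      step2_frac: float = 0.9) -> ChannelThresholds:
    """Derive the dual-threshold quadruple from an IG curve.

    The step-k band is the outermost contiguous run of grid points around
    the peak where ``IG >= step_k_frac * IG(peak)``; its right edge is
    the true-call threshold, its left edge the false-call threshold.
    Step 1 must use the smaller fraction (wider band, stringent calls):
    ``0 < step1_frac < step2_frac < 1``.
    """
    if not 0 < step1_frac < step2_frac < 1:
        raise ValueError(
            f"need 0 < step1_frac < step2_frac < 1, got "
            f"({step1_frac}, {step2_frac})"
        )
    if curve.peak_ig < FLAT_EPS:
        raise DegenerateChannelError(
            f"channel {curve.channel!r}: flat IG curve "
            f"(max {curve.peak_ig:.2e} bits)"
        )
    i_peak = int(np.argmax(curve.ig))

    def band_edges(frac: float) -> tuple[float, float]:
        level = frac * curve.peak_ig
        ok = curve.ig >= level
        lo = i_peak
        while lo > 0 and ok[lo - 1]:
            lo -= 1
        hi = i_peak
        while hi < len(ok) - 1 and ok[hi + 1]:
            hi += 1
        return float(curve.grid[hi]), float(curve.grid[lo])  # (true, false)

    t1_true, t1_false = band_edges(step1_frac)
    t2_true, t2_false = band_edges(step2_frac)
    return ChannelThresholds(t1_true, t2_true, t2_false, t1_false)


def fit_thresholds(dataset: Dataset, step1_frac: float = 0.6,
                   step2_frac: float = 0.9, grid_size: int = 201
                   ) -> tuple[ThresholdSet, dict[str, InfoGainCurve]]:
    """IG curves and threshold quadruples for all four channels."""
    curves = {c: ig_curve(dataset, c, grid_size) for c in CHANNELS}
    ts = ThresholdSet(
        {c: select_thresholds(curves[c], step1_frac, step2_frac) for c in CHANNELS}
    )
    return ts, curves
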