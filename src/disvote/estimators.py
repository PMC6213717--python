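"""Scikit-learn-style estimators wrapping the meta-prediction pipeline.

``ThresholdVoteEncoder`` is a transformer: it learns the per-channel
information-gain thresholds from labelled scores and transforms raw
``(n, 4)`` score matrices into the 10-dimensional vote encoding.
``TanhSoftmaxNetClassifier`` is the 10-20-20-2 network as a classifier on
encoded features.  ``DisorderMetaClassifier`` chains the two and is the
object most users want: ``fit`` on per-residue scores and labels,
``predict_proba`` for disorder probabilities.

All three follow scikit-learn conventions (``get_params``/``set_params``,
fitted attributes with trailing underscores, ``check_is_fitted``) and
compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import network as net
from .encoder import encode_matrix
from .score_io import CHANNELS
from .thresholds import ThresholdSet, ig_curve, select_thresholds


def _check_scores(X) -> np.ndarray:
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] != len(CHANNELS):
        raise ValueError(f"expected (n, {len(CHANNELS)}) score matrix, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("scores must be finite")
    return X


class ThresholdVoteEncoder(TransformerMixin, BaseEstimator):
    """Learn IG dual thresholds and encode scores into vote features.

    Parameters
    ----------
    step1_frac, step2_frac : float
        Fractional IG-peak heights defining the step-1/step-2 threshold
        bands (``0 < step1_frac < step2_frac < 1``; the step-1 band is
        wider, so its calls are more stringent).
    grid_size : int
        Number of grid points for the information-gain curves.

    Attributes
    ----------
    thresholds_ : ThresholdSet
        Per-channel dual-threshold quadruples.
    curves_ : dict
        Per-channel :class:`~disvote.thresholds.InfoGainCurve`.
    """

    def __init__(self, step1_frac: float = 0.6, step2_frac: float = 0.9,
                 grid_size: int = 201):
        self.step1_frac = step1_frac
        self.step2_frac = step2_frac
        self.grid_size = grid_size

    def fit(self, X, y):
        X = _check_scores(X)
        y = np.asarray(y, int)
        self.curves_ = {
            c: ig_curve(y, X[:, i], self.grid_size, channel_name=c)
            for i, c in enumerate(CHANNELS)
        }
        self.thresholds_ = ThresholdSet(
            {c: select_thresholds(curve, self.step1_frac, self.step2_frac)
             for c, curve in self.curves_.items()}
        )
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        feats, _ = encode_matrix(_check_scores(X), self.thresholds_)
        return feats

    def branches(self, X):
        """Voting-tree branch taken by each residue."""
        check_is_fitted(self, "thresholds_")
        _, branches = encode_matrix(_check_scores(X), self.thresholds_)
        return branches


class TanhSoftmaxNetClassifier(ClassifierMixin, BaseEstimator):
    """The fixed 10-20-20-2 tanh/softmax network as a classifier.

    Early stopping monitors a stop set passed to ``fit`` as
    ``stop_X``/``stop_y``; without one, a fraction ``stop_fraction`` of
    the training data is split off (deterministically per
    ``random_state``).
    """

    def __init__(self, learning_rate: float = 0.01, momentum: float = 0.9,
                 batch_size: int = 128, max_epochs: int = 2000,
                 patience: int = 50, class_weights=None,
                 stop_fraction: float = 0.1, random_state: int = 0):
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.class_weights = class_weights
        self.stop_fraction = stop_fraction
        self.random_state = random_state

    def _config(self) -> net.TrainConfig:
        return net.TrainConfig(
            learning_rate=self.learning_rate, momentum=self.momentum,
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            # effective patience can never exceed the epoch budget
            patience=min(self.patience, self.max_epochs),
            seed=self.random_state,
            class_weights=self.class_weights,
        )

    def fit(self, X, y, stop_X=None, stop_y=None):
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training data must contain both classes")
        if stop_X is None:
            rng = np.random.default_rng(self.random_state)
            idx = rng.permutation(len(y))
            n_stop = max(1, int(round(self.stop_fraction * len(y))))
            stop_idx, train_idx = idx[:n_stop], idx[n_stop:]
            X, stop_X = X[train_idx], X[stop_idx]
            y, stop_y = y[train_idx], y[stop_idx]
        self.model_ = net.train(X, y, stop_X, stop_y, self._config())
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.forward(np.asarray(X, float))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class DisorderMetaClassifier(ClassifierMixin, BaseEstimator):
    """Dual-threshold significance-voting meta-predictor.

    Combines four component disorder-predictor score channels: learns
    per-channel information-gain thresholds, encodes every residue with
    the two-step significance-voting tree, and trains the two-hidden-
    layer network on the encoding.  ``X`` is the raw ``(n, 4)`` score
    matrix; ``y`` the per-residue disorder labels.

    Attributes
    ----------
    encoder_ : ThresholdVoteEncoder
    net_ : TanhSoftmaxNetClassifier
    classes_ : ndarray
    """

    def __init__(self, step1_frac: float = 0.6, step2_frac: float = 0.9,
                 grid_size: int = 201, learning_rate: float = 0.01,
                 momentum: float = 0.9, batch_size: int = 128,
                 max_epochs: int = 2000, patience: int = 50,
                 class_weights=None, stop_fraction: float = 0.1,
                 call_cutoff: float = 0.5, random_state: int = 0):
        self.step1_frac = step1_frac
        self.step2_frac = step2_frac
        self.grid_size = grid_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.class_weights = class_weights
        self.stop_fraction = stop_fraction
        self.call_cutoff = call_cutoff
        self.random_state = random_state

    def fit(self, X, y, stop_X=None, stop_y=None):
        X = _check_scores(X)
        y = np.asarray(y, int)
        self.encoder_ = ThresholdVoteEncoder(
            self.step1_frac, self.step2_frac, self.grid_size
        ).fit(X, y)
        enc_stop = None
        if stop_X is not None:
            enc_stop = self.encoder_.transform(_check_scores(stop_X))
        self.net_ = TanhSoftmaxNetClassifier(
            learning_rate=self.learning_rate, momentum=self.momentum,
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            patience=self.patience, class_weights=self.class_weights,
            stop_fraction=self.stop_fraction, random_state=self.random_state,
        ).fit(self.encoder_.transform(X), y, enc_stop, stop_y)
        self.classes_ = self.net_.classes_
        return self

    @property
    def thresholds_(self) -> ThresholdSet:
        check_is_fitted(self, "encoder_")
        return self.encoder_.thresholds_

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(self.encoder_.transform(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.call_cutoff).astype(int)
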