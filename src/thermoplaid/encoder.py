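"""Swim-probability encoding model.

Builds history-design inputs (a strictly causal 1 s temperature history and
1 s bout-end history per 40 ms bin), trains the convolutional network of
:mod:`thermoplaid.nnet` to classify bins into swim/non-swim with binary
cross-entropy, provides the circular-permutation null control, and evaluates
classification (ROC-AUC) and calibration (QQ of predicted probability vs
empirical bout proportion).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .bouts import BoutEvent
from .nnet import MLP, NetSpec
from .simulate import Experiment, POLICY_RATE_HZ


@dataclass
class DesignInputs:
    """Per-bin design matrices for the swim-probability network.

    History convention: column 0 is the most recent bin (lag 40 ms), the last
    column the oldest.  Histories are strictly causal -- no column overlaps
    the bin carrying the label.
    """

    temp_hist: np.ndarray  # samples x H, degC
    bout_hist: np.ndarray  # samples x H, binary bout-end indicator
    labels: np.ndarray  # binary: bout start in the current bin
    exp_ids: np.ndarray  # experiment id per sample
    bin_rate_hz: float = POLICY_RATE_HZ

    @property
    def n_history(self) -> int:
        return self.temp_hist.shape[1]

    @property
    def features(self) -> np.ndarray:
        """Concatenated (temperature, bout) history, samples x 2H."""
        return np.hstack([self.temp_hist, self.bout_hist])


def _trailing_history(series: np.ndarray, n_hist: int) -> np.ndarray:
    """Rows t = n_hist .. len-1; row i, column j holds series[t - 1 - j]."""
    win = np.lib.stride_tricks.sliding_window_view(series, n_hist)[:-1]
    return win[:, ::-1]


def build_inputs(
    experiments: Sequence[Experiment],
    bouts_per_experiment: Sequence[Sequence[BoutEvent]],
    bin_rate_hz: float = POLICY_RATE_HZ,
    history_s: float = 1.0,
) -> DesignInputs:
    """Assemble design matrices from experiments and their (filtered) bouts.

    One sample per 40 ms bin, starting at the first bin with a full history.
    Temperature is averaged within bins; the bout channel marks bins
    containing a bout end; the label marks bins containing a bout start.
    """
    n_hist = int(round(history_s * bin_rate_hz))
    frames_per_bin = int(round(250.0 / bin_rate_hz))
    th, bh, ys, ids = [], [], [], []
    for exp, bouts in zip(experiments, bouts_per_experiment):
        n_bins = exp.temperature.size // frames_per_bin
        if n_bins <= n_hist:
            raise ValueError("history window longer than the experiment")
        temp_bin = exp.temperature[: n_bins * frames_per_bin].reshape(n_bins, -1).mean(axis=1)
        start_raster = np.zeros(n_bins)
        end_raster = np.zeros(n_bins)
        for b in bouts:
            sb = b.start_frame // frames_per_bin
            eb = b.end_frame // frames_per_bin
            if sb < n_bins:
                start_raster[sb] = 1.0
            if eb < n_bins:
                end_raster[eb] = 1.0
        th.append(_trailing_history(temp_bin, n_hist))
        bh.append(_trailing_history(end_raster, n_hist))
        ys.append(start_raster[n_hist:])
        ids.append(np.full(n_bins - n_hist, exp.exp_id, dtype=object))
    return DesignInputs(
        temp_hist=np.vstack(th),
        bout_hist=np.vstack(bh),
        labels=np.concatenate(ys),
        exp_ids=np.concatenate(ids),
        bin_rate_hz=bin_rate_hz,
    )


def circular_permutation_control(
    inputs: DesignInputs, shift_fraction: float = 1.0 / 3.0
) -> DesignInputs:
    """Rotate labels relative to the inputs within each experiment.

    Destroys the input-output coupling while preserving both marginals and
    the autocorrelation structure; used as the null control for receptive
    fields.  The label counts are conserved exactly.
    """
    labels = inputs.labels.copy()
    for eid in np.unique(inputs.exp_ids):
        sel = inputs.exp_ids == eid
        n = int(sel.sum())
        shift = int(round(n * shift_fraction)) % n
        if shift == 0:
            raise ValueError("shift of zero bins would be the identity")
        labels[sel] = np.roll(labels[sel], shift)
    return replace(inputs, labels=labels)


@dataclass
class EncoderSpec:
    """Training configuration for the swim-probability network."""

    net: NetSpec = field(default_factory=NetSpec)
    train_fraction: float = 0.8


@dataclass
class EncoderModel:
    """A trained network plus the standardization and split it was fit with."""

    net: MLP
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    p_bar: float  # empirical bout-start probability per bin on the training split
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    @property
    def trained(self) -> bool:
        return self.net.trained

    @property
    def loss_history(self) -> list[float]:
        return self.net.loss_history

    def predict_logit(self, features: np.ndarray) -> np.ndarray:
        z = (np.asarray(features, dtype=float) - self.feature_mean) / self.feature_sd
        return self.net.predict_logit(z)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return expit(self.predict_logit(features))

    def input_gradient(self, features: np.ndarray) -> np.ndarray:
        """d(log-odds)/d(input) in natural units (per degC / per bout event)."""
        z = (np.asarray(features, dtype=float) - self.feature_mean) / self.feature_sd
        return self.net.input_gradient(z) / self.feature_sd


def _contiguous_split(inputs: DesignInputs, train_fraction: float, rng):
    """Per-experiment contiguous held-out block at a seed-dependent offset."""
    train_mask = np.ones(inputs.labels.size, dtype=bool)
    for eid in np.unique(inputs.exp_ids):
        sel = np.flatnonzero(inputs.exp_ids == eid)
        n = sel.size
        n_test = max(1, int(round(n * (1.0 - train_fraction))))
        start = int(rng.integers(0, n - n_test + 1))
        train_mask[sel[start:start + n_test]] = False
    return np.flatnonzero(train_mask), np.flatnonzero(~train_mask)


def train_encoder(
    inputs: DesignInputs,
    spec: EncoderSpec | None = None,
    seed: int = 0,
) -> EncoderModel:
    """Fit the network on an 80/20 contiguous per-experiment split.

    The seed controls the weight initialization, dropout masks, batch order
    and the placement of the held-out block, so repeated fits sample the
    distribution of solutions; identical seeds give identical models.
    """
    spec = spec or EncoderSpec()
    y = np.asarray(inputs.labels, dtype=float)
    if y.min() == y.max():
        raise ValueError("labels are single-class; nothing to fit")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = _contiguous_split(inputs, spec.train_fraction, rng)
    feats = inputs.features
    mean = feats[train_idx].mean(axis=0)
    sd = feats[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    net_spec = replace(spec.net, n_inputs=feats.shape[1])
    net = MLP(net_spec, seed=int(rng.integers(2**31)))
    # start the output at the base-rate log-odds: with the rare bout class the
    # network otherwise spends training pushing the dense data region down,
    # leaving spurious positive gradients along sparse input directions
    p0 = float(np.clip(y[train_idx].mean(), 1e-6, 1 - 1e-6))
    net.biases[3][:] = np.log(p0 / (1 - p0))
    net.fit((feats[train_idx] - mean) / sd, y[train_idx], seed=int(rng.integers(2**31)))
    return EncoderModel(
        net=net,
        feature_mean=mean,
        feature_sd=sd,
        p_bar=float(y[train_idx].mean()),
        train_idx=train_idx,
        test_idx=test_idx,
        seed=seed,
    )


def evaluate_roc_auc(
    model: EncoderModel, inputs: DesignInputs, idx: np.ndarray | None = None
) -> float:
    """Held-out ROC-AUC of classifying bins into swim vs non-swim.

    Defaults to the model's own held-out block.  Ties count one half, so a
    constant score gives exactly 0.5.
    """
    if idx is None:
        idx = model.test_idx
    y = inputs.labels[idx]
    if y.min() == y.max():
        raise ValueError("held-out set contains a single class")
    scores = model.predict_logit(inputs.features[idx])
    return float(roc_auc_score(y, scores))


def calibration_qq(
    model: EncoderModel,
    inputs: DesignInputs,
    n_bins: int = 10,
    idx: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted-probability bin centers vs empirical bout proportions.

    Samples are split into ``n_bins`` equal-count bins of predicted
    probability.  Returns (bin centers = mean predicted p, empirical
    proportion, bin counts); empty bins are NaN, not zero.  Perfect
    calibration lies on the identity line.
    """
    if not model.trained:
        raise ValueError("model is untrained")
    if idx is None:
        idx = np.arange(inputs.labels.size)
    p = model.predict_proba(inputs.features[idx])
    y = inputs.labels[idx]
    edges = np.quantile(p, np.linspace(0, 1, n_bins + 1))
    which = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, n_bins - 1)
    centers = np.full(n_bins, np.nan)
    props = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for k in range(n_bins):
        sel = which == k
        counts[k] = sel.sum()
        if counts[k]:
            centers[k] = p[sel].mean()
            props[k] = y[sel].mean()
    return centers, props, counts
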