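"""Receptive fields by network differentiation and their behavioral effects.

The trained swim-probability network is differentiated with respect to its
inputs -- the analogue of a spike-triggered average that remains valid for
strongly autocorrelated, self-generated stimuli.  The temperature-history
coefficients k (log-odds per degC at each lag) are converted into
bout-frequency modulation through the logistic transform around the mean
bout probability:

    dlp(t) = k . (s(t) - s_mean)
    lp_mean = log(p_mean / (1 - p_mean))
    dp(t) = logistic(dlp(t) + lp_mean) - p_mean
    dbf(t) = dp(t) * 25 / s

where p_mean is the empirical per-bin bout probability and the 25/s factor
converts per-40 ms-bin probability into bouts per second.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import ranksums, wilcoxon

from .encoder import DesignInputs, EncoderModel, _trailing_history
from .simulate import POLICY_RATE_HZ


@dataclass
class ReceptiveField:
    """Temperature and bout-history coefficient vectors plus the expansion point.

    ``temp_coeffs[j]`` is the change in swim log-odds per degC of temperature
    at lag ``lags_s[j]``; positive means warmer past temperature at that lag
    promotes swim initiation.  ``p_bar`` is the mean per-bin bout probability
    at the expansion point.
    """

    temp_coeffs: np.ndarray
    bout_coeffs: np.ndarray
    temp_mean: np.ndarray  # mean temperature history (degC) at each lag
    bout_mean: np.ndarray
    p_bar: float
    bin_rate_hz: float = POLICY_RATE_HZ

    def __post_init__(self) -> None:
        if not 0.0 < self.p_bar < 1.0:
            raise ValueError("mean bout probability must lie strictly in (0, 1)")

    @property
    def lags_s(self) -> np.ndarray:
        return (np.arange(self.temp_coeffs.size) + 1) / self.bin_rate_hz

    @property
    def lp_bar(self) -> float:
        """Mean log-odds, log(p_bar / (1 - p_bar))."""
        return float(np.log(self.p_bar / (1.0 - self.p_bar)))


@dataclass
class RFEffect:
    """Stimulus-driven modulation of bout probability and frequency."""

    delta_logp: np.ndarray  # change in log-odds vs the mean
    delta_p: np.ndarray  # change in per-bin bout probability
    delta_bf_hz: np.ndarray  # change in bout frequency, bouts/s
    bin_rate_hz: float = POLICY_RATE_HZ


def extract_rf(
    model: EncoderModel,
    inputs: DesignInputs,
    n_eval_samples: int = 10_000,
    seed: int | None = 0,
) -> ReceptiveField:
    """Average the network's input gradient over a random sample of data points.

    The gradient of the scalar log-odds output with respect to each history
    bin, averaged over ``n_eval_samples`` training samples, gives the
    first-order (linear) receptive field of the fitted encoder in natural
    units.  Dropout is off during differentiation.
    """
    if not model.trained:
        raise ValueError("model is untrained")
    rng = np.random.default_rng(seed)
    n = inputs.labels.size
    if n_eval_samples < n:
        idx = rng.choice(n, size=n_eval_samples, replace=False)
    else:
        idx = np.arange(n)
    feats = inputs.features[idx]
    grad = model.input_gradient(feats).mean(axis=0)
    h = inputs.n_history
    return ReceptiveField(
        temp_coeffs=grad[:h],
        bout_coeffs=grad[h:],
        temp_mean=model.feature_mean[:h],
        bout_mean=model.feature_mean[h:],
        p_bar=model.p_bar,
        bin_rate_hz=inputs.bin_rate_hz,
    )


def rf_effect(rf: ReceptiveField, stimulus_25hz: np.ndarray) -> RFEffect:
    """Project a temperature trace through the thermosensory receptive field.

    ``stimulus_25hz`` is a temperature trace sampled at the history bin rate.
    Output covers the bins with a full causal history (length - H samples).
    When ``delta_logp`` is 0 everywhere, both probability and frequency
    modulation are exactly 0; as ``delta_logp -> -inf`` the frequency change
    floors at ``-p_bar * rate`` (the fish cannot swim less than never).
    """
    stimulus_25hz = np.asarray(stimulus_25hz, dtype=float)
    h = rf.temp_coeffs.size
    if stimulus_25hz.size <= h:
        raise ValueError("stimulus shorter than the history window")
    hist = _trailing_history(stimulus_25hz, h)
    dlp = (hist - rf.temp_mean) @ rf.temp_coeffs
    dp = expit(dlp + rf.lp_bar) - rf.p_bar
    return RFEffect(
        delta_logp=dlp,
        delta_p=dp,
        delta_bf_hz=dp * rf.bin_rate_hz,
        bin_rate_hz=rf.bin_rate_hz,
    )


@dataclass
class ModulationSummary:
    """Pooled bout-frequency modulation and per-experiment SD pairs."""

    pooled_dbf_a: np.ndarray
    pooled_dbf_b: np.ndarray
    sd_a: np.ndarray  # per-experiment SD of delta bout frequency under rf_a
    sd_b: np.ndarray
    signed_rank_statistic: float
    signed_rank_p: float


def rf_modulation_summary(
    rf_a: ReceptiveField,
    rf_b: ReceptiveField,
    stimuli_25hz: Sequence[np.ndarray],
) -> ModulationSummary:
    """Compare two receptive fields' bout-frequency modulation on shared stimuli.

    For each stimulus (one per experiment pair -- both members received the
    same trace), the per-time bout-frequency change is computed under each
    receptive field; the per-experiment standard deviations are compared with
    a two-sided Wilcoxon signed-rank test.  Identical receptive fields give
    all SD pairs on the identity line and p = 1.
    """
    if rf_a.bin_rate_hz != rf_b.bin_rate_hz:
        raise ValueError("receptive fields have mismatched bin rates")
    dbf_a, dbf_b, sd_a, sd_b = [], [], [], []
    for stim in stimuli_25hz:
        ea = rf_effect(rf_a, stim).delta_bf_hz
        eb = rf_effect(rf_b, stim).delta_bf_hz
        dbf_a.append(ea)
        dbf_b.append(eb)
        sd_a.append(ea.std())
        sd_b.append(eb.std())
    sd_a = np.asarray(sd_a)
    sd_b = np.asarray(sd_b)
    diffs = sd_a - sd_b
    if np.all(diffs == 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = wilcoxon(diffs)
    return ModulationSummary(
        pooled_dbf_a=np.concatenate(dbf_a),
        pooled_dbf_b=np.concatenate(dbf_b),
        sd_a=sd_a,
        sd_b=sd_b,
        signed_rank_statistic=float(stat),
        signed_rank_p=float(p),
    )


def compare_rf_timepoints(
    rf_fits_a: Sequence[ReceptiveField],
    rf_fits_b: Sequence[ReceptiveField],
    channel: str = "temp_coeffs",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lag rank-sum comparison across fit replicates, Bonferroni corrected.

    Returns (raw p-values, corrected p-values), one per history lag; the
    correction multiplies by the number of lags and clips at 1.  A lag is
    called significant at level alpha when its corrected p <= alpha.
    """
    if len(rf_fits_a) < 3 or len(rf_fits_b) < 3:
        raise ValueError("need at least 3 fits per condition")
    a = np.stack([getattr(r, channel) for r in rf_fits_a])
    b = np.stack([getattr(r, channel) for r in rf_fits_b])
    if a.shape[1] != b.shape[1]:
        raise ValueError("fit sets have different numbers of lags")
    n_lags = a.shape[1]
    raw = np.array([ranksums(a[:, j], b[:, j]).pvalue for j in range(n_lags)])
    return raw, np.minimum(raw * n_lags, 1.0)
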