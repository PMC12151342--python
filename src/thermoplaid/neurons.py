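"""Decoding sensorimotor feedback from mixed-selectivity neuron activity.

Simulated mixed-selectivity neuron responses (5 Hz) to the plaid/replay
experiments are reduced with PCA (10 components) and a ridge-penalized
logistic classifier is trained to call the feedback condition of individual
time bins, with train/test splits made *by experiment* so that no bin of a
held-out experiment leaks into training.  For comparison, classifiers are
trained directly on the raw inputs (temperature, swim starts, displacement,
turn angle) over growing integration windows: the current bin alone uses
4 features + intercept = 5 parameters; the full 10 s window at 5 Hz uses
4 x 50 + 1 = 201 parameters.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score

from .bouts import BoutEvent
from .simulate import Experiment, NEURON_RATE_HZ, NeuronModel, simulate_neurons


# ---------------------------------------------------------------------------
# 5 Hz input channels
# ---------------------------------------------------------------------------

def behavior_channels_5hz(
    experiment: Experiment,
    bouts: Sequence[BoutEvent] | None = None,
    rate_hz: float = NEURON_RATE_HZ,
) -> dict[str, np.ndarray]:
    """Bin an experiment to 5 Hz input channels.

    Returns temperature (bin mean), swim_starts (bout starts per bin),
    displacement (mm started per bin) and turn (degrees turned per bin).
    ``bouts`` defaults to the experiment's ground-truth bout list.
    """
    if bouts is None:
        bouts = experiment.true_bouts
    frames_per_bin = int(round(experiment.trajectory.frame_rate / rate_hz))
    n_bins = experiment.temperature.size // frames_per_bin
    temp = experiment.temperature[: n_bins * frames_per_bin].reshape(n_bins, -1).mean(axis=1)
    starts = np.zeros(n_bins)
    disp = np.zeros(n_bins)
    turn = np.zeros(n_bins)
    for b in bouts:
        k = b.start_frame // frames_per_bin
        if k < n_bins:
            starts[k] += 1.0
            if np.isfinite(b.displacement_mm):
                disp[k] += b.displacement_mm
            if np.isfinite(b.turn_angle_deg):
                turn[k] += abs(b.turn_angle_deg)
    return {"temperature": temp, "swim_starts": starts, "displacement": disp, "turn": turn}


@dataclass
class ActivityData:
    """Pooled 5 Hz neural activity with per-bin condition labels."""

    activity: np.ndarray  # time bins x neurons
    condition: np.ndarray  # "plaid" | "replay" per bin
    exp_ids: np.ndarray

    def __post_init__(self) -> None:
        if not (self.condition.size == self.activity.shape[0] == self.exp_ids.size):
            raise ValueError("activity, condition and exp_ids must align")


def predict_population_activity(
    models: Sequence[NeuronModel],
    experiments: Sequence[Experiment],
    seed: int | None = 0,
) -> ActivityData:
    """Run every experiment's stimulus/behavior through every neuron model."""
    rng = np.random.default_rng(seed)
    blocks, conds, ids = [], [], []
    for exp in experiments:
        ch = behavior_channels_5hz(exp)
        act = simulate_neurons(models, ch["temperature"], ch["swim_starts"],
                               seed=int(rng.integers(2**31)))
        blocks.append(act)
        conds.append(np.full(act.shape[0], exp.condition, dtype=object))
        ids.append(np.full(act.shape[0], exp.exp_id, dtype=object))
    return ActivityData(
        activity=np.vstack(blocks),
        condition=np.concatenate(conds),
        exp_ids=np.concatenate(ids),
    )


# ---------------------------------------------------------------------------
# Decoders
# ---------------------------------------------------------------------------

@dataclass
class DecoderSpec:
    """Split and regularization configuration (splits are by experiment)."""

    n_components: int = 10
    penalty_grid: np.ndarray = field(default_factory=lambda: np.logspace(-3, 3, 7))
    train_fraction: float = 2.0 / 3.0
    inner_folds: int = 5
    n_splits: int = 100
    seed: int = 0


def pca_reduce(activity: np.ndarray, n_components: int = 10) -> tuple[np.ndarray, float]:
    """Centered PCA scores and the variance fraction the components explain."""
    activity = np.asarray(activity, dtype=float)
    if n_components > activity.shape[1]:
        raise ValueError("more components requested than neurons")
    if activity.shape[0] <= n_components:
        raise ValueError("need more time bins than components")
    # full SVD: exact variance fractions (randomized SVD under-resolves
    # near-flat spectra); our matrices are tall and thin enough
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(activity)
    return scores, float(pca.explained_variance_ratio_.sum())


def _split_experiments(exp_ids, condition, train_fraction, base_seed):
    """Stratified-by-condition split of experiment ids into train/test sets.

    Each condition group's partition is seeded by the group's *membership*
    (not its label), so relabeling conditions or reordering groups leaves the
    partition of every experiment set unchanged -- the property that makes
    split-paired decoder comparisons and label-swap symmetry exact.
    """
    train, test = [], []
    for cond in np.unique(condition):
        eids = np.sort(np.unique(exp_ids[condition == cond]))
        key = zlib.crc32(",".join(map(str, eids)).encode())
        rng = np.random.default_rng((int(base_seed) * 1_000_003 + key) % (2**31))
        eids = eids[rng.permutation(eids.size)]
        n_train = max(1, int(round(eids.size * train_fraction)))
        n_train = min(n_train, eids.size - 1)
        train.extend(eids[:n_train])
        test.extend(eids[n_train:])
    return set(train), set(test)


def _fit_score_split(features, y, exp_ids, train_set, test_set, spec):
    """Inner-CV ridge-logistic fit on train-experiment bins; AUC on held-out bins."""
    in_train = np.isin(exp_ids, list(train_set))
    in_test = np.isin(exp_ids, list(test_set))
    # standardize on the training bins (solver conditioning; the ridge
    # penalty is only meaningful on a common feature scale)
    mu = features[in_train].mean(axis=0)
    sd = features[in_train].std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegressionCV(
        Cs=1.0 / spec.penalty_grid,
        cv=spec.inner_folds,
        scoring="roc_auc",
        max_iter=500,
        tol=1e-3,
        random_state=0,
    )
    with warnings.catch_warnings():
        # sklearn 1.10 transition chatter about LogisticRegressionCV defaults
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit((features[in_train] - mu) / sd, y[in_train])
    scores = clf.decision_function((features[in_test] - mu) / sd)
    bin_auc = roc_auc_score(y[in_test], scores)
    # secondary readout: one call per experiment by mean score
    eids = np.asarray(sorted(test_set))
    exp_scores = np.array([scores[exp_ids[in_test] == e].mean() for e in eids])
    exp_labels = np.array([y[in_test][exp_ids[in_test] == e][0] for e in eids])
    if exp_labels.min() == exp_labels.max():
        exp_auc = np.nan
    else:
        exp_auc = roc_auc_score(exp_labels, exp_scores)
    return float(bin_auc), float(exp_auc)


def train_condition_decoder(
    features: np.ndarray,
    condition: np.ndarray,
    exp_ids: np.ndarray,
    spec: DecoderSpec | None = None,
) -> dict:
    """Per-split held-out ROC-AUC of decoding plaid vs replay from features.

    Each of ``spec.n_splits`` random splits holds out one third of the
    experiments (stratified by condition); a ridge-penalized logistic
    regression is fit on the training bins with the penalty chosen by
    ``inner_folds``-fold cross-validation, then scored on all bins of the
    held-out experiments.  Returns bin-level and experiment-level AUC arrays.
    """
    spec = spec or DecoderSpec()
    features = np.asarray(features, dtype=float)
    y = (np.asarray(condition) == "plaid").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both conditions must be present")
    bin_aucs = np.empty(spec.n_splits)
    exp_aucs = np.empty(spec.n_splits)
    for s in range(spec.n_splits):
        train_set, test_set = _split_experiments(exp_ids, np.asarray(condition),
                                                 spec.train_fraction, spec.seed + s)
        bin_aucs[s], exp_aucs[s] = _fit_score_split(
            features, y, np.asarray(exp_ids), train_set, test_set, spec
        )
    return {"bin_auc": bin_aucs, "experiment_auc": exp_aucs, "spec": spec}


def lagged_input_features(
    channels_per_experiment: Sequence[dict[str, np.ndarray]],
    window_s: float,
    rate_hz: float = NEURON_RATE_HZ,
    drop_first_bins: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate lagged input channels over an integration window.

    ``window_s = 0`` uses only the current bin (4 features); a 10 s window at
    5 Hz uses 50 lagged copies of each channel (200 features).  Returns the
    feature matrix and matching per-bin experiment row indices.  Use
    ``drop_first_bins`` to align samples across different window lengths.
    """
    n_lags = max(1, int(round(window_s * rate_hz)))
    offset = max(n_lags - 1, drop_first_bins)
    feats, rows = [], []
    for i, ch in enumerate(channels_per_experiment):
        arr = np.stack([ch["temperature"], ch["swim_starts"],
                        ch["displacement"], ch["turn"]])  # 4 x n_bins
        n_bins = arr.shape[1]
        if n_bins <= offset:
            raise ValueError("integration window exceeds experiment duration")
        block = np.empty((n_bins - offset, 4 * n_lags))
        for lag in range(n_lags):
            cols = arr[:, offset - lag: n_bins - lag].T
            block[:, 4 * lag: 4 * lag + 4] = cols
        feats.append(block)
        rows.append(np.full(block.shape[0], i))
    return np.vstack(feats), np.concatenate(rows)


def input_parameter_count(window_s: float, rate_hz: float = NEURON_RATE_HZ) -> int:
    """Number of fitted parameters of the input decoder (incl. intercept)."""
    return 4 * max(1, int(round(window_s * rate_hz))) + 1


def input_decoder(
    channels_per_experiment: Sequence[dict[str, np.ndarray]],
    condition_per_experiment: Sequence[str],
    windows_s: Sequence[float],
    spec: DecoderSpec | None = None,
    exp_names: Sequence[str] | None = None,
) -> dict[float, dict]:
    """Condition decoders trained directly on lagged raw inputs.

    All windows share the same valid bins (the first ``max window`` bins of
    each experiment are dropped).  Pass the same ``exp_names`` and
    ``spec.seed`` used for a neuron decoder run to obtain identical
    experiment-level splits for split-paired comparison.
    """
    spec = spec or DecoderSpec()
    if exp_names is None:
        exp_names = [f"e{i:04d}" for i in range(len(channels_per_experiment))]
    exp_names = np.asarray(exp_names, dtype=object)
    max_lags = max(max(1, int(round(w * NEURON_RATE_HZ))) for w in windows_s)
    results = {}
    for w in windows_s:
        feats, rows = lagged_input_features(
            channels_per_experiment, w, drop_first_bins=max_lags - 1
        )
        cond = np.asarray(condition_per_experiment, dtype=object)[rows]
        results[w] = train_condition_decoder(feats, cond, exp_names[rows], spec)
    return results


def compare_decoders(neuron_result: dict, input_results: dict[float, dict]) -> dict:
    """Split-paired comparison of the neuron decoder against input decoders.

    For each window: median AUCs, the split-wise paired differences
    (neuron - input), the fraction of splits the neuron decoder wins, and the
    2.5-97.5 percentile interval of the differences.  Requires both runs to
    have used the same split seed.
    """
    out = {"neuron_median_auc": float(np.median(neuron_result["bin_auc"])), "windows": {}}
    for w, res in input_results.items():
        if res["spec"].seed != neuron_result["spec"].seed:
            raise ValueError("decoders were run with mismatched split seeds")
        diffs = neuron_result["bin_auc"] - res["bin_auc"]
        out["windows"][w] = {
            "input_median_auc": float(np.median(res["bin_auc"])),
            "paired_diffs": diffs,
            "fraction_neuron_wins": float(np.mean(diffs > 0)),
            "diff_ci": (float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5))),
        }
    return out
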