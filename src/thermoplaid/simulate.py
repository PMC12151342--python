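"""Virtual thermal-plaid experiments.

Everything downstream of raw data acquisition is testable against this
module: it generates bout-based virtual fish swimming in a 100 mm circular
arena whose water temperature is coupled to position through a sinusoidal
"plaid" laser-power field (closed loop), yoked replay twins receiving the
identical temperature sequence decoupled from their own motion (open loop),
raw tail-angle traces for bout detection, and populations of parameterized
mixed-selectivity neuron models.

The generative swim policy is a logistic point process: in every 40 ms bin
the probability of initiating a bout is

    p(t) = logistic(b0 + k_T . (T_hist(t) - T_ref) + k_B . bout_hist(t))

where ``T_hist`` is the strictly causal 1 s (25-bin) temperature history,
``bout_hist`` the 1 s binary history of bout ends, and ``b0`` the baseline
log-odds.  With both kernels zero, bout starts form a homogeneous Bernoulli
process at rate ``logistic(b0)`` per bin.  The known kernels serve as ground
truth for receptive-field parameter recovery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .bouts import BoutEvent, annotate_interbout_intervals

FRAME_RATE_HZ = 250.0
POLICY_RATE_HZ = 25.0
FRAMES_PER_BIN = int(FRAME_RATE_HZ / POLICY_RATE_HZ)  # 10
HISTORY_BINS = 25  # 1 s at 25 Hz
ARENA_RADIUS_MM = 50.0
ARENA_CENTER_MM = (50.0, 50.0)


# ---------------------------------------------------------------------------
# Thermal field and calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaidField:
    """Doubly periodic sinusoidal laser-power field.

    Coordinates are mm from the top-left corner of the field, x rightward and
    y downward.  Power is bounded in [offset - amplitude, offset + amplitude]
    and periodic with ``axis_period_mm`` along each axis; the repeat distance
    along the (1, 1) diagonal is ``axis_period_mm * sqrt(2)``.
    """

    amplitude_mw: float = 750.0
    offset_mw: float = 1250.0
    axis_period_mm: float = 15.0

    @property
    def diagonal_period_mm(self) -> float:
        return self.axis_period_mm * math.sqrt(2.0)

    def power_at(self, x, y):
        """Laser power (mW) at position (x, y) in mm."""
        w = 2.0 * math.pi / self.axis_period_mm
        return self.offset_mw + self.amplitude_mw * (
            0.5 * np.sin(w * np.asarray(x)) + 0.5 * np.sin(w * np.asarray(y))
        )


def power_at(field: PlaidField, x, y):
    """Module-level alias for :meth:`PlaidField.power_at`."""
    return field.power_at(x, y)


@dataclass(frozen=True)
class Calibration:
    """Affine laser-power -> water-temperature map.

    Defaults map the field's power extremes (500-2000 mW) onto the 25-28 C
    range spanned by the plaid stimulus.
    """

    power_lo_mw: float = 500.0
    temp_lo_c: float = 25.0
    power_hi_mw: float = 2000.0
    temp_hi_c: float = 28.0

    def __post_init__(self) -> None:
        if self.power_hi_mw == self.power_lo_mw:
            raise ValueError("degenerate calibration: power anchors coincide")
        if (self.temp_hi_c - self.temp_lo_c) * (self.power_hi_mw - self.power_lo_mw) <= 0:
            raise ValueError("calibration must be strictly monotone increasing")

    def power_to_temperature(self, power_mw):
        power_mw = np.asarray(power_mw, dtype=float)
        lo = min(self.power_lo_mw, self.power_hi_mw)
        hi = max(self.power_lo_mw, self.power_hi_mw)
        if np.any(power_mw < lo) or np.any(power_mw > hi):
            warnings.warn(
                "power outside calibration anchors; extrapolating the affine map",
                stacklevel=2,
            )
        slope = (self.temp_hi_c - self.temp_lo_c) / (self.power_hi_mw - self.power_lo_mw)
        out = self.temp_lo_c + slope * (power_mw - self.power_lo_mw)
        return out if out.ndim else float(out)


def power_to_temperature(cal: Calibration, power_mw):
    return cal.power_to_temperature(power_mw)


# ---------------------------------------------------------------------------
# Generative swim policy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerativePolicy:
    """Logistic bout-initiation policy plus bout kinematic distributions.

    Kernel convention: index 0 is the most recent history bin (lag 40 ms),
    index 24 the oldest (lag 1 s); this matches the design-matrix layout used
    by the encoder.  ``temp_kernel`` has units of log-odds per degC per bin
    and acts on temperature relative to ``temp_ref_c``; ``bout_kernel`` is
    log-odds per bout-end event at each lag.

    Kinematics: interbout structure emerges from the Bernoulli process (and
    the refractory part of ``bout_kernel``); ``sample_interbout_interval``
    additionally exposes a shifted-gamma draw in the observed 0.5-1.8 s range
    for building bout trains directly.  Bout durations are uniform in
    100-200 ms, displacements lognormal with ~2 mm median, and turn angles a
    mixture of straight swims (sd 5 deg) and +/-30 deg turns.
    """

    base_logit: float = -3.1780538303479458  # logit(0.04): 1 bout/s at 25 Hz
    temp_kernel: np.ndarray = dc_field(default_factory=lambda: np.zeros(HISTORY_BINS))
    bout_kernel: np.ndarray = dc_field(default_factory=lambda: np.zeros(HISTORY_BINS))
    temp_ref_c: float = 26.5
    # kinematic distribution parameters
    ibi_shape: float = 2.5
    ibi_scale_s: float = 0.16
    ibi_min_s: float = 0.5
    ibi_max_s: float = 1.8
    bout_duration_range_s: tuple[float, float] = (0.1, 0.2)
    displacement_median_mm: float = 2.0
    displacement_sigma: float = 0.4
    p_straight: float = 0.6
    straight_sd_deg: float = 5.0
    turn_mean_deg: float = 30.0
    turn_sd_deg: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "temp_kernel", np.asarray(self.temp_kernel, dtype=float))
        object.__setattr__(self, "bout_kernel", np.asarray(self.bout_kernel, dtype=float))
        if self.temp_kernel.shape != (HISTORY_BINS,) or self.bout_kernel.shape != (HISTORY_BINS,):
            raise ValueError(f"kernels must have {HISTORY_BINS} coefficients")

    # -- kinematic samplers ------------------------------------------------
    def sample_interbout_interval(self, rng: np.random.Generator) -> float:
        ibi = self.ibi_min_s + rng.gamma(self.ibi_shape, self.ibi_scale_s)
        return float(min(ibi, self.ibi_max_s))

    def sample_bout_duration(self, rng: np.random.Generator) -> float:
        lo, hi = self.bout_duration_range_s
        return float(rng.uniform(lo, hi))

    def sample_displacement(self, rng: np.random.Generator) -> float:
        return float(
            rng.lognormal(math.log(self.displacement_median_mm), self.displacement_sigma)
        )

    def sample_turn(self, rng: np.random.Generator) -> float:
        """Signed turn in radians."""
        if rng.uniform() < self.p_straight:
            deg = rng.normal(0.0, self.straight_sd_deg)
        else:
            deg = rng.choice([-1.0, 1.0]) * rng.normal(self.turn_mean_deg, self.turn_sd_deg)
        return math.radians(deg)


def default_plaid_policy() -> GenerativePolicy:
    """Policy with realistic thermosensory and bout-history kernels.

    The temperature kernel is derivative-like with a realistic sensorimotor
    latency: warming ~200-300 ms before the bin promotes swim initiation
    (instant reaction would be biologically implausible) while warmth
    ~0.7 s ago suppresses it.  The bout kernel encodes a post-swim
    refractory period (<300 ms) followed by mild facilitation around 0.5 s,
    mirroring the interbout statistics of freely swimming larvae.
    """
    lags = (np.arange(HISTORY_BINS) + 1) / POLICY_RATE_HZ  # 0.04 .. 1.0 s
    temp_k = 0.55 * np.exp(-((lags - 0.24) ** 2) / (2 * 0.08**2)) \
        - 0.35 * np.exp(-((lags - 0.7) ** 2) / (2 * 0.15**2))
    bout_k = -2.5 * (lags < 0.32) + 0.6 * ((lags >= 0.4) & (lags < 0.68))
    return GenerativePolicy(temp_kernel=temp_k, bout_kernel=bout_k.astype(float))


def sample_fish_policy(seed: int | None = 0) -> GenerativePolicy:
    """Draw an individual fish's policy around the population default.

    Real groups of larvae are heterogeneous -- most behavioral variability
    arises between fish rather than between bouts -- and identical clones
    would synchronize unrealistically when driven by a shared stimulus.
    Individual fish vary in sensorimotor latency (excitatory lobe center
    ~N(240, 60) ms), thermosensory gain (lognormal, ~25%), refractory
    strength and baseline swim rate (+/-0.3 log-odds).
    """
    rng = np.random.default_rng(seed)
    lags = (np.arange(HISTORY_BINS) + 1) / POLICY_RATE_HZ
    latency = float(np.clip(rng.normal(0.24, 0.06), 0.12, 0.40))
    gain = float(rng.lognormal(0.0, 0.25))
    temp_k = gain * (
        0.55 * np.exp(-((lags - latency) ** 2) / (2 * 0.08**2))
        - 0.35 * np.exp(-((lags - latency - 0.46) ** 2) / (2 * 0.15**2))
    )
    refr = float(rng.uniform(1.8, 3.2))
    bout_k = -refr * (lags < 0.32) + 0.6 * ((lags >= 0.4) & (lags < 0.68))
    base = -3.1780538303479458 + float(rng.normal(0.0, 0.3))
    return GenerativePolicy(base_logit=base, temp_kernel=temp_k,
                            bout_kernel=bout_k.astype(float))


def null_policy(rate_hz: float = 1.0) -> GenerativePolicy:
    """Kernel-free homogeneous policy with the given bout rate."""
    p = rate_hz / POLICY_RATE_HZ
    return GenerativePolicy(base_logit=float(np.log(p / (1 - p))))


# ---------------------------------------------------------------------------
# Trajectories and experiments
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Per-frame tracking record at 250 Hz."""

    x: np.ndarray  # mm, field coordinates (origin top-left)
    y: np.ndarray
    heading: np.ndarray  # radians
    tail_angle: np.ndarray | None = None  # cumulative tail-bend angle, rad
    frame_rate: float = FRAME_RATE_HZ
    phase: str = "stimulus"  # habituation | baseline | stimulus
    arena_center: tuple[float, float] = ARENA_CENTER_MM
    arena_radius: float = ARENA_RADIUS_MM

    def __post_init__(self) -> None:
        n = self.x.size
        if not (self.y.size == n and self.heading.size == n):
            raise ValueError("trajectory series must share one length")


@dataclass
class Experiment:
    """One phase of one fish: trajectory plus stimulus traces."""

    trajectory: Trajectory
    temperature: np.ndarray  # degC per frame
    power: np.ndarray | None  # mW per frame (None in replay: laser off-policy)
    true_bouts: list[BoutEvent]
    condition: str  # plaid | replay | baseline
    exp_id: str = "exp0"


@dataclass
class ExperimentPair:
    """A plaid experiment and its yoked replay twin sharing one temperature trace."""

    plaid: Experiment
    replay: Experiment
    pair_id: str = "pair0"


def _ou_noise(n: int, sd: float, tau_s: float, dt: float,
              rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path (AR(1) at step dt)."""
    if sd <= 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = math.exp(-dt / tau_s)
    b = sd * math.sqrt(1.0 - a * a)
    x0 = rng.normal(0.0, sd)
    out, _ = lfilter([1.0], [1.0, -a], b * rng.normal(size=n), zi=[a * x0])
    return out


def _reflect_at_wall(x, y, heading, cx, cy, radius):
    """Reflect the heading across the wall normal; clamp position inside."""
    dx, dy = x - cx, y - cy
    r = math.hypot(dx, dy)
    nx, ny = dx / r, dy / r
    vx, vy = math.cos(heading), math.sin(heading)
    dot = vx * nx + vy * ny
    vx, vy = vx - 2 * dot * nx, vy - 2 * dot * ny
    scale = (radius - 1e-6) / r
    return cx + dx * scale, cy + dy * scale, math.atan2(vy, vx)


def simulate_fish(
    policy: GenerativePolicy,
    *,
    field: PlaidField | None = None,
    replay_temperature: np.ndarray | None = None,
    calibration: Calibration | None = None,
    duration_s: float = 1200.0,
    seed: int | None = 0,
    phase: str = "stimulus",
    exp_id: str = "exp0",
    thermal_noise_sd_c: float = 0.115,
    thermal_noise_tau_s: float = 0.2,
) -> Experiment:
    """Simulate one fish for ``duration_s`` seconds.

    Exactly one of ``field`` (closed loop: temperature follows position) or
    ``replay_temperature`` (open loop: a 250 Hz temperature trace is played
    back regardless of motion) must be given.  Bout starts are drawn in every
    40 ms bin from the policy's logistic rate; a start drawn while a bout is
    still in progress truncates it, so the marginal start rate is exactly the
    per-bin Bernoulli rate.  Each bout carries the fish a sampled displacement
    along a heading updated by a sampled turn, with reflective handling of
    the 50 mm arena wall.

    In closed loop the delivered temperature is the field value at the
    current position plus an Ornstein-Uhlenbeck thermal fluctuation
    (``thermal_noise_sd_c``, correlation time ``thermal_noise_tau_s``)
    standing in for laser/thermal dynamics: stationary fish still experience
    small temperature changes, as in the physical setup.  The fluctuation is
    part of the recorded trace, so a yoked replay receives it bitwise.
    Returns an :class:`Experiment` with the per-frame trajectory, the
    experienced temperature trace and the true bout list.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if (field is None) == (replay_temperature is None):
        raise ValueError("give exactly one of field= or replay_temperature=")
    cal = calibration or Calibration()
    n_bins = int(round(duration_s * POLICY_RATE_HZ))
    n_frames = n_bins * FRAMES_PER_BIN
    if replay_temperature is not None:
        replay_temperature = np.asarray(replay_temperature, dtype=float)
        if replay_temperature.size < n_frames:
            raise ValueError("replay temperature trace shorter than duration")
    rng = np.random.default_rng(seed)

    cx, cy = ARENA_CENTER_MM
    r0 = ARENA_RADIUS_MM * 0.8 * math.sqrt(rng.uniform())
    th0 = rng.uniform(0, 2 * math.pi)
    x = cx + r0 * math.cos(th0)
    y = cy + r0 * math.sin(th0)
    heading = rng.uniform(0, 2 * math.pi)

    xs = np.empty(n_frames)
    ys = np.empty(n_frames)
    hs = np.empty(n_frames)
    temp_frames = np.empty(n_frames)
    power_frames = np.empty(n_frames) if field is not None else None
    temp_bins = np.empty(n_bins)
    bout_end_bins = np.zeros(n_bins + HISTORY_BINS, dtype=float)  # padded lead-in
    if field is not None:
        thermal = _ou_noise(n_frames, thermal_noise_sd_c, thermal_noise_tau_s,
                            1.0 / FRAME_RATE_HZ, rng)
        t0 = float(cal.power_to_temperature(field.power_at(x, y))) + thermal[0]
    else:
        t0 = float(replay_temperature[0])
    temp_pad = np.full(HISTORY_BINS, t0)  # history before the experiment starts

    bouts: list[BoutEvent] = []
    # active bout state
    active = False
    bout_frames_left = 0
    step_mm = 0.0
    cur_start = 0
    cur_disp = 0.0
    cur_turn = 0.0
    tk = policy.temp_kernel
    bk = policy.bout_kernel

    def _close_bout(end_frame: int) -> None:
        nonlocal active
        b = BoutEvent(cur_start, end_frame, displacement_mm=cur_disp,
                      turn_angle_deg=abs(math.degrees(cur_turn)), kinematics_valid=True)
        bouts.append(b)
        end_bin = min(end_frame // FRAMES_PER_BIN, n_bins - 1)
        bout_end_bins[end_bin + HISTORY_BINS] = 1.0
        active = False

    for t in range(n_bins):
        # strictly causal histories, most-recent-first
        if t >= HISTORY_BINS:
            t_hist = temp_bins[t - HISTORY_BINS:t][::-1]
        else:
            t_hist = np.concatenate([temp_bins[:t][::-1], temp_pad[: HISTORY_BINS - t]])
        # stored index of bin b is b + HISTORY_BINS, so bins [t-25, t) live at [t, t+25)
        b_hist = bout_end_bins[t:t + HISTORY_BINS][::-1]
        logit = (
            policy.base_logit
            + float(tk @ (t_hist - policy.temp_ref_c))
            + float(bk @ b_hist)
        )
        if rng.uniform() < expit(logit):
            f_start = t * FRAMES_PER_BIN
            if active:
                _close_bout(f_start)
            dur = policy.sample_bout_duration(rng)
            bout_frames_left = max(1, int(round(dur * FRAME_RATE_HZ)))
            cur_disp = policy.sample_displacement(rng)
            cur_turn = policy.sample_turn(rng)
            heading = (heading + cur_turn) % (2 * math.pi)
            step_mm = cur_disp / bout_frames_left
            cur_start = f_start
            active = True

        f0 = t * FRAMES_PER_BIN
        f1 = f0 + FRAMES_PER_BIN
        if not active:  # stationary bin: fill in one shot
            xs[f0:f1] = x
            ys[f0:f1] = y
            hs[f0:f1] = heading
            if field is not None:
                pw = field.power_at(x, y)
                power_frames[f0:f1] = pw
                temp_frames[f0:f1] = float(cal.power_to_temperature(pw)) + thermal[f0:f1]
                temp_bins[t] = temp_frames[f0:f1].mean()
            else:
                temp_frames[f0:f1] = replay_temperature[f0:f1]
                temp_bins[t] = temp_frames[f0:f1].mean()
            continue
        for f in range(f0, f1):
            if active:
                nx = x + step_mm * math.cos(heading)
                ny = y + step_mm * math.sin(heading)
                if math.hypot(nx - cx, ny - cy) >= ARENA_RADIUS_MM:
                    x, y, heading = _reflect_at_wall(nx, ny, heading, cx, cy, ARENA_RADIUS_MM)
                else:
                    x, y = nx, ny
                bout_frames_left -= 1
                if bout_frames_left == 0:
                    _close_bout(f + 1)
            xs[f] = x
            ys[f] = y
            hs[f] = heading
        if field is not None:
            pw = field.power_at(xs[f0:f1], ys[f0:f1])
            power_frames[f0:f1] = pw
            temp_frames[f0:f1] = cal.power_to_temperature(pw) + thermal[f0:f1]
        else:
            temp_frames[f0:f1] = replay_temperature[f0:f1]
        temp_bins[t] = temp_frames[f0:f1].mean()

    if active:
        _close_bout(n_frames)

    traj = Trajectory(x=xs, y=ys, heading=hs, phase=phase)
    cond = "plaid" if field is not None else "replay"
    if phase == "baseline":
        cond = "baseline"
    return Experiment(
        trajectory=traj,
        temperature=temp_frames,
        power=power_frames,
        true_bouts=annotate_interbout_intervals(bouts),
        condition=cond,
        exp_id=exp_id,
    )


def make_replay_pair(
    plaid_experiment: Experiment,
    policy: GenerativePolicy,
    seed: int | None = 0,
) -> ExperimentPair:
    """Simulate a yoked twin receiving the plaid fish's exact temperature trace."""
    if plaid_experiment.temperature is None or len(plaid_experiment.temperature) == 0:
        raise ValueError("plaid experiment has no recorded temperature trace")
    duration_s = plaid_experiment.temperature.size / FRAME_RATE_HZ
    replay = simulate_fish(
        policy,
        replay_temperature=plaid_experiment.temperature,
        duration_s=duration_s,
        seed=seed,
        phase=plaid_experiment.trajectory.phase,
        exp_id=plaid_experiment.exp_id + "_replay",
    )
    return ExperimentPair(plaid=plaid_experiment, replay=replay,
                          pair_id=plaid_experiment.exp_id)


# ---------------------------------------------------------------------------
# Synthetic tail traces
# ---------------------------------------------------------------------------

def synth_tail_trace(
    bouts: Sequence[BoutEvent],
    n_frames: int,
    beat_amplitude_rad: float = 1.0,
    beat_freq_hz: float = 30.0,
    noise_sd_rad: float = 0.01,
    seed: int | None = 0,
    frame_rate: float = FRAME_RATE_HZ,
) -> np.ndarray:
    """Cumulative tail-bend angle: sinusoidal beating inside bouts, noise elsewhere.

    Emulates the tail-angle signal used to delineate bouts; the beat amplitude
    is chosen so that the within-bout sliding-window SD comfortably exceeds
    the 0.1 rad/frame detection threshold.
    """
    rng = np.random.default_rng(seed)
    trace = rng.normal(0.0, noise_sd_rad, n_frames) if noise_sd_rad > 0 else np.zeros(n_frames)
    prev_end = -1
    for b in sorted(bouts, key=lambda b: b.start_frame):
        if b.start_frame < prev_end:
            raise ValueError("overlapping bouts")
        if b.start_frame < 0 or b.end_frame > n_frames:
            raise ValueError("bout outside the trace")
        prev_end = b.end_frame
        tt = np.arange(b.n_frames) / frame_rate
        trace[b.start_frame:b.end_frame] += beat_amplitude_rad * np.sin(
            2 * math.pi * beat_freq_hz * tt
        )
    return trace


def sample_bout_train(
    policy: GenerativePolicy,
    duration_s: float,
    seed: int | None = 0,
    frame_rate: float = FRAME_RATE_HZ,
) -> list[BoutEvent]:
    """Renewal-style bout train with the policy's interbout/duration distributions.

    Useful for building detection test traces with guaranteed non-overlapping
    bouts and realistic 0.5-1.8 s interbout intervals.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate))
    bouts = []
    f = int(round(policy.sample_interbout_interval(rng) * frame_rate))
    while True:
        dur = int(round(policy.sample_bout_duration(rng) * frame_rate))
        if f + dur >= n_frames:
            break
        bouts.append(BoutEvent(f, f + dur))
        f = f + dur + int(round(policy.sample_interbout_interval(rng) * frame_rate))
    return bouts


# ---------------------------------------------------------------------------
# Mixed-selectivity neuron models
# ---------------------------------------------------------------------------

NEURON_RATE_HZ = 5.0


@dataclass(frozen=True)
class NeuronModel:
    """Parameterized sensorimotor response function with a calcium kernel.

    Drive at 5 Hz: ``ws * f(dT/dt) + wm * bouts + wc * f(dT/dt) * bouts``
    where ``f`` is half-wave rectification when ``rectified`` else identity.
    The drive is convolved with a causal exponential calcium-indicator kernel
    (``exp(-t/tau)``, unit peak) and Gaussian noise is added.  A nonzero
    coincidence weight ``wc`` (or rectification) makes the neuron
    mixed-selective in the nonlinear sense: it responds to the co-occurrence
    of temperature change and swimming rather than to either alone.
    """

    w_sensory: float = 0.0  # per degC/s of temperature derivative
    w_motor: float = 0.0  # per bout event
    w_coincidence: float = 0.0  # multiplicative dT/dt x bout term
    rectified: bool = False
    tau_s: float = 2.5  # nuclear GCaMP6s-like decay
    noise_sd: float = 0.05

    @property
    def mixed_selectivity(self) -> bool:
        return self.w_coincidence != 0.0 or self.rectified


def simulate_neurons(
    models: Sequence[NeuronModel],
    temperature_5hz: np.ndarray,
    bout_raster_5hz: np.ndarray,
    seed: int | None = 0,
    rate_hz: float = NEURON_RATE_HZ,
) -> np.ndarray:
    """Predicted calcium activity, time x neurons, at 5 Hz."""
    if len(models) == 0:
        raise ValueError("empty model list")
    temperature_5hz = np.asarray(temperature_5hz, dtype=float)
    bout_raster_5hz = np.asarray(bout_raster_5hz, dtype=float)
    if temperature_5hz.shape != bout_raster_5hz.shape:
        raise ValueError("temperature and bout raster must be binned identically")
    rng = np.random.default_rng(seed)
    dtdt = np.gradient(temperature_5hz) * rate_hz  # degC/s
    n = temperature_5hz.size
    out = np.empty((n, len(models)))
    for j, m in enumerate(models):
        if m.tau_s <= 0:
            raise ValueError("calcium kernel tau must be positive")
        drv = np.maximum(dtdt, 0.0) if m.rectified else dtdt
        drive = m.w_sensory * drv + m.w_motor * bout_raster_5hz \
            + m.w_coincidence * drv * bout_raster_5hz
        klen = max(2, int(round(10 * m.tau_s * rate_hz)))
        kernel = np.exp(-np.arange(klen) / (m.tau_s * rate_hz))
        act = np.convolve(drive, kernel)[:n]
        if m.noise_sd > 0:
            act = act + rng.normal(0.0, m.noise_sd, n)
        out[:, j] = act
    return out


def sample_neuron_population(
    n_neurons: int,
    seed: int | None = 0,
    type_fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> list[NeuronModel]:
    """Sample a population spanning sensory, motor, additive and coincidence types.

    ``type_fractions`` orders (sensory-only, motor-only, additive,
    coincidence).  Coincidence neurons are additionally rectified with
    probability 1/2; they form the nonlinear mixed-selectivity subset used by
    the feedback decoder.
    """
    rng = np.random.default_rng(seed)
    kinds = rng.choice(4, size=n_neurons, p=np.asarray(type_fractions) / sum(type_fractions))
    pop = []
    for k in kinds:
        ws = rng.uniform(0.5, 2.0) * rng.choice([-1, 1])
        wm = rng.uniform(0.5, 2.0)
        wc = rng.uniform(1.0, 3.0) * rng.choice([-1, 1])
        tau = rng.uniform(1.5, 3.5)
        if k == 0:
            pop.append(NeuronModel(w_sensory=ws, tau_s=tau))
        elif k == 1:
            pop.append(NeuronModel(w_motor=wm, tau_s=tau))
        elif k == 2:
            pop.append(NeuronModel(w_sensory=ws, w_motor=wm, tau_s=tau))
        else:
            pop.append(
                NeuronModel(
                    w_sensory=0.3 * ws,
                    w_motor=0.3 * wm,
                    w_coincidence=wc,
                    rectified=bool(rng.uniform() < 0.5),
                    tau_s=tau,
                )
            )
    return pop
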