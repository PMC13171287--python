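"""Synthetic laminar sessions with a known two-state latent structure.

The generator realizes the statistical model the downstream analysis assumes:
a latent first-order Markov chain over {OFF, ON} at 10 ms resolution, shared
by all channels; per-channel Poisson multi-unit counts whose rate depends on
the latent state; and single units placed on a soloist-to-chorister continuum
through a tunable ON/OFF rate ratio ``rho``.  Attention toward the receptive
field lengthens ON dwell times (larger ON self-transition probability) and
scales unit rates by ``1 + gain``.

Single-unit spikes are drawn at 1 ms resolution by thinning within the 10 ms
latent bins and are NOT mixed into the multi-unit train of the hosting
channel, matching the own-channel exclusion applied when the population rate
is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import log_ndtr
from scipy.stats import norm

from popstate.data_model import (
    CONDITIONS,
    SessionValidationError,
    SpikeSession,
    SpikeTrain,
    TrialEpochs,
)

__all__ = [
    "UnitSpec",
    "GeneratorConfig",
    "GroundTruth",
    "sample_state_sequence",
    "generate_channel_counts",
    "generate_unit_spikes",
    "generate_session",
    "generate_continuous_profile",
]

OFF, ON = 0, 1


@dataclass(frozen=True)
class UnitSpec:
    """One synthetic single unit.

    ``rho`` >= 1 is the ON/OFF rate ratio: with ``r_off = 2*base_rate/(1+rho)``
    and ``r_on = rho*r_off`` the state-average rate at 50% ON occupancy equals
    ``base_rate``.  ``rho = 1`` gives a state-independent soloist.
    """

    channel_index: int
    base_rate_hz: float
    rho: float = 1.0
    gain: float = 0.0

    def __post_init__(self) -> None:
        if self.rho < 1.0:
            raise ValueError(f"rho must be >= 1, got {self.rho}")
        if self.base_rate_hz < 0:
            raise ValueError("base_rate_hz must be >= 0")

    def state_rates(self, condition: str = "attend_away") -> tuple[float, float]:
        """(r_off, r_on) in Hz for a condition; attend_RF applies the gain."""
        r_off = 2.0 * self.base_rate_hz / (1.0 + self.rho)
        r_on = self.rho * r_off
        if condition == "attend_RF":
            scale = 1.0 + self.gain
            r_off, r_on = r_off * scale, r_on * scale
        return r_off, r_on


@dataclass
class GeneratorConfig:
    """Parameters of a synthetic session.

    Latent self-transition probabilities may be given per condition as a dict
    keyed by condition name, or as a scalar applied to both conditions.
    Channel rates are in Hz; the defaults target ~100 Hz mean multi-unit
    activity per channel at 50% ON occupancy.
    """

    n_channels: int = 16
    bin_ms: float = 10.0
    p_stay_off: float | dict = 0.9
    p_stay_on: float | dict = field(
        default_factory=lambda: {"attend_away": 0.9, "attend_RF": 0.97}
    )
    channel_rates_on_hz: Optional[Sequence[float]] = None  # default 160 Hz
    channel_rates_off_hz: Optional[Sequence[float]] = None  # default 40 Hz
    units: Sequence[UnitSpec] = ()
    n_trials: tuple[int, int] = (20, 20)  # (attend_RF, attend_away)
    fixation_to_cue_ms: float = 800.0
    cue_to_dimming_ms: float = 1600.0
    post_dimming_ms: float = 200.0
    intertrial_ms: float = 500.0
    monkey_profile: str = "M1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise SessionValidationError("n_channels must be >= 1")
        if self.bin_ms <= 0:
            raise SessionValidationError("bin_ms must be > 0")
        if self.channel_rates_on_hz is None:
            self.channel_rates_on_hz = np.full(self.n_channels, 160.0)
        if self.channel_rates_off_hz is None:
            self.channel_rates_off_hz = np.full(self.n_channels, 40.0)
        self.channel_rates_on_hz = np.asarray(self.channel_rates_on_hz, dtype=float)
        self.channel_rates_off_hz = np.asarray(self.channel_rates_off_hz, dtype=float)
        if (
            self.channel_rates_on_hz.shape != (self.n_channels,)
            or self.channel_rates_off_hz.shape != (self.n_channels,)
        ):
            raise SessionValidationError("channel rate vectors must match n_channels")
        if np.any(self.channel_rates_on_hz < 0) or np.any(
            self.channel_rates_off_hz < 0
        ):
            raise SessionValidationError("channel rates must be >= 0")
        if np.any(self.channel_rates_on_hz < self.channel_rates_off_hz):
            raise SessionValidationError("ON rates must be >= OFF rates per channel")
        for condition in CONDITIONS:
            for p in (
                self.stay_probability(OFF, condition),
                self.stay_probability(ON, condition),
            ):
                if not (0.0 < p < 1.0):
                    raise SessionValidationError(
                        f"self-transition probabilities must lie in (0,1), got {p}"
                    )
        for spec in self.units:
            if spec.channel_index >= self.n_channels:
                raise SessionValidationError(
                    f"unit on channel {spec.channel_index} outside probe"
                )

    def stay_probability(self, state: int, condition: str) -> float:
        raw = self.p_stay_on if state == ON else self.p_stay_off
        if isinstance(raw, dict):
            return float(raw[condition])
        return float(raw)

    def transition_matrix(self, condition: str) -> np.ndarray:
        p_off = self.stay_probability(OFF, condition)
        p_on = self.stay_probability(ON, condition)
        return np.array([[p_off, 1.0 - p_off], [1.0 - p_on, p_on]])

    def emission_matrix(self) -> np.ndarray:
        """True lambda as mean counts per latent bin, shape (2, n_channels)."""
        scale = self.bin_ms / 1000.0
        return np.vstack(
            [self.channel_rates_off_hz * scale, self.channel_rates_on_hz * scale]
        )


@dataclass
class GroundTruth:
    """Latent structure underlying a generated session."""

    states: dict[str, np.ndarray]  # trial_id -> per-bin state over the trial span
    trial_start_ms: dict[str, float]
    bin_ms: float
    emission: np.ndarray  # (2, n_channels) counts per bin
    transition: dict[str, np.ndarray]  # condition -> 2x2 matrix
    pi0: np.ndarray
    unit_rho: dict[str, float]
    unit_gain: dict[str, float]

    def states_in_interval(self, trial_id: str, interval: tuple[float, float]) -> np.ndarray:
        """Latent states of the bins fully inside ``[start, end)`` of a trial."""
        start, end = interval
        t0 = self.trial_start_ms[trial_id]
        first = int(np.ceil((start - t0) / self.bin_ms))
        last = int(np.floor((end - t0) / self.bin_ms))
        seq = self.states[trial_id]
        first = max(first, 0)
        last = min(last, seq.size)
        return seq[first:last]


def sample_state_sequence(
    p_stay_off: float,
    p_stay_on: float,
    pi0: Sequence[float],
    n_bins: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample a first-order Markov {0=OFF, 1=ON} sequence.

    Dwell times are geometric with mean ``1 / (1 - p_stay)`` bins.
    """
    if n_bins <= 0:
        raise ValueError("n_bins must be > 0")
    for name, p in (("p_stay_off", p_stay_off), ("p_stay_on", p_stay_on)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be a probability, got {p}")
    pi0 = np.asarray(pi0, dtype=float)
    if pi0.shape != (2,) or np.any(pi0 < 0) or not np.isclose(pi0.sum(), 1.0):
        raise ValueError("pi0 must be a length-2 probability vector")

    stay = np.array([p_stay_off, p_stay_on])
    states = np.empty(n_bins, dtype=np.int8)
    states[0] = rng.choice(2, p=pi0)
    draws = rng.random(n_bins - 1) if n_bins > 1 else np.empty(0)
    for t in range(1, n_bins):
        s = states[t - 1]
        states[t] = s if draws[t - 1] < stay[s] else 1 - s
    return states


def generate_channel_counts(
    states: np.ndarray,
    rate_on_hz: float,
    rate_off_hz: float,
    bin_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-bin Poisson counts conditioned on the latent state sequence."""
    if rate_on_hz < 0 or rate_off_hz < 0:
        raise ValueError("rates must be >= 0")
    scale = bin_ms / 1000.0
    lam = np.where(np.asarray(states) == ON, rate_on_hz, rate_off_hz) * scale
    return rng.poisson(lam)


def _spike_times_from_counts(
    counts: np.ndarray, bin_width_ms: float, t0_ms: float, rng: np.random.Generator
) -> np.ndarray:
    """Scatter per-bin counts uniformly within their bins (homogeneous within bin)."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    bins = np.repeat(np.arange(counts.size), counts)
    times = t0_ms + (bins + rng.random(total)) * bin_width_ms
    return np.sort(times)


def generate_unit_spikes(
    states: np.ndarray,
    spec: UnitSpec,
    condition: str,
    bin_ms: float,
    t0_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spike times (ms) of a single unit over one latent sequence.

    Spikes are drawn at 1 ms resolution: each 1 ms sub-bin of a latent bin
    receives a Poisson count at the state-dependent rate, then spikes are
    jittered uniformly inside their sub-bin.
    """
    r_off, r_on = spec.state_rates(condition)
    sub_per_bin = max(int(round(bin_ms)), 1)
    rate_hz = np.where(np.asarray(states) == ON, r_on, r_off)
    lam_sub = np.repeat(rate_hz, sub_per_bin) / 1000.0  # per-1 ms expected count
    counts = rng.poisson(lam_sub)
    return _spike_times_from_counts(counts, 1.0, t0_ms, rng)


def generate_session(config: GeneratorConfig) -> tuple[SpikeSession, GroundTruth]:
    """Generate a full session plus its ground truth; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    bin_ms = config.bin_ms
    pi0 = np.array([0.5, 0.5])
    trial_span_ms = (
        config.fixation_to_cue_ms + config.cue_to_dimming_ms + config.post_dimming_ms
    )
    n_bins = int(np.ceil(trial_span_ms / bin_ms))

    n_rf, n_away = config.n_trials
    layout = ["attend_RF"] * n_rf + ["attend_away"] * n_away
    if n_rf < 1 or n_away < 1:
        raise SessionValidationError("need at least one trial per condition")

    trials: list[TrialEpochs] = []
    states_by_trial: dict[str, np.ndarray] = {}
    start_by_trial: dict[str, float] = {}
    unit_times: dict[str, list[np.ndarray]] = {
        f"su{idx:02d}": [] for idx in range(len(config.units))
    }
    mua_times: dict[int, list[np.ndarray]] = {j: [] for j in range(config.n_channels)}

    cursor = config.intertrial_ms
    for i, condition in enumerate(layout):
        trial_id = f"tr{i:03d}"
        fixation = cursor
        cue = fixation + config.fixation_to_cue_ms
        dimming = cue + config.cue_to_dimming_ms
        cursor = dimming + config.post_dimming_ms + config.intertrial_ms
        trials.append(
            TrialEpochs(
                trial_id=trial_id,
                fixation_onset_ms=fixation,
                cue_onset_ms=cue,
                first_dimming_ms=dimming,
                condition=condition,
            )
        )

        states = sample_state_sequence(
            config.stay_probability(OFF, condition),
            config.stay_probability(ON, condition),
            pi0,
            n_bins,
            rng,
        )
        states_by_trial[trial_id] = states
        start_by_trial[trial_id] = fixation

        for j in range(config.n_channels):
            counts = generate_channel_counts(
                states,
                config.channel_rates_on_hz[j],
                config.channel_rates_off_hz[j],
                bin_ms,
                rng,
            )
            mua_times[j].append(
                _spike_times_from_counts(counts, bin_ms, fixation, rng)
            )
        for idx, spec in enumerate(config.units):
            unit_times[f"su{idx:02d}"].append(
                generate_unit_spikes(states, spec, condition, bin_ms, fixation, rng)
            )

    trains: list[SpikeTrain] = []
    for j in range(config.n_channels):
        trains.append(
            SpikeTrain(
                unit_id=f"mua{j:02d}",
                channel_index=j,
                kind="multi_unit",
                spike_times=np.concatenate(mua_times[j]) if mua_times[j] else np.empty(0),
            )
        )
    for idx, spec in enumerate(config.units):
        uid = f"su{idx:02d}"
        trains.append(
            SpikeTrain(
                unit_id=uid,
                channel_index=spec.channel_index,
                kind="single_unit",
                spike_times=np.concatenate(unit_times[uid]),
            )
        )

    session = SpikeSession(
        session_id=f"synthetic-seed{config.seed}",
        monkey_profile=config.monkey_profile,
        spike_trains=tuple(trains),
        trials=tuple(trials),
        area_labels=tuple(
            "V1" if j < config.n_channels // 2 else "V4"
            for j in range(config.n_channels)
        )
        if config.n_channels > 1
        else ("V1",),
    )
    truth = GroundTruth(
        states=states_by_trial,
        trial_start_ms=start_by_trial,
        bin_ms=bin_ms,
        emission=config.emission_matrix(),
        transition={c: config.transition_matrix(c) for c in CONDITIONS},
        pi0=pi0,
        unit_rho={f"su{i:02d}": s.rho for i, s in enumerate(config.units)},
        unit_gain={f"su{i:02d}": s.gain for i, s in enumerate(config.units)},
    )
    return session, truth


def latency_model(
    t: np.ndarray, mu: float, sigma: float, alpha: float, c: float, d: float
) -> np.ndarray:
    """Visual-response model: dissipating ex-Gaussian plus cumulative Gaussian.

    ``y(t) = d*exp(mu*alpha + 0.5*sigma^2*alpha^2 - alpha*t) * G(t, mu+sigma^2*alpha, sigma)
    + c*G(t, mu, sigma)`` with G a cumulative Gaussian.  Evaluated in log space
    to stay finite for large exponential arguments.
    """
    t = np.asarray(t, dtype=float)
    rising = c * norm.cdf(t, loc=mu, scale=sigma)
    if d == 0.0:
        return rising
    with np.errstate(over="ignore", invalid="ignore"):
        log_amp = mu * alpha + 0.5 * (sigma * alpha) ** 2 - alpha * t
        z = (t - (mu + sigma**2 * alpha)) / sigma
        exponent = log_amp + log_ndtr(z)
    # clip so optimizer excursions into huge sigma*alpha stay finite
    dissipating = d * np.exp(np.clip(np.nan_to_num(exponent, nan=-np.inf), None, 700.0))
    return dissipating + rising


def generate_continuous_profile(
    kind: str,
    params: dict,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Deterministic continuous test signals.

    ``latency_model`` evaluates the parametric visual response on ``t_ms``
    (params: mu, sigma, alpha, c, d, optional noise_sd).  ``csd_test`` returns
    a voltage-by-depth profile on ``depth_um`` (params: profile in
    {linear, quadratic, gaussian_sink}, plus slope/offset or sink_depth_um,
    sink_width_um, amplitude).
    """
    if kind == "latency_model":
        t = np.asarray(params["t_ms"], dtype=float)
        sigma = float(params.get("sigma", 5.0))
        alpha = float(params.get("alpha", 0.05))
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        if alpha <= 0:
            raise ValueError("alpha must be > 0")
        y = latency_model(
            t,
            float(params.get("mu", 50.0)),
            sigma,
            alpha,
            float(params.get("c", 1.0)),
            float(params.get("d", 0.0)),
        )
        noise_sd = float(params.get("noise_sd", 0.0))
        if noise_sd > 0:
            if rng is None:
                raise ValueError("noise requires an rng")
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
        return y
    if kind == "csd_test":
        x = np.asarray(params["depth_um"], dtype=float)
        profile = params.get("profile", "quadratic")
        if profile == "linear":
            return params.get("slope", 1.0) * x + params.get("offset", 0.0)
        if profile == "quadratic":
            return params.get("curvature", 1.0) * x**2
        if profile == "gaussian_sink":
            mu = float(params["sink_depth_um"])
            width = float(params.get("sink_width_um", 200.0))
            amp = float(params.get("amplitude", -1.0))
            return amp * np.exp(-0.5 * ((x - mu) / width) ** 2)
        raise ValueError(f"unknown csd_test profile {profile!r}")
    raise ValueError(f"unknown profile kind {kind!r}")
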