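"""Binning, smoothing, population-rate construction, and inclusion filters."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from popstate.data_model import (
    AnalysisWindow,
    CONDITIONS,
    SpikeSession,
    SpikeTrain,
    TrialEpochs,
    resolve_window,
)

__all__ = [
    "SmoothedSignal",
    "bin_spikes",
    "gaussian_kernel",
    "gaussian_smooth",
    "population_rate",
    "energy",
    "select_stable_window",
    "inclusion_filter",
    "response_filter",
    "InclusionReport",
]

#: default kernel width; "half-width" is read as the Gaussian sigma in ms
KERNEL_HALF_WIDTH_MS = 12.0
#: single-unit trains use a sqrt(2)-narrower kernel by default
UNIT_KERNEL_DIVISOR = np.sqrt(2.0)


@dataclass(frozen=True)
class SmoothedSignal:
    """A 1 ms-resolution signal after Gaussian smoothing and mean subtraction."""

    values: np.ndarray
    kernel_half_width_ms: float
    mean_subtracted: bool
    source: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.mean_subtracted and values.size:
            scale = max(np.abs(values).max(), 1.0)
            if abs(values.mean()) > 1e-9 * scale:
                raise ValueError("mean_subtracted signal has nonzero mean")

    def __len__(self) -> int:
        return self.values.size


def bin_spikes(
    spike_times: np.ndarray | SpikeTrain,
    interval: tuple[float, float],
    bin_ms: float = 1.0,
) -> np.ndarray:
    """Count spikes in half-open bins tiling ``[start, end)``.

    The last bin may be truncated by ``end``; spikes at exactly ``end`` are
    excluded, so the sum of counts equals the number of spikes in the
    interval.
    """
    if isinstance(spike_times, SpikeTrain):
        spike_times = spike_times.spike_times
    start, end = interval
    if end <= start:
        raise ValueError(f"empty interval [{start}, {end})")
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    n_bins = int(np.ceil((end - start) / bin_ms))
    edges = start + bin_ms * np.arange(n_bins + 1)
    edges[-1] = min(edges[-1], end)
    times = np.asarray(spike_times, dtype=float)
    times = times[(times >= start) & (times < end)]
    counts, _ = np.histogram(times, bins=edges)
    return counts


def gaussian_kernel(half_width_ms: float, bin_ms: float = 1.0) -> np.ndarray:
    """Unit-area Gaussian kernel truncated at +/-4 sigma."""
    if half_width_ms <= 0:
        raise ValueError("half_width_ms must be > 0")
    sigma_bins = half_width_ms / bin_ms
    radius = int(np.ceil(4.0 * sigma_bins))
    support = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (support / sigma_bins) ** 2)
    return kernel / kernel.sum()


def gaussian_smooth(
    counts: np.ndarray,
    half_width_ms: float,
    bin_ms: float = 1.0,
    subtract_mean: bool = False,
    source: str = "",
) -> SmoothedSignal:
    """Convolve with a unit-area Gaussian (reflect-padded at the edges).

    Reflection keeps a constant input constant everywhere, so total mass is
    conserved in the interior and a flat signal stays flat.
    """
    counts = np.asarray(counts, dtype=float)
    kernel = gaussian_kernel(half_width_ms, bin_ms)
    radius = kernel.size // 2
    if counts.size <= radius:
        raise ValueError(
            f"signal of {counts.size} bins shorter than kernel radius {radius}"
        )
    padded = np.pad(counts, radius, mode="reflect")
    smoothed = np.convolve(padded, kernel, mode="valid")
    if subtract_mean:
        smoothed = smoothed - smoothed.mean()
    return SmoothedSignal(
        values=smoothed,
        kernel_half_width_ms=half_width_ms,
        mean_subtracted=subtract_mean,
        source=source,
    )


def _included_channels(
    session: SpikeSession,
    target_channel: int,
    min_contact_separation_um: float,
) -> list[int]:
    spacing = session.probe_spacing_um
    channels = []
    for j in range(session.n_channels):
        if j == target_channel:
            continue
        if abs(j - target_channel) * spacing < min_contact_separation_um:
            continue
        channels.append(j)
    return channels


def population_rate(
    session: SpikeSession,
    target_unit: str | SpikeTrain,
    interval: tuple[float, float],
    min_contact_separation_um: float = 150.0,
    kernel_half_width_ms: float = KERNEL_HALF_WIDTH_MS,
    smooth: bool = True,
) -> SmoothedSignal:
    """Summed 1 ms activity of all channels far enough from the target unit.

    The target unit's own channel is always excluded; raising
    ``min_contact_separation_um`` to 300 additionally drops the immediate
    neighbors (leakage control).  The summed counts are smoothed with the
    population kernel and mean-subtracted unless ``smooth=False`` (raw sum).
    """
    if isinstance(target_unit, str):
        target_unit = session.unit(target_unit)
    channels = _included_channels(
        session, target_unit.channel_index, min_contact_separation_um
    )
    if not channels:
        raise ValueError(
            f"no channels remain at separation >= {min_contact_separation_um} um "
            f"from channel {target_unit.channel_index}"
        )
    keep = set(channels)
    n_bins = int(np.ceil(interval[1] - interval[0]))
    total = np.zeros(n_bins)
    for train in session.spike_trains:
        if train.unit_id == target_unit.unit_id:
            continue
        if train.channel_index not in keep:
            continue
        total += bin_spikes(train, interval, bin_ms=1.0)
    if not smooth:
        return SmoothedSignal(
            values=total, kernel_half_width_ms=0.0, mean_subtracted=False,
            source="population_raw",
        )
    return gaussian_smooth(
        total, kernel_half_width_ms, subtract_mean=True, source="population"
    )


def energy(signal: np.ndarray, interval: Optional[tuple[int, int]] = None) -> float:
    """Sum of signal values over an inclusive index range ``i..j``."""
    signal = np.asarray(signal, dtype=float)
    if interval is None:
        i, j = 0, signal.size - 1
    else:
        i, j = interval
    if signal.size == 0 or j < i:
        raise ValueError("empty interval")
    return float(signal[i : j + 1].sum())


def select_stable_window(
    energies: np.ndarray, tolerance_sd: float = 3.0
) -> tuple[int, int]:
    """Longest contiguous trial run with stable energy on every channel.

    ``energies`` is (n_trials, n_channels).  The per-channel noise scale is
    estimated robustly from successive trial differences
    (``1.4826 * median|diff| / sqrt(2)``); a run is stable when every energy
    stays within ``tolerance_sd`` noise scales of the run median on every
    channel.  Returns a half-open trial index range ``[i, j)``; ties go to the
    earliest run.  Replaces the visual-inspection step with a reproducible
    criterion.
    """
    energies = np.asarray(energies, dtype=float)
    if energies.ndim == 1:
        energies = energies[:, None]
    n_trials, _ = energies.shape
    if n_trials == 1:
        return (0, 1)
    diffs = np.abs(np.diff(energies, axis=0))
    scale = 1.4826 * np.median(diffs, axis=0) / np.sqrt(2.0)
    band = tolerance_sd * scale  # per channel

    best = (0, 1)
    for i in range(n_trials):
        for j in range(i + 1, n_trials + 1):
            if j - i <= best[1] - best[0]:
                continue
            run = energies[i:j]
            dev = np.abs(run - np.median(run, axis=0))
            if np.all(dev <= band + 1e-12):
                best = (i, j)
    return best


@dataclass(frozen=True)
class InclusionReport:
    unit_id: str
    included: bool
    reasons: tuple[str, ...]
    max_rate_hz: float
    trials_per_condition: dict


def _window_rate_hz(
    train: SpikeTrain, trials: Sequence[TrialEpochs], window: AnalysisWindow
) -> float:
    """Mean firing rate of a unit over all trials of one window."""
    total_spikes = 0
    total_ms = 0.0
    for trial in trials:
        start, end = resolve_window(window, trial)
        times = train.spike_times
        total_spikes += int(np.count_nonzero((times >= start) & (times < end)))
        total_ms += end - start
    if total_ms == 0:
        return 0.0
    return 1000.0 * total_spikes / total_ms


def inclusion_filter(
    unit: str | SpikeTrain,
    session: SpikeSession,
    windows: Optional[Iterable[AnalysisWindow]] = None,
    min_rate_hz: float = 5.0,
    min_trials: int = 10,
) -> InclusionReport:
    """Keep units firing >= 5 Hz in some window with >= 10 trials per condition."""
    if isinstance(unit, str):
        unit = session.unit(unit)
    if windows is None:
        windows = session.windows().values()
    rates = [_window_rate_hz(unit, session.trials, w) for w in windows]
    max_rate = max(rates) if rates else 0.0
    per_condition = {c: len(session.trials_in(c)) for c in CONDITIONS}

    reasons = []
    if max_rate < min_rate_hz:
        reasons.append("rate")
    if any(n < min_trials for n in per_condition.values()):
        reasons.append("trials")
    return InclusionReport(
        unit_id=unit.unit_id,
        included=not reasons,
        reasons=tuple(reasons),
        max_rate_hz=max_rate,
        trials_per_condition=per_condition,
    )


def response_filter(
    unit: str | SpikeTrain,
    session: SpikeSession,
    alpha: float = 0.05,
    baseline: Optional[AnalysisWindow] = None,
    onset: Optional[AnalysisWindow] = None,
) -> tuple[bool, float]:
    """Keep units whose onset response differs from baseline.

    Per-trial spike counts in the pre-onset (-250..0 ms) and onset-response
    (50..300 ms) windows are compared with a two-sided Wilcoxon signed-rank
    test; the unit passes at p < alpha.  Returns ``(included, p_value)``.
    """
    if isinstance(unit, str):
        unit = session.unit(unit)
    windows = session.windows()
    baseline = baseline or windows["baseline"]
    onset = onset or windows["onset_response"]
    if len(session.trials) < 10:
        raise ValueError("response_filter needs at least 10 trials")

    base_counts = []
    onset_counts = []
    for trial in session.trials:
        b = resolve_window(baseline, trial)
        o = resolve_window(onset, trial)
        times = unit.spike_times
        base_counts.append(int(np.count_nonzero((times >= b[0]) & (times < b[1]))))
        onset_counts.append(int(np.count_nonzero((times >= o[0]) & (times < o[1]))))
    diffs = np.asarray(onset_counts) - np.asarray(base_counts)
    if not np.any(diffs):
        return (False, 1.0)
    stat = stats.wilcoxon(onset_counts, base_counts, zero_method="wilcox")
    return (bool(stat.pvalue < alpha), float(stat.pvalue))
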