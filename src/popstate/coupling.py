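"""Single-unit population coupling: raw C[0], normalized C_norm, Fisher Z.

The raw coupling ``C[0]`` is the zero-lag cross-covariance between the
smoothed, mean-subtracted unit train and population rate, scaled by the
unit's spike count.  The normalized coupling is the plain Pearson correlation
of the two signals (the spike-count scaling is kept only in ``C[0]``, since
``Z = atanh`` requires a bona fide correlation in [-1, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from popstate.data_model import (
    AnalysisWindow,
    SpikeSession,
    SpikeTrain,
    resolve_window,
)
from popstate.preprocessing import (
    KERNEL_HALF_WIDTH_MS,
    UNIT_KERNEL_DIVISOR,
    SmoothedSignal,
    bin_spikes,
    gaussian_smooth,
    population_rate,
)

__all__ = [
    "CouplingResult",
    "CouplingUndefined",
    "cross_correlation",
    "coupling_at_zero",
    "normalized_coupling",
    "fisher_z",
    "unit_population_coupling",
]


class CouplingUndefined(ValueError):
    """Coupling is undefined (silent unit or zero-variance signal)."""


@dataclass(frozen=True)
class CouplingResult:
    """Per-unit coupling in one window and condition."""

    unit_id: str
    window: str
    condition: str
    C0: float
    C_norm: float
    Z: float
    n_samples: int
    spike_norm: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.C_norm <= 1.0:
            raise ValueError(f"C_norm {self.C_norm} outside [-1, 1]")


def _as_values(x) -> np.ndarray:
    if isinstance(x, SmoothedSignal):
        return x.values
    return np.asarray(x, dtype=float)


def cross_correlation(
    x, y, max_lag: int, norm: Optional[float] = None
) -> np.ndarray:
    """Spike-normalized cross-correlation ``R_xy[k]`` for lags -max_lag..max_lag.

    ``R_xy[k] = (1/norm) * sum_n (x[n+k] - mean_x) (y[n] - mean_y)`` with
    out-of-range indices contributing zero.  ``norm`` defaults to the unit's
    spike count and must be positive; mean subtraction is applied here so
    already-centered inputs are unchanged.
    """
    x = _as_values(x)
    y = _as_values(y)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if norm is None:
        norm = float(np.abs(x).sum())
    if norm <= 0:
        raise CouplingUndefined("spike norm is zero (silent unit)")
    xc = x - x.mean()
    yc = y - y.mean()
    # full correlation of (xc, yc); index n+k in x against n in y
    full = np.correlate(xc, yc, mode="full")  # lag = index - (N-1), x shifted
    center = y.size - 1
    lags = np.arange(-max_lag, max_lag + 1)
    out = np.zeros(lags.size)
    for i, k in enumerate(lags):
        idx = center + k
        if 0 <= idx < full.size:
            out[i] = full[idx]
    return out / norm


def coupling_at_zero(x, y, norm: Optional[float] = None) -> float:
    """``C[0] = R_xy[0]``: zero-lag cross-covariance scaled by spike count."""
    x = _as_values(x)
    y = _as_values(y)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if norm is None:
        norm = float(np.abs(x).sum())
    if norm <= 0:
        raise CouplingUndefined("spike norm is zero (silent unit)")
    return float(np.dot(x - x.mean(), y - y.mean()) / norm)


def normalized_coupling(x, y) -> float:
    """Pearson correlation of the two signals, bounded in [-1, 1]."""
    x = _as_values(x)
    y = _as_values(y)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.dot(xc, xc) * np.dot(yc, yc))
    if denom == 0:
        raise CouplingUndefined("zero-variance signal")
    r = float(np.dot(xc, yc) / denom)
    return float(np.clip(r, -1.0, 1.0))


def fisher_z(c_norm: float) -> float:
    """Variance-stabilizing transform ``Z = atanh(C_norm)``."""
    if not -1.0 < c_norm < 1.0:
        raise ValueError(f"|C_norm| must be < 1 for atanh, got {c_norm}")
    return float(np.arctanh(c_norm))


def _segment_signals(
    session: SpikeSession,
    unit: SpikeTrain,
    window: AnalysisWindow,
    condition: str,
    min_contact_separation_um: float,
    kernel_half_width_ms: float,
    unit_kernel_mode: str,
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Per-trial smoothed, mean-subtracted (unit, population) segment pairs."""
    if unit_kernel_mode == "literal":
        pop_width = kernel_half_width_ms
        unit_width = kernel_half_width_ms / UNIT_KERNEL_DIVISOR
    elif unit_kernel_mode == "matched":
        pop_width = kernel_half_width_ms / UNIT_KERNEL_DIVISOR
        unit_width = kernel_half_width_ms / UNIT_KERNEL_DIVISOR
    else:
        raise ValueError(f"unknown unit_kernel_mode {unit_kernel_mode!r}")

    xs, ys = [], []
    spike_norm = 0.0
    for trial in session.trials_in(condition):
        interval = resolve_window(window, trial)
        counts = bin_spikes(unit, interval, bin_ms=1.0)
        spike_norm += float(counts.sum())
        x = gaussian_smooth(counts, unit_width, subtract_mean=True)
        y = population_rate(
            session,
            unit,
            interval,
            min_contact_separation_um=min_contact_separation_um,
            kernel_half_width_ms=pop_width,
        )
        xs.append(x.values)
        ys.append(y.values)
    return xs, ys, spike_norm


def unit_population_coupling(
    session: SpikeSession,
    unit: str | SpikeTrain,
    window: str | AnalysisWindow,
    condition: str,
    min_contact_separation_um: float = 150.0,
    kernel_half_width_ms: float = KERNEL_HALF_WIDTH_MS,
    unit_kernel_mode: str = "literal",
) -> CouplingResult:
    """Population coupling of one unit over all trials of a window/condition.

    Each trial's window segment is binned at 1 ms, smoothed and
    mean-subtracted independently, and cross-products are pooled across
    segments (no smoothing or covariance across trial boundaries).
    """
    if isinstance(unit, str):
        unit = session.unit(unit)
    if isinstance(window, str):
        window = session.windows()[window]
    xs, ys, spike_norm = _segment_signals(
        session,
        unit,
        window,
        condition,
        min_contact_separation_um,
        kernel_half_width_ms,
        unit_kernel_mode,
    )
    if not xs:
        raise ValueError(f"no trials in condition {condition}")
    if spike_norm <= 0:
        raise CouplingUndefined(f"unit {unit.unit_id} silent in window {window.name}")

    sxy = sum(float(np.dot(x, y)) for x, y in zip(xs, ys))
    sxx = sum(float(np.dot(x, x)) for x in xs)
    syy = sum(float(np.dot(y, y)) for y in ys)
    n_samples = sum(x.size for x in xs)
    if sxx == 0 or syy == 0:
        raise CouplingUndefined("zero-variance signal after smoothing")

    c0 = sxy / spike_norm
    # keep degenerate perfect correlations (self-copies) just inside (-1, 1)
    # so the Fisher transform stays finite
    eps = 1e-12
    c_norm = float(np.clip(sxy / np.sqrt(sxx * syy), -1.0 + eps, 1.0 - eps))
    return CouplingResult(
        unit_id=unit.unit_id,
        window=window.name,
        condition=condition,
        C0=c0,
        C_norm=c_norm,
        Z=fisher_z(c_norm),
        n_samples=n_samples,
        spike_norm=spike_norm,
    )
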