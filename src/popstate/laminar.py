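"""Continuous-signal utilities for laminar probes.

Finite-difference current source density, SNR screening, parametric visual
response latency fitting, layer-compartment assignment relative to the
granular reference channel, and z-scored receptive-field maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize

from popstate.synthetic import latency_model

__all__ = [
    "DepthProfile",
    "LatencyFit",
    "LayerAssignment",
    "csd_finite_difference",
    "snr",
    "fit_latency",
    "assign_layers",
    "rf_zmap",
]

PROBE_SPACING_UM = 150.0


@dataclass(frozen=True)
class DepthProfile:
    """Per-channel voltages at equally spaced depths along the probe."""

    values: np.ndarray
    spacing_um: float = PROBE_SPACING_UM

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.spacing_um <= 0:
            raise ValueError("spacing must be > 0")


@dataclass(frozen=True)
class LatencyFit:
    mu: float
    sigma: float
    alpha: float
    c: float
    d: float
    latency_ms: Optional[float]
    residual: float
    converged: bool


@dataclass(frozen=True)
class LayerAssignment:
    compartments: tuple[str, ...]
    reference_channel: int
    area: str


def csd_finite_difference(
    profile: DepthProfile | np.ndarray,
    spacing_um: float = PROBE_SPACING_UM,
    sink_negative: bool = False,
) -> np.ndarray:
    """Second spatial difference ``[phi(x+h) - 2 phi(x) + phi(x-h)] / h^2``.

    Defined at interior channels only; the two end channels yield NaN.  The
    printed formula carries no negative sign; ``sink_negative=True`` flips the
    sign for the physical sink/source convention.
    """
    if isinstance(profile, DepthProfile):
        values = profile.values
        spacing_um = profile.spacing_um
    else:
        values = np.asarray(profile, dtype=float)
    if values.size < 3:
        raise ValueError("CSD needs at least 3 channels")
    out = np.full(values.size, np.nan)
    out[1:-1] = (values[2:] - 2.0 * values[1:-1] + values[:-2]) / spacing_um**2
    if sink_negative:
        out = -out
    return out


def snr(
    signal_window_means: Sequence[float],
    noise_mean: float,
    noise_sd: float,
    threshold: float = 3.0,
) -> tuple[np.ndarray, bool]:
    """``(signal - noise) / sigma_noise`` per window; pass iff max strictly > 3.

    The screening protocol uses eight 50 ms windows (30-80 ms through
    100-150 ms after stimulus onset) against the -200..50 ms baseline; the
    caller supplies the window means.
    """
    if noise_sd <= 0:
        raise ValueError("noise SD must be > 0")
    values = (np.asarray(signal_window_means, dtype=float) - noise_mean) / noise_sd
    return values, bool(values.max() > threshold)


def _earliest_peak(y: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    """(time, value) of the earliest local maximum, else the global maximum."""
    interior = np.flatnonzero((y[1:-1] >= y[:-2]) & (y[1:-1] > y[2:])) + 1
    if interior.size:
        i = int(interior[0])
    else:
        i = int(np.argmax(y))
    return float(t[i]), float(y[i])


def fit_latency(
    trace: np.ndarray,
    t_grid: np.ndarray,
    n_starts: int = 20,
    threshold_fraction: float = 0.33,
    rtol: float = 1e-8,
) -> LatencyFit:
    """Fit the 5-parameter visual-response model and read off latency.

    The model (dissipating ex-Gaussian plus cumulative Gaussian) is fit by
    multi-start nonlinear least squares; latency is the earliest time where
    the fitted curve reaches ``threshold_fraction`` of the earliest-peak
    maximum.  The 33% rule is scale invariant, so amplitude changes leave the
    latency unchanged.  A flat trace yields a non-converged flag.
    """
    trace = np.asarray(trace, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if trace.shape != t_grid.shape:
        raise ValueError("trace and t_grid must have the same shape")
    span = float(trace.max() - trace.min())
    if span <= 0 or not np.isfinite(span):
        return LatencyFit(np.nan, np.nan, np.nan, np.nan, np.nan, None,
                          np.inf, converged=False)

    t_lo, t_hi = float(t_grid[0]), float(t_grid[-1])
    amplitude = float(trace.max())
    # starts span the rise region of the trace
    rise_candidates = t_grid[trace >= 0.5 * trace.max()]
    rise_center = float(rise_candidates[0]) if rise_candidates.size else 0.5 * (t_lo + t_hi)

    def residuals(params: np.ndarray) -> np.ndarray:
        mu, log_sigma, log_alpha, c, d = params
        return latency_model(
            t_grid, mu, np.exp(log_sigma), np.exp(log_alpha), c, d
        ) - trace

    best = None
    mu_starts = np.linspace(
        max(t_lo, rise_center - 30.0), min(t_hi, rise_center + 30.0), 5
    )
    sigma_starts = (2.0, 8.0)
    d_starts = (0.0, amplitude)
    starts = [
        (mu0, s0, d0)
        for mu0 in mu_starts
        for s0 in sigma_starts
        for d0 in d_starts
    ][:n_starts]
    perfect = 1e-16 * max(span, 1.0) ** 2 * trace.size
    for mu0, s0, d0 in starts:
        x0 = np.array([mu0, np.log(s0), np.log(0.05), amplitude, d0])
        try:
            res = optimize.least_squares(residuals, x0, ftol=rtol, xtol=rtol)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < perfect:  # noiseless exact fit, stop early
            break
    if best is None:
        return LatencyFit(np.nan, np.nan, np.nan, np.nan, np.nan, None,
                          np.inf, converged=False)

    mu, log_sigma, log_alpha, c, d = best.x
    sigma, alpha = float(np.exp(log_sigma)), float(np.exp(log_alpha))
    dense_t = np.linspace(t_lo, t_hi, max(10 * t_grid.size, 2000))
    dense_y = latency_model(dense_t, mu, sigma, alpha, c, d)
    _, peak_value = _earliest_peak(dense_y, dense_t)
    if peak_value <= 0:
        return LatencyFit(mu, sigma, alpha, float(c), float(d), None,
                          float(best.cost), converged=False)
    above = np.flatnonzero(dense_y >= threshold_fraction * peak_value)
    latency = float(dense_t[above[0]]) if above.size else None
    residual = float(np.sqrt(2.0 * best.cost / trace.size))
    good = residual < 0.05 * span and latency is not None
    return LatencyFit(
        mu=float(mu), sigma=sigma, alpha=alpha, c=float(c), d=float(d),
        latency_ms=latency, residual=residual, converged=bool(good),
    )


# layer-band edges in um above (+) / below (-) the reference channel
_BANDS = {
    "V1": {"supra": (250.0, 1000.0), "gran": (-250.0, 250.0), "infra": (-750.0, -250.0)},
    "V4": {"supra": (100.0, 1000.0), "gran": (-100.0, 100.0), "infra": (-750.0, -100.0)},
}


def assign_layers(
    reference_channel: int,
    n_channels: int,
    area: str,
    spiking_flags: Optional[Sequence[bool]] = None,
    spacing_um: float = PROBE_SPACING_UM,
) -> LayerAssignment:
    """Assign each channel to a layer compartment relative to the reference.

    Contact 0 is most superficial, so channels with smaller indices lie above
    the reference.  Channels beyond the supragranular band that still show
    spiking are pulled into supragranular (V1 rule); channels beyond the
    infragranular band with spiking are pulled into infragranular; everything
    else out of band is 'outside'.
    """
    if area not in _BANDS:
        raise ValueError(f"area must be one of {sorted(_BANDS)}")
    if not 0 <= reference_channel < n_channels:
        raise ValueError("reference channel outside probe")
    if spiking_flags is None:
        spiking_flags = [True] * n_channels
    if len(spiking_flags) != n_channels:
        raise ValueError("spiking_flags length mismatch")
    bands = _BANDS[area]

    compartments = []
    for ch in range(n_channels):
        offset = (reference_channel - ch) * spacing_um  # + above, - below
        lo_g, hi_g = bands["gran"]
        lo_s, hi_s = bands["supra"]
        lo_i, hi_i = bands["infra"]
        if lo_g <= offset <= hi_g:
            label = "granular"
        elif lo_s < offset <= hi_s:
            label = "supragranular"
        elif lo_i <= offset < hi_i:
            label = "infragranular"
        elif offset > hi_s:
            label = "supragranular" if spiking_flags[ch] else "outside"
        elif offset < lo_i:
            label = "infragranular" if spiking_flags[ch] else "outside"
        else:
            label = "outside"
        if label != "granular" and not spiking_flags[ch]:
            label = "outside"
        compartments.append(label)

    # non-spiking runs at the top of the probe are outside cortex
    for ch in range(n_channels):
        if spiking_flags[ch]:
            break
        compartments[ch] = "outside"

    return LayerAssignment(
        compartments=tuple(compartments),
        reference_channel=reference_channel,
        area=area,
    )


def rf_zmap(
    response_map: np.ndarray,
    baseline_mean: float,
    baseline_sd: float,
    threshold: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score a stimulus-response grid and outline the peak RF region.

    Returns ``(zmap, mask)`` where the mask is the 4-connected component of
    ``z >= threshold`` cells containing the peak; an empty mask means the peak
    never reaches threshold.
    """
    if baseline_sd <= 0:
        raise ValueError("baseline SD must be > 0")
    grid = np.asarray(response_map, dtype=float)
    zmap = (grid - baseline_mean) / baseline_sd
    above = zmap >= threshold
    mask = np.zeros_like(above)
    if above.any():
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        labeled, _ = ndimage.label(above, structure=structure)
        peak = np.unravel_index(np.argmax(zmap), zmap.shape)
        if above[peak]:
            mask = labeled == labeled[peak]
    return zmap, mask
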