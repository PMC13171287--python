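"""Per-unit and pairwise state metrics: ON/OFF ratio, attention index,
noise correlations, rate matching, and cross-metric correlation analyses."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from popstate.coupling import CouplingResult
from popstate.data_model import (
    AnalysisWindow,
    SpikeSession,
    SpikeTrain,
    TrialEpochs,
    resolve_window,
)
from popstate.hmm import StateTrajectory

__all__ = [
    "RatioResult",
    "PairMetrics",
    "RateMatchResult",
    "UnitMetrics",
    "on_off_ratio",
    "attention_modulation_index",
    "noise_correlation",
    "rate_match",
    "metric_correlations",
    "paircoupling_regression",
    "compare_conditions",
]


@dataclass(frozen=True)
class RatioResult:
    """Trial-averaged ON/OFF firing-rate ratio of one unit."""

    unit_id: str
    ratio: Optional[float]  # None when no trial had both phases
    n_trials_used: int
    n_trials_excluded: int

    @property
    def defined(self) -> bool:
        return self.ratio is not None


@dataclass(frozen=True)
class PairMetrics:
    unit_i: str
    unit_j: str
    condition: str
    noise_correlation: float
    n_trials: int

    def __post_init__(self) -> None:
        if self.unit_i == self.unit_j:
            raise ValueError("noise correlation needs two distinct units")
        if not -1.0 <= self.noise_correlation <= 1.0:
            raise ValueError("noise correlation outside [-1, 1]")


@dataclass(frozen=True)
class RateMatchResult:
    kept_a: np.ndarray  # retained trial indices, condition A
    kept_b: np.ndarray
    matched: bool
    relative_difference: float
    n_removed: int


@dataclass
class UnitMetrics:
    """Bundle of per-unit metrics feeding the correlation analyses."""

    unit_id: str
    condition: str
    window: str
    on_off_ratio: Optional[float] = None
    att_mi: Optional[float] = None
    coupling: Optional[CouplingResult] = None
    layer: Optional[str] = None
    area: Optional[str] = None
    included: bool = True
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.att_mi is not None and not -1.0 <= self.att_mi <= 1.0:
            raise ValueError("attMI outside [-1, 1]")
        if self.on_off_ratio is not None and self.on_off_ratio <= 0:
            raise ValueError("on_off_ratio must be > 0 when defined")


def _phase_rates(
    spike_times: np.ndarray,
    trajectory: StateTrajectory,
    interval: tuple[float, float],
) -> tuple[Optional[float], Optional[float]]:
    """(off_rate_hz, on_rate_hz) of a unit over one decoded trial window.

    The trajectory's bins are assumed to tile ``interval`` from its start.
    Returns None for a phase absent from the trial.
    """
    if trajectory.labels is None:
        raise ValueError("trajectory lacks ON/OFF labels (need a two-phase model)")
    bin_ms = trajectory.bin_ms
    start = interval[0]
    labels = trajectory.labels
    n_bins = labels.size
    t = spike_times
    t = t[(t >= start) & (t < start + n_bins * bin_ms)]
    bins = np.floor((t - start) / bin_ms).astype(int)
    counts = np.bincount(bins, minlength=n_bins)

    out = []
    for label in ("OFF", "ON"):
        mask = labels == label
        duration_s = mask.sum() * bin_ms / 1000.0
        if duration_s == 0:
            out.append(None)
        else:
            out.append(float(counts[mask].sum() / duration_s))
    return out[0], out[1]


def on_off_ratio(
    unit: SpikeTrain,
    trajectories: Mapping[str, StateTrajectory],
    intervals: Mapping[str, tuple[float, float]],
) -> RatioResult:
    """Trial-averaged ratio of ON-phase to OFF-phase firing rate.

    Per trial the unit's rate in ON bins is divided by its rate in OFF bins;
    trials missing either phase or with a zero OFF rate are excluded from the
    average (and counted), never mapped to infinity.
    """
    ratios = []
    excluded = 0
    for trial_id, trajectory in trajectories.items():
        off_rate, on_rate = _phase_rates(
            unit.spike_times, trajectory, intervals[trial_id]
        )
        if off_rate is None or on_rate is None or off_rate == 0.0:
            excluded += 1
            continue
        ratios.append(on_rate / off_rate)
    ratio = float(np.mean(ratios)) if ratios else None
    return RatioResult(
        unit_id=unit.unit_id,
        ratio=ratio,
        n_trials_used=len(ratios),
        n_trials_excluded=excluded,
    )


def attention_modulation_index(a_rf: float, a_away: float) -> float:
    """``attMI = (A_RF - A_away) / (A_RF + A_away)``; positive favors attend-RF."""
    if a_rf < 0 or a_away < 0:
        raise ValueError("activities must be >= 0")
    total = a_rf + a_away
    if total == 0:
        raise ValueError("attMI undefined: both activities are zero")
    return (a_rf - a_away) / total


def unit_attention_index(
    unit: SpikeTrain,
    session: SpikeSession,
    window: str | AnalysisWindow = "cue_to_dimming",
) -> float:
    """attMI of one unit from mean rates in an analysis window."""
    if isinstance(window, str):
        window = session.windows()[window]
    means = {}
    for condition in ("attend_RF", "attend_away"):
        rates = []
        for trial in session.trials_in(condition):
            start, end = resolve_window(window, trial)
            n = np.count_nonzero(
                (unit.spike_times >= start) & (unit.spike_times < end)
            )
            rates.append(1000.0 * n / (end - start))
        means[condition] = float(np.mean(rates))
    return attention_modulation_index(means["attend_RF"], means["attend_away"])


def _per_trial_counts(
    unit: SpikeTrain, trials: Sequence[TrialEpochs], window: AnalysisWindow
) -> np.ndarray:
    counts = []
    for trial in trials:
        start, end = resolve_window(window, trial)
        counts.append(
            int(np.count_nonzero((unit.spike_times >= start) & (unit.spike_times < end)))
        )
    return np.asarray(counts, dtype=float)


def noise_correlation(
    unit_i: SpikeTrain,
    unit_j: SpikeTrain,
    session: SpikeSession,
    condition: str,
    window: str | AnalysisWindow = "pre_dimming",
    min_trials: int = 10,
) -> PairMetrics:
    """Pearson correlation of two units' per-trial spike counts.

    Counts are taken from the 500-0 ms pre-dimming window by default.
    """
    if isinstance(window, str):
        window = session.windows()[window]
    trials = session.trials_in(condition)
    if len(trials) < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {len(trials)}")
    ci = _per_trial_counts(unit_i, trials, window)
    cj = _per_trial_counts(unit_j, trials, window)
    if np.std(ci) == 0 or np.std(cj) == 0:
        raise ValueError(
            f"zero count variance for pair ({unit_i.unit_id}, {unit_j.unit_id})"
        )
    r = float(np.corrcoef(ci, cj)[0, 1])
    return PairMetrics(
        unit_i=unit_i.unit_id,
        unit_j=unit_j.unit_id,
        condition=condition,
        noise_correlation=float(np.clip(r, -1.0, 1.0)),
        n_trials=len(trials),
    )


def _relative_difference(mean_a: float, mean_b: float) -> float:
    denom = 0.5 * (mean_a + mean_b)
    if denom == 0:
        return 0.0
    return abs(mean_a - mean_b) / denom


def rate_match(
    rates_a: Sequence[float],
    rates_b: Sequence[float],
    tolerance: float = 0.02,
    min_trials: int = 10,
) -> RateMatchResult:
    """Equalize condition means by dropping low-activity trials.

    The lowest-rate trial is removed from whichever condition currently has
    the LOWER mean (raising it toward the other) until the relative mean
    difference — ``|mean_a - mean_b| / ((mean_a + mean_b)/2)`` — drops below
    ``tolerance``, or either condition reaches ``min_trials`` trials, in which
    case the result is flagged unmatched.
    """
    rates_a = np.asarray(rates_a, dtype=float)
    rates_b = np.asarray(rates_b, dtype=float)
    kept_a = list(range(rates_a.size))
    kept_b = list(range(rates_b.size))
    removed = 0

    while True:
        mean_a = rates_a[kept_a].mean()
        mean_b = rates_b[kept_b].mean()
        diff = _relative_difference(mean_a, mean_b)
        if diff < tolerance:
            return RateMatchResult(
                kept_a=np.asarray(kept_a),
                kept_b=np.asarray(kept_b),
                matched=True,
                relative_difference=diff,
                n_removed=removed,
            )
        lower_is_a = mean_a < mean_b
        pool = kept_a if lower_is_a else kept_b
        rates = rates_a if lower_is_a else rates_b
        if len(pool) <= min_trials:
            return RateMatchResult(
                kept_a=np.asarray(kept_a),
                kept_b=np.asarray(kept_b),
                matched=False,
                relative_difference=diff,
                n_removed=removed,
            )
        drop = min(pool, key=lambda i: rates[i])
        pool.remove(drop)
        removed += 1


def metric_correlations(
    units: Iterable[UnitMetrics],
) -> dict[str, dict[str, float]]:
    """Pearson correlations of coupling Z against ON/OFF ratio and attMI.

    Units lacking a metric are dropped pairwise; at least 3 complete units
    are required per comparison.
    """
    units = [u for u in units if u.coupling is not None]
    out: dict[str, dict[str, float]] = {}
    for name, getter in (
        ("z_vs_on_off_ratio", lambda u: u.on_off_ratio),
        ("z_vs_att_mi", lambda u: u.att_mi),
    ):
        pairs = [
            (u.coupling.Z, getter(u)) for u in units if getter(u) is not None
        ]
        if len(pairs) < 3:
            raise ValueError(
                f"{name}: need >= 3 units with defined metrics, got {len(pairs)}"
            )
        z, m = map(np.asarray, zip(*pairs))
        if np.std(z) == 0 or np.std(m) == 0:
            raise ValueError(f"{name}: degenerate variance")
        r, p = stats.pearsonr(z, m)
        out[name] = {"r": float(r), "p": float(p), "r2": float(r**2), "n": len(pairs)}
    return out


def paircoupling_regression(
    pairs: Sequence[PairMetrics],
    coupling_z: Mapping[str, float],
    symmetric: bool = True,
) -> dict:
    """Least-squares fit of pair noise correlation on member couplings.

    Symmetric design (default) regresses ``r_ij`` on ``Z_i + Z_j`` and
    ``Z_i * Z_j`` plus an intercept, making the fit invariant under swapping
    the pair members; ``symmetric=False`` uses separate Z_i and Z_j terms.
    """
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 pairs, got {len(pairs)}")
    zi = np.array([coupling_z[p.unit_i] for p in pairs])
    zj = np.array([coupling_z[p.unit_j] for p in pairs])
    r = np.array([p.noise_correlation for p in pairs])

    if symmetric:
        design = np.column_stack([np.ones_like(r), zi + zj, zi * zj])
        names = ["intercept", "z_sum", "z_product"]
    else:
        design = np.column_stack([np.ones_like(r), zi, zj, zi * zj])
        names = ["intercept", "z_i", "z_j", "z_product"]
    coef, _, rank, _ = np.linalg.lstsq(design, r, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fitted = design @ coef
    ss_res = float(((r - fitted) ** 2).sum())
    ss_tot = float(((r - r.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return {
        "coefficients": dict(zip(names, coef.tolist())),
        "r_squared": r2,
        "n_pairs": len(pairs),
    }


def compare_conditions(
    *groups: Sequence[float],
    paired: bool = False,
    alpha: float = 0.05,
) -> dict:
    """Nonparametric comparison of two or more samples.

    Two groups: Wilcoxon signed-rank (paired) or rank-sum (unpaired).  Three
    or more: Kruskal-Wallis with Bonferroni-corrected pairwise rank-sum post
    hocs.  Identical paired samples yield p = 1 rather than an error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")

    if len(arrays) == 2:
        a, b = arrays
        if paired:
            if a.size != b.size:
                raise ValueError("paired comparison needs equal sizes")
            if not np.any(a - b):
                return {"test": "wilcoxon_signed_rank", "p": 1.0,
                        "significant": False}
            res = stats.wilcoxon(a, b, zero_method="wilcox")
            return {
                "test": "wilcoxon_signed_rank",
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
                "significant": bool(res.pvalue < alpha),
            }
        res = stats.ranksums(a, b)
        return {
            "test": "rank_sum",
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "significant": bool(res.pvalue < alpha),
        }

    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return {"test": "kruskal_wallis", "p": 1.0, "significant": False,
                "posthoc": []}
    res = stats.kruskal(*arrays)
    report = {
        "test": "kruskal_wallis",
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "significant": bool(res.pvalue < alpha),
        "posthoc": [],
    }
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            ph = stats.ranksums(arrays[i], arrays[j])
            p_adj = min(float(ph.pvalue) * n_pairs, 1.0)
            report["posthoc"].append(
                {
                    "groups": (i, j),
                    "p_bonferroni": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return report
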