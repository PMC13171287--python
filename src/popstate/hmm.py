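"""Multichannel Poisson hidden Markov model of ON/OFF population states.

Spike counts in 10 ms bins on each channel are modeled as Poisson with a
channel- and phase-specific mean; all channels share one latent first-order
Markov phase sequence.  Fitting uses Baum-Welch EM with 10 random restarts,
decoding uses Viterbi, and the number of phases is selected by fourfold
leave-one-channel-out cross-validation with a 10% elbow rule.

Count matrices are channel x time (J x T); internally trials of equal length
are batched so the forward-backward and Viterbi recursions run vectorized
across trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy.special import gammaln

from popstate.data_model import AnalysisWindow, SpikeSession, resolve_window
from popstate.preprocessing import bin_spikes

__all__ = [
    "PoissonHMM",
    "StateTrajectory",
    "CVReport",
    "emission_logprob",
    "forward_backward",
    "em_fit",
    "multi_restart_fit",
    "viterbi",
    "cv_error",
    "select_num_phases",
    "label_on_off",
    "session_counts",
]

LAMBDA_FLOOR = 1e-8  # numerical guard against log(0) for phase-silent channels
DEFAULT_BIN_MS = 10.0
LOGLIK_RTOL = 1e-3
PARAM_ATOL = 1e-5
MAX_ITER = 500
N_RESTARTS = 10


@dataclass
class PoissonHMM:
    """Fitted model: emissions ``lam`` (S x J counts/bin), transitions, start."""

    lam: np.ndarray
    P: np.ndarray
    pi0: np.ndarray
    log_likelihood: float = np.nan
    n_iterations: int = 0
    converged: bool = False
    bin_ms: float = DEFAULT_BIN_MS

    def __post_init__(self) -> None:
        self.lam = np.atleast_2d(np.asarray(self.lam, dtype=float))
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        self.pi0 = np.asarray(self.pi0, dtype=float)
        S = self.lam.shape[0]
        if self.P.shape != (S, S):
            raise ValueError(f"P must be {S}x{S}")
        if self.pi0.shape != (S,):
            raise ValueError(f"pi0 must have length {S}")
        if np.any(self.lam < 0):
            raise ValueError("emission rates must be >= 0")
        if np.max(np.abs(self.P.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("rows of P must sum to 1")
        if abs(self.pi0.sum() - 1.0) > 1e-12:
            raise ValueError("pi0 must sum to 1")

    @property
    def n_phases(self) -> int:
        return self.lam.shape[0]

    @property
    def n_channels(self) -> int:
        return self.lam.shape[1]

    def to_dict(self) -> dict:
        return {
            "n_phases": self.n_phases,
            "lam": self.lam.tolist(),
            "P": self.P.tolist(),
            "pi0": self.pi0.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "bin_ms": self.bin_ms,
        }


@dataclass(frozen=True)
class StateTrajectory:
    """Most-likely phase sequence of one trial, with ON/OFF labels when S=2."""

    trial_id: str
    phases: np.ndarray
    labels: Optional[np.ndarray] = None  # 'ON'/'OFF' per bin, two-phase only
    bin_ms: float = DEFAULT_BIN_MS


@dataclass
class CVReport:
    """Leave-one-channel-out cross-validation across phase counts."""

    cv_var: dict  # S -> normalized CV error (S=1 -> 1.0)
    per_fold: dict  # S -> list of per-fold normalized errors
    selected: int
    passed: Optional[bool]
    folds: int = 4

    def reduction(self, s: int) -> float:
        """Fractional CV-error reduction going from S=s-1 to S=s."""
        return 1.0 - self.cv_var[s] / self.cv_var[s - 1]


def emission_logprob(n: int, lam: float) -> float:
    """Log Poisson pmf ``log P(n | lam)``; lam = 0 is the point mass at 0."""
    if n < 0 or int(n) != n:
        raise ValueError(f"count must be a nonnegative integer, got {n}")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0.0:
        return 0.0 if n == 0 else -np.inf
    return float(n * np.log(lam) - lam - gammaln(n + 1.0))


def _as_trials(counts) -> list[np.ndarray]:
    """Normalize input to a list of (J, T) integer matrices."""
    if isinstance(counts, np.ndarray) and counts.ndim == 2:
        counts = [counts]
    out = []
    for c in counts:
        c = np.asarray(c)
        if c.ndim != 2:
            raise ValueError("each trial must be a J x T count matrix")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")
        out.append(c)
    if not out:
        raise ValueError("no trials supplied")
    J = out[0].shape[0]
    if any(c.shape[0] != J for c in out):
        raise ValueError("all trials must share the channel dimension")
    return out


def _emission_const(batch: np.ndarray) -> np.ndarray:
    """(K, T) factorial term of the Poisson log pmf; independent of lam."""
    return -gammaln(batch + 1.0).sum(axis=2)


def _log_emissions(
    batch: np.ndarray, lam: np.ndarray, const: Optional[np.ndarray] = None
) -> np.ndarray:
    """(K, T, S) log emission probabilities for a (K, T, J) count batch."""
    # sum_j [ n log lam - lam - log n! ]; the floor only guards the log term,
    # so lam = 0 with n = 0 contributes exactly 0
    log_lam = np.log(np.maximum(lam, LAMBDA_FLOOR))
    if const is None:
        const = _emission_const(batch)  # recomputable but cached inside EM
    return batch @ log_lam.T - lam.sum(axis=1) + const[:, :, None]


def _group_by_length(trials: list[np.ndarray]) -> dict[int, tuple[list[int], np.ndarray]]:
    """Group (J,T) trials by T into batched (K,T,J) arrays, keeping indices."""
    groups: dict[int, list[int]] = {}
    for i, c in enumerate(trials):
        groups.setdefault(c.shape[1], []).append(i)
    return {
        T: (idx, np.stack([trials[i].T for i in idx]).astype(float))
        for T, idx in groups.items()
    }


@njit(cache=True)
def _fb_kernel(B, P, pi0):  # pragma: no cover - exercised via wrapper
    """Scaled forward-backward recursions on a (K, T, S) emission batch."""
    K, T, S = B.shape
    alpha = np.empty((K, T, S))
    beta = np.empty((K, T, S))
    gamma = np.empty((K, T, S))
    c = np.empty((K, T))
    xi_sum = np.zeros((S, S))
    log_c_total = 0.0
    for k in range(K):
        # forward
        total = 0.0
        for s in range(S):
            alpha[k, 0, s] = pi0[s] * B[k, 0, s]
            total += alpha[k, 0, s]
        if total <= 0.0:
            raise FloatingPointError("all-zero emission row in forward pass")
        c[k, 0] = total
        for s in range(S):
            alpha[k, 0, s] /= total
        for t in range(1, T):
            total = 0.0
            for s2 in range(S):
                acc = 0.0
                for s1 in range(S):
                    acc += alpha[k, t - 1, s1] * P[s1, s2]
                acc *= B[k, t, s2]
                alpha[k, t, s2] = acc
                total += acc
            if total <= 0.0:
                raise FloatingPointError("all-zero emission row in forward pass")
            c[k, t] = total
            for s2 in range(S):
                alpha[k, t, s2] /= total
        # backward + xi accumulation
        for s in range(S):
            beta[k, T - 1, s] = 1.0
        for t in range(T - 2, -1, -1):
            for s1 in range(S):
                acc = 0.0
                for s2 in range(S):
                    bb = B[k, t + 1, s2] * beta[k, t + 1, s2] / c[k, t + 1]
                    acc += P[s1, s2] * bb
                    xi_sum[s1, s2] += alpha[k, t, s1] * P[s1, s2] * bb
                beta[k, t, s1] = acc
        for t in range(T):
            norm = 0.0
            for s in range(S):
                gamma[k, t, s] = alpha[k, t, s] * beta[k, t, s]
                norm += gamma[k, t, s]
            for s in range(S):
                gamma[k, t, s] /= norm
            log_c_total += np.log(c[k, t])
    return gamma, xi_sum, log_c_total


def _forward_backward_batch(
    batch: np.ndarray,
    model: PoissonHMM,
    const: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Scaled forward-backward on a (K, T, J) batch.

    Returns (gamma (K,T,S), xi_sum (S,S) pooled over the batch,
    gamma0 (K,S), total log-likelihood).
    """
    logB = _log_emissions(batch, model.lam, const)  # (K,T,S)
    shift = logB.max(axis=2, keepdims=True)
    B = np.exp(logB - shift)  # max 1 per (k,t)
    gamma, xi_sum, log_c = _fb_kernel(
        np.ascontiguousarray(B),
        np.ascontiguousarray(model.P),
        np.ascontiguousarray(model.pi0),
    )
    loglik = float(log_c + shift.sum())
    return gamma, xi_sum, gamma[:, 0, :], loglik


def forward_backward(counts, model: PoissonHMM) -> tuple[np.ndarray, float]:
    """Per-bin phase posteriors and log-likelihood for one (J, T) trial."""
    trial = _as_trials(counts)[0]
    if trial.shape[0] != model.n_channels:
        raise ValueError(
            f"counts have {trial.shape[0]} channels, model has {model.n_channels}"
        )
    batch = trial.T[None, :, :].astype(float)
    gamma, _, _, loglik = _forward_backward_batch(batch, model)
    return gamma[0], loglik


def _loglik(trials: list[np.ndarray], model: PoissonHMM) -> float:
    total = 0.0
    for _, (idx, batch) in _group_by_length(trials).items():
        _, _, _, ll = _forward_backward_batch(batch, model)
        total += ll
    return total


def em_fit(
    counts,
    n_phases: int,
    init: Optional[PoissonHMM] = None,
    loglik_rtol: float = LOGLIK_RTOL,
    param_atol: float = PARAM_ATOL,
    max_iter: int = MAX_ITER,
) -> PoissonHMM:
    """Baum-Welch EM from one initialization.

    Terminates when the relative log-likelihood change ``|new - old| / |old|``
    falls below ``loglik_rtol`` AND the maximum absolute elementwise change of
    the emission and transition matrices falls below ``param_atol``, or at
    ``max_iter`` iterations.  The log-likelihood is nondecreasing across
    iterations.
    """
    trials = _as_trials(counts)
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    J = trials[0].shape[0]

    if n_phases == 1:
        # exact Poisson ML: per-channel mean count
        total = sum(c.sum(axis=1) for c in trials)
        n_bins = sum(c.shape[1] for c in trials)
        lam = (total / n_bins)[None, :]
        model = PoissonHMM(
            lam=lam, P=np.array([[1.0]]), pi0=np.array([1.0]), converged=True
        )
        model.log_likelihood = _loglik(trials, model)
        return model

    if init is None:
        mean_rate = sum(c.sum(axis=1) for c in trials) / sum(
            c.shape[1] for c in trials
        )
        # spread deterministic starts around the mean rate
        factors = np.linspace(0.5, 1.5, n_phases)
        lam = np.maximum(np.outer(factors, mean_rate), LAMBDA_FLOOR)
        P = np.full((n_phases, n_phases), 0.1 / max(n_phases - 1, 1))
        np.fill_diagonal(P, 0.9)
        pi0 = np.full(n_phases, 1.0 / n_phases)
        model = PoissonHMM(lam=lam, P=P, pi0=pi0)
    else:
        model = PoissonHMM(
            lam=init.lam.copy(), P=init.P.copy(), pi0=init.pi0.copy(),
            bin_ms=init.bin_ms,
        )
    if model.n_channels != J:
        raise ValueError("init model channel count mismatch")

    groups = _group_by_length(trials)
    consts = {T: _emission_const(batch) for T, (_, batch) in groups.items()}
    prev_ll = -np.inf
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        S = n_phases
        gamma_n_sum = np.zeros((S, J))
        gamma_sum = np.zeros(S)
        xi_total = np.zeros((S, S))
        gamma_last_sum = np.zeros(S)  # occupancy of final bins (excluded from P denom)
        pi0_acc = np.zeros(S)
        n_trials = 0
        ll = 0.0
        for T, (idx, batch) in groups.items():
            gamma, xi_sum, gamma0, part = _forward_backward_batch(
                batch, model, consts[T]
            )
            ll += part
            xi_total += xi_sum
            S_dim, J_dim = n_phases, batch.shape[2]
            gamma_n_sum += (
                gamma.reshape(-1, S_dim).T @ batch.reshape(-1, J_dim)
            )
            gamma_sum += gamma.sum(axis=(0, 1))
            gamma_last_sum += gamma[:, -1, :].sum(axis=0)
            pi0_acc += gamma0.sum(axis=0)
            n_trials += batch.shape[0]

        new_lam = np.maximum(
            gamma_n_sum / np.maximum(gamma_sum[:, None], 1e-300), LAMBDA_FLOOR
        )
        denom = np.maximum(gamma_sum - gamma_last_sum, 1e-300)
        new_P = xi_total / denom[:, None]
        new_P = np.maximum(new_P, 1e-300)
        new_P /= new_P.sum(axis=1, keepdims=True)
        new_pi0 = pi0_acc / n_trials
        new_pi0 = np.maximum(new_pi0, 1e-300)
        new_pi0 /= new_pi0.sum()

        param_delta = max(
            float(np.abs(new_lam - model.lam).max()),
            float(np.abs(new_P - model.P).max()),
        )
        model = PoissonHMM(lam=new_lam, P=new_P, pi0=new_pi0, bin_ms=model.bin_ms)

        if np.isfinite(prev_ll):
            rel = abs(ll - prev_ll) / max(abs(prev_ll), 1e-300)
            if rel < loglik_rtol and param_delta < param_atol:
                converged = True
                prev_ll = ll
                break
        prev_ll = ll

    model.log_likelihood = _loglik(trials, model)
    model.n_iterations = iteration
    model.converged = converged
    return model


def _random_init(
    trials: list[np.ndarray], n_phases: int, rng: np.random.Generator
) -> PoissonHMM:
    """Random start: Dirichlet(1) rows for pi0/P, Uniform(0, 2*mean) emissions."""
    mean_rate = sum(c.sum(axis=1) for c in trials) / sum(c.shape[1] for c in trials)
    lam = rng.uniform(0.0, 2.0 * np.maximum(mean_rate, LAMBDA_FLOOR),
                      size=(n_phases, mean_rate.size))
    lam = np.maximum(lam, LAMBDA_FLOOR)
    P = rng.dirichlet(np.ones(n_phases), size=n_phases)
    pi0 = rng.dirichlet(np.ones(n_phases))
    return PoissonHMM(lam=lam, P=P, pi0=pi0)


def multi_restart_fit(
    counts,
    n_phases: int,
    rng: np.random.Generator,
    n_restarts: int = N_RESTARTS,
    **em_kwargs,
) -> PoissonHMM:
    """Best-of-``n_restarts`` EM fits by training log-likelihood."""
    trials = _as_trials(counts)
    if n_phases == 1:
        return em_fit(trials, 1)
    best: Optional[PoissonHMM] = None
    for _ in range(n_restarts):
        model = em_fit(trials, n_phases, init=_random_init(trials, n_phases, rng),
                       **em_kwargs)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    assert best is not None
    return best


def viterbi(counts, model: PoissonHMM, trial_id: str = "") -> StateTrajectory:
    """Most likely phase path of one (J, T) trial (log-space recursion).

    Ties are broken toward the lower phase index.
    """
    trial = _as_trials(counts)[0]
    path = _viterbi_batch(trial.T[None, :, :].astype(float), model)[0]
    labels = None
    if model.n_phases == 2:
        mapping = label_on_off(model)
        labels = np.array([mapping[p] for p in path])
    return StateTrajectory(
        trial_id=trial_id, phases=path, labels=labels, bin_ms=model.bin_ms
    )


@njit(cache=True)
def _viterbi_kernel(logB, logP, logpi):  # pragma: no cover - via wrapper
    K, T, S = logB.shape
    paths = np.empty((K, T), dtype=np.int64)
    delta = np.empty(S)
    new_delta = np.empty(S)
    psi = np.empty((T, S), dtype=np.int64)
    for k in range(K):
        for s in range(S):
            delta[s] = logpi[s] + logB[k, 0, s]
        for t in range(1, T):
            for s2 in range(S):
                best = -np.inf
                arg = 0
                for s1 in range(S):
                    v = delta[s1] + logP[s1, s2]
                    if v > best:  # strict > keeps ties at the lower index
                        best = v
                        arg = s1
                psi[t, s2] = arg
                new_delta[s2] = best + logB[k, t, s2]
            for s2 in range(S):
                delta[s2] = new_delta[s2]
        best = -np.inf
        arg = 0
        for s in range(S):
            if delta[s] > best:
                best = delta[s]
                arg = s
        paths[k, T - 1] = arg
        for t in range(T - 2, -1, -1):
            paths[k, t] = psi[t + 1, paths[k, t + 1]]
    return paths


def _viterbi_batch(batch: np.ndarray, model: PoissonHMM) -> np.ndarray:
    """Viterbi paths for a (K, T, J) batch; returns (K, T) int paths."""
    logB = _log_emissions(batch, model.lam)
    with np.errstate(divide="ignore"):
        logP = np.log(model.P)
        logpi = np.log(model.pi0)
    return _viterbi_kernel(
        np.ascontiguousarray(logB),
        np.ascontiguousarray(logP),
        np.ascontiguousarray(logpi),
    )


def label_on_off(model: PoissonHMM) -> dict[int, str]:
    """Map the higher-rate phase to 'ON' (two-phase models only)."""
    if model.n_phases != 2:
        raise ValueError("ON/OFF labeling is defined for two-phase models only")
    means = model.lam.mean(axis=1)
    if means[0] == means[1]:
        raise ValueError("phases have equal mean rates; labeling ambiguous")
    on = int(np.argmax(means))
    return {on: "ON", 1 - on: "OFF"}


def _fold_assignment(
    n_trials: int, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    order = rng.permutation(n_trials)
    return [np.sort(part) for part in np.array_split(order, folds)]


def _held_out_error(
    test_trials: list[np.ndarray], model: PoissonHMM
) -> np.ndarray:
    """Per-channel leave-one-channel-out squared error on held-out trials.

    For each channel j the phase path is decoded by Viterbi from all channels
    except j, then ``sum_t (n_tj - lam_j,s_t)^2`` is accumulated.
    """
    J = model.n_channels
    err = np.zeros(J)
    groups = _group_by_length(test_trials)
    for T, (idx, batch) in groups.items():
        if model.n_phases == 1:
            lam = model.lam[0]
            err += ((batch - lam[None, None, :]) ** 2).sum(axis=(0, 1))
            continue
        for j in range(J):
            keep = [k for k in range(J) if k != j]
            sub_model = PoissonHMM(
                lam=model.lam[:, keep],
                P=model.P,
                pi0=model.pi0,
                bin_ms=model.bin_ms,
            )
            paths = _viterbi_batch(batch[:, :, keep], sub_model)  # (K, T)
            predicted = model.lam[paths, j]  # (K, T)
            err[j] += ((batch[:, :, j] - predicted) ** 2).sum()
    return err


def cv_error(
    counts,
    n_phases: int,
    folds: int = 4,
    rng: Optional[np.random.Generator] = None,
    n_restarts: int = N_RESTARTS,
    fold_sets: Optional[list[np.ndarray]] = None,
    **em_kwargs,
) -> tuple[float, list[float]]:
    """Normalized fourfold leave-one-channel-out CV error for one phase count.

    Per fold, the model is fit on 3/4 of the trials; on each held-out trial,
    each channel's counts are predicted from the phase path decoded without
    that channel.  Per-channel errors are normalized to the one-phase model's
    error on the same fold, averaged over channels, then over folds.
    Returns ``(mean normalized error, per-fold values)``.
    """
    trials = _as_trials(counts)
    if len(trials) < folds:
        raise ValueError(f"need at least {folds} trials, got {len(trials)}")
    if rng is None:
        rng = np.random.default_rng()
    if fold_sets is None:
        fold_sets = _fold_assignment(len(trials), folds, rng)

    per_fold = []
    for test_idx in fold_sets:
        test_set = set(int(i) for i in test_idx)
        train = [c for i, c in enumerate(trials) if i not in test_set]
        test = [c for i, c in enumerate(trials) if i in test_set]
        if not train or not test:
            raise ValueError("fold with empty train or test set")
        base = em_fit(train, 1)
        base_err = _held_out_error(test, base)
        if n_phases == 1:
            model = base
        else:
            model = multi_restart_fit(
                train, n_phases, rng, n_restarts=n_restarts, **em_kwargs
            )
        err = _held_out_error(test, model)
        ratio = err / np.maximum(base_err, 1e-300)
        per_fold.append(float(ratio.mean()))
    return float(np.mean(per_fold)), per_fold


def select_num_phases(
    counts,
    s_range: Sequence[int] = range(1, 9),
    folds: int = 4,
    rng: Optional[np.random.Generator] = None,
    n_restarts: int = N_RESTARTS,
    reduction_threshold: float = 0.10,
    **em_kwargs,
) -> CVReport:
    """Apply the 10% CV-error elbow rule across a range of phase counts.

    A recording passes when adding a second phase reduces the normalized CV
    error by at least ``reduction_threshold`` while no later phase adds
    another reduction above it.  The same fold split is reused for every S.
    """
    s_range = sorted(set(int(s) for s in s_range))
    if s_range[0] != 1:
        s_range = [1] + s_range
    trials = _as_trials(counts)
    if rng is None:
        rng = np.random.default_rng()
    fold_sets = _fold_assignment(len(trials), folds, rng)

    cv: dict[int, float] = {}
    per_fold: dict[int, list[float]] = {}
    for s in s_range:
        mean_err, fold_vals = cv_error(
            trials, s, folds=folds, rng=rng, n_restarts=n_restarts,
            fold_sets=fold_sets, **em_kwargs,
        )
        cv[s], per_fold[s] = mean_err, fold_vals

    if len(s_range) == 1:
        return CVReport(cv_var=cv, per_fold=per_fold, selected=s_range[0],
                        passed=None, folds=folds)

    reductions = {
        s: 1.0 - cv[s] / cv[prev]
        for prev, s in zip(s_range[:-1], s_range[1:])
    }
    qualifying = [s for s, r in reductions.items() if r >= reduction_threshold]
    selected = max(qualifying) if qualifying else 1
    passed = selected == 2 if 2 in reductions else None
    return CVReport(cv_var=cv, per_fold=per_fold, selected=selected,
                    passed=passed, folds=folds)


def session_counts(
    session: SpikeSession,
    window: str | AnalysisWindow,
    condition: str,
    bin_ms: float = DEFAULT_BIN_MS,
    channels: Optional[Sequence[int]] = None,
) -> tuple[list[np.ndarray], list[str]]:
    """Per-trial (J, T) multi-unit count matrices for an HMM fit.

    Only whole bins inside the resolved window are used, so the latent
    trajectory aligns with 10 ms bin edges.  Returns the matrices and the
    matching trial ids.
    """
    if isinstance(window, str):
        window = session.windows()[window]
    if channels is None:
        channels = range(session.n_channels)
    channels = list(channels)
    mua = {t.channel_index: t for t in session.multi_units()}
    missing = [j for j in channels if j not in mua]
    if missing:
        raise ValueError(f"no multi-unit train on channels {missing}")

    matrices, trial_ids = [], []
    for trial in session.trials_in(condition):
        start, end = resolve_window(window, trial)
        n_bins = int(np.floor((end - start) / bin_ms))
        if n_bins < 1:
            continue
        stop = start + n_bins * bin_ms
        rows = [
            bin_spikes(mua[j], (start, stop), bin_ms=bin_ms) for j in channels
        ]
        matrices.append(np.vstack(rows))
        trial_ids.append(trial.trial_id)
    if not matrices:
        raise ValueError(f"window {window.name} empty on every {condition} trial")
    return matrices, trial_ids
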