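"""Configuration handling and end-to-end orchestration.

A run chains: load-or-generate session -> unit filters -> two-phase HMM fit
and per-trial decoding -> per-unit population coupling -> state metrics ->
TSV/JSON report bundle with a manifest.  One global seed fans out to
per-stage independent substreams so stages are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

import popstate
from popstate.coupling import CouplingUndefined, unit_population_coupling
from popstate.data_model import (
    CONDITIONS,
    SpikeSession,
    read_session,
    resolve_window,
)
from popstate.hmm import (
    multi_restart_fit,
    select_num_phases,
    session_counts,
    viterbi,
)
from popstate.metrics import (
    UnitMetrics,
    metric_correlations,
    noise_correlation,
    on_off_ratio,
    unit_attention_index,
)
from popstate.preprocessing import inclusion_filter
from popstate.synthetic import GeneratorConfig, UnitSpec, generate_session

logger = logging.getLogger("popstate")

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """A run configuration is invalid; the message lists every violation."""


_DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "popstate_out",
    "input": None,
    "generator": None,
    "windows": {"pc": "cue_to_dimming", "att_mi": "cue_to_dimming",
                "hmm": "cue_to_dimming", "noise": "pre_dimming"},
    "hmm": {"s_range": [1, 2, 3], "folds": 4, "restarts": 10,
            "run_selection": True},
    "pc": {"kernel_half_width_ms": 12.0, "unit_kernel_mode": "literal",
           "leakage_min_separation_um": 150.0},
    "metrics": {"rate_match_tolerance": 0.02, "min_trials": 10,
                "min_rate_hz": 5.0},
}


@dataclass
class RunConfig:
    seed: int
    output_dir: str
    input: Optional[str]
    generator: Optional[dict]
    windows: dict
    hmm: dict
    pc: dict
    metrics: dict

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _merge(defaults: dict, overrides: dict, prefix: str, errors: list[str]) -> dict:
    merged = {}
    for key, value in defaults.items():
        if isinstance(value, dict) and key in overrides:
            sub = overrides[key]
            if not isinstance(sub, dict):
                errors.append(f"{prefix}{key}: expected a mapping")
                merged[key] = dict(value)
            else:
                merged[key] = _merge(value, sub, f"{prefix}{key}.", errors)
        else:
            merged[key] = overrides.get(key, value)
    for key in overrides:
        if key not in defaults:
            errors.append(f"{prefix}{key}: unknown key")
    return merged


def validate_config(source: str | Path | dict) -> RunConfig:
    """Load, default-fill, and validate a run configuration.

    ``source`` may be a YAML/JSON file path or an already-parsed mapping.
    Every schema violation is collected and reported at once.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)

    errors: list[str] = []
    merged = _merge(_DEFAULTS, raw, "", errors)

    if merged["input"] is not None and merged["generator"] is not None:
        errors.append("input/generator: provide a session path OR a generator "
                      "block, not both (ambiguous source)")
    if merged["input"] is None and merged["generator"] is None:
        errors.append("input/generator: one data source is required")
    if merged["metrics"]["rate_match_tolerance"] <= 0:
        errors.append("metrics.rate_match_tolerance: must be > 0")
    if merged["pc"]["kernel_half_width_ms"] <= 0:
        errors.append("pc.kernel_half_width_ms: must be > 0")
    if merged["pc"]["unit_kernel_mode"] not in ("literal", "matched"):
        errors.append("pc.unit_kernel_mode: must be 'literal' or 'matched'")
    if merged["hmm"]["folds"] < 2:
        errors.append("hmm.folds: must be >= 2")
    if merged["hmm"]["restarts"] < 1:
        errors.append("hmm.restarts: must be >= 1")
    if not merged["hmm"]["s_range"] or min(merged["hmm"]["s_range"]) < 1:
        errors.append("hmm.s_range: must be nonempty with values >= 1")
    known_windows = {"spontaneous", "cue_to_dimming", "pre_dimming",
                     "baseline", "onset_response"}
    for key, name in merged["windows"].items():
        if name not in known_windows:
            errors.append(f"windows.{key}: unknown window {name!r}")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(**merged)


def _build_generator_config(block: dict, seed: int) -> GeneratorConfig:
    block = dict(block)
    units = [UnitSpec(**u) for u in block.pop("units", [])]
    n_trials = tuple(block.pop("n_trials", (20, 20)))
    return GeneratorConfig(units=units, n_trials=n_trials, seed=seed, **block)


def _load_session(config: RunConfig, rng_seed: int) -> SpikeSession:
    if config.input is not None:
        return read_session(config.input)
    session, _ = generate_session(_build_generator_config(config.generator, rng_seed))
    return session


def run_pipeline(config: RunConfig | str | Path | dict) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a summary dict (also written as ``manifest.json``).  Deterministic
    given the config seed.
    """
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(config.seed).spawn(3)
    generator_seed = int(seeds[0].generate_state(1)[0])
    hmm_rng = np.random.default_rng(seeds[1])
    cv_rng = np.random.default_rng(seeds[2])

    session = _load_session(config, generator_seed)
    windows = session.windows()
    logger.info("session %s: %d units, %d trials", session.session_id,
                len(session.spike_trains), len(session.trials))

    # --- unit inclusion -------------------------------------------------
    reports = {
        u.unit_id: inclusion_filter(
            u, session,
            min_rate_hz=config.metrics["min_rate_hz"],
            min_trials=config.metrics["min_trials"],
        )
        for u in session.single_units()
    }
    included = [u for u in session.single_units() if reports[u.unit_id].included]
    logger.info("inclusion: %d/%d single units kept", len(included), len(reports))

    # --- HMM ------------------------------------------------------------
    hmm_window = windows[config.windows["hmm"]]
    cv_report = None
    trajectories: dict[str, dict] = {c: {} for c in CONDITIONS}
    intervals: dict[str, dict] = {c: {} for c in CONDITIONS}
    models = {}
    for condition in CONDITIONS:
        counts, trial_ids = session_counts(session, hmm_window, condition)
        if config.hmm["run_selection"] and cv_report is None:
            cv_report = select_num_phases(
                counts, s_range=config.hmm["s_range"],
                folds=config.hmm["folds"], rng=cv_rng,
                n_restarts=config.hmm["restarts"],
            )
            logger.info("phase selection: S=%d pass=%s cv=%s",
                        cv_report.selected, cv_report.passed, cv_report.cv_var)
        model = multi_restart_fit(counts, 2, hmm_rng,
                                  n_restarts=config.hmm["restarts"])
        models[condition] = model
        for mat, trial_id in zip(counts, trial_ids):
            trajectories[condition][trial_id] = viterbi(mat, model, trial_id)
            trial = next(t for t in session.trials if t.trial_id == trial_id)
            start, _ = resolve_window(hmm_window, trial)
            n_bins = trajectories[condition][trial_id].phases.size
            intervals[condition][trial_id] = (start, start + n_bins * model.bin_ms)

    # --- per-unit metrics ----------------------------------------------
    pc_window = config.windows["pc"]
    att_window = config.windows["att_mi"]
    rows = []
    unit_metrics: dict[str, list[UnitMetrics]] = {c: [] for c in CONDITIONS}
    for unit in included:
        att_mi = None
        try:
            att_mi = unit_attention_index(unit, session, att_window)
        except ValueError:
            pass
        for condition in CONDITIONS:
            flags = []
            coupling = None
            try:
                coupling = unit_population_coupling(
                    session, unit, pc_window, condition,
                    min_contact_separation_um=config.pc["leakage_min_separation_um"],
                    kernel_half_width_ms=config.pc["kernel_half_width_ms"],
                    unit_kernel_mode=config.pc["unit_kernel_mode"],
                )
            except CouplingUndefined as exc:
                flags.append(f"coupling_undefined:{exc}")
            ratio_result = on_off_ratio(
                unit, trajectories[condition], intervals[condition]
            )
            if not ratio_result.defined:
                flags.append("ratio_undefined")
            metrics = UnitMetrics(
                unit_id=unit.unit_id,
                condition=condition,
                window=pc_window,
                on_off_ratio=ratio_result.ratio,
                att_mi=att_mi,
                coupling=coupling,
                area=session.area_labels[unit.channel_index],
                included=True,
                flags=tuple(flags),
            )
            unit_metrics[condition].append(metrics)
            rows.append({
                "unit_id": unit.unit_id,
                "condition": condition,
                "window": pc_window,
                "C0": coupling.C0 if coupling else np.nan,
                "C_norm": coupling.C_norm if coupling else np.nan,
                "Z": coupling.Z if coupling else np.nan,
                "on_off_ratio": ratio_result.ratio,
                "att_mi": att_mi,
                "area": metrics.area,
                "flags": ";".join(flags),
            })
    unit_table = pd.DataFrame(rows)
    unit_table.to_csv(out / "unit_metrics.tsv", sep="\t", index=False)

    # --- pair metrics ---------------------------------------------------
    pair_rows = []
    noise_window = config.windows["noise"]
    for condition in CONDITIONS:
        for i in range(len(included)):
            for j in range(i + 1, len(included)):
                try:
                    pair = noise_correlation(
                        included[i], included[j], session, condition,
                        window=noise_window,
                        min_trials=config.metrics["min_trials"],
                    )
                except ValueError:
                    continue
                pair_rows.append({
                    "unit_i": pair.unit_i, "unit_j": pair.unit_j,
                    "condition": pair.condition,
                    "noise_correlation": pair.noise_correlation,
                    "n_trials": pair.n_trials,
                })
    pd.DataFrame(pair_rows).to_csv(out / "pair_metrics.tsv", sep="\t", index=False)

    # --- correlation table ---------------------------------------------
    correlations = {}
    for condition in CONDITIONS:
        try:
            correlations[condition] = metric_correlations(unit_metrics[condition])
        except ValueError as exc:
            correlations[condition] = {"error": str(exc)}
    with open(out / "correlations.json", "w") as fh:
        json.dump(correlations, fh, indent=2)

    # --- trajectories + models ------------------------------------------
    traj_rows = []
    for condition in CONDITIONS:
        for trial_id, traj in trajectories[condition].items():
            for b, phase in enumerate(traj.phases):
                traj_rows.append({
                    "trial_id": trial_id, "condition": condition,
                    "bin_index": b, "phase": int(phase),
                    "label": traj.labels[b] if traj.labels is not None else "",
                })
    pd.DataFrame(traj_rows).to_csv(out / "trajectories.tsv", sep="\t", index=False)
    with open(out / "hmm_models.json", "w") as fh:
        json.dump({c: m.to_dict() for c, m in models.items()}, fh, indent=2)
    if cv_report is not None:
        with open(out / "cv_report.json", "w") as fh:
            json.dump({
                "cv_var": cv_report.cv_var,
                "per_fold": cv_report.per_fold,
                "selected": cv_report.selected,
                "passed": cv_report.passed,
            }, fh, indent=2)

    manifest = {
        "package_version": popstate.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "session_id": session.session_id,
        "n_single_units": len(reports),
        "n_included_units": len(included),
        "n_unit_metric_rows": len(rows),
        "n_pairs": len(pair_rows),
        "phase_selection": None if cv_report is None else {
            "selected": cv_report.selected, "passed": cv_report.passed,
        },
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
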