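"""End-to-end orchestration: synth -> extract -> build -> select -> associate.

The pipeline wires the modules together under one seeded configuration and
writes a self-describing report bundle: an exclusion-flow JSON, a
frequency table of influential variables, OR/aOR tables for the binary and
multinomial models, collinearity diagnostics, the selection result, and a
run manifest (seed, config, record counts).  The same configuration and
seed reproduce the bundle byte for byte.

The synthetic stage couples the cohort generator to the signal generator:
each participant's walking trials are synthesised *from that participant's
drawn gait parameters* (speed sets trial duration, cadence the step
interval, stride-time CV the step-interval spread, swing times the
toe-offs), so extraction applied to the signals recovers the parameters the
pain outcome was generated from, and known effects survive the full
pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cohort, features, io, selection, synth
from .errors import ConfigError

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, in one place.

    Stage toggles let a run start from existing intermediate files; every
    module parameter that is not a universal constant is exposed here so a
    run is fully described by (config, seed).
    """

    seed: int = 0
    out_dir: str = "gaitpain_run"

    # stage toggles
    run_synth: bool = True
    run_extract: bool = True
    run_build: bool = True
    run_select: bool = True
    run_associate: bool = True

    # synth
    n_participants: int = 150
    coefficients: dict = field(default_factory=lambda: {
        "gait_speed": float(np.log(0.8)),
        "cadence": float(np.log(0.8)),
    })
    intercept: float = -1.2
    intercept_modsev: float = -3.0
    coefficients_modsev: dict = field(default_factory=dict)
    bilateral_rate: float = 0.03
    signal_noise_sd: float = 0.08
    sampling_rate: float = 100.0
    walk_distance: float = 20.0
    write_signals: bool = False

    # extract
    use_true_events: bool = True
    speed_low: float = 0.3
    speed_high: float = 2.3

    # select
    n_runs: int = 5
    train_fraction: float = 0.7
    folds: int = 5
    top_k: int = 10
    profile: str = "desk"
    mice_iterations: int = 3
    vim_repeats: int = 3

    # associate
    speed_sensitivity_high: float = 1.8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _synth_stage(config: PipelineConfig, out: Path) -> dict:
    """Cohort + per-participant signal trials consistent with the cohort."""
    spec = synth.CohortSpec(
        n_participants=config.n_participants,
        coefficients=config.coefficients,
        intercept=config.intercept,
        coefficients_modsev=config.coefficients_modsev,
        intercept_modsev=config.intercept_modsev,
        bilateral_rate=config.bilateral_rate,
        seed=config.seed,
    )
    participants, feats, truth = synth.generate_cohort(spec)

    signals, events = {}, {}
    seeds = np.random.SeedSequence(config.seed + 1).generate_state(
        2 * config.n_participants
    ) % (2**31)
    for i, row in feats.iterrows():
        speed = float(np.clip(row["gait_speed"], 0.5, 2.2))
        cadence = float(np.clip(row["cadence"], 80.0, 140.0))
        step_cv = float(np.clip(row["stride_time_cv"], 0.0, 10.0)) / 100.0
        stride = 2 * 60.0 / cadence
        swing_l = float(np.clip(row["swing_time_left"], 0.2, 0.8 * stride))
        swing_r = float(np.clip(row["swing_time_right"], 0.2, 0.8 * stride))
        trials, trial_events = [], []
        for t in range(2):
            sspec = synth.SignalSpec(
                sampling_rate=config.sampling_rate,
                duration=config.walk_distance / speed,
                cadence=cadence,
                step_time_cv=step_cv,
                swing_time_left=swing_l,
                swing_time_right=swing_r,
                noise_sd=config.signal_noise_sd,
                walk_distance=config.walk_distance,
                seed=int(seeds[2 * i + t]),
                trial_id=f"{row['id']}_t{t + 1}",
            )
            sig, ev = synth.generate_signal(sspec)
            trials.append(sig)
            trial_events.append(ev)
        signals[row["id"]] = trials
        events[row["id"]] = trial_events

    participants.to_csv(out / "participants.csv", index=False)
    feats.to_csv(out / "generated_features.csv", index=False)
    io.write_json(
        {k: v for k, v in truth.items() if k not in ("category", "roa_count_true")},
        out / "truth.json",
    )
    if config.write_signals:
        sig_dir = out / "signals"
        sig_dir.mkdir(exist_ok=True)
        for pid, trials in signals.items():
            for sig in trials:
                io.write_signal_csv(sig, sig_dir / f"{sig.trial_id}.csv")
    return {"participants": participants, "signals": signals, "events": events,
            "truth": truth}


def _extract_stage(config: PipelineConfig, state: dict, out: Path) -> dict:
    rows = []
    for pid, trials in state["signals"].items():
        evs = state["events"][pid] if config.use_true_events else None
        vec = features.extract_all(trials, evs)
        vec["id"] = pid
        rows.append(vec)
    table = pd.DataFrame(rows)
    table = table[["id"] + [c for c in table.columns if c != "id"]]
    # drop features never defined on these trials (e.g. too short for some)
    all_missing = [c for c in table.columns
                   if c != "id" and table[c].isna().all()]
    if all_missing:
        log.info("dropping features undefined on every trial: %s", all_missing)
        table = table.drop(columns=all_missing)
    filtered, excluded = features.speed_validity_filter(
        table, config.speed_low, config.speed_high
    )
    filtered.to_csv(out / "features.csv", index=False)
    excluded.to_csv(out / "speed_excluded.csv", index=False)
    return {"features": filtered, "speed_excluded": excluded}


def _build_stage(state: dict, out: Path) -> dict:
    analysis, flow = cohort.assemble_analysis_table(
        state["participants"], state["features"]
    )
    flow["n_speed_excluded"] = int(len(state.get("speed_excluded", [])))
    analysis.to_csv(out / "analysis_table.csv", index=False)
    io.write_json(flow, out / "exclusion_flow.json")
    return {"analysis": analysis, "flow": flow}


def _select_stage(config: PipelineConfig, state: dict, out: Path) -> dict:
    result = selection.run_selection_loop(
        state["analysis"],
        n_runs=config.n_runs,
        train_fraction=config.train_fraction,
        folds=config.folds,
        top_k=config.top_k,
        profile=config.profile,
        mice_iterations=config.mice_iterations,
        vim_repeats=config.vim_repeats,
        seed=config.seed + 2,
    )
    io.write_json(result.to_dict(), out / "selection.json")
    result.frequency_table().to_csv(
        out / "influential_frequencies.csv", index=False, float_format="%.1f"
    )
    return {"selection": result}


def _associate_stage(config: PipelineConfig, state: dict, out: Path) -> dict:
    analysis = state["analysis"]
    if "selection" in state:
        selected = state["selection"].selected
    else:
        sel_path = out / "selection.json"
        if not sel_path.exists():
            raise ConfigError(
                "association stage needs a selection result; enable the "
                "selection stage or provide selection.json"
            )
        selected = io.read_json(sel_path)["selected"]
    gait_predictors = [v for v in selected if v in synth.GAIT_FEATURES
                       and v in analysis.columns]
    if not gait_predictors:
        # a legitimate outcome of selection on null-ish data: nothing to model
        log.info("selection chose no gait variables; association stage skipped")
        io.write_json({"skipped": "no gait variables selected"},
                      out / "association_models.json")
        return {}
    covs = [c for c in association.ADJUSTMENT_COVARIATES if c in analysis.columns]

    # screen the gait exposures for collinearity and drop offenders before
    # modelling (confounders always stay)
    if len(gait_predictors) >= 2:
        screen = association.collinearity_diagnostics(analysis, gait_predictors)
        for var in screen["drop_recommendations"]:
            if var in gait_predictors:
                log.info("dropping '%s' from the models (collinearity screen)", var)
                gait_predictors.remove(var)
    if not gait_predictors:
        raise ConfigError("collinearity screening removed every gait predictor")

    report = association.AssociationReport()
    report.models["unadjusted"] = association.fit_binary_logistic(
        analysis, gait_predictors
    )
    report.models["adjusted"] = association.fit_binary_logistic(
        analysis, gait_predictors, covs
    )
    report.collinearity = association.collinearity_diagnostics(
        analysis, gait_predictors + covs
    )

    counts3 = analysis["outcome3"].value_counts()
    if (counts3 >= 10).sum() >= 3:
        report.proportional_odds = association.proportional_odds_check(
            analysis, gait_predictors, covs
        )
        report.models["multinomial"] = association.fit_multinomial_sensitivity(
            analysis, gait_predictors, covs
        )
    else:
        log.info("3-category outcome too sparse; multinomial sensitivity skipped")

    # fast-walker sensitivity: refit the adjusted model under speed < 1.8 m/s
    if "gait_speed_raw" in state:
        keep = state["gait_speed_raw"] < config.speed_sensitivity_high
        restricted = analysis.loc[keep.to_numpy()]
    else:
        restricted = analysis
    try:
        report.models["adjusted_speed_restricted"] = association.fit_binary_logistic(
            restricted, gait_predictors, covs, model_label="adjusted_speed_restricted"
        )
    except Exception as exc:
        log.info("speed-restricted sensitivity model skipped: %s", exc)

    report.to_table().to_csv(out / "association_models.csv", index=False,
                             float_format="%.6f")
    collin = {
        "tolerance": report.collinearity["tolerance"].to_dict(),
        "vif": report.collinearity["vif"].to_dict(),
        "eigenvalues": list(report.collinearity["eigenvalues"]),
        "condition_indices": list(report.collinearity["condition_indices"]),
        "flags": report.collinearity["flags"],
    }
    io.write_json(collin, out / "collinearity.json")
    if report.proportional_odds is not None:
        io.write_json(report.proportional_odds, out / "proportional_odds.json")
    return {"report": report}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and write the report bundle.

    Returns a state dictionary holding the in-memory stage outputs
    (participant table, feature table, analysis table, selection result,
    association report) plus the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}

    stages = [
        ("synth", config.run_synth, lambda: _synth_stage(config, out)),
        ("extract", config.run_extract, lambda: _extract_stage(config, state, out)),
        ("build", config.run_build, lambda: _build_stage(state, out)),
        ("select", config.run_select, lambda: _select_stage(config, state, out)),
        ("associate", config.run_associate,
         lambda: _associate_stage(config, state, out)),
    ]
    requirements = {
        "extract": ["signals"],
        "build": ["participants", "features"],
        "select": ["analysis"],
        "associate": ["analysis"],
    }
    for name, enabled, fn in stages:
        if not enabled:
            continue
        missing = [r for r in requirements.get(name, []) if r not in state]
        if missing:
            raise ConfigError(
                f"stage '{name}' needs {missing} from an earlier stage; "
                "enable the producing stage or load its outputs"
            )
        log.info("pipeline stage: %s", name)
        try:
            state.update(fn())
        except ConfigError:
            raise
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        # keep raw gait speed around for the restricted sensitivity model
        if name == "build":
            raw = state["features"].set_index("id")["gait_speed"]
            state["gait_speed_raw"] = raw.loc[state["analysis"]["id"]].reset_index(
                drop=True
            )

    config_text = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "counts": state.get("flow", {}),
    }
    io.write_json(manifest, out / "manifest.json")
    state["manifest"] = manifest
    return state
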