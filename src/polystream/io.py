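"""File formats, configuration, and the end-to-end pipeline.

Trial-level data travel as UTF-8 CSV with a header row (one row per trial,
the TrialRecord columns; unknown extra columns are tolerated and ignored,
column order is free).  Schedules export as trial CSV plus a JSON session
manifest; posteriors export as one CSV per parameter group plus a JSON
summary.  ``run_pipeline`` chains design -> simulate -> aggregate -> fit ->
report and writes a run manifest echoing every seed for reproducibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import Schedule, exp1_schedule, exp2_schedule, rating_schedule
from .model import (ModelConfig, PosteriorSamples, cell_effects, contrast,
                    fit_model, hdi)
from .sdt import (ATTENTION_LEVELS, MeasurementCell, ResponseCounts,
                  TIMBRE_LEVELS, TrialRecord, aggregate_counts)
from .simulate import TruthParams, exp1_default_truth, simulate_cohort
from .stats import (group_summary, morph_effect, spearman, split_half_reliability,
                    subject_scores)

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ("subject_id", "experiment", "group", "run_index", "block_index",
                 "trial_index", "composition_id", "triplet_version", "attention",
                 "timbre_level", "response", "outcome")


class ParseError(ValueError):
    """A malformed input file; the message names the offending row."""


def write_trials(trials, path) -> None:
    rows = []
    for t in trials:
        d = asdict(t)
        d["timbre_level"] = d["timbre_level"] if d["timbre_level"] is not None else "NA"
        rows.append(d)
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_trials(path) -> list[TrialRecord]:
    """Read and validate a trial CSV; parse errors name the 1-based data row."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "outcome"]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            timbre = getattr(row, "timbre_level")
            rec = TrialRecord(
                subject_id=row.subject_id,
                experiment=row.experiment,
                group=row.group,
                run_index=int(row.run_index),
                block_index=int(row.block_index),
                trial_index=int(row.trial_index),
                composition_id=row.composition_id,
                triplet_version=row.triplet_version,
                attention=row.attention,
                timbre_level=None if timbre in ("NA", "") else timbre,
                response=row.response,
                outcome=getattr(row, "outcome", "invalid") or "invalid",
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_cells(cells, path) -> None:
    rows = [{
        "subject_id": c.subject_id, "attention": c.attention,
        "timbre_level": c.timbre_level if c.timbre_level is not None else "NA",
        "n_hit": c.counts.n_hit, "n_miss": c.counts.n_miss,
        "n_fa": c.counts.n_fa, "n_cr": c.counts.n_cr,
        "dprime_ec": c.dprime_ec, "bias_ec": c.bias_ec,
    } for c in cells]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cells(path) -> list[MeasurementCell]:
    from .sdt import edge_corrected_bias, edge_corrected_dprime

    df = pd.read_csv(path, keep_default_na=False)
    cells = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            counts = ResponseCounts(int(row.n_hit), int(row.n_miss),
                                    int(row.n_fa), int(row.n_cr))
            timbre = row.timbre_level if row.timbre_level not in ("NA", "") else None
            cells.append(MeasurementCell(
                subject_id=str(row.subject_id), attention=row.attention,
                timbre_level=timbre, counts=counts,
                dprime_ec=edge_corrected_dprime(counts),
                bias_ec=edge_corrected_bias(counts),
            ))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"row {i}: {exc}") from exc
    return cells


def write_schedule(schedule: Schedule, csv_path, manifest_path=None) -> None:
    rows = []
    for ri, run in enumerate(schedule.runs, 1):
        for bi, block in enumerate(run, 1):
            for ti, stub in enumerate(block.trials, 1):
                if schedule.experiment == "rating":
                    rows.append({
                        "run_index": ri, "block_index": bi, "trial_index": ti,
                        "voice": stub.voice, "morph_step": stub.morph_step,
                        "morph_fraction": stub.morph_fraction,
                        "composition_id": stub.composition_id,
                    })
                else:
                    rows.append({
                        "run_index": ri, "block_index": bi, "trial_index": ti,
                        "attention": block.attention,
                        "composition_id": stub.composition_id,
                        "triplet_version": stub.triplet_version,
                        "timbre_level": stub.timbre_level or "NA",
                        "crossing_start": stub.crossing_start or "NA",
                    })
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if manifest_path is not None:
        manifest = {
            "experiment": schedule.experiment, "group": schedule.group,
            "participant_index": schedule.participant_index,
            "seed": schedule.seed, "n_trials": schedule.n_trials,
            "constraint_report": list(schedule.constraint_report),
        }
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))


def write_ratings(records, path) -> None:
    pd.DataFrame(records).to_csv(path, index=False)


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"voice", "morph_fraction", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(sorted(missing))}")
    return df


# --------------------------------------------------------------------------
# posterior export


def export_posterior(samples: PosteriorSamples, outdir) -> list[str]:
    """One CSV per parameter group (chain, draw, value columns) + JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in samples.draws.items():
        n_chain, n_draw = arr.shape[:2]
        flat = arr.reshape(n_chain, n_draw, -1)
        frames = []
        for ch in range(n_chain):
            df = pd.DataFrame(flat[ch])
            df.columns = [f"{name}[{j}]" for j in range(flat.shape[2])]
            df.insert(0, "draw", np.arange(n_draw))
            df.insert(0, "chain", ch)
            frames.append(df)
        path = outdir / f"posterior_{name}.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        written.append(str(path))
    summary = posterior_summary(samples)
    path = outdir / "posterior_summary.json"
    path.write_text(json.dumps(summary, indent=2))
    written.append(str(path))
    return written


def _hdi_dict(draws, mass=0.95) -> dict:
    iv = hdi(draws, mass)
    return {"low": iv.low, "high": iv.high, "mass": mass,
            "mean": float(np.mean(draws)), "excludes_zero": iv.excludes_zero}


def posterior_summary(samples: PosteriorSamples) -> dict:
    eff = cell_effects(samples)
    summary: dict = {
        "experiment": samples.data.experiment,
        "n_cells": samples.data.n_cells,
        "n_chains": samples.n_chains,
        "n_samples_per_chain": samples.n_samples,
        "grand_mean": _hdi_dict(eff.grand_mean),
        "attention_effects": {
            lev: _hdi_dict(eff.attention[:, i])
            for i, lev in enumerate(eff.att_levels)
        },
        "diagnostics": {
            "max_rhat": {k: float(np.nanmax(v)) for k, v in samples.rhat.items()},
            "min_ess": {k: float(np.nanmin(v)) for k, v in samples.ess.items()},
        },
        "warnings": list(samples.warnings),
    }
    pairs = [(a, b) for i, a in enumerate(eff.att_levels)
             for b in eff.att_levels[i + 1:]]
    summary["attention_contrasts"] = {
        f"{a}-{b}": _hdi_dict(contrast(samples, "attention", a, b).draws)
        for a, b in pairs
    }
    if eff.timbre is not None:
        summary["timbre_effects"] = {
            lev: _hdi_dict(eff.timbre[:, i])
            for i, lev in enumerate(eff.timb_levels)
        }
        tpairs = [(a, b) for i, a in enumerate(eff.timb_levels)
                  for b in eff.timb_levels[i + 1:]]
        summary["timbre_contrasts"] = {
            f"{a}-{b}": _hdi_dict(contrast(samples, "timbre", a, b).draws)
            for a, b in tpairs
        }
    return summary


# --------------------------------------------------------------------------
# pipeline configuration


_CONFIG_SCHEMA = {
    "experiment": str, "group": str, "n_subjects": int, "n_compositions": int,
    "seed": int, "output_dir": str, "log_level": str,
    "model": dict, "truth": dict,
}


@dataclass(frozen=True)
class PipelineConfig:
    experiment: str = "exp2"
    group: str = "LAB"
    n_subjects: int = 19
    n_compositions: int = 16
    seed: int = 0
    output_dir: str = "polystream_out"
    log_level: str = "INFO"
    model: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(_CONFIG_SCHEMA)
        if unknown:
            raise ParseError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for key, typ in _CONFIG_SCHEMA.items():
            if key in raw and not isinstance(raw[key], typ):
                raise ParseError(f"config key {key!r} must be {typ.__name__}")
        return cls(**raw)

    def make_truth(self) -> TruthParams:
        if self.experiment == "exp1":
            return exp1_default_truth(n_subjects=self.n_subjects, seed=self.seed,
                                      **self.truth)
        return TruthParams(experiment="exp2", n_subjects=self.n_subjects,
                           seed=self.seed, **self.truth)

    def make_model_config(self) -> ModelConfig:
        kwargs = dict(experiment=self.experiment, seed=self.seed)
        kwargs.update(self.model)
        return ModelConfig(**kwargs)


def build_report(trials, samples: PosteriorSamples, seed: int = 0) -> dict:
    """Descriptive + reliability + posterior report for one simulated cohort."""
    experiment = samples.data.experiment
    scores = subject_scores(trials, "all_trials")
    rates = [s.correct_rate for s in scores]
    med, (q25, q75) = group_summary(rates)
    r_split, p_split = split_half_reliability(trials, seed=seed)
    report = {
        "experiment": experiment,
        "n_subjects": len(scores),
        "subject_scores": [asdict(s) for s in scores],
        "correct_rate_median": med,
        "correct_rate_iqr": [q25, q75],
        "split_half_reliability": {"r": r_split, "p": p_split},
        "posterior": posterior_summary(samples),
    }
    if experiment == "exp2":
        effects = morph_effect(trials)
        report["morph_effect"] = {"per_subject": effects}
        if len(scores) >= 4:  # rank correlation needs at least 4 subjects
            ordered = [effects[s.subject_id] for s in scores]
            rho, p = spearman(rates, ordered)
            report["morph_effect"]["spearman_vs_correct_rate"] = {"rho": rho, "p": p}
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """design -> simulate -> aggregate -> fit -> report; returns the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    stage = "design"
    try:
        if config.experiment == "exp1":
            sched = exp1_schedule(0, n_compositions=config.n_compositions,
                                  seed=config.seed)
        else:
            sched = exp2_schedule(0, group=config.group, seed=config.seed)
        schedule_csv = outdir / "schedule.csv"
        write_schedule(sched, schedule_csv, outdir / "schedule_manifest.json")
        logger.info("design: %d trials, seed %d", sched.n_trials, config.seed)

        stage = "simulate"
        truth = config.make_truth()
        trials, _subjects = simulate_cohort(
            truth, group=config.group, n_compositions=config.n_compositions)
        trials_csv = outdir / "trials.csv"
        write_trials(trials, trials_csv)
        logger.info("simulate: %d subjects, %d trials", truth.n_subjects, len(trials))

        stage = "aggregate"
        cells = aggregate_counts(trials)
        cells_csv = outdir / "cells.csv"
        write_cells(cells, cells_csv)
        logger.info("aggregate: %d measurement cells", len(cells))

        stage = "fit"
        mconfig = config.make_model_config()
        samples = fit_model(cells, mconfig)
        posterior_files = export_posterior(samples, outdir / "posterior")

        stage = "report"
        report = build_report(trials, samples, seed=config.seed)
        report_json = outdir / "report.json"
        report_json.write_text(json.dumps(report, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "created": datetime.now(timezone.utc).isoformat(),
        "config": asdict(config),
        "seeds": {"global": config.seed, "schedule": sched.seed,
                  "model": mconfig.seed},
        "artifacts": {
            "schedule_csv": str(schedule_csv),
            "trials_csv": str(trials_csv),
            "cells_csv": str(cells_csv),
            "posterior": posterior_files,
            "report_json": str(report_json),
        },
        "warnings": list(samples.warnings),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
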