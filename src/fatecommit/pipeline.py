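"""End-to-end pipeline: simulate (or load) -> QC -> fate/threshold -> hit
times -> dynamics -> divergence -> report, with one global seed that spawns
per-stage substreams so stage reordering cannot silently reshuffle the
randomness."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import commitment, divergence, dynamics, report, simulate, traces
from .qc import QCParams, apply_qc

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("fatecommit")


class PipelineError(RuntimeError):
    """A stage failed; the stage name is in the message."""


def _from_dict(cls, data: dict, path: str):
    """Build a (frozen) dataclass from a dict, rejecting unknown keys and
    recursing into dataclass-typed fields."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section {path!r}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        if dataclasses.is_dataclass(f.type) and isinstance(value, dict):
            kwargs[name] = _from_dict(f.type, value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


@dataclass(frozen=True)
class DivergenceSettings:
    scenarios: tuple[str, ...] = ("siCEBPB", "siCEBPA", "siFABP4")
    channel: str = "PPARG"
    log_threshold: float = -20.0
    log_base: str = "natural"
    n_cells: int = 700


@dataclass(frozen=True)
class PipelineConfig:
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    qc: QCParams = field(default_factory=QCParams)
    t_dec: float = 48.0
    fpr_max: float = 0.05
    divergence: DivergenceSettings = field(default_factory=DivergenceSettings)
    seed: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        section_types = {
            "sim": simulate.SimConfig,
            "qc": QCParams,
            "divergence": DivergenceSettings,
        }
        top = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(top)
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
        kwargs = {}
        for name, value in data.items():
            if name in section_types and isinstance(value, dict):
                if name == "sim" and isinstance(value.get("canonical"), dict):
                    value = dict(value)
                    value["canonical"] = _from_dict(
                        simulate.CanonicalParams, value["canonical"], "sim.canonical")
                if name == "sim" and isinstance(value.get("grid"), dict):
                    value = dict(value)
                    value["grid"] = traces.TimeGrid(**value["grid"])
                kwargs[name] = _from_dict(section_types[name], value, name)
            else:
                kwargs[name] = value
        return cls(**kwargs)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, out_dir, traces_path=None) -> dict:
    """Run the full analysis; intermediate files and report.json land in
    ``out_dir``. Returns the report payload."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]

    sections: dict = {}

    @_stage("simulate")
    def _simulate():
        if traces_path is not None:
            return traces.read_traces(traces_path)
        cfg = dataclasses.replace(config.sim, seed=seeds[0])
        ts = simulate.simulate_population(cfg)
        traces.write_traces(ts, out_dir / "traces.csv")
        return ts

    ts = _simulate()
    sections["sim"] = {
        "n_cells": ts.n_cells,
        "scenario": config.sim.scenario if traces_path is None else "loaded",
        "grid": dataclasses.asdict(ts.grid),
    }

    @_stage("qc")
    def _qc():
        kept, rep = apply_qc(ts, config.qc)
        traces.write_traces(kept, out_dir / "kept.csv")
        return kept, rep

    kept, qc_report = _qc()
    sections["qc"] = {
        "n_input": qc_report.n_input,
        "n_kept": qc_report.n_kept,
        "removed_by_rule": qc_report.removed_by_rule,
    }

    @_stage("threshold")
    def _threshold():
        endpoint = kept.endpoint_values("PPARG")
        fit = commitment.fit_endpoint_mixture(endpoint)
        fate_list = commitment.classify_fate(fit, endpoint)
        fates = dict(zip(endpoint.cell_ids, fate_list))
        vals48, ids48 = kept.values_at(config.t_dec, "PPARG")
        model = commitment.select_threshold(
            vals48, [fates[c] for c in ids48], config.fpr_max, config.t_dec)
        return fit, fates, model

    fit, fates, model = _threshold()
    sections["threshold"] = {
        "threshold_au": model.threshold,
        "t_dec": model.t_dec,
        "fpr": model.fpr,
        "tpr": model.tpr,
        "constraint_met": model.constraint_met,
        "mixture_means_log10": list(fit.means),
        "fraction_differentiated": float(
            np.mean([f == commitment.DIFF for f in fates.values()])),
    }

    @_stage("hits")
    def _hits():
        return commitment.threshold_hit_times(kept, model.threshold, fates)

    hits = _hits()
    sections["hits"] = {
        "mean_h": hits.mean,
        "sd_h": hits.sd,
        "n_cells": len(hits.hit_times),
        "n_never": hits.n_never,
    }

    @_stage("dynamics")
    def _dynamics():
        diff_ids = [c for c, f in fates.items() if f == commitment.DIFF]
        folds_P, folds_F = [], []
        for tr in kept.traces:
            if tr.cell_id in set(diff_ids):
                folds_P.append(dynamics.fold_change(tr, "PPARG"))
                folds_F.append(dynamics.fold_change(tr, "FABP4"))
        paths = dynamics.unit_square_normalize(kept, cells=diff_ids)
        mean_slopes = dynamics.population_mean_slope(kept, fates=fates)
        engagement = {}
        for fate, ss_ in mean_slopes.items():
            engagement[fate] = dynamics.detect_engagement(ss_)
        return {
            "median_fold_PPARG": float(np.median(folds_P)),
            "median_fold_FABP4": float(np.median(folds_F)),
            "path_asymmetry": paths.asymmetry,
            "engagement_h": engagement,
        }

    sections["dynamics"] = _dynamics()

    if config.divergence.scenarios:
        @_stage("divergence")
        def _diverge():
            out = {}
            ctrl_cfg = dataclasses.replace(
                config.sim, scenario="control",
                n_cells=config.divergence.n_cells, seed=seeds[1])
            ctrl = simulate.simulate_population(ctrl_cfg)
            for i, scen in enumerate(config.divergence.scenarios):
                cfg = dataclasses.replace(
                    config.sim, scenario=scen,
                    n_cells=config.divergence.n_cells, seed=seeds[2 + i])
                kd = simulate.simulate_population(cfg)
                prof = divergence.pvalue_timecourse(ctrl, kd, config.divergence.channel)
                out[scen] = divergence.divergence_time(
                    prof, config.divergence.log_threshold, config.divergence.log_base)
            return out

        sections["divergence"] = {"divergence_h": _diverge(),
                                  "log_threshold": config.divergence.log_threshold,
                                  "log_base": config.divergence.log_base}

    payload = report.build_report(sections, seed=config.seed, config=config)
    (out_dir / "report.json").write_text(report.report_to_json(payload))
    return payload
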