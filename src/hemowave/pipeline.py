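"""Study orchestration: baseline -> banding -> remodeling + analytics.

``run_study`` executes the three hemodynamic states on one fixture
(optionally per age), runs pulse wave analysis and wave separation on
each converged beat, and emits a report with one row per state plus the
remodeling trace.  ``run_analytics`` applies the same analytics to any
externally supplied single-beat waveform CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import metadata, resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures, pwa, wsa
from .cardiac import VentricleParams
from .network import ArterialTree, total_compliance, total_peripheral_resistance
from .scenarios import (RemodelingResult, ScenarioSpec, apply_banding,
                        remodel, scale_tpr, stress_index, tune_pfill)
from .simulate import BeatResult, RunControls, run_to_periodic

__all__ = ["ScenarioReport", "StudyResult", "run_study", "run_analytics",
           "load_config", "default_config"]

log = logging.getLogger(__name__)

try:
    _VERSION = metadata.version("hemowave")
except metadata.PackageNotFoundError:      # pragma: no cover
    _VERSION = "unknown"


@dataclass
class ScenarioReport:
    """One per-state row: beat metrics + pulse wave + wave separation."""

    state: str
    beat_metrics: dict
    pwa: pwa.PressureWaveMetrics
    wsa_summary: dict
    heart: dict
    tree_summary: dict
    provenance: dict = field(default_factory=dict)

    def row(self) -> dict:
        r = {"state": self.state}
        r.update({k: self.beat_metrics[k]
                  for k in ("SV", "EDV", "ESV", "EF", "CO", "MAP",
                            "max_flow")})
        r.update(self.pwa.to_dict())
        r.update(self.wsa_summary)
        r.update({f"heart_{k}": v for k, v in self.heart.items()})
        r.update(self.tree_summary)
        return r


@dataclass
class StudyResult:
    reports: list
    remodeling: RemodelingResult
    beats: dict
    config: dict
    provenance: dict

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.row() for r in self.reports])

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "config": self.config,
            "reports": [r.row() for r in self.reports],
            "remodeling": {
                "Ees_remodel": self.remodeling.Ees_remodel,
                "beta_remodel": self.remodeling.beta_remodel,
                "Pfill_remodel": self.remodeling.Pfill_remodel,
                "sigma_target": self.remodeling.sigma_target,
                "sigma_final": self.remodeling.sigma_final,
                "iterations": self.remodeling.iterations,
                "trace": self.remodeling.trace,
            },
        }
        return json.dumps(payload, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def default_config() -> dict:
    with (resources.files("hemowave") / "data" /
          "default_study.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_config(path=None) -> dict:
    """Load a study config, filling unspecified blocks with defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for block, vals in user.items():
            if isinstance(vals, dict) and isinstance(cfg.get(block), dict):
                cfg[block].update(vals)
            else:
                cfg[block] = vals
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _build_inputs(cfg: dict) -> tuple[VentricleParams, ArterialTree]:
    tcfg = cfg.get("tree", {})
    if "file" in tcfg and tcfg["file"]:
        tree = ArterialTree.from_yaml(tcfg["file"])
    else:
        tree = fixtures.default_tree(
            fixtures.fixture_spec(str(tcfg.get("age", "study-default"))))
    heart = VentricleParams(**cfg.get("heart", {}))
    return heart, tree


def _controls(cfg: dict) -> RunControls:
    return RunControls(**cfg.get("solver", {}))


def _analyze_state(state: str, beat: BeatResult, heart: VentricleParams,
                   tree: ArterialTree, provenance: dict) -> ScenarioReport:
    metrics = pwa.analyze_pressure(beat.t, beat.P_root, beat.period)
    spec = wsa.input_impedance(beat.P_root, beat.Q_root, beat.period)
    sep = wsa.separate(beat.t, beat.P_root, beat.Q_root, spec.Zc)
    summary = wsa.separation_metrics(sep, metrics.aPP)
    return ScenarioReport(
        state=state,
        beat_metrics=beat.metrics(),
        pwa=metrics,
        wsa_summary=summary,
        heart={k: getattr(heart, k)
               for k in ("Ees", "Vd", "P0", "beta", "Pfill", "period",
                         "t_systole")},
        tree_summary={"CT": total_compliance(tree),
                      "TPR": total_peripheral_resistance(tree)},
        provenance=provenance,
    )


def run_study(config=None, outdir=None) -> StudyResult:
    """Execute the full three-state study defined by ``config``.

    ``config`` may be None (shipped defaults), a path to a YAML file, or
    an already-loaded dict.  Deterministic: identical configs produce
    identical results.  When ``outdir`` is given, writes report.json,
    report.csv and per-state waveform CSVs there.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    ctrl = _controls(cfg)
    scen = ScenarioSpec(name="baseline", **cfg.get("scenario", {}))
    heart0, tree0 = _build_inputs(cfg)
    prov = {"config_hash": _config_hash(cfg), "version": _VERSION,
            "solver": cfg.get("solver", {})}

    t0 = time.perf_counter()
    beat0 = run_to_periodic(heart0, tree0, ctrl)
    log.info("baseline converged in %d beats (%.1f s)", beat0.beats_run,
             time.perf_counter() - t0)
    sv_target = scen.sv_target if scen.sv_target is not None else beat0.SV
    sigma_target = stress_index(beat0.peak_lv_pressure, beat0.EDV,
                                heart0.Ees)

    tree_band = scale_tpr(apply_banding(tree0, scen.banding_fraction),
                          scen.tpr_scale)
    heart_band0 = heart0.replace(Vd=heart0.Vd + scen.vd_shift)
    t0 = time.perf_counter()
    heart_band, beat_band = tune_pfill(heart_band0, tree_band, sv_target,
                                       ctrl)
    log.info("banding state tuned (Pfill %.2f mmHg, %.1f s)",
             heart_band.Pfill, time.perf_counter() - t0)

    t0 = time.perf_counter()
    rem = remodel(heart_band, tree_band, sigma_target, sv_target, ctrl)
    log.info("remodeling converged in %d iterations (%.1f s)",
             rem.iterations, time.perf_counter() - t0)

    reports = [
        _analyze_state("baseline", beat0, heart0, tree0, prov),
        _analyze_state("banding", beat_band, heart_band, tree_band, prov),
        _analyze_state("remodeling", rem.beat, rem.heart, tree_band, prov),
    ]
    beats = {"baseline": beat0, "banding": beat_band,
             "remodeling": rem.beat}
    result = StudyResult(reports=reports, remodeling=rem, beats=beats,
                         config=cfg, provenance=prov)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(result.to_json())
        result.frame().to_csv(outdir / "report.csv", index=False)
        for state, beat in beats.items():
            beat.to_csv(outdir / f"waveforms_{state}.csv")
    return result


def run_analytics(path, mode: str = "both") -> dict:
    """Standalone analytics on an external single-beat waveform CSV.

    The CSV must contain columns t and P (aortic pressure); wave
    separation additionally requires a Q column.  ``mode`` is one of
    pwa | wsa | both.
    """
    if mode not in ("pwa", "wsa", "both"):
        raise ValueError(f"unknown analytics mode {mode!r}")
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "t" not in cols or "p" not in cols and "p_root" not in cols:
        raise ValueError("waveform CSV needs columns t and P")
    t = df[cols["t"]].to_numpy(float)
    P = df[cols.get("p", cols.get("p_root"))].to_numpy(float)
    period = float(t[-1] + (t[1] - t[0]))
    out: dict = {}
    if mode in ("pwa", "both"):
        out["pwa"] = pwa.analyze_pressure(t, P, period).to_dict()
    if mode in ("wsa", "both"):
        qcol = cols.get("q", cols.get("q_root"))
        if qcol is None:
            raise ValueError("wave separation requires a Q column")
        Q = df[qcol].to_numpy(float)
        spec = wsa.input_impedance(P, Q, period)
        sep = wsa.separate(t, P, Q, spec.Zc)
        app = float(np.max(P) - np.min(P))
        out["wsa"] = wsa.separation_metrics(sep, app)
    return out
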