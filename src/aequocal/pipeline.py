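"""End-to-end orchestration: simulate/load -> calibrate -> features -> stats.

A run is declared by a TOML config (conditions, calibration constants,
feature thresholds, statistics family, seed) and produces the strain-level
report tables: Rest/Peak [Ca2+] summaries (micromolar), growth half-times,
and pairwise comparisons.  Every intermediate artifact is persisted as CSV
and a log records seeds, timings and a config hash, so a run is
reproducible byte-for-byte from its config.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .calibration import CalibrationConstants, calibrate
from .features import (
    DEFAULT_MIN_SEPARATION_S,
    DEFAULT_PROMINENCE_FRAC,
    DEFAULT_SMOOTHING_WINDOW_S,
    release_features,
)
from .growth import GrowthCurve, t50_per_replicate
from .stats import GroupSummary, anova_bonferroni, comparisons_table, ttest_unpaired
from .synthetic import AequorinParams, generate_ca_trajectory, preset, simulate_photon_trace


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class ConditionSpec:
    name: str
    preset: str | None = None
    paths: list[str] = field(default_factory=list)
    n_replicates: int = 24


@dataclass
class RunConfig:
    conditions: list[ConditionSpec]
    seed: int | None = None
    out_dir: str = "aequocal_run"
    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)
    initial_quanta: float = 1.0e8
    smoothing_window_s: float = DEFAULT_SMOOTHING_WINDOW_S
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S
    comparisons: list[tuple[str, str]] | str = "all"
    growth_paths: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        import tomllib

        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config not found: {path}")
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        conditions = [
            ConditionSpec(
                name=name,
                preset=spec.get("preset"),
                paths=list(spec.get("paths", [])),
                n_replicates=int(spec.get("n_replicates", 24)),
            )
            for name, spec in raw.get("conditions", {}).items()
        ]
        cal = CalibrationConstants(**raw.get("calibration", {}))
        feats = raw.get("features", {})
        stats_cfg = raw.get("stats", {})
        comparisons = stats_cfg.get("comparisons", "all")
        if comparisons != "all":
            comparisons = [tuple(p) for p in comparisons]
        cfg = cls(
            conditions=conditions,
            seed=raw.get("seed"),
            out_dir=raw.get("out_dir", "aequocal_run"),
            calibration=cal,
            initial_quanta=float(raw.get("simulate", {}).get("initial_quanta", 1.0e8)),
            smoothing_window_s=feats.get("smoothing_window_s", DEFAULT_SMOOTHING_WINDOW_S),
            prominence_frac=feats.get("prominence_frac", DEFAULT_PROMINENCE_FRAC),
            min_separation_s=feats.get("min_separation_s", DEFAULT_MIN_SEPARATION_S),
            comparisons=comparisons,
            growth_paths=dict(raw.get("growth", {}).get("paths", {})),
        )
        for key, value in overrides.items():
            setattr(cfg, key, value)
        return cfg

    def digest(self) -> str:
        payload = json.dumps(
            {
                "conditions": [
                    (c.name, c.preset, c.paths, c.n_replicates) for c in self.conditions
                ],
                "seed": self.seed,
                "calibration": [
                    self.calibration.k_r,
                    self.calibration.k_tr,
                    self.calibration.lambda_sat,
                    self.calibration.background_rate,
                ],
                "initial_quanta": self.initial_quanta,
                "features": [
                    self.smoothing_window_s,
                    self.prominence_frac,
                    self.min_separation_s,
                ],
                "comparisons": self.comparisons,
                "growth_paths": self.growth_paths,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportTables:
    rest_peak_table: pd.DataFrame
    growth_table: pd.DataFrame
    comparisons_table: pd.DataFrame
    features: pd.DataFrame


def _condition_features(cfg: RunConfig, cond: ConditionSpec, log) -> pd.DataFrame:
    rows = []
    if cond.preset is not None:
        if cfg.seed is None:
            raise PipelineError(
                f"stage simulate, condition {cond.name!r}: a seed is mandatory "
                "for simulation"
            )
        protocol, params = preset(cond.preset)
        truth = generate_ca_trajectory(protocol, params)
        aeq = AequorinParams(
            initial_quanta=cfg.initial_quanta,
            lambda_sat=cfg.calibration.lambda_sat,
            k_r=cfg.calibration.k_r,
            k_tr=cfg.calibration.k_tr,
            background_rate=cfg.calibration.background_rate,
        )
        name_key = int(hashlib.sha256(cond.name.encode()).hexdigest()[:8], 16) % (2**31)
        seeds = np.random.SeedSequence([cfg.seed, name_key]).generate_state(
            cond.n_replicates
        ) % (2**31)
        traces = [
            calibrate(simulate_photon_trace(truth, aeq, int(s)), cfg.calibration)
            for s in seeds
        ]
        log(f"condition {cond.name}: simulated {cond.n_replicates} replicates "
            f"(preset {cond.preset})")
    else:
        if not cond.paths:
            raise PipelineError(
                f"stage load, condition {cond.name!r}: neither a preset nor "
                "input paths were given"
            )
        try:
            photon = [aio.read_photon_trace(p) for p in cond.paths]
        except FileNotFoundError as exc:
            raise PipelineError(f"stage load, condition {cond.name!r}: {exc}") from exc
        traces = [calibrate(tr, cfg.calibration) for tr in photon]
        log(f"condition {cond.name}: loaded {len(traces)} records")

    for i, tr in enumerate(traces):
        try:
            feats = release_features(
                tr,
                smoothing_window_s=cfg.smoothing_window_s,
                prominence_frac=cfg.prominence_frac,
                min_separation_s=cfg.min_separation_s,
            )
        except ValueError as exc:
            raise PipelineError(
                f"stage features, condition {cond.name!r}, replicate {i}: {exc}"
            ) from exc
        row = feats.to_row(f"{cond.name}/{i}")
        row["condition"] = cond.name
        rows.append(row)
    return pd.DataFrame(rows)


def run(config: RunConfig) -> ReportTables:
    """Execute the full pipeline and persist all artifacts under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t_start = _time.perf_counter()

    def log(msg: str) -> None:
        log_lines.append(f"[{_time.perf_counter() - t_start:8.2f}s] {msg}")

    log(f"config digest {config.digest()}, seed {config.seed}")

    features_frames = [_condition_features(config, c, log) for c in config.conditions]
    features = pd.concat(features_frames, ignore_index=True)
    features.to_csv(out / "features.csv", index=False, float_format="%.6g")

    # strain-level Rest/Peak summary (micromolar, 2 decimals as reported)
    rest_peak_rows = []
    summaries_rest, summaries_peak = [], []
    for cond, sub in features.groupby("condition", sort=False):
        rest = GroupSummary.from_values(cond, sub["rest_ca_um"])
        peak = GroupSummary.from_values(cond, sub["peak_ca_um"])
        summaries_rest.append(rest)
        summaries_peak.append(peak)
        rest_peak_rows.append(
            {
                "condition": cond,
                "rest_ca_um_mean": round(rest.mean, 2),
                "rest_ca_um_sd": round(rest.sd, 2),
                "peak_ca_um_mean": round(peak.mean, 2),
                "peak_ca_um_sd": round(peak.sd, 2),
                "time_to_peak_s_mean": round(float(sub["time_to_peak_s"].mean()), 1),
                "decay_half_time_s_mean": round(
                    float(sub["decay_half_time_s"].mean()), 1
                ),
                "n": rest.n,
            }
        )
    rest_peak = pd.DataFrame(rest_peak_rows)
    rest_peak.to_csv(out / "rest_peak_table.csv", index=False)
    log("rest/peak table written")

    # growth stage (optional CSV inputs)
    growth_rows = []
    for strain, path in config.growth_paths.items():
        try:
            curve = aio.read_growth_curve(path)
        except FileNotFoundError as exc:
            raise PipelineError(f"stage growth, strain {strain!r}: {exc}") from exc
        per_rep = t50_per_replicate(curve)
        growth_rows.append(
            {
                "strain": strain,
                "t50_h_mean": round(float(per_rep["t50_h"].mean()), 2),
                "t50_h_sd": round(float(per_rep["t50_h"].std(ddof=1)), 2)
                if len(per_rep) > 1
                else 0.0,
                "n": len(per_rep),
            }
        )
    growth_table = pd.DataFrame(growth_rows)
    if not growth_table.empty:
        growth_table.to_csv(out / "growth_table.csv", index=False)
        log("growth table written")

    # statistics: Bonferroni family over rest and peak separately
    comp_frames = []
    if len(summaries_rest) >= 2:
        for metric, summaries in (("rest", summaries_rest), ("peak", summaries_peak)):
            results = anova_bonferroni(summaries, comparisons=config.comparisons)
            frame = comparisons_table(results)
            frame.insert(0, "metric", metric)
            comp_frames.append(frame)
    comparisons = (
        pd.concat(comp_frames, ignore_index=True) if comp_frames else pd.DataFrame()
    )
    if not comparisons.empty:
        comparisons.to_csv(out / "comparisons.csv", index=False, float_format="%.6g")
        log("comparisons table written")

    log("run complete")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return ReportTables(
        rest_peak_table=rest_peak,
        growth_table=growth_table,
        comparisons_table=comparisons,
        features=features,
    )
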