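"""Reproducible simulate -> segment -> fit -> stats runs.

`run_reproduce` executes the full chain on the named presets with fixed
seeds and emits a summary table of derived quantities (fin-body ratio, fin
bias, Spearman correlation of attack angle and posture change, postural
deviation) together with worked-example arithmetic checks (fin-bias index
of published slopes, binomial chance-level p-values).  A saved
configuration re-run with the same seed byte-reproduces all tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import kinematics, models, simulate, stats
from .presets import PRESET_LABELS, preset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_reproduce", "run_stage"]

# Published worked examples used as arithmetic self-checks: maximal sigmoid
# slope -> fin bias per age, and binomial chance-level tests
# (n_success, n_subset, chance rate, reported p).
FIN_BIAS_CHECKS = {2.76: 0.73, 2.89: 0.74, 7.03: 0.88, 12.01: 0.92}
BINOMIAL_CHECKS = [
    (193, 210, 0.634, 1.5e-21),
    (112, 141, 0.579, 5.2e-8),
    (90, 144, 0.660, 0.215),
]

_VARIANT_BY_LABEL = {
    "4dpf": "one_param", "1wpf": "one_param", "2wpf": "one_param",
    "3wpf": "one_param", "otog": "two_param", "finless": "two_param",
    "lesion": "double",
}


@dataclass
class RunConfig:
    """Fully serializable description of a reproduction run."""

    presets: tuple[str, ...] = PRESET_LABELS
    n_bouts: int = 3000
    seed: int = 0
    boot_reps: int = 300
    n_render_bouts: int = 40
    variants: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_bouts < 1:
            raise ValueError(f"n_bouts must be >= 1, got {self.n_bouts}")
        if self.boot_reps < 200:
            raise ValueError(f"boot_reps must be >= 200, got {self.boot_reps}")
        unknown = set(self.presets) - set(PRESET_LABELS)
        if unknown:
            raise ValueError(f"unknown presets: {sorted(unknown)}")

    def variant_for(self, label: str) -> str:
        return self.variants.get(label, _VARIANT_BY_LABEL.get(label, "four_param"))

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["presets"] = list(self.presets)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["presets"] = tuple(d.get("presets", PRESET_LABELS))
        return cls(**d)


def _fit_for(config: RunConfig, label: str, bouts: pd.DataFrame):
    variant = config.variant_for(label)
    r = bouts["posture_change_deg"].to_numpy()
    gamma = bouts["attack_angle_deg"].to_numpy()
    return models.bootstrap_fit(r, gamma, variant=variant,
                                n_reps=config.boot_reps, seed=config.seed)


def _round_trip(config: RunConfig, label: str, bouts: pd.DataFrame) -> dict:
    """Render a subset and check segmentation recovers it."""
    sub = bouts.iloc[: config.n_render_bouts]
    ep = simulate.render_epoch(sub, preset(label))
    segd = kinematics.segment_bouts(ep)
    rec = kinematics.bout_table(segd)
    out = {"n_rendered": int(len(sub)), "n_recovered": int(len(rec))}
    if len(rec) == len(sub):
        out["max_attack_err_deg"] = float(
            np.max(np.abs(rec["attack_angle_deg"].to_numpy()
                          - sub["attack_angle_deg"].to_numpy()))
        )
        valid = rec["valid_posture_change"].to_numpy().astype(bool)
        out["max_posture_change_err_deg"] = float(
            np.max(np.abs(rec["posture_change_deg"].to_numpy()[valid]
                          - sub["posture_change_deg"].to_numpy()[valid]))
        )
    return out


def run_reproduce(config: RunConfig, out_dir=None) -> dict:
    """Execute the full chain on synthetic presets and bundle the results.

    Returns a report dict with a per-preset summary table, round-trip
    checks, worked-example checks, and (if ``out_dir`` is given) writes all
    tables plus a digest for byte-reproducibility.
    """
    config.validate()
    report: dict = {"config": dataclasses.asdict(config), "presets": {}, "checks": {}}
    summary_rows = []
    tables: dict[str, pd.DataFrame] = {}
    for label in config.presets:
        t0 = _time.perf_counter()
        bouts = simulate.generate_bout_table(preset(label), config.n_bouts, seed=config.seed)
        tables[label] = bouts
        fit = _fit_for(config, label, bouts)
        rho = sps.spearmanr(bouts["posture_change_deg"], bouts["attack_angle_deg"]).statistic
        slope = fit.max_slope
        row = {
            "preset": label,
            "n_bouts": len(bouts),
            "variant": fit.variant,
            "fin_body_ratio": slope,
            "slope_ci_lo": fit.slope_ci95[0],
            "slope_ci_hi": fit.slope_ci95[1],
            "fin_bias": models.fin_bias(max(slope, 0.0)),
            "r_squared": fit.r_squared,
            "spearman_rho": float(rho),
            "mean_attack_deg": float(bouts["attack_angle_deg"].mean()),
            "mean_abs_posture_deg": float(bouts["posture_deg"].abs().mean()),
            "shallow_slope": stats.robust_shallow_slope(bouts),
        }
        summary_rows.append(row)
        report["presets"][label] = {
            "fit": {**{k: float(v) for k, v in _param_summary(fit).items()},
                    "r_squared": fit.r_squared},
            "round_trip": _round_trip(config, label, bouts),
        }
        logger.info("stage %s done in %.2f s", label, _time.perf_counter() - t0)
    summary = pd.DataFrame(summary_rows)
    report["summary"] = summary

    # Conflicting-action proportions: lesion vs the 1 wpf control preset.
    for label in ("1wpf", "lesion"):
        if label in tables:
            down, up = stats.conflict_proportions(tables[label], seed=config.seed)
            report["presets"][label]["conflict"] = {
                "nose_down": down.proportion, "nose_down_ci": down.ci95,
                "nose_up": up.proportion, "nose_up_ci": up.ci95,
            }

    # Worked-example arithmetic checks.
    fb = {
        f"fin_bias({s})": {
            "value": round(models.fin_bias(s), 2),
            "expected": e,
            "pass": round(models.fin_bias(s), 2) == e,
        }
        for s, e in FIN_BIAS_CHECKS.items()
    }
    bn = {}
    for k, n, p, expected in BINOMIAL_CHECKS:
        res = stats.chance_level_binomial(k, n, p)
        ok = (abs(res.p_value - expected) < 0.02 if expected > 1e-3
              else 1 / 3 < res.p_value / expected < 3)
        bn[f"binomial({k}/{n} vs {p})"] = {
            "value": res.p_value, "expected": expected, "pass": bool(ok),
        }
    report["checks"] = {**fb, **bn}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        digests = {}
        for label, table in tables.items():
            path = out / f"bouts_{label}.csv"
            table.to_csv(path, index=False)
            digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        spath = out / "summary.csv"
        summary.to_csv(spath, index=False)
        digests[spath.name] = hashlib.sha256(spath.read_bytes()).hexdigest()
        serializable = dict(report)
        serializable["summary"] = summary.to_dict(orient="records")
        (out / "report.yaml").write_text(
            yaml.safe_dump(_plainify(serializable), sort_keys=False))
        report["digests"] = digests
    return report


def _param_summary(fit) -> dict:
    p = fit.params
    if isinstance(p, models.DoubleSigmoidParams):
        d = {"chi": p.chi, "k": p.k, "gamma0": p.gamma0, "r_rise": p.r_rise,
             "nose_up_slope": p.nose_up_slope, "nose_down_slope": p.nose_down_slope}
    else:
        d = {"k": p.k, "gamma0": p.gamma0, "gamma_max": p.gamma_max,
             "r_rise": p.r_rise, "max_slope": p.max_slope}
    return d


def _plainify(obj):
    """Recursively convert numpy/pandas scalars for YAML output."""
    if isinstance(obj, dict):
        return {str(k): _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return _plainify(obj.to_dict(orient="records"))
    return obj


def run_stage(stage: str, **inputs):
    """Run a single pipeline stage with results identical to the full run.

    Stages: ``simulate`` (preset label or object, n_bouts, seed),
    ``segment`` (epoch or epochs), ``fit`` (bouts, variant, optional
    boot_reps/seed), ``stats`` (bouts, optional seed).
    """
    if stage == "simulate":
        p = inputs["preset"]
        p = preset(p) if isinstance(p, str) else p
        return simulate.generate_bout_table(p, inputs["n_bouts"], seed=inputs.get("seed"))
    if stage == "segment":
        epochs = inputs["epochs"]
        if isinstance(epochs, kinematics.TrackedEpoch):
            epochs = [epochs]
        bouts = [b for e in epochs for b in kinematics.segment_bouts(e)]
        return kinematics.bout_table(bouts)
    if stage == "fit":
        bouts = inputs["bouts"]
        r = bouts["posture_change_deg"].to_numpy()
        gamma = bouts["attack_angle_deg"].to_numpy()
        variant = inputs.get("variant", "one_param")
        if inputs.get("boot_reps"):
            return models.bootstrap_fit(r, gamma, variant=variant,
                                        n_reps=inputs["boot_reps"],
                                        seed=inputs.get("seed"))
        if variant == "double":
            return models.fit_double_sigmoid(r, gamma)
        return models.fit_sigmoid(r, gamma, variant=variant)
    if stage == "stats":
        bouts = inputs["bouts"]
        if len(bouts) == 0:
            return {"status": "no data", "n_bouts": 0}
        down, up = stats.conflict_proportions(bouts, seed=inputs.get("seed"))
        return {
            "status": "ok",
            "n_bouts": int(len(bouts)),
            "shallow_slope": stats.robust_shallow_slope(bouts),
            "conflict_nose_down": down.proportion,
            "conflict_nose_up": up.proportion,
            "climb_mean_abs_posture": stats.climb_posture_stats(bouts).mean_abs_posture,
        }
    raise ValueError(f"unknown stage {stage!r}; expected simulate/segment/fit/stats")
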