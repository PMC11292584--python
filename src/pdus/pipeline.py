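"""End-to-end orchestration: synthetic cohort -> profiles -> parameters ->
statistics, with an optional full-RF branch exercising the echo-level path
(simulate -> register -> SVD filter -> PD-US -> normalize).

Every stochastic stage derives its own sub-seed from the run seed, so a
rerun with the same config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .acquisition import AcquisitionGeometry
from .clutterfilter import FilterConfig
from .io import ensure_dir, geometry_from_config, rois_from_config
from .ischemia import params_table
from .perfusion import (
    PerfusionProfile,
    cohort_average,
    normalize_profile,
    process_ensemble,
    profiles_to_tidy,
)
from .schedule import SCHEDULE_LABELS
from .simdata import (
    CohortSpec,
    GroundTruthSpec,
    ischemic_truth_curve,
    simulate_cohort,
    simulate_ensemble,
)
from .stats import compare_profiles

_TOP_LEVEL_KEYS = {
    "seed", "geometry", "rois", "registration", "filter", "cohort",
    "rf_demo", "stats",
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "registration": True,
    "filter": {"n_removed": 1},
    "cohort": {
        "groups": [["HS", "M"], ["HE", "M"], ["DS", "M"], ["DE", "M"]],
        "n_per_group": 5,
        "noise_sd_db": 0.5,
    },
    "rf_demo": {
        "enabled": False,
        "truth": {"p_max_db": 3.0, "p_min_db": -6.0, "t_days": 9.0},
        "n_ensembles": 2,
        # blood echoes must sit above the noise floor for the RF path to
        # track perfusion, and the rank-1 clutter filter presumes a
        # motionless probe/tissue; see docs/methods.md
        "noise_power_db": -10.0,
        "clutter_power_db": 40.0,
        "respiration_amplitude_mm": 0.0,
        "axial_drift_mm_per_s": 0.0,
    },
    "stats": {
        "pairs": [["HS", "DS"], ["HE", "DE"], ["HS", "HE"], ["DS", "DE"]],
        "methods": ["t", "kruskal_wallis", "wilcoxon"],
    },
}


def _merged_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in (config or {}).items():
        if k not in _TOP_LEVEL_KEYS:
            raise ValueError(f"unknown config key {k!r}")
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def rf_mouse_profile(
    truth: dict,
    geom: AcquisitionGeometry,
    rois: Sequence,
    base_spec: GroundTruthSpec | None = None,
    n_ensembles: int = 2,
    register: bool = True,
    filter_cfg: FilterConfig = FilterConfig(),
    seed: int = 0,
    labels: Sequence[str] = SCHEDULE_LABELS,
    mouse_id: str = "rf-demo",
) -> PerfusionProfile:
    """Measure one mouse's perfusion profile through the full echo path.

    For each schedule time, RF ensembles are simulated with the blood power
    scaled by the true ischemic curve, optionally registered, SVD-filtered,
    and power-averaged; the resulting linear powers are normalized by the
    measured pre-ligation baseline.
    """
    curve = ischemic_truth_curve(
        truth["p_max_db"], truth["p_min_db"], truth["t_days"]
    )
    if base_spec is None:
        base_spec = GroundTruthSpec()
    powers: dict[str, float] = {}
    ss = np.random.SeedSequence([int(seed), 0x5F])
    children = ss.spawn(len(labels))
    for lab, child in zip(labels, children):
        spec = GroundTruthSpec(
            clutter_power_db=base_spec.clutter_power_db,
            blood_power_db=base_spec.blood_power_db,
            noise_power_db=base_spec.noise_power_db,
            respiration_amplitude_mm=base_spec.respiration_amplitude_mm,
            respiration_period_s=base_spec.respiration_period_s,
            axial_drift_mm_per_s=base_spec.axial_drift_mm_per_s,
            blood_speed_mm_per_s=base_spec.blood_speed_mm_per_s,
            scatterer_density_per_mm2=base_spec.scatterer_density_per_mm2,
            perfusion_curve=curve,
            seed=base_spec.seed,
        )
        rngs = [np.random.default_rng(s) for s in child.spawn(n_ensembles)]
        p = []
        for rng in rngs:
            ens = simulate_ensemble(spec, geom, t=lab, rng=rng)
            roi_powers, _ = process_ensemble(
                ens, rois, filter_cfg, register=register
            )
            p.extend(roi_powers)
        powers[lab] = float(np.mean(p))
    return normalize_profile(powers, mouse_id=mouse_id, limb="ischemic")


def run_pipeline(
    config: dict | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis on a synthetic cohort.

    Returns a dict of artifact DataFrames; writes them as CSV (plus a
    ``run.json`` provenance record) when ``out_dir`` is given.  Identical
    config + seed give identical outputs.
    """
    cfg = _merged_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    run_seed = int(cfg["seed"])

    cohort_cfg = cfg["cohort"]
    cs = CohortSpec(
        groups=[tuple(g) for g in cohort_cfg["groups"]],
        n_per_group=int(cohort_cfg["n_per_group"]),
        noise_sd_db=float(cohort_cfg["noise_sd_db"]),
        seed=run_seed,
    )
    cohort = simulate_cohort(cs)

    artifacts: dict = {
        "profiles": profiles_to_tidy(cohort.profiles),
        "records": cohort.records,
        "true_params": cohort.true_params,
        "params": params_table(cohort.profiles),
    }

    curves = []
    for g_label in sorted({g for g, _ in cs.groups}):
        c = cohort_average(cohort.profiles, group=g_label)
        c.insert(0, "group", g_label)
        curves.append(c)
    artifacts["group_curves"] = pd.concat(curves, ignore_index=True)

    rows = []
    gc = artifacts["group_curves"]
    for a, b in cfg["stats"]["pairs"]:
        ca = gc[gc.group == a]
        cb = gc[gc.group == b]
        if ca.empty or cb.empty:
            continue
        for method in cfg["stats"]["methods"]:
            p = compare_profiles(
                ca.mean_db.to_numpy(), cb.mean_db.to_numpy(), method=method,
                labels_a=list(ca.time_label), labels_b=list(cb.time_label),
            )
            rows.append({"group_a": a, "group_b": b, "method": method, "p": p})
    artifacts["stats"] = pd.DataFrame(rows)

    if cfg["rf_demo"].get("enabled"):
        geom = geometry_from_config(cfg)
        rois = rois_from_config(cfg, geom)
        demo = cfg["rf_demo"]
        base = GroundTruthSpec(
            clutter_power_db=float(demo.get("clutter_power_db", 40.0)),
            noise_power_db=float(demo.get("noise_power_db", -10.0)),
            respiration_amplitude_mm=float(
                demo.get("respiration_amplitude_mm", 0.0)
            ),
            axial_drift_mm_per_s=float(demo.get("axial_drift_mm_per_s", 0.0)),
            seed=run_seed,
        )
        prof = rf_mouse_profile(
            demo["truth"], geom, rois,
            base_spec=base,
            n_ensembles=int(demo.get("n_ensembles", 2)),
            register=bool(cfg["registration"]),
            filter_cfg=FilterConfig(n_removed=int(cfg["filter"]["n_removed"])),
            seed=run_seed,
        )
        artifacts["rf_profile"] = prof.to_frame()

    if out_dir is not None:
        out = ensure_dir(out_dir)
        for name, df in artifacts.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "run.json").write_text(
            json.dumps(
                {
                    "config": cfg,
                    "config_hash": config_hash(cfg),
                    "seed": run_seed,
                    "version": __version__,
                },
                indent=2,
            )
        )
    return artifacts
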