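"""End-to-end pipeline: generate → impute → calibrate → simulate →
economics → PSA, with serialized outputs and a run manifest.

A single master seed spawns independent per-stage substreams so any stage
can be re-run in isolation reproducibly.  Outputs: a burden table CSV
(condition rows, totals row and change-from-baseline columns per scenario),
a cost-effectiveness-plane CSV, a PSA summary CSV, and a JSON manifest.
"""

from __future__ import annotations

import logging
import pathlib
import time

import numpy as np
import pandas as pd

from . import calibration, economics, uncertainty
from .config import load_config, make_manifest, write_manifest
from .engine import DALYParameters, SimulationConfig, run_simulation
from .errors import NcdsimError
from .interventions import ReachCurve, intervention_library
from .population import PopulationSpec, generate_population, impute_missing, induce_lab_missingness
from .risk import default_models

__all__ = ["run_pipeline", "stage_seeds"]

log = logging.getLogger("ncdsim")

_STAGES = ("generate", "missingness", "impute", "calibrate", "simulate", "psa")


def stage_seeds(master_seed: int) -> dict:
    """Independent per-stage integer seeds spawned from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(_STAGES))
    return {name: int(child.generate_state(1)[0] % 2**31)
            for name, child in zip(_STAGES, children)}


def run_pipeline(config: dict | None = None, output_dir=None) -> dict:
    """Execute the full pipeline for a validated configuration dict (or the
    shipped defaults).  Returns the in-memory results and writes CSV/JSON
    outputs when ``output_dir`` (or the configured one) is set."""
    cfg = config if isinstance(config, dict) else load_config(config)
    seeds = stage_seeds(cfg["seed"])
    out_dir = pathlib.Path(output_dir or cfg.get("output_dir", "results"))
    stage = "setup"
    try:
        t0 = time.time()
        stage = "generate"
        spec = PopulationSpec.default()
        pop = generate_population(spec, cfg["population"]["n"], seeds["generate"])
        stage = "missingness"
        pop = induce_lab_missingness(pop, cfg["population"]["lab_observed_fraction"],
                                     seeds["missingness"])
        stage = "impute"
        if cfg["population"].get("impute", True):
            pop = impute_missing(pop, seeds["impute"],
                                 n_chains=cfg["population"].get("n_chains", 5))
        log.info("population ready (n=%d) in %.1fs", len(pop), time.time() - t0)

        stage = "calibrate"
        t0 = time.time()
        sim_cfg = SimulationConfig(
            horizon_years=cfg["simulation"]["horizon_years"],
            population_size=cfg["simulation"]["population_size"],
            discount_rate=cfg["simulation"]["discount_rate"],
            seed=seeds["simulate"],
            replicates=cfg["simulation"]["replicates"],
        )
        daly_params = DALYParameters.default()
        targets = calibration.default_targets(cfg["calibration"]["tolerance"])
        models = calibration.calibrate_all(pop, default_models(), targets, sim_cfg, daly_params)
        log.info("calibration done in %.1fs", time.time() - t0)

        stage = "simulate"
        t0 = time.time()
        baseline = run_simulation(pop, models, daly_params, sim_cfg)
        lib = intervention_library()
        curve = ReachCurve(final_reach=cfg["interventions"]["final_reach"],
                           ramp=cfg["interventions"]["ramp"])
        scenarios = {}
        for who_id in cfg["interventions"]["selected"]:
            spec_i = lib[who_id]
            spec_i.reach = curve
            scenarios[who_id] = run_simulation(pop, models, daly_params, sim_cfg,
                                               scenario=spec_i)
        log.info("simulation done in %.1fs", time.time() - t0)

        stage = "economics"
        selected = {w: lib[w] for w in cfg["interventions"]["selected"]}
        if cfg["economics"]["mode"] == "panel":
            league = economics.league_table(selected,
                                            rate=cfg["simulation"]["discount_rate"])
        else:
            league = economics.league_table(selected, results=scenarios, baseline=baseline,
                                            rate=cfg["simulation"]["discount_rate"])
        plane = economics.ce_plane_export(league)

        stage = "psa"
        t0 = time.time()
        dists = uncertainty.default_psa_distributions(cfg["psa"].get("cost_cv", 0.2))
        dists.params = {k: v for k, v in dists.params.items()
                        if k.split(":", 1)[1] in selected}
        psa = uncertainty.run_psa(
            uncertainty.panel_psa_evaluator(selected,
                                            rate=cfg["simulation"]["discount_rate"]),
            dists, cfg["psa"]["n_draws"], seeds["psa"],
        )
        log.info("psa done in %.1fs", time.time() - t0)

        manifest = make_manifest(cfg, seeds)
        results = {
            "population": pop, "models": models, "baseline": baseline,
            "scenarios": scenarios, "league": league, "ce_plane": plane,
            "psa": psa, "manifest": manifest,
        }
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            tables = [baseline.to_table()] + [
                s.to_table(baseline) for s in scenarios.values()
            ]
            pd.concat(tables).to_csv(out_dir / "burden_table.csv",
                                     index_label="condition")
            plane.to_csv(out_dir / "ce_plane.csv", index=False)
            psa.summary.to_csv(out_dir / "psa_summary.csv", index_label="who_id")
            write_manifest(manifest, out_dir / "manifest.json")
        return results
    except NcdsimError as err:
        raise NcdsimError(f"pipeline failed at stage {stage!r}: {err}") from err
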