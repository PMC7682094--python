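"""End-to-end orchestration: synth -> clonality -> branch counts -> divergence
timing -> doubling time -> relapse-scenario simulation, with a run manifest.

One global seed fans out to per-stage seeds through numpy's SeedSequence
(stage k uses spawn child k, in the fixed stage order below), so replaying a
manifest reproduces every output bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clonality import annotate
from .divergence_clock import ClockConfig, count_branches, estimate_cohort
from .doubling_time import (
    fit_doubling_time,
    flag_detectability,
    population_at_diagnosis,
)
from .io_tables import mutations_frame, read_blasts, write_cohort
from .synthetic_cohort import CohortConfig, gen_cohort
from .wf_simulator import SimConfig, run_scenario

log = logging.getLogger("tallevo")

STAGES = ("synth", "clonality", "branches", "divtime", "doubling", "simulate")

#: Demo-scale defaults: every stage runs in about a minute on one CPU while
#: keeping the study's structural parameters (rates, windows, thresholds).
DEFAULT_CONFIG: dict = {
    "cohort": {"n_patients": 6},
    "clock": {"n_grid": 40, "n_sims": 40},
    "doubling": {"n_starts": 20},
    "sim": {
        "pop_size": 20_000,
        "burn_in_generations": 400,
        "regrow_generations": 30,
        "bottleneck_removed_range": (2_000, 20_000),
        "resistant_marker_freq_range": (1e-3, 5e-2),
        "mu": 5e-7,
    },
}


def load_config(path=None) -> dict:
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values or {})
    return cfg


def _stage_seed(root_seed: int, stage: str) -> int:
    children = np.random.SeedSequence(root_seed).spawn(len(STAGES))
    child = children[STAGES.index(stage)]
    return int(child.generate_state(1)[0] % (2**31))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def run_all(config_path, out_dir, seed: int) -> dict:
    """Run every stage on a fresh synthetic cohort; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = load_config(config_path)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stage_seeds": {s: _stage_seed(seed, s) for s in STAGES},
        "inputs": {},
        "outputs": {},
    }

    # synth
    cohort_cfg = CohortConfig(
        **_tuplify(config.get("cohort", {})), seed=manifest["stage_seeds"]["synth"]
    )
    patients = gen_cohort(cohort_cfg)
    paths = write_cohort(patients, out)
    manifest["inputs"] = {k: _digest(p) for k, p in paths.items()}
    log.info("synth: wrote %d patients", len(patients))

    # clonality: annotate each (patient, sample) separately
    annotated = []
    purity_rows = []
    for p in patients:
        for sample in ("primary", "relapse"):
            recs = [r for r in p.mutations if r.sample == sample]
            called, fit = annotate(recs)
            annotated.extend(called)
            purity_rows.append(
                {
                    "patient_id": p.patient_id,
                    "sample": sample,
                    "purity": fit.purity,
                    "true_purity": p.purity[sample],
                    "clonal_mean_vaf": fit.betabinom_params[0],
                    "clonal_rho": fit.betabinom_params[1],
                }
            )
    annot_path = out / "mutations.annotated.tsv"
    mutations_frame(annotated).to_csv(annot_path, sep="\t", index=False)
    purity_path = out / "purity.tsv"
    pd.DataFrame(purity_rows).to_csv(purity_path, sep="\t", index=False)
    log.info("clonality: annotated %d records", len(annotated))

    # branch counts
    clocks = []
    for p in patients:
        recs = [r for r in annotated if r.patient_id == p.patient_id]
        clocks.append(
            count_branches(
                recs, p.counts.age_dx_days, p.counts.age_rel_days, patient_id=p.patient_id
            )
        )
    counts_path = out / "branch_counts.tsv"
    pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in clocks],
            "n_primary_private": [c.n_primary_private for c in clocks],
            "n_shared": [c.n_shared for c in clocks],
            "n_relapse_private": [c.n_relapse_private for c in clocks],
        }
    ).to_csv(counts_path, sep="\t", index=False)

    # divergence timing
    clock_cfg = ClockConfig(**config.get("clock", {}))
    estimates, posterior, grids = estimate_cohort(
        clocks, clock_cfg, seed=manifest["stage_seeds"]["divtime"]
    )
    est_path = out / "divergence_estimates.tsv"
    estimates.to_csv(est_path, sep="\t", index=False)
    grid_path = out / "hypothesis_grids.tsv"
    pd.concat([g.to_dataframe() for g in grids]).to_csv(grid_path, sep="\t", index=False)

    # doubling time and population sizes
    blasts = read_blasts(paths["blasts"])
    fit = fit_doubling_time(
        blasts,
        n_starts=config.get("doubling", {}).get("n_starts", 50),
        seed=manifest["stage_seeds"]["doubling"],
    )
    pops = [
        population_at_diagnosis(
            o.biopsy_blast_frac, o.delta_t_days, fit, patient_id=o.patient_id
        )
        for o in blasts
    ]
    flags = flag_detectability(pops)
    doubling_path = out / "doubling.tsv"
    pd.DataFrame(
        [
            {
                **flag,
                "T_D": fit.T_D,
                "T_D_q1": fit.T_D_quartiles[0],
                "T_D_q3": fit.T_D_quartiles[1],
                "generations": pop.generations,
            }
            for flag, pop in zip(flags, pops)
        ]
    ).to_csv(doubling_path, sep="\t", index=False)

    # relapse scenarios
    sim_cfg = SimConfig(**_tuplify(config.get("sim", {})))
    sim_rows = []
    hist_rows = []
    for i, scenario in enumerate(("resistant", "non_resistant")):
        comparison, summary = run_scenario(
            sim_cfg, scenario, seed=manifest["stage_seeds"]["simulate"] + i
        )
        sim_rows.append(summary)
        for b, frac in enumerate(comparison.histogram):
            hist_rows.append(
                {
                    "scenario": scenario,
                    "ccf_bin_low": comparison.bin_edges[b],
                    "ccf_bin_high": comparison.bin_edges[b + 1],
                    "fraction": frac,
                }
            )
    sim_path = out / "scenario_summary.tsv"
    pd.DataFrame(sim_rows).to_csv(sim_path, sep="\t", index=False)
    hist_path = out / "scenario_ccf_histograms.tsv"
    pd.DataFrame(hist_rows).to_csv(hist_path, sep="\t", index=False)

    # report + manifest
    report = out / "report.txt"
    with report.open("w") as fh:
        fh.write(f"tallevo {__version__} run (seed {seed})\n\n")
        fh.write(f"Doubling time T_D = {fit.T_D:.2f} d "
                 f"(Q1-Q3 {fit.T_D_quartiles[0]:.2f}-{fit.T_D_quartiles[1]:.2f})\n\n")
        fh.write("Per-patient divergence (days pre-diagnosis) and relapse-clone size:\n")
        for row, flag in zip(estimates.itertuples(), flags):
            fh.write(
                f"  {row.patient_id}: divergence {row.divergence_days:7.1f} d, "
                f"N_d {flag['N_d']:.3g} cells, "
                f"{'present' if flag['above_one_cell'] else 'possibly absent'} at diagnosis\n"
            )
        fh.write("\nScenario verdict (low-bin mass of relapse-fixed mutations):\n")
        for row in sim_rows:
            fh.write(f"  {row['scenario']}: {row['low_bin_mass']:.3f}\n")

    for name, p in [
        ("mutations_annotated", annot_path),
        ("purity", purity_path),
        ("branch_counts", counts_path),
        ("divergence_estimates", est_path),
        ("hypothesis_grids", grid_path),
        ("doubling", doubling_path),
        ("scenario_summary", sim_path),
        ("scenario_ccf_histograms", hist_path),
        ("report", report),
    ]:
        manifest["outputs"][name] = {"path": p.name, "sha256": _digest(p)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
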