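"""TSV/JSON schemas and readers/writers shared across pipeline stages.

All tabular interchange is tab-separated with a one-line header; manifests
and ground truth are JSON.  Validation reports the offending row and field
for each violation instead of failing wholesale.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clonality import MutationRecord
from .divergence_clock import PatientClock
from .doubling_time import BlastObservation
from .mutation_process import DAYS_PER_YEAR
from .synthetic_cohort import SyntheticPatient

SCHEMAS: dict[str, dict] = {
    "patients": {
        "columns": [
            "patient_id",
            "age_dx_years",
            "age_rel_years",
            "n_primary_private",
            "n_shared",
            "n_relapse_private",
        ],
        "checks": [
            ("age_rel_years", lambda row: row["age_rel_years"] > row["age_dx_years"],
             "age_rel_years must exceed age_dx_years"),
            ("n_shared", lambda row: min(row["n_primary_private"], row["n_shared"],
                                         row["n_relapse_private"]) >= 0,
             "branch counts must be non-negative"),
        ],
    },
    "mutations": {
        "columns": [
            "patient_id", "sample", "chrom", "pos", "ref", "alt",
            "alt_reads", "depth", "cn", "signature",
        ],
        "checks": [
            ("alt_reads", lambda row: 0 <= row["alt_reads"] <= row["depth"],
             "alt_reads must lie in [0, depth]"),
            ("cn", lambda row: row["cn"] >= 0, "copy number must be >= 0"),
            ("sample", lambda row: row["sample"] in ("primary", "relapse"),
             "sample must be primary or relapse"),
        ],
    },
    "blasts": {
        "columns": [
            "patient_id", "t0_days", "blast_frac0", "t1_days", "blast_frac1",
            "biopsy_blast_frac", "delta_t_days",
        ],
        "checks": [
            ("t1_days", lambda row: row["t1_days"] > row["t0_days"],
             "t1_days must exceed t0_days"),
            ("blast_frac0", lambda row: 0 < row["blast_frac0"] < 1,
             "blast fractions must be in (0, 1)"),
            ("blast_frac1", lambda row: 0 < row["blast_frac1"] < 1,
             "blast fractions must be in (0, 1)"),
        ],
    },
}


def validate_table(path, schema_name: str) -> tuple[int, list[str]]:
    """Count schema-conforming rows; list violations as 'row N: message'."""
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = SCHEMAS[schema_name]
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return 0, ["file is empty"]
    violations: list[str] = []
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        return 0, [f"missing columns: {', '.join(missing)}"]
    n_valid = 0
    for i, row in df.iterrows():
        ok = True
        for fieldname, check, message in schema["checks"]:
            try:
                passed = bool(check(row))
            except Exception:
                passed = False
            if not passed:
                violations.append(f"row {i}, field {fieldname}: {message}")
                ok = False
        if ok:
            n_valid += 1
    return n_valid, violations


# -- writers ---------------------------------------------------------------


def patients_frame(patients: Sequence[SyntheticPatient]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "age_dx_years": [p.age_dx for p in patients],
            "age_rel_years": [p.age_rel for p in patients],
            "n_primary_private": [p.counts.n_primary_private for p in patients],
            "n_shared": [p.counts.n_shared for p in patients],
            "n_relapse_private": [p.counts.n_relapse_private for p in patients],
        }
    )


def mutations_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "sample": [r.sample for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
            "alt_reads": [r.alt_reads for r in records],
            "depth": [r.depth for r in records],
            "cn": [r.cn for r in records],
            "signature": [r.signature for r in records],
            "ccf": [r.ccf for r in records],
            "clonality": [r.clonality for r in records],
        }
    )


def blasts_frame(patients: Sequence[SyntheticPatient]) -> pd.DataFrame:
    rows = []
    for p in patients:
        o = p.blast_obs
        rows.append(
            {
                "patient_id": p.patient_id,
                "t0_days": o.t0,
                "blast_frac0": o.y0,
                "t1_days": o.t1,
                "blast_frac1": o.y1,
                "biopsy_blast_frac": o.biopsy_blast_frac,
                "delta_t_days": o.delta_t_days,
            }
        )
    return pd.DataFrame(rows)


def write_cohort(patients: Sequence[SyntheticPatient], outdir) -> dict[str, Path]:
    """Write patients/mutations/blasts TSVs plus the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": outdir / "patients.tsv",
        "mutations": outdir / "mutations.tsv",
        "blasts": outdir / "blasts.tsv",
        "truth": outdir / "truth.json",
    }
    patients_frame(patients).to_csv(paths["patients"], sep="\t", index=False)
    all_records = [r for p in patients for r in p.mutations]
    mutations_frame(all_records).to_csv(paths["mutations"], sep="\t", index=False)
    blasts_frame(patients).to_csv(paths["blasts"], sep="\t", index=False)
    truth = {
        p.patient_id: {
            "true_t_accel_days": p.true_t_accel,
            "true_t_div_days": p.true_t_div,
            "true_rate_param": p.true_rate_param,
            "purity": p.purity,
            "true_blast_offset_days": p.blast_obs.true_offset if p.blast_obs else None,
        }
        for p in patients
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths


# -- readers ---------------------------------------------------------------


def read_patients(path) -> list[PatientClock]:
    df = pd.read_csv(path, sep="\t")
    return [
        PatientClock(
            patient_id=str(row.patient_id),
            age_dx_days=float(row.age_dx_years) * DAYS_PER_YEAR,
            age_rel_days=float(row.age_rel_years) * DAYS_PER_YEAR,
            n_primary_private=int(row.n_primary_private),
            n_shared=int(row.n_shared),
            n_relapse_private=int(row.n_relapse_private),
        )
        for row in df.itertuples()
    ]


def read_mutations(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples():
        records.append(
            MutationRecord(
                patient_id=str(row.patient_id),
                sample=str(row.sample),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                alt_reads=int(row.alt_reads),
                depth=int(row.depth),
                cn=int(row.cn),
                signature=str(row.signature),
                clonality=str(getattr(row, "clonality", "unset")),
                ccf=float(row.ccf) if hasattr(row, "ccf") and np.isfinite(row.ccf) else None,
            )
        )
    return records


def read_blasts(path) -> list[BlastObservation]:
    df = pd.read_csv(path, sep="\t")
    return [
        BlastObservation(
            patient_id=str(row.patient_id),
            t0=float(row.t0_days),
            t1=float(row.t1_days),
            y0=float(row.blast_frac0),
            y1=float(row.blast_frac1),
            biopsy_blast_frac=float(row.biopsy_blast_frac),
            delta_t_days=float(row.delta_t_days),
        )
        for row in df.itertuples()
    ]
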