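"""End-to-end orchestration: cohort -> connectivity -> networks -> report.

``run_pipeline`` executes every stage for every configured measure and
writes a results directory of tidy CSVs plus a JSON manifest; rerunning with
the same config reproduces identical files. ``validate_inputs`` checks
real-data inputs (EDF + sensor CSV alignment, grey-matter availability)
without raising — problems come back as report entries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .conditions import cohort_report, conditions_frame, run_conditions
from .config import RunConfig
from .connectivity import connectivity_matrix
from .distance import fit_class_models, residualize
from .io import (
    read_edf,
    read_matrix_csv,
    read_sensor_table,
    save_fits,
    save_network,
    write_edf,
    write_matrix_csv,
    write_sensor_table,
)
from .metrics import (
    louvain_partition,
    node_strength,
    normalized_strength,
    participation_coefficient,
)
from .network import build_patient_network
from .synthetic import generate_cohort
from .types import AdjacencyMatrix, InvalidSpecError, PatientNetwork, SENSOR_COLUMNS

logger = logging.getLogger(__name__)


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _report_to_json(report: dict) -> dict:
    """Stringify tuple keys so the cohort report serializes as JSON."""
    out = {}
    for key, value in report.items():
        if isinstance(value, dict):
            value = { (k if isinstance(k, str) else "_".join(map(str, k))): v
                      for k, v in value.items() }
        out[key] = value
    return out


def run_pipeline(config: RunConfig, output_dir: Optional[str] = None) -> Path:
    """Run the full pipeline and return the results directory.

    Synthetic mode generates the cohort from ``config.cohort``; real-data
    mode (``config.patients``) loads EDF recordings or precomputed adjacency
    CSVs. Outputs per measure: per-patient D_rs under GM/DC/UL/AR
    (``drs/<measure>.csv``), pooled distance fits (``fits/<measure>.json``),
    node metrics (``metrics/<measure>.csv``) and the cohort report
    (``report/<measure>.json``); plus cohort sensor tables and a manifest.
    """
    config.validate()
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in ("cohort", "fits", "drs", "report", "metrics"):
        (out / sub).mkdir(exist_ok=True)

    synthetic = config.patients is None
    if synthetic:
        patients = generate_cohort(config.cohort, seed=config.seed)
        sensor_tables = {p.patient_id: p.sensors for p in patients}
        recordings = {p.patient_id: p.recording for p in patients}
        modality = {p.patient_id: p.modality for p in patients}
        precomputed: Dict[str, AdjacencyMatrix] = {}
        for p in patients:
            write_sensor_table(p.sensors, out / "cohort" / f"{p.patient_id}_sensors.csv")
            write_matrix_csv(p.truth.weights, p.truth.contact_ids,
                             out / "cohort" / f"{p.patient_id}_truth.csv")
            if config.write_recordings:
                write_edf(p.recording, out / "cohort" / f"{p.patient_id}.edf")
    else:
        sensor_tables, recordings, precomputed, modality = {}, {}, {}, {}
        for p in config.patients:
            sensors = read_sensor_table(p.sensors_csv)
            sensor_tables[p.patient_id] = sensors
            modality[p.patient_id] = p.modality
            if p.edf:
                recordings[p.patient_id] = read_edf(p.edf)
            else:
                values, ids = read_matrix_csv(p.adjacency_csv)
                precomputed[p.patient_id] = AdjacencyMatrix(
                    values=values, channel_ids=ids, measure=config.measures[0]
                )

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "mode": "synthetic" if synthetic else "real",
        "patients": sorted(sensor_tables),
    }

    for measure in config.measures:
        networks: List[PatientNetwork] = []
        for pid in sorted(sensor_tables):
            if pid in precomputed:
                adjacency = precomputed[pid]
            else:
                adjacency = connectivity_matrix(
                    recordings[pid], measure=measure, window_s=config.window_s,
                    nw=config.taper_nw, k_tapers=config.taper_k,
                    lag_max_ms=config.lag_max_ms,
                )
            networks.append(
                build_patient_network(sensor_tables[pid], adjacency,
                                      modality[pid], measure=measure, patient_id=pid)
            )

        fits = fit_class_models(networks, n_starts=config.distance_starts,
                                seed=config.stage_seed("distance_fit"))
        save_fits(fits, out / "fits" / f"{measure}.json")

        condition_sets = [run_conditions(net, fits) for net in networks]
        frame = conditions_frame(condition_sets)
        frame.to_csv(out / "drs" / f"{measure}.csv", index=False)

        metric_rows = []
        for i, net in enumerate(networks):
            strengths = node_strength(net.adjacency)
            z = normalized_strength(strengths)
            row = pd.DataFrame({
                "patient_id": net.patient_id,
                "contact_id": net.node_ids,
                "strength": strengths,
                "normalized_strength": z,
                "resected": net.resected_mask,
                "electrode_type": net.nodes["electrode_type"],
            })
            if config.compute_participation:
                dc = residualize(net, fits).network
                part = louvain_partition(
                    dc.adjacency, gamma=config.louvain_gamma,
                    n_runs=config.louvain_runs,
                    seed=config.stage_seed("louvain", i),
                )
                row["community"] = part.labels
                row["participation"] = participation_coefficient(dc.adjacency,
                                                                 part.labels)
            metric_rows.append(row)
        pd.concat(metric_rows, ignore_index=True).to_csv(
            out / "metrics" / f"{measure}.csv", index=False
        )

        report = cohort_report(condition_sets, patient_tables=sensor_tables)
        (out / "report" / f"{measure}.json").write_text(
            json.dumps(_report_to_json(report), indent=2, default=_json_default)
        )

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default)
    )
    return out


def validate_inputs(paths: dict) -> dict:
    """Check real-data inputs for conformance; problems become report entries.

    ``paths`` maps patient ids to dicts with ``sensors_csv`` and optionally
    ``edf`` / ``adjacency_csv``. Returns ``{"ok": bool, "problems": [...]}``
    where each problem has ``patient``, ``severity`` ('fatal'/'warning') and
    ``message``.
    """
    problems = []

    def fatal(pid, msg):
        problems.append({"patient": pid, "severity": "fatal", "message": msg})

    def warn(pid, msg):
        problems.append({"patient": pid, "severity": "warning", "message": msg})

    for pid, entry in paths.items():
        sensors = None
        spath = entry.get("sensors_csv")
        if not spath or not Path(spath).exists():
            fatal(pid, f"sensor CSV missing: {spath}")
        else:
            try:
                raw = pd.read_csv(spath)
                missing = [c for c in SENSOR_COLUMNS if c not in raw.columns]
                if missing:
                    fatal(pid, f"sensor CSV missing columns: {missing}")
                else:
                    sensors = read_sensor_table(spath)
            except Exception as exc:  # noqa: BLE001
                fatal(pid, f"sensor CSV unreadable: {exc}")
        if sensors is not None:
            if not (sensors["tissue"] == "GM").any():
                fatal(pid, "no grey-matter contacts")
            if not sensors["resected"].any():
                warn(pid, "no resected contacts; D_rs undefined")
        edf = entry.get("edf")
        if edf:
            if not Path(edf).exists():
                fatal(pid, f"EDF missing: {edf}")
            elif sensors is not None:
                try:
                    rec = read_edf(edf)
                except Exception as exc:  # noqa: BLE001
                    fatal(pid, f"EDF unreadable: {exc}")
                else:
                    if rec.n_channels != len(sensors):
                        fatal(pid, f"EDF has {rec.n_channels} channels but "
                                   f"sensor CSV lists {len(sensors)} contacts")
        adj = entry.get("adjacency_csv")
        if adj:
            if not Path(adj).exists():
                fatal(pid, f"adjacency CSV missing: {adj}")
            elif sensors is not None:
                try:
                    values, ids = read_matrix_csv(adj)
                except Exception as exc:  # noqa: BLE001
                    fatal(pid, f"adjacency CSV unreadable: {exc}")
                else:
                    if set(ids) != set(sensors["contact_id"].astype(str)):
                        fatal(pid, "adjacency ids do not match sensor CSV")
                    elif not np.allclose(values, values.T):
                        warn(pid, "adjacency not symmetric; will be symmetrized")
    return {"ok": not any(p["severity"] == "fatal" for p in problems),
            "problems": problems}
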