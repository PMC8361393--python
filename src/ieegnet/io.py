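"""File formats: EDF recordings, CSV tables/matrices, network directories.

Sensor tables are CSV with exactly the canonical column set; adjacency and
distance matrices are square CSVs with contact ids as header row and column.
Recordings are European Data Format (EDF): reading goes through
:func:`mne.io.read_raw_edf`; writing uses a minimal EDF writer (16-bit,
1-second data records) because signals here are synthetic or already
preprocessed and need no vendor-specific header fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd

from .types import (
    InvalidSpecError,
    PatientNetwork,
    Rat11Fit,
    Recording,
    SENSOR_COLUMNS,
    validate_sensor_table,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# CSV tables and matrices
# ---------------------------------------------------------------------------


def write_sensor_table(sensors: pd.DataFrame, path: PathLike) -> None:
    """Write a sensor table as CSV with the canonical columns and a header."""
    validate_sensor_table(sensors).to_csv(path, index=False)


def read_sensor_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "resected" in df.columns:
        df["resected"] = df["resected"].astype(bool)
    return validate_sensor_table(df)


def write_matrix_csv(values: np.ndarray, ids: list, path: PathLike) -> None:
    """Write a square matrix as CSV with contact ids as header row/column."""
    values = np.asarray(values)
    if values.shape != (len(ids), len(ids)):
        raise InvalidSpecError("matrix shape does not match id count")
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path)


def read_matrix_csv(path: PathLike):
    """Read a square id-labelled matrix CSV -> (values, ids)."""
    df = pd.read_csv(path, index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise InvalidSpecError(f"{path}: row and column ids disagree")
    return df.to_numpy(dtype=float), ids


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", "replace")[:width]
    return raw + b" " * (width - len(raw))


def write_edf(rec: Recording, path: PathLike) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    Sampling rate must be a whole number of Hz; a trailing partial second is
    dropped. Signal values are stored as microvolt physical units.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise InvalidSpecError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_records = rec.data.shape[1] // fs
    if n_records < 1:
        raise InvalidSpecError("recording shorter than one 1-second EDF record")
    n_ch = rec.n_channels
    data = rec.data[:, : n_records * fs]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    def num(v: float) -> str:
        s = f"{v:.6g}"
        return s[:8]

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X", 80),
        _pad("01.01.01", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (n_ch + 1)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    fields = [
        [_pad(str(cid), 16) for cid in rec.channel_ids],
        [_pad("synthetic iEEG", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(num(v), 8) for v in pmin],
        [_pad(num(v), 8) for v in pmax],
        [_pad(str(dmin), 8)] * n_ch,
        [_pad(str(dmax), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(fs), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for field in fields:
            fh.write(b"".join(field))
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_edf(path: PathLike) -> Recording:
    """Read an EDF recording (microvolt channels) into a :class:`Recording`."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads EEG channels in volts
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     channel_ids=list(raw.ch_names))


# ---------------------------------------------------------------------------
# Network directories and fits
# ---------------------------------------------------------------------------


def save_network(net: PatientNetwork, directory: PathLike) -> None:
    """Write a PatientNetwork as a directory of CSVs plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = net.node_ids
    write_matrix_csv(net.adjacency, ids, directory / "adjacency.csv")
    write_matrix_csv(net.distances, ids, directory / "distances.csv")
    net.nodes.to_csv(directory / "nodes.csv", index=False)
    manifest = {
        "modality": net.modality,
        "measure": net.measure,
        "condition": net.condition,
        "patient_id": net.patient_id,
        "n_nodes": net.n_nodes,
        "exclusions": list(net.exclusions),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_network(directory: PathLike) -> PatientNetwork:
    from .network import classify_edges

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    adjacency, ids = read_matrix_csv(directory / "adjacency.csv")
    distances, _ = read_matrix_csv(directory / "distances.csv")
    nodes = pd.read_csv(directory / "nodes.csv")
    nodes["resected"] = nodes["resected"].astype(bool)
    if [str(i) for i in nodes["contact_id"]] != ids:
        raise InvalidSpecError(f"{directory}: nodes.csv does not match adjacency ids")
    return PatientNetwork(
        adjacency=adjacency,
        nodes=nodes,
        distances=distances,
        edge_class=classify_edges(nodes["electrode_type"].to_numpy()),
        modality=manifest["modality"],
        measure=manifest["measure"],
        condition=manifest.get("condition", "GM"),
        patient_id=manifest.get("patient_id", ""),
        exclusions=list(manifest.get("exclusions", [])),
    )


def save_fits(fits: Dict, path: PathLike) -> None:
    """Serialize {(modality, class): Rat11Fit} (or {class: fit}) as JSON."""
    entries = []
    for key, fit in fits.items():
        entry = dataclasses.asdict(fit)
        if isinstance(key, tuple):
            entry["modality"], entry["edge_class"] = key
        else:
            entry["edge_class"] = key
        entries.append(entry)
    Path(path).write_text(json.dumps(entries, indent=2))


def load_fits(path: PathLike) -> Dict:
    entries = json.loads(Path(path).read_text())
    fits = {}
    for entry in entries:
        fit = Rat11Fit(**entry)
        fits[(fit.modality, fit.edge_class)] = fit
    return fits
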