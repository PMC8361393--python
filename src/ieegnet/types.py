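"""Shared domain containers for the iEEG network pipeline.

Sensor metadata travels as a plain :class:`pandas.DataFrame` with the column
set in :data:`SENSOR_COLUMNS`; everything else is a small dataclass. Arrays
are kept as plain numpy arrays so every stage can be inspected and serialized
as CSV/JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Required columns of a sensor (contact) metadata table, in canonical order.
SENSOR_COLUMNS = (
    "contact_id",
    "x",
    "y",
    "z",
    "electrode_type",
    "tissue",
    "roi_label",
    "hemisphere",
    "resected",
)

ELECTRODE_TYPES = ("surface", "depth")
TISSUE_TYPES = ("GM", "WM")
HEMISPHERES = ("left", "right")
EDGE_CLASSES = ("S-S", "S-D", "D-D")
MODALITIES = ("ECoG", "SEEG")
CONDITIONS = ("GM", "DC", "UL", "AR")
MEASURES = ("beta_coherence", "lowgamma_coherence", "broadband_xcorr")

#: Default analysis band edges in Hz per connectivity measure.
MEASURE_BANDS = {
    "beta_coherence": (15.0, 25.0),
    "lowgamma_coherence": (30.0, 40.0),
    "broadband_xcorr": (5.0, 115.0),
}


class InvalidSpecError(ValueError):
    """A layout / effect / run configuration violates its schema."""


def validate_sensor_table(sensors: pd.DataFrame) -> pd.DataFrame:
    """Validate a sensor table and return it with canonical column order.

    Raises
    ------
    InvalidSpecError
        If columns are missing, contact ids are not unique, or categorical
        fields contain unknown values.
    """
    missing = [c for c in SENSOR_COLUMNS if c not in sensors.columns]
    if missing:
        raise InvalidSpecError(f"sensor table missing columns: {missing}")
    if sensors["contact_id"].duplicated().any():
        dups = sensors.loc[sensors["contact_id"].duplicated(), "contact_id"].tolist()
        raise InvalidSpecError(f"duplicate contact ids: {dups}")
    for col, allowed in (
        ("electrode_type", ELECTRODE_TYPES),
        ("tissue", TISSUE_TYPES),
        ("hemisphere", HEMISPHERES),
    ):
        bad = set(sensors[col].unique()) - set(allowed)
        if bad:
            raise InvalidSpecError(f"unknown values in {col!r}: {sorted(bad)}")
    if not np.isfinite(sensors[["x", "y", "z"]].to_numpy(dtype=float)).all():
        raise InvalidSpecError("non-finite contact coordinates")
    return sensors.loc[:, list(SENSOR_COLUMNS)]


@dataclass
class Recording:
    """Multichannel iEEG signal aligned to a sensor table.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
    fs : float
        Sampling rate in Hz.
    channel_ids : list of str
        One id per row of ``data``, matching ``contact_id`` values.
    """

    data: np.ndarray
    fs: float
    channel_ids: list

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidSpecError("recording data must be 2-D (channels x samples)")
        if len(self.channel_ids) != self.data.shape[0]:
            raise InvalidSpecError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[0]} rows"
            )
        if self.fs <= 0:
            raise InvalidSpecError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs


@dataclass
class AdjacencySeries:
    """Per-window adjacency matrices for one connectivity measure.

    ``matrices`` has shape (n_windows, N, N); every slice is symmetric with a
    zero diagonal. ``band`` holds the analysis band edges in Hz.
    """

    matrices: np.ndarray
    measure: str
    band: tuple
    channel_ids: list

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]


@dataclass
class AdjacencyMatrix:
    """A single symmetric zero-diagonal adjacency matrix with node ids."""

    values: np.ndarray
    channel_ids: list
    measure: str
    band: Optional[tuple] = None

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class GroundTruthNetwork:
    """Planted true adjacency used to synthesize recordings.

    Weights are symmetric, zero-diagonal and lie in [0, 1).
    """

    weights: np.ndarray
    contact_ids: list
    config: "object"
    seed: int


@dataclass
class PatientNetwork:
    """Adjacency + node metadata + geometry for one patient.

    All matrices are N x N and index-aligned with ``nodes`` (grey-matter
    contacts only after :func:`ieegnet.network.filter_gray_matter`).
    ``edge_class`` entries are 'S-S', 'S-D' or 'D-D'.
    """

    adjacency: np.ndarray
    nodes: pd.DataFrame
    distances: np.ndarray
    edge_class: np.ndarray
    modality: str
    measure: str = "beta_coherence"
    condition: str = "GM"
    patient_id: str = ""
    exclusions: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def node_ids(self) -> list:
        return self.nodes["contact_id"].tolist()

    @property
    def resected_mask(self) -> np.ndarray:
        return self.nodes["resected"].to_numpy(dtype=bool)


@dataclass
class Rat11Fit:
    """Fitted rational-polynomial distance model w(d) = (p1*d + p2)/(d + q1)."""

    p1: float
    p2: float
    q1: float
    edge_class: str = ""
    modality: str = ""
    n_edges: int = 0
    rmse: float = float("nan")
    sse: float = float("nan")
    constant: bool = False

    def predict(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return (self.p1 * d + self.p2) / (d + self.q1)


@dataclass
class ResidualNetwork:
    """Distance-corrected network: residuals r_ij = A_ij - w_class(d_ij).

    ``network`` is a :class:`PatientNetwork` whose adjacency holds the signed
    residuals (condition tag 'DC'); ``parent`` and ``fits`` record provenance.
    """

    network: PatientNetwork
    parent: PatientNetwork
    fits: dict


@dataclass
class Partition:
    """Community partition from modularity maximization."""

    labels: np.ndarray
    q: float
    gamma: float
    n_communities: int
    seed: Optional[int] = None


@dataclass
class DrsResult:
    """Resection-zone distinguishability (normalized U statistic, in [0, 1])."""

    value: float
    n_resected: int
    n_spared: int
    condition: str = "GM"
    measure: str = ""


@dataclass
class GroupComparison:
    """Result of a two-group or paired statistical test."""

    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    median_a: float = float("nan")
    median_b: float = float("nan")
    method: str = ""


@dataclass
class ConditionSet:
    """Per-patient D_rs values under the GM / DC / UL / AR conditions."""

    patient_id: str
    modality: str
    measure: str
    drs: dict = field(default_factory=dict)
    node_counts: dict = field(default_factory=dict)
    skip_reasons: dict = field(default_factory=dict)
    n_resected_rois: int = 0
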