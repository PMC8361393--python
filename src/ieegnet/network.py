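"""Assemble patient networks: grey-matter filtering, distances, edge classes.

Networks only ever contain grey-matter contacts; contacts localized to white
matter (or otherwise excluded) are removed once, before any analysis, and
recorded in an exclusion log.
"""

from __future__ import annotations

from typing import List, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .types import (
    AdjacencyMatrix,
    InvalidSpecError,
    PatientNetwork,
    validate_sensor_table,
)


def filter_gray_matter(
    sensors: pd.DataFrame, adjacency: np.ndarray
) -> Tuple[pd.DataFrame, np.ndarray, List[str]]:
    """Drop non-grey-matter contacts from a sensor table and its adjacency.

    Returns the filtered table (original order preserved), the reduced
    adjacency, and an exclusion log with one entry per dropped contact.
    Raises if no grey-matter contact remains.
    """
    sensors = validate_sensor_table(sensors)
    adjacency = np.asarray(adjacency, dtype=float)
    if adjacency.shape != (len(sensors), len(sensors)):
        raise InvalidSpecError(
            f"adjacency shape {adjacency.shape} does not match {len(sensors)} contacts"
        )
    keep = (sensors["tissue"] == "GM").to_numpy()
    if not keep.any():
        raise InvalidSpecError("no grey-matter contacts remain after filtering")
    log = [
        f"excluded {row.contact_id}: tissue={row.tissue}"
        + (" (was flagged resected)" if row.resected else "")
        for row in sensors.loc[~keep].itertuples()
    ]
    filtered = sensors.loc[keep].reset_index(drop=True)
    return filtered, adjacency[np.ix_(keep, keep)], log


def compute_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances (mm) between contact coordinates."""
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise InvalidSpecError("non-finite coordinates")
    return cdist(coords, coords)


def classify_edges(types: np.ndarray) -> np.ndarray:
    """Unordered-pair edge classes from contact types.

    'S-S' surface-surface, 'S-D' surface-depth, 'D-D' depth-depth; an
    all-depth (SEEG) table yields only 'D-D'.
    """
    types = np.asarray(types)
    unknown = set(types) - {"surface", "depth"}
    if unknown:
        raise InvalidSpecError(f"unknown electrode types: {sorted(unknown)}")
    is_depth = types == "depth"
    n_deep = is_depth[:, None].astype(int) + is_depth[None, :].astype(int)
    classes = np.empty((len(types), len(types)), dtype="<U3")
    classes[n_deep == 0] = "S-S"
    classes[n_deep == 1] = "S-D"
    classes[n_deep == 2] = "D-D"
    return classes


def median_internodal_distance(net: PatientNetwork) -> float:
    """Median pairwise distance between a patient's GM nodes (mm)."""
    iu = np.triu_indices(net.n_nodes, k=1)
    return float(np.median(net.distances[iu]))


def build_patient_network(
    sensors: pd.DataFrame,
    adjacency: Union[AdjacencyMatrix, np.ndarray],
    modality: str,
    measure: str = "beta_coherence",
    patient_id: str = "",
) -> PatientNetwork:
    """Build a grey-matter PatientNetwork from contact metadata and adjacency.

    If ``adjacency`` is an :class:`AdjacencyMatrix`, its channel ids are
    aligned to the sensor table first (an error if they disagree).
    """
    sensors = validate_sensor_table(sensors)
    if isinstance(adjacency, AdjacencyMatrix):
        ids = sensors["contact_id"].tolist()
        if adjacency.channel_ids != ids:
            if set(adjacency.channel_ids) != set(ids):
                raise InvalidSpecError("adjacency channels do not match sensor table")
            order = [adjacency.channel_ids.index(i) for i in ids]
            a = adjacency.values[np.ix_(order, order)]
        else:
            a = adjacency.values
        measure = adjacency.measure
    else:
        a = np.asarray(adjacency, dtype=float)
    nodes, a_gm, log = filter_gray_matter(sensors, a)
    coords = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    return PatientNetwork(
        adjacency=a_gm,
        nodes=nodes,
        distances=compute_distances(coords),
        edge_class=classify_edges(nodes["electrode_type"].to_numpy()),
        modality=modality,
        measure=measure,
        condition="GM",
        patient_id=patient_id,
        exclusions=log,
    )


def subset_network(net: PatientNetwork, keep: np.ndarray, condition: str = None) -> PatientNetwork:
    """Index-aligned subnetwork over a boolean node mask."""
    keep = np.asarray(keep, dtype=bool)
    if keep.sum() == 0:
        raise InvalidSpecError("subset would remove every node")
    ix = np.ix_(keep, keep)
    return PatientNetwork(
        adjacency=net.adjacency[ix],
        nodes=net.nodes.loc[keep].reset_index(drop=True),
        distances=net.distances[ix],
        edge_class=net.edge_class[ix],
        modality=net.modality,
        measure=net.measure,
        condition=condition if condition is not None else net.condition,
        patient_id=net.patient_id,
        exclusions=list(net.exclusions),
    )
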