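"""Sampling-bias corrections (DC / UL / AR) and the cohort-level report.

Three network modifications probe how spatial sampling shapes the resected
vs spared strength relationship:

* DC - distance correction: residualize edges on the per-modality,
  per-edge-class rational distance model;
* UL - unilateral restriction: keep only nodes ipsilateral to the resection
  (the hemisphere holding the majority of resected nodes);
* AR - atlas reduction: one node per atlas ROI, inter-ROI edges averaged.

Conditions compose in the order DC -> UL -> AR; D_rs is reported at every
stage, alongside the uncorrected grey-matter (GM) network. The cohort report
compares modalities per condition (rank-sum), each condition against GM
within modality (sign-rank), and correlates AR-condition D_rs with surgical
focality (the number of resected atlas ROIs, Pearson).
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import stats as istats
from .distance import residualize
from .metrics import node_strength
from .network import compute_distances, subset_network
from .types import (
    ConditionSet,
    GroupComparison,
    InvalidSpecError,
    PatientNetwork,
)

logger = logging.getLogger(__name__)


class AmbiguousHemisphereError(InvalidSpecError):
    """Resected nodes split evenly across hemispheres: no resection side."""


def resection_hemisphere(net: PatientNetwork) -> str:
    """Hemisphere containing the majority of resected nodes (tie -> error)."""
    res = net.nodes.loc[net.resected_mask, "hemisphere"]
    if res.empty:
        raise InvalidSpecError("network has no resected nodes")
    n_left = int((res == "left").sum())
    n_right = int((res == "right").sum())
    if n_left == n_right:
        raise AmbiguousHemisphereError(
            f"resected nodes split {n_left}/{n_right} across hemispheres"
        )
    return "left" if n_left > n_right else "right"


def unilateral_filter(net: PatientNetwork) -> PatientNetwork:
    """Keep only nodes ipsilateral to the resection zone (condition 'UL').

    Resected nodes in the minority hemisphere (rare) are dropped with the
    rest of that hemisphere; the count is logged, never silently discarded.
    """
    side = resection_hemisphere(net)
    keep = (net.nodes["hemisphere"] == side).to_numpy()
    dropped_resected = int((net.resected_mask & ~keep).sum())
    if dropped_resected:
        logger.warning(
            "%s: unilateral filter drops %d resected contralateral node(s)",
            net.patient_id, dropped_resected,
        )
    out = subset_network(net, keep, condition="UL")
    out.exclusions = out.exclusions + [
        f"UL: dropped {int((~keep).sum())} contralateral node(s), "
        f"{dropped_resected} of them resected"
    ]
    return out


def atlas_reduce(net: PatientNetwork) -> PatientNetwork:
    """Reduce a contact-level network to one node per atlas ROI ('AR').

    The ROI-ROI edge is the arithmetic mean of all contact-level edges
    between the two ROIs; within-ROI edges are discarded. A ROI is resected
    iff it contains at least one resected contact. Idempotent: reducing an
    already ROI-level network returns it unchanged.
    """
    rois = net.nodes["roi_label"].to_numpy()
    unique_rois = list(dict.fromkeys(rois))  # first-appearance order
    if len(unique_rois) < 2:
        raise InvalidSpecError("atlas reduction needs at least 2 sampled ROIs")
    k = len(unique_rois)
    index = {r: i for i, r in enumerate(unique_rois)}
    member = np.zeros((net.n_nodes, k))
    member[np.arange(net.n_nodes), [index[r] for r in rois]] = 1.0
    sizes = member.sum(axis=0)
    counts = np.outer(sizes, sizes)  # contact pairs between each ROI pair
    sums = member.T @ net.adjacency @ member
    adj = sums / counts
    np.fill_diagonal(adj, 0.0)

    rows = []
    for r in unique_rois:
        m = rois == r
        sub = net.nodes.loc[m]
        rows.append({
            "contact_id": r,
            "x": float(sub["x"].mean()),
            "y": float(sub["y"].mean()),
            "z": float(sub["z"].mean()),
            "electrode_type": sub["electrode_type"].mode().iloc[0],
            "tissue": "GM",
            "roi_label": r,
            "hemisphere": sub["hemisphere"].mode().iloc[0],
            "resected": bool(sub["resected"].any()),
        })
    nodes = pd.DataFrame(rows)
    coords = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    is_depth = (nodes["electrode_type"] == "depth").to_numpy()
    n_deep = is_depth[:, None].astype(int) + is_depth[None, :].astype(int)
    classes = np.empty((k, k), dtype="<U3")
    classes[n_deep == 0] = "S-S"
    classes[n_deep == 1] = "S-D"
    classes[n_deep == 2] = "D-D"
    return PatientNetwork(
        adjacency=(adj + adj.T) / 2.0,
        nodes=nodes,
        distances=compute_distances(coords),
        edge_class=classes,
        modality=net.modality,
        measure=net.measure,
        condition="AR",
        patient_id=net.patient_id,
        exclusions=list(net.exclusions) + [f"AR: {net.n_nodes} contacts -> {k} ROIs"],
    )


def n_resected_rois(net: PatientNetwork) -> int:
    """Number of atlas ROIs containing at least one resected contact."""
    return int(net.nodes.loc[net.resected_mask, "roi_label"].nunique())


def _drs_of(net: PatientNetwork, condition: str) -> "object":
    return istats.distinguishability(
        node_strength(net.adjacency), net.resected_mask,
        condition=condition, measure=net.measure,
    )


def run_conditions(net: PatientNetwork, fits: Dict) -> ConditionSet:
    """Compute D_rs under GM, DC, UL and AR for one patient.

    Conditions compose DC -> UL -> AR. A stage error is recorded as a skip
    reason; later conditions fall back to the last successful stage (e.g. AR
    is computed from DC when the unilateral filter is ambiguous).
    """
    result = ConditionSet(
        patient_id=net.patient_id,
        modality=net.modality,
        measure=net.measure,
        n_resected_rois=n_resected_rois(net),
    )

    def record(condition, network):
        result.drs[condition] = _drs_of(network, condition)
        result.node_counts[condition] = network.n_nodes

    record("GM", net)
    stage = net
    try:
        stage = residualize(net, fits).network
        record("DC", stage)
    except Exception as exc:  # noqa: BLE001 - skip reason, pipeline continues
        result.skip_reasons["DC"] = str(exc)
        logger.warning("%s: DC skipped (%s)", net.patient_id, exc)
    try:
        stage = unilateral_filter(stage)
        record("UL", stage)
    except Exception as exc:  # noqa: BLE001
        result.skip_reasons["UL"] = str(exc)
        logger.warning("%s: UL skipped (%s)", net.patient_id, exc)
    try:
        ar = atlas_reduce(stage)
        record("AR", ar)
    except Exception as exc:  # noqa: BLE001
        result.skip_reasons["AR"] = str(exc)
        logger.warning("%s: AR skipped (%s)", net.patient_id, exc)
    return result


def conditions_frame(condition_sets: Iterable[ConditionSet]) -> pd.DataFrame:
    """Tidy per-patient table: patient, modality, measure, condition, D_rs."""
    rows = []
    for cs in condition_sets:
        for condition, drs in cs.drs.items():
            rows.append({
                "patient_id": cs.patient_id,
                "modality": cs.modality,
                "measure": cs.measure,
                "condition": condition,
                "drs": drs.value,
                "n_nodes": cs.node_counts.get(condition),
                "n_resected": drs.n_resected,
                "n_resected_rois": cs.n_resected_rois,
            })
    return pd.DataFrame(rows)


def cohort_report(
    condition_sets: Sequence[ConditionSet],
    patient_tables: Optional[Dict[str, pd.DataFrame]] = None,
) -> dict:
    """Cohort-level statistics over a set of per-patient condition results.

    Returns a dict with:

    * ``modality_comparisons``: rank-sum ECoG vs SEEG D_rs per condition;
    * ``condition_vs_gm``: sign-rank of each corrected condition against GM
      within each modality;
    * ``focality``: Pearson correlation of AR-condition D_rs with the number
      of resected atlas ROIs, across all patients;
    * ``table1``: cohort summary (group sizes, GM / depth-GM / resected node
      counts with rank-sum p, surgery-type Fisher test when >= 2 ROI classes
      are distinguishable) built from ``patient_tables`` (patient_id ->
      sensor table) when provided;
    * ``incomplete``: conditions missing in more than half the patients.
    """
    frame = conditions_frame(condition_sets)
    if frame.empty:
        raise InvalidSpecError("no condition results")
    report: dict = {
        "modality_comparisons": {},
        "condition_vs_gm": {},
        "focality": None,
        "incomplete": [],
    }
    n_patients = len(condition_sets)
    for condition in ("GM", "DC", "UL", "AR"):
        sub = frame[frame["condition"] == condition]
        if len(sub) < n_patients / 2:
            report["incomplete"].append(condition)
        a = sub.loc[sub["modality"] == "ECoG", "drs"].to_numpy()
        b = sub.loc[sub["modality"] == "SEEG", "drs"].to_numpy()
        if a.size >= 2 and b.size >= 2:
            report["modality_comparisons"][condition] = istats.rank_sum(a, b)

    wide = frame.pivot_table(index=["patient_id", "modality"], columns="condition",
                             values="drs")
    for modality in ("ECoG", "SEEG"):
        try:
            grp = wide.xs(modality, level="modality")
        except KeyError:
            continue
        for condition in ("DC", "UL", "AR"):
            if "GM" not in grp or condition not in grp:
                continue
            diffs = (grp[condition] - grp["GM"]).dropna().to_numpy()
            if diffs.size and (diffs != 0).any():
                report["condition_vs_gm"][(modality, condition)] = istats.sign_rank(diffs)

    ar = frame[frame["condition"] == "AR"].dropna(subset=["drs"])
    if len(ar) >= 3 and ar["n_resected_rois"].nunique() > 1:
        rho, p = istats.pearson_correlation(
            ar["n_resected_rois"].to_numpy(dtype=float), ar["drs"].to_numpy()
        )
        report["focality"] = {"rho": rho, "p_value": p, "n": len(ar)}

    if patient_tables is not None:
        report["table1"] = _table1_summary(condition_sets, patient_tables)
    return report


def _table1_summary(
    condition_sets: Sequence[ConditionSet],
    patient_tables: Dict[str, pd.DataFrame],
) -> dict:
    """Cohort characteristics per modality with group-comparison statistics."""
    per_group: Dict[str, dict] = {"ECoG": [], "SEEG": []}
    focal = {"ECoG": [], "SEEG": []}
    for cs in condition_sets:
        sensors = patient_tables.get(cs.patient_id)
        if sensors is None:
            continue
        gm = sensors[sensors["tissue"] == "GM"]
        per_group[cs.modality].append({
            "gm": len(gm),
            "depth_gm": int((gm["electrode_type"] == "depth").sum()),
            "resected_gm": int(gm["resected"].sum()),
            "depth_resected_gm": int(
                (gm["resected"] & (gm["electrode_type"] == "depth")).sum()
            ),
        })
        focal[cs.modality].append(cs.n_resected_rois)

    out: dict = {"n_subjects": {m: len(v) for m, v in per_group.items()}}
    for key in ("gm", "depth_gm", "resected_gm", "depth_resected_gm"):
        vals = {m: np.array([p[key] for p in per_group[m]], dtype=float)
                for m in per_group}
        entry = {
            m: {"mean": float(v.mean()) if v.size else float("nan"),
                "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan")}
            for m, v in vals.items()
        }
        if all(v.size >= 2 for v in vals.values()):
            entry["rank_sum"] = istats.rank_sum(vals["ECoG"], vals["SEEG"])
        out[key] = entry
    # surgery-type analogue: focal targets (<= 2 ROIs) behave like ablations,
    # broader ones like resections
    if all(len(v) for v in focal.values()):
        table = [
            [int(sum(np.array(focal["ECoG"]) > 2)), int(sum(np.array(focal["SEEG"]) > 2))],
            [int(sum(np.array(focal["ECoG"]) <= 2)), int(sum(np.array(focal["SEEG"]) <= 2))],
        ]
        if all(sum(row) for row in table):
            out["surgery_type"] = {
                "table": table,
                "fisher": istats.fisher_exact(table),
            }
    return out
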