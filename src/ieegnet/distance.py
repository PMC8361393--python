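"""Electrode-class-specific distance correction of edge weights.

Functional connectivity decays with internodal distance, and the decay
profile differs between surface and depth contacts. Following the pipeline's
correction strategy, a rational polynomial

    w(d) = (p1 * d + p2) / (d + q1)

is fit per modality and edge class (ECoG S-S / S-D / D-D curves and a SEEG
D-D curve), pooling edges across patients, and networks are residualized
edgewise (the "DC" condition): r_ij = A_ij - w_class(d_ij). Residuals may be
negative and are deliberately not re-clipped; downstream modularity uses a
signed extension.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .types import (
    InvalidSpecError,
    PatientNetwork,
    Rat11Fit,
    ResidualNetwork,
)

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Optimization failed on every start; carries the best attempt."""

    def __init__(self, message: str, best: Optional[Rat11Fit] = None):
        super().__init__(message)
        self.best = best


def rat11(d: np.ndarray, p1: float, p2: float, q1: float) -> np.ndarray:
    """Evaluate the rational-polynomial distance profile."""
    d = np.asarray(d, dtype=float)
    return (p1 * d + p2) / (d + q1)


def _linear_given_q1(d: np.ndarray, w: np.ndarray, q1: float) -> Tuple[float, float]:
    """Least-squares (p1, p2) given q1 — the model is linear in them."""
    denom = d + q1
    design = np.column_stack([d / denom, 1.0 / denom])
    coef, *_ = np.linalg.lstsq(design, w, rcond=None)
    return float(coef[0]), float(coef[1])


class Rat11Model:
    """Multi-start least-squares fitter for the rat11 distance profile.

    Twenty starts by default: q1 initialized log-uniformly on [1, 200] mm,
    (p1, p2) by linear least squares given q1, then joint refinement with
    q1 constrained to keep the pole outside the observed distance range.
    Best SSE wins; ties break toward the smallest |q1|.
    """

    def __init__(self, n_starts: int = 20, q1_range: Tuple[float, float] = (1.0, 200.0),
                 seed: Optional[int] = 0):
        self.n_starts = n_starts
        self.q1_range = q1_range
        self.seed = seed
        self.fit_: Optional[Rat11Fit] = None

    def fit(self, distances: np.ndarray, weights: np.ndarray) -> "Rat11Model":
        d = np.asarray(distances, dtype=float).ravel()
        w = np.asarray(weights, dtype=float).ravel()
        if d.shape != w.shape:
            raise InvalidSpecError("distances and weights differ in length")
        if d.size < 4:
            raise InvalidSpecError(f"need >= 4 (distance, weight) pairs, got {d.size}")
        if (d <= 0).any():
            raise InvalidSpecError("distances must be positive")

        if np.ptp(w) < 1e-12:
            # degenerate constant-weight input: exact constant-function fit
            c = float(w.mean())
            q1 = float(np.median(d))
            fit = Rat11Fit(p1=c, p2=c * q1, q1=q1, n_edges=d.size, rmse=0.0,
                           sse=0.0, constant=True)
            logger.info("constant-weight input: returning constant fit w(d)=%g", c)
            self.fit_ = fit
            return self

        rng = np.random.default_rng(self.seed)
        eps = 1e-3
        q1_lo = -d.min() + eps
        lo, hi = self.q1_range
        q1_starts = np.exp(rng.uniform(np.log(lo), np.log(hi), size=self.n_starts))

        def resid(theta):
            return rat11(d, *theta) - w

        best = None
        for q1_0 in q1_starts:
            p1_0, p2_0 = _linear_given_q1(d, w, q1_0)
            try:
                sol = least_squares(
                    resid,
                    x0=np.array([p1_0, p2_0, q1_0]),
                    bounds=([-np.inf, -np.inf, q1_lo], [np.inf, np.inf, np.inf]),
                    method="trf",
                )
            except Exception:  # pragma: no cover - pathological start
                continue
            if not np.isfinite(sol.cost):
                continue
            sse = 2.0 * sol.cost
            cand = (sse, abs(sol.x[2]), sol.x)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is None:
            raise FitError("rat11 fit failed to converge from any start")
        sse, _, x = best
        fit = Rat11Fit(
            p1=float(x[0]), p2=float(x[1]), q1=float(x[2]),
            n_edges=d.size, rmse=float(np.sqrt(sse / d.size)), sse=float(sse),
        )
        self.fit_ = fit
        return self

    def predict(self, distances: np.ndarray) -> np.ndarray:
        if self.fit_ is None:
            raise RuntimeError("model is not fitted")
        return self.fit_.predict(distances)


def fit_rat11(distances: np.ndarray, weights: np.ndarray, n_starts: int = 20,
              seed: Optional[int] = 0) -> Rat11Fit:
    """Fit the rat11 model to (distance, weight) pairs; see :class:`Rat11Model`."""
    model = Rat11Model(n_starts=n_starts, seed=seed)
    return model.fit(distances, weights).fit_


def pooled_class_edges(
    networks: Iterable[PatientNetwork],
) -> Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]]:
    """Pool upper-triangle (distance, weight) pairs per (modality, edge class)."""
    pools: Dict[Tuple[str, str], list] = {}
    for net in networks:
        iu = np.triu_indices(net.n_nodes, k=1)
        classes = net.edge_class[iu]
        d = net.distances[iu]
        w = net.adjacency[iu]
        for cls_name in np.unique(classes):
            m = classes == cls_name
            pools.setdefault((net.modality, str(cls_name)), []).append(
                (d[m], w[m])
            )
    return {
        key: (np.concatenate([p[0] for p in parts]),
              np.concatenate([p[1] for p in parts]))
        for key, parts in pools.items()
    }


def fit_class_models(
    networks: Iterable[PatientNetwork], n_starts: int = 20, seed: Optional[int] = 0
) -> Dict[Tuple[str, str], Rat11Fit]:
    """Fit one rat11 model per (modality, edge class), pooling across patients.

    Mirrors the four-curve correction (ECoG S-S, S-D, D-D and SEEG D-D when
    both modalities are present).
    """
    fits = {}
    for (modality, cls_name), (d, w) in sorted(pooled_class_edges(networks).items()):
        fit = fit_rat11(d, w, n_starts=n_starts, seed=seed)
        fits[(modality, cls_name)] = replace(fit, edge_class=cls_name, modality=modality)
    return fits


def fits_for_network(
    net: PatientNetwork, fits: Dict
) -> Dict[str, Rat11Fit]:
    """Select the per-class fits relevant to one network.

    Accepts either {(modality, class): fit} or {class: fit} keyed dicts.
    Raises if any edge class present in the network lacks a fit.
    """
    iu = np.triu_indices(net.n_nodes, k=1)
    present = {str(c) for c in np.unique(net.edge_class[iu])}
    out = {}
    for cls_name in sorted(present):
        if (net.modality, cls_name) in fits:
            out[cls_name] = fits[(net.modality, cls_name)]
        elif cls_name in fits:
            out[cls_name] = fits[cls_name]
        else:
            raise InvalidSpecError(
                f"no distance fit for edge class {cls_name} ({net.modality})"
            )
    return out


def residualize(net: PatientNetwork, fits: Dict) -> ResidualNetwork:
    """Distance-correct a network: r_ij = A_ij - w_class(i,j)(d_ij).

    ``fits`` maps edge class (or (modality, class)) to :class:`Rat11Fit`.
    The result's adjacency holds signed residuals with a zero diagonal and
    carries the 'DC' condition tag.
    """
    class_fits = fits_for_network(net, fits)
    pred = np.zeros_like(net.adjacency)
    off = ~np.eye(net.n_nodes, dtype=bool)
    for cls_name, fit in class_fits.items():
        mask = (net.edge_class == cls_name) & off
        pred[mask] = fit.predict(net.distances[mask])
    resid = net.adjacency - pred
    np.fill_diagonal(resid, 0.0)
    resid = (resid + resid.T) / 2.0
    corrected = PatientNetwork(
        adjacency=resid,
        nodes=net.nodes.copy(),
        distances=net.distances,
        edge_class=net.edge_class,
        modality=net.modality,
        measure=net.measure,
        condition="DC",
        patient_id=net.patient_id,
        exclusions=list(net.exclusions),
    )
    return ResidualNetwork(network=corrected, parent=net, fits=class_fits)


def residual_sd(rnet: ResidualNetwork) -> float:
    """Sample standard deviation (ddof=1) of the upper-triangle residuals."""
    net = rnet.network if isinstance(rnet, ResidualNetwork) else rnet
    iu = np.triu_indices(net.n_nodes, k=1)
    r = net.adjacency[iu]
    if r.size < 2:
        raise InvalidSpecError("need at least 2 edges for a residual SD")
    return float(np.std(r, ddof=1))
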