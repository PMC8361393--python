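"""Synthetic ECoG/SEEG cohorts with plantable network effects.

This module emulates the two implant strategies compared throughout the
package — cortical-predominant ECoG (grid + strips + a small number of depth
electrodes) and depth-only SEEG — in a toy head coordinate space, together
with a ground-truth connectivity model and multichannel recordings whose band
coherence realizes that ground truth. Every downstream stage (connectivity
estimation, grey-matter filtering, distance correction, graph metrics, the
D_rs statistic and the DC/UL/AR conditions) can therefore be tested against
known truth without patient data.

Toy head space: right-handed coordinates in mm, origin mid-head; the
hemisphere of a contact is the sign of x (x < 0 left, x >= 0 right).
Contacts with |x| >= MESIAL_X are "cortical", the rest "mesial", and a fixed
16-region synthetic atlas is assigned from the spatial octant plus depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .types import (
    EDGE_CLASSES,
    GroundTruthNetwork,
    InvalidSpecError,
    Recording,
    validate_sensor_table,
)

logger = logging.getLogger(__name__)

#: |x| below this (mm) counts as mesial ("deep") for atlas assignment.
MESIAL_X = 35.0

#: y (mm) boundaries between anterior / mid / posterior atlas thirds.
AP_BOUNDS = (15.0, -15.0)

#: The fixed synthetic atlas: 2 hemispheres x ant/mid/post x sup/inf x
#: cortical/mesial = 24 named regions.
ATLAS_ROIS = tuple(
    f"{hemi}_{ap}_{si}_{depth}"
    for hemi in ("left", "right")
    for ap in ("ant", "mid", "post")
    for si in ("sup", "inf")
    for depth in ("cortical", "mesial")
)

#: Order in which a growing surgical target spreads over ipsilateral ROIs,
#: starting at the mesial anterior-inferior region (the toy analogue of the
#: mesial temporal structures targeted in temporal lobe epilepsy).
RESECTION_SPREAD = (
    "{h}_ant_inf_mesial",
    "{h}_mid_inf_mesial",
    "{h}_ant_inf_cortical",
    "{h}_mid_inf_cortical",
    "{h}_ant_sup_mesial",
    "{h}_post_inf_mesial",
    "{h}_ant_sup_cortical",
    "{h}_post_inf_cortical",
)


def assign_roi(x: float, y: float, z: float) -> str:
    """Atlas ROI of a point: spatial octant (ant/mid/post thirds) plus depth."""
    hemi = "left" if x < 0 else "right"
    ap = "ant" if y >= AP_BOUNDS[0] else ("mid" if y >= AP_BOUNDS[1] else "post")
    si = "sup" if z >= 0 else "inf"
    depth = "cortical" if abs(x) >= MESIAL_X else "mesial"
    return f"{hemi}_{ap}_{si}_{depth}"


def resection_rois(hemisphere: str, n_rois: int) -> List[str]:
    """First ``n_rois`` regions of the surgical spread order in a hemisphere."""
    if not 1 <= n_rois <= len(RESECTION_SPREAD):
        raise InvalidSpecError(f"n_rois must be in 1..{len(RESECTION_SPREAD)}")
    return [r.format(h=hemisphere) for r in RESECTION_SPREAD[:n_rois]]


# ---------------------------------------------------------------------------
# Layout specifications
# ---------------------------------------------------------------------------


@dataclass
class ECoGLayout:
    """Grid + strips + a small number of depth electrodes.

    Defaults give 8x8 grid (10 mm pitch) + 2 six-contact strips (one
    contralateral) + 2 eight-contact depth shafts targeting the mesial
    anterior-inferior region: 92 implanted contacts, ~88 grey matter.
    """

    grid_shape: Tuple[int, int] = (8, 8)
    grid_pitch: float = 10.0
    n_strips: int = 2
    strip_contacts: int = 6
    strip_pitch: float = 10.0
    n_contralateral_strips: int = 1
    n_depth: int = 2
    depth_contacts: int = 8
    depth_pitch: float = 6.0
    wm_fraction: float = 0.25
    hemisphere: str = "right"
    n_resection_rois: int = 3
    jitter_mm: float = 0.5

    def validate(self) -> None:
        if min(self.grid_shape) <= 0 or self.grid_pitch <= 0:
            raise InvalidSpecError("grid dimensions and pitch must be positive")
        if self.n_strips < 0 or self.strip_contacts <= 0 or self.strip_pitch <= 0:
            raise InvalidSpecError("strip counts and pitch must be positive")
        if self.n_depth < 0 or self.depth_contacts <= 0 or self.depth_pitch <= 0:
            raise InvalidSpecError("depth shaft counts and pitch must be positive")
        if not 0.0 <= self.wm_fraction < 1.0:
            raise InvalidSpecError("wm_fraction must be in [0, 1)")
        if self.n_contralateral_strips > self.n_strips:
            raise InvalidSpecError("more contralateral strips than strips")
        if self.hemisphere not in ("left", "right"):
            raise InvalidSpecError("hemisphere must be 'left' or 'right'")


@dataclass
class SEEGLayout:
    """Depth-only stereotactic implant.

    Defaults give 10 twelve-contact shafts (3 contralateral), 4 mm contact
    pitch: 120 implanted contacts, ~90 grey matter.
    """

    n_shafts: int = 10
    contacts_per_shaft: int = 12
    contact_pitch: float = 4.0
    n_contralateral: int = 3
    wm_fraction: float = 0.25
    hemisphere: str = "right"
    n_resection_rois: int = 2
    jitter_mm: float = 1.0

    def validate(self) -> None:
        if self.n_shafts <= 0 or self.contacts_per_shaft <= 0:
            raise InvalidSpecError("shaft counts must be positive")
        if self.contact_pitch <= 0:
            raise InvalidSpecError("contact pitch must be positive")
        if not 0.0 <= self.wm_fraction < 1.0:
            raise InvalidSpecError("wm_fraction must be in [0, 1)")
        if self.n_contralateral > self.n_shafts:
            raise InvalidSpecError("more contralateral shafts than shafts")
        if self.hemisphere not in ("left", "right"):
            raise InvalidSpecError("hemisphere must be 'left' or 'right'")


# (y, z) targets of ipsilateral SEEG shaft tips, biased toward the
# anterior-inferior (temporal) region; cycled if more shafts are requested.
_SEEG_TARGETS = (
    (22.0, -20.0),
    (10.0, -26.0),
    (-16.0, -20.0),
    (26.0, 4.0),
    (-26.0, 10.0),
    (8.0, 24.0),
    (-8.0, -4.0),
    (18.0, 12.0),
    (-20.0, -12.0),
    (2.0, -14.0),
)


def _finish_table(rows: list, rng: np.random.Generator, jitter: float,
                  hemisphere: str, n_resection_rois: int) -> pd.DataFrame:
    df = pd.DataFrame(
        rows,
        columns=["contact_id", "x", "y", "z", "electrode_type", "tissue"],
    )
    # contacts sit well off the midline (|x| >= 18), so jitter cannot flip
    # a contact's hemisphere
    df[["x", "y", "z"]] += rng.normal(0.0, jitter, size=(len(df), 3))
    df["roi_label"] = [assign_roi(x, y, z) for x, y, z in df[["x", "y", "z"]].to_numpy()]
    df["hemisphere"] = np.where(df["x"] < 0, "left", "right")
    targets = set(resection_rois(hemisphere, n_resection_rois))
    df["resected"] = df["roi_label"].isin(targets)
    return validate_sensor_table(df)


def generate_layout(modality: str, layout_spec=None, seed: int = 0) -> pd.DataFrame:
    """Generate a synthetic electrode layout as a sensor table.

    Parameters
    ----------
    modality : {'ECoG', 'SEEG'}
    layout_spec : ECoGLayout or SEEGLayout, optional
        Defaults to the modality's default layout.
    seed : int
        Controls coordinate jitter and white-matter assignment; the same
        spec + seed always yields an identical table.

    Returns
    -------
    pandas.DataFrame
        A validated sensor table. Resected flags cover all contacts (GM and
        WM) inside the target ROIs; WM contacts are dropped later by
        grey-matter filtering.
    """
    rng = np.random.default_rng(seed)
    if modality == "ECoG":
        spec = layout_spec if layout_spec is not None else ECoGLayout()
        if not isinstance(spec, ECoGLayout):
            raise InvalidSpecError("ECoG modality requires an ECoGLayout spec")
        spec.validate()
        return _generate_ecog(spec, rng)
    if modality == "SEEG":
        spec = layout_spec if layout_spec is not None else SEEGLayout()
        if not isinstance(spec, SEEGLayout):
            raise InvalidSpecError("SEEG modality requires an SEEGLayout spec")
        spec.validate()
        return _generate_seeg(spec, rng)
    raise InvalidSpecError(f"unknown modality {modality!r}")


def _generate_ecog(spec: ECoGLayout, rng: np.random.Generator) -> pd.DataFrame:
    s = 1.0 if spec.hemisphere == "right" else -1.0
    rows = []
    ny, nz = spec.grid_shape
    ys = (np.arange(ny) - (ny - 1) / 2) * spec.grid_pitch
    zs = (np.arange(nz) - (nz - 1) / 2) * spec.grid_pitch
    k = 1
    for zi in zs:
        for yi in ys:
            rows.append((f"G{k:02d}", s * 60.0, yi, zi, "surface", "GM"))
            k += 1
    for j in range(spec.n_strips):
        contralateral = j < spec.n_contralateral_strips
        sx = -s if contralateral else s
        z0 = 0.0 if contralateral else -48.0
        for c in range(spec.strip_contacts):
            y = (c - (spec.strip_contacts - 1) / 2) * spec.strip_pitch
            rows.append((f"S{j + 1}_{c + 1:02d}", sx * 58.0, y, z0, "surface", "GM"))
    # depth shafts enter laterally and run medially toward the mesial
    # anterior-inferior target (hippocampal analogue)
    depth_targets = [(20.0, -18.0), (10.0, -24.0), (24.0, 6.0), (-14.0, -20.0)]
    for j in range(spec.n_depth):
        ty, tz = depth_targets[j % len(depth_targets)]
        for c in range(spec.depth_contacts):
            # contact 1 is the tip (most mesial)
            x = s * (18.0 + c * spec.depth_pitch)
            tissue = "WM" if rng.random() < spec.wm_fraction else "GM"
            rows.append((f"D{j + 1}_{c + 1:02d}", x, ty, tz, "depth", tissue))
    return _finish_table(rows, rng, spec.jitter_mm, spec.hemisphere,
                         spec.n_resection_rois)


def _generate_seeg(spec: SEEGLayout, rng: np.random.Generator) -> pd.DataFrame:
    s = 1.0 if spec.hemisphere == "right" else -1.0
    rows = []
    for j in range(spec.n_shafts):
        contralateral = j >= spec.n_shafts - spec.n_contralateral
        sx = -s if contralateral else s
        ty, tz = _SEEG_TARGETS[j % len(_SEEG_TARGETS)]
        for c in range(spec.contacts_per_shaft):
            x = sx * (18.0 + c * spec.contact_pitch)
            tissue = "WM" if rng.random() < spec.wm_fraction else "GM"
            rows.append((f"E{j + 1}_{c + 1:02d}", x, ty, tz, "depth", tissue))
    return _finish_table(rows, rng, spec.jitter_mm, spec.hemisphere,
                         spec.n_resection_rois)


# ---------------------------------------------------------------------------
# Ground-truth connectivity
# ---------------------------------------------------------------------------


@dataclass
class EffectConfig:
    """Knobs of the planted ground-truth connectivity.

    ``distance_params`` maps each edge class ('S-S', 'S-D', 'D-D') to the
    (p1, p2, q1) of the rational decay w(d) = (p1*d + p2)/(d + q1).
    ``depth_elevation`` is an additive bonus on depth-depth edges (the
    elevated depth-electrode coherence the pipeline must detect and correct).
    ``resection_effect`` shifts every edge with at least one resected
    endpoint; negative values make resected tissue weaker (high D_rs).
    """

    distance_params: dict = field(
        default_factory=lambda: {c: (0.08, 12.0, 25.0) for c in EDGE_CLASSES}
    )
    depth_elevation: float = 0.1
    community_contrast: float = 0.06
    community_labels: Optional[np.ndarray] = None
    resection_effect: float = 0.0
    edge_noise_sd: float = 0.02
    weight_floor: float = 0.0
    weight_ceiling: float = 0.95

    def validate(self) -> None:
        if self.edge_noise_sd < 0:
            raise InvalidSpecError("edge_noise_sd must be >= 0")
        if not 0.0 <= self.weight_floor < self.weight_ceiling < 1.0:
            raise InvalidSpecError("need 0 <= floor < ceiling < 1")
        missing = [c for c in EDGE_CLASSES if c not in self.distance_params]
        if missing:
            raise InvalidSpecError(f"distance_params missing classes {missing}")

    @classmethod
    def constant(cls, c: float, **kwargs) -> "EffectConfig":
        """A degenerate config with constant distance profile f(d) = c.

        Achieved with p1 = c, p2 = c*q1 so that (p1*d + p2)/(d + q1) = c.
        All other effects default to zero.
        """
        params = {k: (c, c * 25.0, 25.0) for k in EDGE_CLASSES}
        defaults = dict(
            distance_params=params,
            depth_elevation=0.0,
            community_contrast=0.0,
            resection_effect=0.0,
            edge_noise_sd=0.0,
        )
        defaults.update(kwargs)
        return cls(**defaults)


def default_community_labels(sensors: pd.DataFrame) -> np.ndarray:
    """Default planted communities: hemisphere x anterior/posterior (4 blocks)."""
    hemi = (sensors["x"].to_numpy() < 0).astype(int)
    ant = (sensors["y"].to_numpy() >= 0).astype(int)
    return hemi * 2 + ant


def plant_ground_truth(
    sensors: pd.DataFrame, cfg: EffectConfig, seed: int = 0
) -> GroundTruthNetwork:
    """Plant a true adjacency over a sensor table.

    w_ij = f_class(d_ij) + depth bonus (D-D only) + community term
    + resection term + Gaussian noise, clipped to [floor, ceiling],
    symmetric with zero diagonal.

    Raises
    ------
    InvalidSpecError
        If a rational-decay pole (d = -q1) lies inside the observed distance
        range or predictions are non-positive over it.
    """
    sensors = validate_sensor_table(sensors)
    cfg.validate()
    rng = np.random.default_rng(seed)
    coords = sensors[["x", "y", "z"]].to_numpy(dtype=float)
    n = len(sensors)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    types = sensors["electrode_type"].to_numpy()
    is_depth = types == "depth"
    dd = np.outer(is_depth, is_depth)
    ss = np.outer(~is_depth, ~is_depth)
    sd = ~(dd | ss)

    off = ~np.eye(n, dtype=bool)
    dmin, dmax = d[off].min(), d[off].max()
    w = np.zeros((n, n))
    for cls_name, mask in (("S-S", ss), ("S-D", sd), ("D-D", dd)):
        p1, p2, q1 = cfg.distance_params[cls_name]
        if (dmin + q1) * (dmax + q1) <= 0:
            raise InvalidSpecError(
                f"rational decay pole d = {-q1} inside distance range "
                f"[{dmin:.1f}, {dmax:.1f}] for class {cls_name}"
            )
        pred = (p1 * d + p2) / (d + q1)
        if mask.any() and (pred[mask & off] <= 0).any():
            raise InvalidSpecError(
                f"distance profile for {cls_name} non-positive over data range"
            )
        w[mask] = pred[mask]

    w = w + cfg.depth_elevation * dd
    if cfg.community_contrast:
        labels = (
            cfg.community_labels
            if cfg.community_labels is not None
            else default_community_labels(sensors)
        )
        labels = np.asarray(labels)
        within = labels[:, None] == labels[None, :]
        w = w + cfg.community_contrast * within
    if cfg.resection_effect:
        res = sensors["resected"].to_numpy(dtype=bool)
        incident = res[:, None] | res[None, :]
        w = w + cfg.resection_effect * incident
    if cfg.edge_noise_sd > 0:
        noise = squareform(rng.normal(0.0, cfg.edge_noise_sd, size=n * (n - 1) // 2))
        w = w + noise

    w = np.clip(w, cfg.weight_floor, cfg.weight_ceiling)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return GroundTruthNetwork(
        weights=w,
        contact_ids=sensors["contact_id"].tolist(),
        config=cfg,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------


def _band_gain(freqs: np.ndarray, band: Tuple[float, float], order: int = 4) -> np.ndarray:
    """Smooth band-limited power profile (Butterworth-like magnitude squared)."""
    f_lo, f_hi = band
    f0 = np.sqrt(f_lo * f_hi)
    bw = f_hi - f_lo
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(freqs > 0, (freqs**2 - f0**2) / (np.maximum(freqs, 1e-12) * bw), np.inf)
    return 1.0 / (1.0 + x ** (2 * order))


def synthesize_recording(
    truth: GroundTruthNetwork,
    fs: float = 256.0,
    duration: float = 300.0,
    band: Tuple[float, float] = (15.0, 25.0),
    seed: int = 0,
    noise_floor: float = 0.01,
) -> Recording:
    """Synthesize a multichannel recording realizing a planted adjacency.

    Channels are jointly Gaussian mixtures of shared band-limited sources
    plus independent noise; the per-edge mixing inverts the two-channel
    closed form msc = (SNR/(1+SNR))^2, i.e. the normalized in-band
    cross-spectrum between channels i and j is set to sqrt(w_ij). Sampling
    uses the equivalent frequency-domain factorization of that source model:
    R = I + offdiag(sqrt(W)) is factorized (eigenvalue-clipped to the nearest
    PSD matrix when the planted matrix is not jointly realizable) and applied
    to white spectra shaped by a band-limited gain. For two channels the
    realized in-band coherence equals w exactly; for dense networks exact
    joint realization is not guaranteed and the tested contract is rank
    agreement (Spearman >= 0.8) between estimated and planted weights.

    Parameters
    ----------
    truth : GroundTruthNetwork
    fs : float
        Sampling rate in Hz; must exceed twice the band's top edge.
    duration : float
        Recording length in seconds; at least 60 s.
    band : (f_lo, f_hi)
        Band (Hz) carrying the planted coherence.
    noise_floor : float
        Relative broadband white-noise power added to every channel.
    """
    w = np.asarray(truth.weights, dtype=float)
    n = w.shape[0]
    if (w >= 1.0).any():
        raise InvalidSpecError("true weights must be < 1 to be realizable")
    if duration < 60.0:
        raise InvalidSpecError("duration must be >= 60 s")
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi < fs / 2:
        raise InvalidSpecError(f"band {band} not inside (0, fs/2)")

    rng = np.random.default_rng(seed)
    t = int(round(duration * fs))
    r = np.sqrt(np.clip(w, 0.0, None))
    np.fill_diagonal(r, 1.0)
    # nearest-PSD repair: clip negative eigenvalues, renormalize to unit power
    evals, evecs = np.linalg.eigh(r)
    if evals[0] < 1e-9:
        evals = np.clip(evals, 1e-9, None)
    mix = evecs * np.sqrt(evals)
    norm = np.sqrt((mix**2).sum(axis=1, keepdims=True))
    mix /= norm

    freqs = np.fft.rfftfreq(t, d=1.0 / fs)
    gain = _band_gain(freqs, band)
    # white spectra via rFFT of white noise (keeps Hermitian symmetry exact)
    zf = np.fft.rfft(rng.standard_normal((n, t)), axis=1)
    xf = (mix @ zf) * np.sqrt(gain)
    if noise_floor > 0:
        wf = np.fft.rfft(rng.standard_normal((n, t)), axis=1)
        xf = xf + np.sqrt(noise_floor) * wf
    data = np.fft.irfft(xf, n=t, axis=1)
    return Recording(data=data, fs=fs, channel_ids=list(truth.contact_ids))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class PatientRecord:
    """One synthetic patient: metadata, signal and the generating truth."""

    patient_id: str
    modality: str
    sensors: pd.DataFrame
    recording: Recording
    truth: GroundTruthNetwork
    n_resection_rois: int


@dataclass
class CohortSpec:
    """Study-level configuration of a synthetic cohort.

    Defaults emulate the reference cohort: 16 ECoG + 17 SEEG patients, with
    broad surgical targets (2-4 ROIs, mostly resections) in ECoG and focal
    targets (1-3 ROIs, mostly ablations) in SEEG, a depth-depth coherence
    elevation of 0.1, and a per-patient resection effect

        effect = shift[modality] + focality_slope * (n_rois - focality_pivot)

    with a positive ECoG shift (resected cortex stronger than spared,
    pulling D_rs below 0.5) and a negative SEEG shift (focal targets weaker
    than their surroundings, pushing D_rs above 0.5), and a focality slope
    that makes more-focal surgeries remove relatively weaker tissue — the
    source of the negative D_rs vs resected-ROI-count correlation.
    """

    n_ecog: int = 16
    n_seeg: int = 17
    fs: float = 256.0
    duration: float = 300.0
    band: Tuple[float, float] = (15.0, 25.0)
    ecog_rois: Sequence[int] = (2, 3, 4)
    seeg_rois: Sequence[int] = (1, 2, 3)
    depth_elevation: float = 0.1
    community_contrast: float = 0.06
    ecog_resection_shift: float = 0.03
    seeg_resection_shift: float = -0.02
    focality_slope: float = 0.02
    focality_pivot: float = 2.5
    ecog_edge_noise: float = 0.02
    seeg_edge_noise: float = 0.03
    noise_floor: float = 0.01

    def validate(self) -> None:
        if self.n_ecog + self.n_seeg <= 0:
            raise InvalidSpecError("cohort must contain at least one patient")
        if self.n_ecog < 0 or self.n_seeg < 0:
            raise InvalidSpecError("group sizes must be >= 0")


def generate_patient(
    modality: str,
    spec: CohortSpec,
    n_rois: int,
    hemisphere: str,
    seed_seq: np.random.SeedSequence,
) -> PatientRecord:
    """Generate one synthetic patient from a cohort spec."""
    s_layout, s_truth, s_signal = (int(s.generate_state(1)[0] % 2**31)
                                   for s in seed_seq.spawn(3))
    if modality == "ECoG":
        layout = ECoGLayout(hemisphere=hemisphere, n_resection_rois=n_rois)
        noise = spec.ecog_edge_noise
        shift = spec.ecog_resection_shift
    else:
        layout = SEEGLayout(hemisphere=hemisphere, n_resection_rois=n_rois)
        noise = spec.seeg_edge_noise
        shift = spec.seeg_resection_shift
    sensors = generate_layout(modality, layout, seed=s_layout)
    cfg = EffectConfig(
        depth_elevation=spec.depth_elevation,
        community_contrast=spec.community_contrast,
        resection_effect=shift + spec.focality_slope * (n_rois - spec.focality_pivot),
        edge_noise_sd=noise,
    )
    truth = plant_ground_truth(sensors, cfg, seed=s_truth)
    rec = synthesize_recording(
        truth,
        fs=spec.fs,
        duration=spec.duration,
        band=spec.band,
        seed=s_signal,
        noise_floor=spec.noise_floor,
    )
    return PatientRecord(
        patient_id="",
        modality=modality,
        sensors=sensors,
        recording=rec,
        truth=truth,
        n_resection_rois=n_rois,
    )


def generate_cohort(
    cohort_spec: Optional[CohortSpec] = None, seed: int = 0
) -> List[PatientRecord]:
    """Generate a full synthetic cohort.

    Per-patient seeds derive deterministically from the master seed via
    spawn keys, so the same spec + seed always reproduces the same cohort.
    Default spec yields 33 patients: 16 ECoG + 17 SEEG.
    """
    spec = cohort_spec if cohort_spec is not None else CohortSpec()
    spec.validate()
    master = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(master.spawn(1)[0])
    patients: List[PatientRecord] = []
    plan = [("ECoG", i, spec.ecog_rois) for i in range(spec.n_ecog)]
    plan += [("SEEG", i, spec.seeg_rois) for i in range(spec.n_seeg)]
    for k, (modality, idx, roi_choices) in enumerate(plan):
        n_rois = int(draw_rng.choice(np.asarray(roi_choices)))
        hemisphere = str(draw_rng.choice(["left", "right"]))
        patient = generate_patient(
            modality, spec, n_rois, hemisphere,
            np.random.SeedSequence(entropy=seed, spawn_key=(1, k)),
        )
        patient.patient_id = f"{modality}_{idx + 1:02d}"
        patients.append(patient)
    return patients
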