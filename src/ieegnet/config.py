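"""Run configuration: schema, validation and seed derivation.

A run is configured by one YAML/JSON document with a master seed; every
stochastic stage derives its own seed deterministically from it, so a
manifest recording the config is sufficient to regenerate every number in
the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import yaml

from .synthetic import CohortSpec
from .types import InvalidSpecError, MEASURES


@dataclass
class RealDataPatient:
    """Paths describing one real-data patient."""

    patient_id: str
    modality: str
    sensors_csv: str
    edf: Optional[str] = None
    adjacency_csv: Optional[str] = None

    def validate(self) -> None:
        if self.modality not in ("ECoG", "SEEG"):
            raise InvalidSpecError(f"unknown modality {self.modality!r}")
        if (self.edf is None) == (self.adjacency_csv is None):
            raise InvalidSpecError(
                f"{self.patient_id}: give exactly one of 'edf' or 'adjacency_csv'"
            )


@dataclass
class RunConfig:
    """Full pipeline configuration.

    ``cohort`` configures the synthetic generator; setting ``patients``
    switches to real-data mode instead. The measure list defaults to the
    three connectivity measures of the analysis (beta coherence, low-gamma
    coherence, broadband cross-correlation).
    """

    seed: int = 0
    measures: List[str] = field(default_factory=lambda: list(MEASURES))
    cohort: CohortSpec = field(default_factory=CohortSpec)
    patients: Optional[List[RealDataPatient]] = None
    window_s: float = 1.0
    taper_nw: float = 2.0
    taper_k: int = 3
    lag_max_ms: float = 100.0
    louvain_gamma: float = 1.0
    louvain_runs: int = 100
    compute_participation: bool = True
    distance_starts: int = 20
    write_recordings: bool = False
    output_dir: str = "ieegnet_results"

    def validate(self) -> None:
        unknown = [m for m in self.measures if m not in MEASURES]
        if unknown:
            raise InvalidSpecError(
                f"unknown measures {unknown}; choose from {list(MEASURES)}"
            )
        if not self.measures:
            raise InvalidSpecError("at least one measure required")
        if self.window_s <= 0 or self.taper_k < 1 or self.louvain_runs < 1:
            raise InvalidSpecError("window_s, taper_k and louvain_runs must be positive")
        if not 0 <= self.seed < 2**31:
            raise InvalidSpecError("seed must be a non-negative 31-bit integer")
        if self.patients is not None:
            for p in self.patients:
                p.validate()
        else:
            self.cohort.validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            cohort_known = {f.name for f in dataclasses.fields(CohortSpec)}
            bad = set(raw["cohort"]) - cohort_known
            if bad:
                raise InvalidSpecError(f"unknown cohort keys: {sorted(bad)}")
            c = dict(raw["cohort"])
            for key in ("band", "ecog_rois", "seeg_rois"):
                if key in c:
                    c[key] = tuple(c[key])
            raw["cohort"] = CohortSpec(**c)
        if raw.get("patients") is not None:
            raw["patients"] = [
                p if isinstance(p, RealDataPatient) else RealDataPatient(**p)
                for p in raw["patients"]
            ]
        config = cls(**raw)
        config.validate()
        return config

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise InvalidSpecError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def digest(self) -> str:
        """Stable hash of the configuration (for the run manifest)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str, index: int = 0) -> int:
        """Deterministic child seed for a named stage (counter-based)."""
        h = hashlib.sha256(f"{self.seed}:{stage}:{index}".encode()).digest()
        return int.from_bytes(h[:4], "little") % 2**31
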