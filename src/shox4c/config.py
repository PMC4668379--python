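"""Run configuration: every tunable parameter of the pipeline in one place.

A resolved copy of the configuration is written next to every run's outputs
so any run can be reproduced byte-for-byte from its output directory.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path


@dataclass
class EnzymeConfig:
    name: str
    site: str
    cut_offset: int


@dataclass
class RunConfig:
    """Pipeline parameters with their defaults.

    min_fragment_length is the only parameter fixed by the assay definition
    (fragments under 40 bp are unmappable and filtered); the remaining
    defaults are package design choices documented in the methods note.
    """

    primary_enzyme: EnzymeConfig = field(
        default_factory=lambda: EnzymeConfig("DpnII", "GATC", 0)
    )
    secondary_enzyme: EnzymeConfig = field(
        default_factory=lambda: EnzymeConfig("Csp6I", "GTAC", 1)
    )
    min_fragment_length: int = 40  # bp; strict: 39 filtered, 40 retained
    window_size: int = 21  # running-mean window, in fragends (odd)
    mask_k: int = 2  # fragends masked on each side of the viewpoint
    background_quantile: float = 0.75
    gap_tolerance: int = 25  # sub-threshold fragends bridged inside a domain
    ambiguity_band: float = 0.15  # copy-number half-integer flag band
    calibrator_cn: int = 2
    seed: int = 0
    output_dir: str = "shox4c_out"

    def validate(self) -> None:
        if self.min_fragment_length < 0:
            raise ValueError("min_fragment_length must be >= 0")
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 1")
        if self.mask_k < 0:
            raise ValueError("mask_k must be >= 0")
        if not (0 < self.background_quantile < 1):
            raise ValueError("background_quantile must be in (0, 1)")
        if self.gap_tolerance < 0:
            raise ValueError("gap_tolerance must be >= 0")
        if self.ambiguity_band < 0:
            raise ValueError("ambiguity_band must be >= 0")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("primary_enzyme", "secondary_enzyme"):
            if key in data:
                data[key] = EnzymeConfig(**data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg
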