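"""Run configuration: one flat, validated record of every threshold and
scale knob, loadable from YAML, hashable for reproducible manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "asreg_run"
    conditions: list[str] = field(default_factory=lambda: ["YPAD", "YPGal", "YPE", "SC"])

    # panel / screen scale
    n_tss_overlap: int = 81
    n_no_overlap: int = 81
    n_no_as: int = 26
    replicates_per_construct: int = 2
    cells_per_well: int = 300
    frac_regulated: float = 0.2
    onoff_fraction: float = 0.1
    planted_log2_effect: float = 1.0

    # flow cytometry
    n_facs_genes: int = 66
    events_per_sample: int = 100_000
    denoise_factor: float = 0.5
    gate_fraction: float = 0.10
    gate_bins: int = 64

    # thresholds
    p_threshold: float = 0.01
    range_factor: float = 1.5
    min_cells: int = 100
    expression_quantile: float = 0.99
    discordance_factor: float = 2.0
    condition_specific_p: float = 0.05

    # metagene
    bin_size: int = 10
    window_up: int = 500
    window_down: int = 500
    smooth_bins: int = 5
    n_boot: int = 1000

    # optional direct inputs (skip the corresponding synth stage)
    cells_csv: str | None = None
    wells_csv: str | None = None
    annotation_gff3: str | None = None

    def validate(self) -> None:
        if self.p_threshold <= 0 or self.p_threshold >= 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0 < self.expression_quantile < 1:
            raise ValueError("expression_quantile must be in (0, 1)")
        if not 0 < self.gate_fraction <= 1:
            raise ValueError("gate_fraction must be in (0, 1]")
        if self.range_factor < 1 or self.discordance_factor < 1:
            raise ValueError("range factors must be >= 1")
        if min(self.n_tss_overlap, self.n_no_overlap, self.n_no_as) < 0:
            raise ValueError("gene counts must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
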