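"""Run configuration: every pipeline threshold with its default, YAML-backed."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fdr: float = 0.05
    min_upc: float = 6.0
    min_cov: int = 10
    merge_gap: int = 30
    min_width: int = 30
    window: int = 100
    min_mapq: int = 10
    homopolymer_k: int = 10
    min_fpkm: float = 0.1
    logfc: float = 1.0
    p: float = 0.05
    n_shuffles: int = 100
    min_support: int = 2
    seed: int = 0

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def echo(self) -> None:
        for f in dataclasses.fields(self):
            log.info("config: %s = %r", f.name, getattr(self, f.name))
        if self.min_width == 0:
            log.warning("config: min_width=0 disables the peak width filter")

    def write_provenance(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dump(out / "run_config.yaml")
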