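"""Run configuration: a validated key-value (YAML) file, overridable by CLI
flags.  Unknown keys are rejected before any stage runs."""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import yaml

from mretarget.errors import ConfigurationError


@dataclass
class RunConfig:
    """Everything the end-to-end prediction pipeline needs."""

    mirna_fasta: Optional[str] = None
    transcript_fasta: Optional[str] = None
    regions_tsv: Optional[str] = None
    conservation_tsv: Optional[str] = None
    conservation_bigwig: Optional[str] = None
    utr3_model_dir: Optional[str] = None
    cds_model_dir: Optional[str] = None
    meta_model_path: Optional[str] = None
    site_threshold: float = 0.5
    interaction_threshold: float = 0.5
    seed: int = 0
    n_threads: int = 1
    log_level: str = "INFO"

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ConfigurationError(f"missing required configuration keys: {missing}")


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Load YAML config (if given), apply non-None overrides, reject unknowns."""
    known = {f.name for f in fields(RunConfig)}
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        unknown = set(loaded) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown configuration keys {sorted(unknown)}")
        data.update(loaded)
    for k, v in overrides.items():
        if k not in known:
            raise ConfigurationError(f"unknown configuration key {k!r}")
        if v is not None:
            data[k] = v
    return RunConfig(**data)
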