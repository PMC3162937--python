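"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    The subfamily window (50-300 sequences), the 4-of-7 helix quality rule,
    the <10-residue per-species dedup, the 100-sequences-per-species floor and
    the 95% artificial-sequence calibration are the method's operating
    conditions; the rest are reproducibility knobs.
    """

    min_subfamily: int = 50
    max_subfamily: int = 300
    max_failed_helices: int = 4
    dedup_diff: int = 10
    species_min: int = 100
    calib_n: int = 10_000
    calib_length: int = 350
    pseudocount: float = 1.0
    aggregate: str = "min"
    corner: str = "theoretical"
    seed: int = 0

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        """Build from an optional YAML file; keyword overrides win."""
        values: dict = {}
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(loaded) - known
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def echo(self, path: str | Path) -> None:
        """Write the resolved configuration next to a run's outputs."""
        payload = {"sstea_version": __version__, **dataclasses.asdict(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
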