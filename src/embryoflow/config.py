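"""Run configuration: flat key=value files with unit-suffixed keys."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

__all__ = ["RunConfig", "parse_config", "load_config"]


@dataclass
class RunConfig:
    """Resolved configuration for a CLI run.

    Physical quantities carry unit suffixes in their key names (``bx_um``,
    ``chi_step_um`` ...) to keep units explicit in config files.
    """

    bx_um: float = 110.0
    bz_um: float = 270.0
    solver: str = "exact"  # "exact" | "lubrication"
    nmax: int = 14
    slip: str = "drosophila"
    n_particles: int = 40
    kernel_bandwidth_um: float = 7.0
    n_seeds: int = 100
    base_seed: int = 0
    chi_max_um: float = 400.0
    chi_step_um: float = 2.0
    dchi_um: float = 0.5
    measure: str = "kernel"
    n_strips: int = 100
    z0_frac: float = 60.0 / 270.0  # reduced-model initial half-width, 60 um / bz
    eval_chi_um: tuple = ()  # extra chi values reported on the curve
    snapshot_chi_um: tuple = (0.0, 100.0, 159.0, 250.0, 400.0)
    outdir: str = "runs"

    def chi_grid(self) -> np.ndarray:
        return np.arange(0.0, self.chi_max_um + 0.5 * self.chi_step_um, self.chi_step_um)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


def _coerce(raw: str, like):
    if isinstance(like, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(like, int):
        return int(raw)
    if isinstance(like, float):
        return float(raw)
    if isinstance(like, tuple):
        return tuple(float(x) for x in raw.split(",") if x.strip())
    return raw


def parse_config(text: str) -> RunConfig:
    """Parse ``key = value`` lines (``#`` comments allowed) into a RunConfig."""
    cfg = RunConfig()
    known = {f.name: getattr(cfg, f.name) for f in fields(cfg)}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise KeyError(f"line {lineno}: unknown config key {key!r}")
        setattr(cfg, key, _coerce(raw, known[key]))
    return cfg


def load_config(path: str | Path) -> RunConfig:
    return parse_config(Path(path).read_text())
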