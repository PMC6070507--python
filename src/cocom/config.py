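"""Run configuration loading and the machine-readable run log."""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "write_run_log"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    genotypes_a: str = ""
    genotypes_b: str = ""
    phenotypes: str = ""
    pairing: str = ""
    treatment: str = "co"
    growth_model: str = "richards"
    cov_structure: str = "ar1"
    log_scale: bool = True
    maf_min: float = 0.1
    missing_max: float = 0.2
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "cocom_out"
    verbosity: int = 1

    def validate_paths(self):
        for name in ("genotypes_a", "genotypes_b", "phenotypes", "pairing"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        return self


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    return RunConfig(**raw)


def write_run_log(config: RunConfig, outdir, timings: dict | None = None) -> Path:
    """Echo config, seed, versions and timings to a JSON run log."""
    import numpy
    import pandas
    import scipy

    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {
            "cocom": __version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "timings_s": timings or {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = outdir / "run_log.json"
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2)
    return path
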