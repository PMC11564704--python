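"""Run configuration and reproducibility manifests.

Defaults mirror the pipeline's canonical settings: 4-level db4
decomposition, block size 19, selection sweep 100..512, 1NN with
city-block distance under seeded stratified 10-fold CV.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "log_run"]


@dataclass(frozen=True)
class PipelineConfig:
    wavelet: str = "db4"
    wavelet_levels: int = 4
    boundary_mode: str = "symmetric"
    block_size: int = 19
    iv: int = 100
    fv: int = 512
    k: int = 1
    distance: str = "cityblock"
    folds: int = 10
    nca_max_iter: int = 15
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    Missing keys are filled with the defaults above; unknown keys raise.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        values.update(loaded)
    values.update(overrides)
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    filled = known - set(values)
    if filled and path is not None:
        import logging

        logging.getLogger(__name__).info(
            "config keys filled with defaults: %s", sorted(filled)
        )
    return PipelineConfig(**values)


def log_run(
    config: PipelineConfig,
    results: dict,
    out_dir: str | Path | None = None,
    timings: dict | None = None,
) -> dict:
    """Emit a run manifest: config + hash, seeds, library versions, timings."""
    import numpy
    import pywt
    import scipy
    import sklearn

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "pywavelets": pywt.__version__,
        },
        "timings": timings or {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "results": results,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest
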