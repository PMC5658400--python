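"""YAML configuration and run logging.

A config file holds the analysis thresholds (log fold-change cutoff,
alpha, pseudo-count, mean nucleotide mass) and optional default paths;
every CLI run appends its parameters and the package version to a run-log
file so analyses stay reproducible.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional, Union

import yaml


@dataclass
class AnalysisConfig:
    """Tunable thresholds shared across pipeline stages."""

    lfc_threshold: float = 1.7  # log10 fold-change cutoff (~50-fold)
    alpha: float = 0.05
    pseudo_count: Optional[float] = None  # None = half the min nonzero fmol
    mean_nt_mass_g_per_mol: float = 320.5
    min_drop: float = 0.5
    window: int = 3
    log_base: float = 2.0
    top_n: int = 500
    top_share_q: float = 0.8
    paths: Dict[str, str] = field(default_factory=dict)


def load_config(path: Union[str, Path, None]) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML; missing file or None gives
    defaults, unknown keys are rejected."""
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in AnalysisConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)


def save_config(config: AnalysisConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def log_run(log_path: Union[str, Path], command: str, params: Dict[str, Any]) -> None:
    """Append one JSON line describing a run (command, parameters,
    version, timestamp)."""
    from . import __version__

    entry = {
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "command": command,
        "version": __version__,
        "params": {k: str(v) for k, v in params.items()},
    }
    path = Path(log_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("a") as fh:
        fh.write(json.dumps(entry) + "\n")
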