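"""Delimited-text dataset I/O, config loading, run manifests and fixtures.

All file outputs are plain text: datasets and result tables as CSV/TSV
(numeric values at 17 significant digits so round-trips are lossless),
configs as YAML, manifests as JSON.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import DataValidationError, SurvivalDataset
from .simulate import SimulationConfig

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_table",
    "load_config",
    "dump_config",
    "write_manifest",
    "fixture_generator",
    "FIXTURES",
]

_FLOAT_FMT = "%.17g"


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(
    path,
    time_col: str = "time",
    event_col: str = "event",
    covariate_cols: Sequence[str] | None = None,
) -> SurvivalDataset:
    """Read a survival dataset from delimited text with a header row.

    The file must contain ``time_col`` and ``event_col``; remaining
    columns (or the declared subset) are covariates. Validation failures
    raise :class:`DataValidationError` naming the offending row/column.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    return SurvivalDataset.from_frame(
        frame, time_col=time_col, event_col=event_col, covariate_cols=covariate_cols
    )


def write_dataset(data: SurvivalDataset, path) -> Path:
    """Write a dataset as delimited text (full float precision)."""
    path = Path(path)
    data.to_frame().to_csv(path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT)
    return path


def write_table(frame: pd.DataFrame, path, precision: int | None = None) -> Path:
    """Write a result table; ``precision`` rounds for human-facing output."""
    path = Path(path)
    fmt = _FLOAT_FMT if precision is None else f"%.{precision}f"
    frame.to_csv(path, sep=_sep_for(path), index=False, float_format=fmt)
    return path


# ---------------------------------------------------------------------------
# configs and manifests
# ---------------------------------------------------------------------------


def load_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML mapping; validates keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise DataValidationError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    aliases = {"lambda": "lambda_"}
    kwargs = {}
    for key, value in raw.items():
        key = aliases.get(key, key)
        if key not in known:
            raise DataValidationError(f"unknown config key '{key}'")
        kwargs[key] = value
    if "n" not in kwargs:
        raise DataValidationError("config must set 'n'")
    return SimulationConfig(**kwargs)


def dump_config(config: SimulationConfig, path) -> Path:
    path = Path(path)
    d = dataclasses.asdict(config)
    d = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
    return path


def write_manifest(command: str, params: dict, outputs: Sequence[str], path) -> Path:
    """Write a JSON run manifest capturing everything needed for replay."""
    path = Path(path)

    def _clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {k: _clean(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_clean(x) for x in v]
        return v

    manifest = {
        "command": command,
        "package": "coxcal",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "params": _clean(params),
        "outputs": [str(o) for o in outputs],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


# ---------------------------------------------------------------------------
# named test fixtures
# ---------------------------------------------------------------------------

FIXTURES: dict[str, dict] = {
    "null_g01_small": dict(n=50, model="g01", p=5, target_event_rate=0.2),
    "null_g01_medium": dict(n=500, model="g01", p=5, target_event_rate=0.2),
    "gA1_one_interaction_small": dict(
        n=50, model="gA1", p=5, target_event_rate=0.2, beta_ge=[0.5, 0, 0, 0, 0]
    ),
    "gA3_gaussian_small": dict(n=50, model="gA3", target_event_rate=0.2, beta_z1z2=0.3),
    "gA4_additive_small": dict(n=50, model="gA4", p=5, target_event_rate=0.2, beta_g=0.3),
}


def fixture_generator(name: str, seed: int = 0) -> SurvivalDataset:
    """Deterministic small synthetic cohort for unit tests.

    Wraps the cohort simulator at small n under a named scenario; the same
    (name, seed) pair always yields an identical dataset.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture '{name}'; available: {sorted(FIXTURES)}")
    from .simulate import simulate_cohort

    cfg = SimulationConfig(**FIXTURES[name])
    return simulate_cohort(cfg, rng=seed)
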