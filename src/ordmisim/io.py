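"""CSV/YAML round-tripping for cohorts, weight vectors and run configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from ._design import CODEBOOK, COHORT_COLUMNS


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as CSV (integer category codes) plus a sidecar
    ``<path>.codebook.json`` mapping codes to labels."""
    path = Path(path)
    cohort[COHORT_COLUMNS].to_csv(path, index=False)
    with open(f"{path}.codebook.json", "w") as fh:
        json.dump(CODEBOOK, fh, indent=1)


def read_cohort(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file lacks columns {missing}")
    return frame[COHORT_COLUMNS]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {(k if isinstance(k, str) else "|".join(map(str, k))): _to_plain(v)
                for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def save_config(config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def load_run_config(path):
    """Build a :class:`ordmisim.pipeline.RunConfig` from a YAML file; absent
    keys keep their defaults."""
    from .pipeline import RunConfig
    from .registry_synth import CensoringSpec, DependenceSpec, GeneratorConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    gen_raw = raw.pop("generator", {}) or {}
    dep_raw = gen_raw.pop("dependence", None)
    cen_raw = gen_raw.pop("censoring", "default")
    gen = GeneratorConfig(**gen_raw)
    if dep_raw is not None:
        core = {tuple(k.split("|")): v
                for k, v in (dep_raw.get("core_corr") or {}).items()}
        loadings = {k: tuple(v)
                    for k, v in (dep_raw.get("therapy_loadings") or {}).items()}
        spec = DependenceSpec()
        if core:
            spec.core_corr = core
        if loadings:
            spec.therapy_loadings = loadings
        gen = dataclasses.replace(gen, dependence=spec)
    if cen_raw != "default":
        gen = dataclasses.replace(
            gen, censoring=None if cen_raw is None else CensoringSpec(**cen_raw))
    return RunConfig(generator=gen, **raw)
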