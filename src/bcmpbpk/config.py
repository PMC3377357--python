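"""Run configuration: file loading, validation, hashing.

A run config is a plain mapping (JSON or YAML) whose keys mirror the model
constants; every value is optional and overrides the package default::

    bw_kg: 0.25
    qcc: 15.0
    qv_ratio: 1.7
    flow_fractions: {adipose: 0.082, slowly_perfused: 0.257, kidney: 0.138, liver: 0.242}
    volume_fractions: {slowly_perfused: 0.674, liver: 0.044, kidney: 0.0075, adipose: 0.112}
    partitions: {blood_air: 41.5, liver: 0.7, rapidly_perfused: 0.7, kidney: 0.7,
                 slowly_perfused: 0.267, adipose: 7.8}
    mw: 129.38
    chamber: {volume_l: 9.0, n_rats: 3, loss_per_hr: 0.025}
    hypothesis: two_pathway
    metabolic: {vmax: 3.8, km: 0.35, kgst: 4.7}      # or {vmax1, km1, cl2}
    design: {c0_ppm: [200, 500, 1000, 2000, 4000], t_start: 0.1, t_end: 6.0, t_step: 0.1}
    noise_cv: 0.05
    seed: 0
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .datasets import DEFAULT_C0_PPM, DEFAULT_NOISE_CV, default_obs_times
from .errors import ConfigError
from .kinetics import MetabolicParamsTwoPathway, MetabolicParamsTwoSite
from .model import ClosedChamberConfig
from .physiology import ChemicalParams, PhysiologicalParams

__all__ = ["load_config", "build_chamber_config", "build_design", "config_hash"]

_TOP_KEYS = {
    "bw_kg", "qcc", "qv_ratio", "flow_fractions", "volume_fractions",
    "partitions", "mw", "chamber", "hypothesis", "metabolic", "design",
    "noise_cv", "seed",
}
_CHAMBER_KEYS = {"volume_l", "n_rats", "loss_per_hr"}
_DESIGN_KEYS = {"c0_ppm", "t_start", "t_end", "t_step"}


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML config file into a dict (YAML parses both)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: cannot parse config: {e}") from None
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    return data


def _wrap(key: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (ValueError, ConfigError, TypeError) as e:
        raise ConfigError(f"config key {key!r}: {e}") from None


def build_chamber_config(overrides: Mapping[str, Any] | None = None) -> ClosedChamberConfig:
    """Turn a (possibly empty) override mapping into a validated config.

    Raises :class:`ConfigError` naming the offending key on any invalid or
    unknown entry.
    """
    d = dict(overrides or {})
    unknown = set(d) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    phys_kwargs: dict[str, Any] = {}
    for src, dst in (("bw_kg", "bw_kg"), ("qcc", "qcc"), ("qv_ratio", "qv_ratio")):
        if src in d:
            phys_kwargs[dst] = d[src]
    for frac_key in ("flow_fractions", "volume_fractions"):
        if frac_key in d:
            base = dict(getattr(PhysiologicalParams(), frac_key))
            if not isinstance(d[frac_key], Mapping):
                raise ConfigError(f"config key {frac_key!r}: expected a mapping")
            unknown_t = set(d[frac_key]) - set(base)
            if unknown_t:
                raise ConfigError(f"config key {frac_key!r}: unknown tissues {sorted(unknown_t)}")
            base.update(d[frac_key])
            phys_kwargs[frac_key] = base
    physiology = _wrap("bw_kg/qcc/qv_ratio/fractions", PhysiologicalParams, **phys_kwargs)

    chem_kwargs: dict[str, Any] = {}
    if "mw" in d:
        chem_kwargs["mw"] = d["mw"]
    if "partitions" in d:
        p = d["partitions"]
        if not isinstance(p, Mapping):
            raise ConfigError("config key 'partitions': expected a mapping")
        p = dict(p)
        if "blood_air" in p:
            chem_kwargs["p_blood_air"] = p.pop("blood_air")
        if p:
            base = dict(ChemicalParams().tissue_blood_partitions)
            unknown_t = set(p) - set(base)
            if unknown_t:
                raise ConfigError(f"config key 'partitions': unknown tissues {sorted(unknown_t)}")
            base.update(p)
            chem_kwargs["tissue_blood_partitions"] = base
    chemical = _wrap("mw/partitions", ChemicalParams, **chem_kwargs)

    chamber = d.get("chamber", {})
    if not isinstance(chamber, Mapping):
        raise ConfigError("config key 'chamber': expected a mapping")
    unknown_c = set(chamber) - _CHAMBER_KEYS
    if unknown_c:
        raise ConfigError(f"config key 'chamber': unknown keys {sorted(unknown_c)}")

    hypothesis = d.get("hypothesis", "two_pathway")
    met = d.get("metabolic", {})
    if not isinstance(met, Mapping):
        raise ConfigError("config key 'metabolic': expected a mapping")
    if hypothesis == "two_pathway":
        metabolic = _wrap("metabolic", MetabolicParamsTwoPathway, **met)
    elif hypothesis == "two_site":
        metabolic = _wrap("metabolic", MetabolicParamsTwoSite, **met)
    else:
        raise ConfigError(f"config key 'hypothesis': unknown value {hypothesis!r}")

    kwargs: dict[str, Any] = {}
    if "volume_l" in chamber:
        kwargs["v_chamber"] = chamber["volume_l"]
    if "n_rats" in chamber:
        kwargs["n_rats"] = chamber["n_rats"]
    if "loss_per_hr" in chamber:
        kwargs["k_loss"] = chamber["loss_per_hr"]
    return _wrap(
        "chamber",
        ClosedChamberConfig,
        hypothesis=hypothesis,
        metabolic=metabolic,
        physiology=physiology,
        chemical=chemical,
        **kwargs,
    )


def build_design(overrides: Mapping[str, Any] | None = None):
    """(c0 list, observation-time grid, noise CV, seed) from a config mapping."""
    d = dict(overrides or {})
    design = d.get("design", {})
    if not isinstance(design, Mapping):
        raise ConfigError("config key 'design': expected a mapping")
    unknown = set(design) - _DESIGN_KEYS
    if unknown:
        raise ConfigError(f"config key 'design': unknown keys {sorted(unknown)}")
    c0_list = [float(c) for c in design.get("c0_ppm", DEFAULT_C0_PPM)]
    t_start = float(design.get("t_start", 0.1))
    t_end = float(design.get("t_end", 6.0))
    t_step = float(design.get("t_step", 0.1))
    if not (0 <= t_start < t_end and t_step > 0):
        raise ConfigError(
            f"config key 'design': need 0 <= t_start < t_end and t_step > 0, "
            f"got t_start={t_start}, t_end={t_end}, t_step={t_step}"
        )
    obs_times = default_obs_times(t_start, t_end, t_step)
    noise_cv = float(d.get("noise_cv", DEFAULT_NOISE_CV))
    if noise_cv < 0:
        raise ConfigError(f"config key 'noise_cv': must be non-negative, got {noise_cv}")
    seed = int(d.get("seed", 0))
    return c0_list, obs_times, noise_cv, seed


def config_hash(obj: Any) -> str:
    """Short stable hash of any JSON-serialisable config-like object."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return repr(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
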