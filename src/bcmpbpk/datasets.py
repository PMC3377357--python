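"""Synthetic closed-chamber gas-uptake datasets.

The historical vapor-uptake experiments this package targets (five chamber
runs at starting concentrations spanning 200-4000 ppm, 3 rats in a 9 L
chamber, 0.025/hr chamber leak) exist only as digitized figures, so the
generator emulates them: each series is the PBPK model's own chamber curve,
sampled on a regular grid and optionally perturbed with multiplicative
lognormal measurement noise, ``c_obs = c_model * exp(eps)``,
``eps ~ N(0, cv**2)``.  Sampling starts at 0.1 hr, after post-bolus chamber
mixing.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DatasetError
from .kinetics import MetabolicParamsTwoPathway, MetabolicParamsTwoSite
from .model import ClosedChamberConfig, simulate

__all__ = [
    "ChamberSeries",
    "ChamberDataset",
    "DEFAULT_C0_PPM",
    "DEFAULT_NOISE_CV",
    "default_obs_times",
    "generate_dataset",
    "read_dataset",
    "write_dataset",
]

#: Default experimental design: five starting concentrations, ppm.
DEFAULT_C0_PPM = (200.0, 500.0, 1000.0, 2000.0, 4000.0)

#: Default multiplicative measurement-noise coefficient of variation.
DEFAULT_NOISE_CV = 0.05


def default_obs_times(
    t_start: float = 0.1, t_end: float = 6.0, t_step: float = 0.1
) -> np.ndarray:
    """Regular observation grid, 0.1 to 6 hr every 0.1 hr by default."""
    n = int(round((t_end - t_start) / t_step))
    return np.round(np.linspace(t_start, t_start + n * t_step, n + 1), 10)


@dataclass(frozen=True)
class ChamberSeries:
    """One chamber run: declining concentration after a single bolus."""

    series_id: str
    c0_ppm_nominal: float
    t_hr: np.ndarray
    c_ppm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_hr, dtype=float)
        c = np.asarray(self.c_ppm, dtype=float)
        object.__setattr__(self, "t_hr", t)
        object.__setattr__(self, "c_ppm", c)
        if t.size != c.size:
            raise DatasetError(f"series {self.series_id!r}: time/concentration length mismatch")
        if t.size < 2:
            raise DatasetError(f"series {self.series_id!r}: needs >= 2 observations, has {t.size}")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise DatasetError(
                f"series {self.series_id!r}: times must be non-negative and strictly increasing"
            )
        if np.any(c < 0):
            raise DatasetError(f"series {self.series_id!r}: negative concentrations")

    @property
    def n_obs(self) -> int:
        return int(self.t_hr.size)


@dataclass(frozen=True)
class ChamberDataset:
    """A collection of chamber series plus generator provenance.

    ``provenance`` is either the literal string ``"external"`` (data read from
    disk without a sidecar) or a dict echoing the generator settings.
    """

    series: tuple[ChamberSeries, ...]
    provenance: dict | str = "external"

    def __post_init__(self) -> None:
        object.__setattr__(self, "series", tuple(self.series))
        if not self.series:
            raise DatasetError("dataset has no series")
        ids = [s.series_id for s in self.series]
        if len(set(ids)) != len(ids):
            raise DatasetError(f"duplicate series ids: {ids}")

    def __iter__(self):
        return iter(self.series)

    def __len__(self) -> int:
        return len(self.series)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.series)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [
                pd.DataFrame(
                    {
                        "series_id": s.series_id,
                        "c0_ppm_nominal": s.c0_ppm_nominal,
                        "t_hr": s.t_hr,
                        "c_ppm": s.c_ppm,
                    }
                )
                for s in self.series
            ],
            ignore_index=True,
        )


def generate_dataset(
    metabolic: MetabolicParamsTwoPathway | MetabolicParamsTwoSite,
    hypothesis: str,
    c0_list: Sequence[float] = DEFAULT_C0_PPM,
    obs_times: np.ndarray | None = None,
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int | None = 0,
    base_config: ClosedChamberConfig | None = None,
) -> ChamberDataset:
    """Simulate the experimental design and apply measurement noise.

    ``metabolic``/``hypothesis`` are the generating truth; chamber, rat and
    chemical constants come from ``base_config`` (package defaults if omitted,
    its ``c0_ppm`` is overridden per series).  ``noise_cv = 0`` returns the
    exact model curves; the RNG stream depends only on ``seed``.
    """
    if len(c0_list) == 0:
        raise DatasetError("c0_list must be non-empty")
    if noise_cv < 0:
        raise DatasetError(f"noise_cv must be non-negative, got {noise_cv}")
    if obs_times is None:
        obs_times = default_obs_times()
    obs_times = np.asarray(obs_times, dtype=float)
    if obs_times.size < 2 or np.any(obs_times < 0) or np.any(np.diff(obs_times) <= 0):
        raise DatasetError("obs_times must be >= 2 non-negative, strictly increasing values")

    base = base_config if base_config is not None else ClosedChamberConfig()
    base = base.replace(hypothesis=hypothesis, metabolic=metabolic)
    rng = np.random.default_rng(seed)
    series = []
    for i, c0 in enumerate(c0_list):
        cfg = base.replace(c0_ppm=float(c0))
        res = simulate(cfg, t_grid=obs_times)
        c = res.chamber_ppm.copy()
        if noise_cv > 0:
            c = c * np.exp(rng.normal(0.0, noise_cv, size=c.size))
        series.append(
            ChamberSeries(
                series_id=f"s{i + 1}_{c0:g}ppm",
                c0_ppm_nominal=float(c0),
                t_hr=obs_times,
                c_ppm=c,
            )
        )
    provenance = {
        "generator": "bcmpbpk.datasets.generate_dataset",
        "hypothesis": hypothesis,
        "truth": dataclasses.asdict(metabolic),
        "c0_list_ppm": [float(c) for c in c0_list],
        "t_start_hr": float(obs_times[0]),
        "t_end_hr": float(obs_times[-1]),
        "n_obs_per_series": int(obs_times.size),
        "noise_cv": float(noise_cv),
        "seed": seed,
    }
    return ChamberDataset(series=tuple(series), provenance=provenance)


def write_dataset(ds: ChamberDataset, path: str | Path) -> None:
    """Write CSV (series_id, c0_ppm_nominal, t_hr, c_ppm) + provenance sidecar.

    The sidecar ``<path>.provenance.json`` is written only for generated
    datasets (dict provenance); full float precision is kept so the round
    trip is lossless.
    """
    path = Path(path)
    ds.to_frame().to_csv(path, index=False, float_format="%.17g")
    if isinstance(ds.provenance, dict):
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(ds.provenance, indent=2) + "\n")


def read_dataset(path: str | Path) -> ChamberDataset:
    """Read a dataset CSV written by :func:`write_dataset`.

    Malformed files raise :class:`DatasetError` naming the offending column,
    row or series; a provenance sidecar is picked up when present.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DatasetError(f"{path}: file is empty or has no header") from None
    required = ["series_id", "c0_ppm_nominal", "t_hr", "c_ppm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing columns {missing}")
    if df.empty:
        raise DatasetError(f"{path}: no data rows")
    for col in ("c0_ppm_nominal", "t_hr", "c_ppm"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: one for the header line, one for 0- vs 1-based numbering
            raise DatasetError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
            )
        df[col] = pd.to_numeric(df[col])

    series = []
    for sid, g in df.groupby("series_id", sort=False):
        c0s = g["c0_ppm_nominal"].unique()
        if len(c0s) != 1:
            raise DatasetError(f"{path}: series {sid!r} has conflicting c0_ppm_nominal {c0s}")
        series.append(
            ChamberSeries(
                series_id=str(sid),
                c0_ppm_nominal=float(c0s[0]),
                t_hr=g["t_hr"].to_numpy(),
                c_ppm=g["c_ppm"].to_numpy(),
            )
        )
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    provenance: dict | str = "external"
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
    return ChamberDataset(series=tuple(series), provenance=provenance)
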