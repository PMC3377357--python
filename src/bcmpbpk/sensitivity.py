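"""Normalized local sensitivity analysis and identifiability diagnostics.

The normalized sensitivity coefficient of output ``y(t)`` with respect to a
scalar parameter ``p`` is ``S(t) = (p / y(t)) * dy(t)/dp`` — the fractional
change of the output per fractional change of the parameter.  Outputs of
interest are the chamber-air concentration (the measured variable of a
vapor-uptake experiment) and the liver concentration (a candidate invasive
measurement).

Two routes are provided: central finite differences on the full simulation
(default; robust and solver-agnostic) and forward-sensitivity integration of
the augmented ODE system (the verification oracle).  Surfaces stack
time courses over a grid of parameter values to show how the sensitivity
landscape moves with the parameter itself.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import (
    DEFAULT_T_END,
    DEFAULT_T_STEP,
    ClosedChamberConfig,
    make_rhs,
    simulate,
)
from .physiology import TISSUES

__all__ = [
    "VARIABLES",
    "SensitivityResult",
    "SensitivitySurface",
    "IdentifiabilityDiagnostic",
    "list_parameters",
    "get_param",
    "with_param",
    "sensitivity_timecourse",
    "sensitivity_surface",
    "identifiability_check",
]

VARIABLES = ("chamber_air", "liver_concentration")

#: Below this output magnitude (mg/L) the normalization p/y is singular and
#: the coefficient is defined as 0 (the liver starts the experiment empty).
NORMALIZATION_GUARD = 1e-12

#: Solver tolerances for sensitivity runs; tighter than the plain-simulation
#: defaults because finite differencing amplifies integration noise.
_SENS_RTOL = 1e-10
_SENS_ATOL = 1e-12

_ILIV = TISSUES.index("liver")


# --- scalar-parameter registry -------------------------------------------
# Each entry maps a public name to (getter, setter) acting on a config copy.

def _metabolic_field(name):
    def get(cfg):
        return getattr(cfg.metabolic, name)

    def set_(cfg, v):
        return cfg.replace(metabolic=dataclasses.replace(cfg.metabolic, **{name: v}))

    return get, set_


def _chamber_field(name):
    def get(cfg):
        return getattr(cfg, name)

    def set_(cfg, v):
        return cfg.replace(**{name: v})

    return get, set_


def _physiology_field(name):
    def get(cfg):
        return getattr(cfg.physiology, name)

    def set_(cfg, v):
        return cfg.replace(physiology=dataclasses.replace(cfg.physiology, **{name: v}))

    return get, set_


def _fraction_field(attr, tissue):
    def get(cfg):
        return getattr(cfg.physiology, attr)[tissue]

    def set_(cfg, v):
        new = dict(getattr(cfg.physiology, attr))
        new[tissue] = v
        return cfg.replace(
            physiology=dataclasses.replace(cfg.physiology, **{attr: new})
        )

    return get, set_


def _partition_field(tissue):
    def get(cfg):
        return cfg.chemical.tissue_blood_partitions[tissue]

    def set_(cfg, v):
        new = dict(cfg.chemical.tissue_blood_partitions)
        new[tissue] = v
        return cfg.replace(
            chemical=dataclasses.replace(cfg.chemical, tissue_blood_partitions=new)
        )

    return get, set_


def _chemical_field(name):
    def get(cfg):
        return getattr(cfg.chemical, name)

    def set_(cfg, v):
        return cfg.replace(chemical=dataclasses.replace(cfg.chemical, **{name: v}))

    return get, set_


def _build_registry():
    reg = {}
    for n in ("vmax", "km", "kgst", "vmax1", "km1", "cl2"):
        reg[n] = _metabolic_field(n)
    for n in ("v_chamber", "k_loss", "c0_ppm"):
        reg[n] = _chamber_field(n)
    reg["bw"] = _physiology_field("bw_kg")
    reg["qcc"] = _physiology_field("qcc")
    reg["qv"] = _physiology_field("qv_ratio")
    for t in ("adipose", "slowly_perfused", "kidney", "liver"):
        reg[f"flow_{t}"] = _fraction_field("flow_fractions", t)
        reg[f"vol_{t}"] = _fraction_field("volume_fractions", t)
    reg["p_blood_air"] = _chemical_field("p_blood_air")
    reg["mw"] = _chemical_field("mw")
    for t in TISSUES:
        reg[f"p_{t}"] = _partition_field(t)
    return reg


_REGISTRY = _build_registry()


def list_parameters() -> tuple[str, ...]:
    """Names accepted by :func:`sensitivity_timecourse` and friends."""
    return tuple(sorted(_REGISTRY))


def get_param(cfg: ClosedChamberConfig, name: str) -> float:
    """Read a scalar parameter by registry name."""
    try:
        get, _ = _REGISTRY[name]
    except KeyError:
        raise ConfigError(
            f"unknown parameter {name!r}; known: {', '.join(list_parameters())}"
        ) from None
    try:
        return float(get(cfg))
    except AttributeError:
        raise ConfigError(
            f"parameter {name!r} does not apply to hypothesis {cfg.hypothesis!r}"
        ) from None


def with_param(cfg: ClosedChamberConfig, name: str, value: float) -> ClosedChamberConfig:
    """Copy of the config with one scalar parameter replaced (closures re-derived)."""
    get_param(cfg, name)  # validates name and applicability
    _, set_ = _REGISTRY[name]
    return set_(cfg, value)


# --- sensitivity computation ----------------------------------------------

@dataclass
class SensitivityResult:
    """Normalized sensitivity time course of one variable to one parameter."""

    variable: str
    parameter: str
    t: np.ndarray
    s: np.ndarray
    method: str
    c0_ppm: float

    def peak_time(self) -> float:
        """Grid argmax of |S| — where the parameter is most informative."""
        return float(self.t[int(np.argmax(np.abs(self.s)))])

    def peak_magnitude(self) -> float:
        return float(np.max(np.abs(self.s)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_hr": self.t,
                "parameter": self.parameter,
                "variable": self.variable,
                "S": self.s,
            }
        )


@dataclass
class SensitivitySurface:
    """Sensitivity time courses stacked over a grid of parameter values."""

    parameter: str
    variable: str
    param_grid: np.ndarray
    t: np.ndarray
    s: np.ndarray  # shape (len(param_grid), len(t))
    c0_ppm: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.param_grid):
            rows.append(
                pd.DataFrame(
                    {"t_hr": self.t, "param_value": p, "S": self.s[i]}
                )
            )
        out = pd.concat(rows, ignore_index=True)
        out.insert(0, "parameter", self.parameter)
        out.insert(1, "variable", self.variable)
        return out


def _default_grid() -> np.ndarray:
    n = int(round(DEFAULT_T_END / DEFAULT_T_STEP))
    return np.linspace(0.0, DEFAULT_T_END, n + 1)


def _extract(variable: str, res) -> np.ndarray:
    if variable == "chamber_air":
        return res.chamber_mgl
    if variable == "liver_concentration":
        return res.c_tissue["liver"]
    raise ConfigError(f"unknown variable {variable!r}; expected one of {VARIABLES}")


def sensitivity_timecourse(
    cfg: ClosedChamberConfig,
    parameter: str,
    variable: str = "chamber_air",
    method: str = "central_fd",
    h: float = 1e-4,
    t_grid: np.ndarray | None = None,
) -> SensitivityResult:
    """Normalized sensitivity ``S(t) = (p/y) dy/dp`` of one output variable.

    ``central_fd`` re-simulates at ``p*(1 +/- h)``; ``forward_ode`` integrates
    the augmented forward-sensitivity system.  Where the output magnitude is
    below the normalization guard, S is defined as 0; a parameter whose
    nominal value is exactly 0 has S identically 0 by the normalization.
    """
    if t_grid is None:
        t_grid = _default_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    p0 = get_param(cfg, parameter)
    if variable not in VARIABLES:
        raise ConfigError(f"unknown variable {variable!r}; expected one of {VARIABLES}")
    if p0 == 0.0:
        return SensitivityResult(
            variable, parameter, t_grid, np.zeros_like(t_grid), method, cfg.c0_ppm
        )

    if method == "central_fd":
        res_p = simulate(
            with_param(cfg, parameter, p0 * (1 + h)),
            t_grid=t_grid, rtol=_SENS_RTOL, atol=_SENS_ATOL,
        )
        res_m = simulate(
            with_param(cfg, parameter, p0 * (1 - h)),
            t_grid=t_grid, rtol=_SENS_RTOL, atol=_SENS_ATOL,
        )
        res_0 = simulate(cfg, t_grid=t_grid, rtol=_SENS_RTOL, atol=_SENS_ATOL)
        y = _extract(variable, res_0)
        dy = (_extract(variable, res_p) - _extract(variable, res_m)) / (2 * h)
        s = np.where(np.abs(y) < NORMALIZATION_GUARD, 0.0, dy / np.where(y == 0, 1.0, y))
    elif method == "forward_ode":
        t, y_traj, s_traj = _forward_sensitivity(cfg, parameter, t_grid)
        idx = 0 if variable == "chamber_air" else 1 + _ILIV
        y = y_traj[idx] / (cfg.v_chamber if variable == "chamber_air" else 1.0)
        dy = s_traj[idx] / (cfg.v_chamber if variable == "chamber_air" else 1.0)
        s = np.where(
            np.abs(y) < NORMALIZATION_GUARD, 0.0, p0 * dy / np.where(y == 0, 1.0, y)
        )
    else:
        raise ConfigError(f"unknown method {method!r}; expected central_fd or forward_ode")
    return SensitivityResult(variable, parameter, t_grid, s, method, cfg.c0_ppm)


def _forward_sensitivity(cfg, parameter, t_grid):
    """Integrate y' = f(y; p), s' = (df/dy) s + df/dp jointly.

    Jacobian-vector products and df/dp are formed by central differencing of
    the right-hand side itself, so this route never differences whole
    trajectories and is independent of the ``central_fd`` path.
    """
    from scipy.integrate import solve_ivp

    from .model import ppm_to_mg_per_liter
    from .errors import SolverError

    p0 = get_param(cfg, parameter)
    dp = 1e-6 * abs(p0)
    f0 = make_rhs(cfg)
    f_plus = make_rhs(with_param(cfg, parameter, p0 + dp))
    f_minus = make_rhs(with_param(cfg, parameter, p0 - dp))
    n = 10

    def aug(t, ys):
        y, s = ys[:n], ys[n:]
        fy = f0(t, y)
        # directional derivative (df/dy) @ s
        smax = np.max(np.abs(s))
        if smax == 0:
            jvp = np.zeros(n)
        else:
            eps = 1e-7 * (1.0 + np.max(np.abs(y))) / smax
            jvp = (f0(t, y + eps * s) - f0(t, y - eps * s)) / (2 * eps)
        fp = (f_plus(t, y) - f_minus(t, y)) / (2 * dp)
        return np.concatenate([fy, jvp + fp])

    y0 = np.zeros(2 * n)
    y0[0] = ppm_to_mg_per_liter(cfg.c0_ppm, cfg.chemical.mw) * cfg.v_chamber
    sol = solve_ivp(
        aug,
        (0.0, float(t_grid[-1])),
        y0,
        method="LSODA",
        t_eval=t_grid,
        rtol=_SENS_RTOL,
        atol=_SENS_ATOL,
    )
    if not sol.success:
        raise SolverError(f"forward sensitivity integration failed: {sol.message}")
    return sol.t, sol.y[:n], sol.y[n:]


def sensitivity_surface(
    cfg: ClosedChamberConfig,
    parameter: str,
    value_range: tuple[float, float],
    n_sub: int,
    variable: str = "chamber_air",
    method: str = "central_fd",
    h: float = 1e-4,
    t_grid: np.ndarray | None = None,
) -> SensitivitySurface:
    """Sensitivity time courses over ``n_sub`` subintervals of a parameter range.

    The range is divided into ``n_sub`` subintervals (``n_sub + 1`` grid
    values including both endpoints); each row of the surface is the full
    time course recomputed with the parameter set to that grid value.
    """
    lo, hi = value_range
    if not lo < hi:
        raise ConfigError(f"require lo < hi, got ({lo}, {hi})")
    if n_sub < 2:
        raise ConfigError(f"n_sub must be >= 2, got {n_sub}")
    if lo <= 0:
        raise ConfigError(f"parameter range must stay positive, got lo = {lo}")
    if t_grid is None:
        t_grid = _default_grid()
    grid = np.linspace(lo, hi, n_sub + 1)
    rows = []
    for v in grid:
        tc = sensitivity_timecourse(
            with_param(cfg, parameter, float(v)),
            parameter,
            variable=variable,
            method=method,
            h=h,
            t_grid=t_grid,
        )
        rows.append(tc.s)
    return SensitivitySurface(
        parameter=parameter,
        variable=variable,
        param_grid=grid,
        t=np.asarray(t_grid, dtype=float),
        s=np.vstack(rows),
        c0_ppm=cfg.c0_ppm,
    )


@dataclass
class IdentifiabilityDiagnostic:
    """Rank/conditioning summary of a sensitivity time-course matrix.

    Columns that are all of one sign cannot cancel each other in a sum, which
    is the classical sufficient hint for unique identifiability; the smallest
    singular value and condition number quantify how close the columns come
    to linear dependence.  Diagnostic only — no hard threshold is applied.
    """

    parameters: tuple[str, ...]
    variable: str
    singular_values: np.ndarray
    smallest_singular_value: float
    condition_number: float
    same_sign: dict[str, bool]
    zero_columns: tuple[str, ...]


def identifiability_check(
    cfg: ClosedChamberConfig,
    parameters: list[str],
    variable: str = "chamber_air",
    t_grid: np.ndarray | None = None,
    h: float = 1e-4,
) -> IdentifiabilityDiagnostic:
    """Assemble normalized sensitivity columns and report their conditioning."""
    if len(parameters) < 1:
        raise ConfigError("at least one parameter required")
    cols = []
    same_sign = {}
    zero_cols = []
    for name in parameters:
        tc = sensitivity_timecourse(cfg, name, variable=variable, h=h, t_grid=t_grid)
        cols.append(tc.s)
        nz = tc.s[np.abs(tc.s) > 0]
        if nz.size == 0:
            zero_cols.append(name)
            same_sign[name] = True
        else:
            same_sign[name] = bool(np.all(nz > 0) or np.all(nz < 0))
    m = np.column_stack(cols)
    sv = np.linalg.svd(m, compute_uv=False)
    smallest = float(sv[-1])
    cond = float(sv[0] / sv[-1]) if smallest > 0 else float("inf")
    return IdentifiabilityDiagnostic(
        parameters=tuple(parameters),
        variable=variable,
        singular_values=sv,
        smallest_singular_value=smallest,
        condition_number=cond,
        same_sign=same_sign,
        zero_columns=tuple(zero_cols),
    )
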