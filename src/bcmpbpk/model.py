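"""Flow-limited PBPK model of a rat in a closed recirculating chamber.

One rat is described by five well-stirred tissue compartments (adipose,
rapidly perfused, slowly perfused, liver, kidney) with flow-limited uptake;
lung and blood are algebraic under a steady-state assumption, giving the
arterial concentration as a flow-weighted mix of venous return and chamber
air.  ``n_rats`` identical animals share the chamber, so one rat's ODEs are
integrated and the body burden scaled by the count in the chamber exchange.
The chamber itself loses chemical to a first-order leak (``k_loss``).

State vector (length 10):

==  =========================  =====
 0  A_chamber                  mg
1-5 C_tissue (TISSUES order)   mg/L
 6  A_met_liver (cumulative)   mg
 7  A_met_kidney (cumulative)  mg
 8  A_met_linear (cumulative)  mg
 9  A_lost (cumulative leak)   mg
==  =========================  =====

``A_met_linear`` tracks the share of metabolism flowing through the linear
term of the active hypothesis (the GST pathway, or the effector-site ``CL2``
term), summed over both organs.  Mass is conserved exactly:
``A_chamber + n_rats*(sum V_t*C_t + A_met_liver + A_met_kidney) + A_lost``
is constant along any trajectory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigError, SolverError
from .kinetics import (
    HYPOTHESES,
    MetabolicParamsTwoPathway,
    MetabolicParamsTwoSite,
    met_rates_two_pathway,
    met_rates_two_site,
)
from .physiology import (
    TISSUES,
    ChemicalParams,
    DerivedPhysiology,
    PhysiologicalParams,
    derive_physiology,
    mg_per_liter_to_ppm,
    ppm_to_mg_per_liter,
)

__all__ = [
    "ClosedChamberConfig",
    "ModelState",
    "SimulationResult",
    "arterial_concentration",
    "venous_concentration",
    "rhs",
    "simulate",
    "mass_balance_residual",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
    "DEFAULT_T_END",
    "DEFAULT_T_STEP",
]

#: Solver contract: stiff method, tight tolerances, dense default grid.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_T_END = 6.0
DEFAULT_T_STEP = 0.02

_ILIV = TISSUES.index("liver")
_IKID = TISSUES.index("kidney")


@dataclass(frozen=True)
class ClosedChamberConfig:
    """One closed-chamber experiment: chamber, animals, chemical, kinetics.

    ``physiology`` holds the primitive constants; the absolute flows and
    volumes the ODEs consume are re-derived on demand (:attr:`derived`), so a
    perturbed copy of any primitive value stays self-consistent.
    """

    c0_ppm: float = 500.0
    v_chamber: float = 9.0
    n_rats: int = 3
    k_loss: float = 0.025
    hypothesis: str = "two_pathway"
    metabolic: MetabolicParamsTwoPathway | MetabolicParamsTwoSite = field(
        default_factory=MetabolicParamsTwoPathway
    )
    physiology: PhysiologicalParams = field(default_factory=PhysiologicalParams)
    chemical: ChemicalParams = field(default_factory=ChemicalParams)

    def __post_init__(self) -> None:
        if self.v_chamber <= 0:
            raise ConfigError(f"v_chamber must be positive, got {self.v_chamber}")
        if not (isinstance(self.n_rats, (int, np.integer)) and self.n_rats >= 1):
            raise ConfigError(f"n_rats must be an integer >= 1, got {self.n_rats!r}")
        if self.k_loss < 0:
            raise ConfigError(f"k_loss must be non-negative, got {self.k_loss}")
        if self.c0_ppm < 0:
            raise ConfigError(f"c0_ppm must be non-negative, got {self.c0_ppm}")
        if self.hypothesis not in HYPOTHESES:
            raise ConfigError(
                f"unknown hypothesis {self.hypothesis!r}; expected one of {HYPOTHESES}"
            )
        expected = (
            MetabolicParamsTwoPathway
            if self.hypothesis == "two_pathway"
            else MetabolicParamsTwoSite
        )
        if not isinstance(self.metabolic, expected):
            raise ConfigError(
                f"hypothesis {self.hypothesis!r} requires {expected.__name__}, "
                f"got {type(self.metabolic).__name__}"
            )

    @property
    def derived(self) -> DerivedPhysiology:
        return derive_physiology(self.physiology)

    def replace(self, **changes) -> "ClosedChamberConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class ModelState:
    """Explicit, named view of one point of the state vector."""

    a_chamber: float
    c_tissue: dict[str, float]
    a_met_liver: float = 0.0
    a_met_kidney: float = 0.0
    a_met_linear: float = 0.0
    a_lost: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.a_chamber]
            + [self.c_tissue[t] for t in TISSUES]
            + [self.a_met_liver, self.a_met_kidney, self.a_met_linear, self.a_lost]
        )

    @classmethod
    def from_vector(cls, y: Sequence[float]) -> "ModelState":
        y = np.asarray(y, dtype=float)
        return cls(
            a_chamber=float(y[0]),
            c_tissue={t: float(y[1 + i]) for i, t in enumerate(TISSUES)},
            a_met_liver=float(y[6]),
            a_met_kidney=float(y[7]),
            a_met_linear=float(y[8]),
            a_lost=float(y[9]),
        )

    @classmethod
    def zero(cls) -> "ModelState":
        return cls(a_chamber=0.0, c_tissue={t: 0.0 for t in TISSUES})


def arterial_concentration(
    c_ven: float, c_chamber: float, qc: float, qp: float, p_b: float
) -> float:
    """Steady-state lung/blood mix: ``(QC*C_ven + QP*C_air)/(QC + QP/P_b)``.

    The value lies between the venous concentration and the air concentration
    expressed in blood equivalents (``P_b * C_air``).
    """
    return (qc * c_ven + qp * c_chamber) / (qc + qp / p_b)


def venous_concentration(
    c_tissue: Mapping[str, float],
    flows: Mapping[str, float],
    partitions: Mapping[str, float],
    qc: float,
) -> float:
    """Flow-weighted venous return, each tissue leaving at ``C_t / P_t``."""
    if set(c_tissue) != set(flows) or set(c_tissue) != set(partitions):
        raise ValueError(
            "compartment keys of concentrations, flows and partitions must match"
        )
    return sum(flows[t] * c_tissue[t] / partitions[t] for t in c_tissue) / qc


def _met_terms(
    cfg: ClosedChamberConfig, c_liv: float, c_kid: float, v_liv: float, v_kid: float
) -> tuple[float, float, float]:
    """(Met_liver, Met_kidney, linear-pathway part of their sum), mg/hr.

    Concentrations are clamped at zero before the rate laws: stiff solvers
    probe slightly negative states near the origin.
    """
    c_liv = max(c_liv, 0.0)
    c_kid = max(c_kid, 0.0)
    p = cfg.metabolic
    if cfg.hypothesis == "two_pathway":
        met_l, met_k = met_rates_two_pathway(c_liv, c_kid, p, v_liv, v_kid)
        linear = p.kgst * (p.liver_share * c_liv * v_liv + p.kidney_share * c_kid * v_kid)
    else:
        met_l, met_k = met_rates_two_site(c_liv, c_kid, p, v_liv, v_kid)
        linear = p.cl2 * (
            p.liver_share * c_liv**2 / (p.km1 + c_liv)
            + p.kidney_share * c_kid**2 / (p.km1 + c_kid)
        )
    return met_l, met_k, linear


def rhs(t: float, state: ModelState, cfg: ClosedChamberConfig) -> ModelState:
    """Time derivative of the model state (mass-conservative by construction).

    Reference implementation on the named state; :func:`simulate` uses an
    equivalent vectorised closure.  ``t`` is accepted for ODE-solver signature
    compatibility; the system is autonomous.
    """
    del t
    d = cfg.derived
    parts = cfg.chemical.tissue_blood_partitions
    c_ch = state.a_chamber / cfg.v_chamber
    c_ven = venous_concentration(state.c_tissue, d.flows, parts, d.qc)
    c_art = arterial_concentration(c_ven, c_ch, d.qc, d.qp, cfg.chemical.p_blood_air)
    met_l, met_k, linear = _met_terms(
        cfg,
        state.c_tissue["liver"],
        state.c_tissue["kidney"],
        d.volumes["liver"],
        d.volumes["kidney"],
    )
    dc = {
        tname: d.flows[tname] * (c_art - state.c_tissue[tname] / parts[tname]) / d.volumes[tname]
        for tname in TISSUES
    }
    dc["liver"] -= met_l / d.volumes["liver"]
    dc["kidney"] -= met_k / d.volumes["kidney"]
    da_ch = (
        cfg.n_rats * d.qp * (c_art / cfg.chemical.p_blood_air - c_ch)
        - cfg.k_loss * state.a_chamber
    )
    return ModelState(
        a_chamber=da_ch,
        c_tissue=dc,
        a_met_liver=met_l,
        a_met_kidney=met_k,
        a_met_linear=linear,
        a_lost=cfg.k_loss * state.a_chamber,
    )


def make_rhs(cfg: ClosedChamberConfig) -> Callable[[float, np.ndarray], np.ndarray]:
    """Vectorised right-hand side ``f(t, y)`` with physiology pre-extracted."""
    d = cfg.derived
    flows = np.array([d.flows[t] for t in TISSUES])
    vols = np.array([d.volumes[t] for t in TISSUES])
    parts = np.array([cfg.chemical.tissue_blood_partitions[t] for t in TISSUES])
    qc, qp = d.qc, d.qp
    p_b = cfg.chemical.p_blood_air
    denom = qc + qp / p_b
    n, k_loss, v_ch = cfg.n_rats, cfg.k_loss, cfg.v_chamber
    v_liv, v_kid = vols[_ILIV], vols[_IKID]
    flow_over_part = flows / parts

    def f(t: float, y: np.ndarray) -> np.ndarray:
        c = y[1:6]
        c_ch = y[0] / v_ch
        c_ven = flow_over_part @ c / qc
        c_art = (qc * c_ven + qp * c_ch) / denom
        met_l, met_k, linear = _met_terms(cfg, c[_ILIV], c[_IKID], v_liv, v_kid)
        dc = flows * (c_art - c / parts) / vols
        dc[_ILIV] -= met_l / v_liv
        dc[_IKID] -= met_k / v_kid
        da_ch = n * qp * (c_art / p_b - c_ch) - k_loss * y[0]
        out = np.empty(10)
        out[0] = da_ch
        out[1:6] = dc
        out[6] = met_l
        out[7] = met_k
        out[8] = linear
        out[9] = k_loss * y[0]
        return out

    return f


@dataclass
class SimulationResult:
    """Dense trajectory of one closed-chamber run."""

    t: np.ndarray
    chamber_mgl: np.ndarray
    chamber_ppm: np.ndarray
    c_tissue: dict[str, np.ndarray]
    a_met_liver: np.ndarray
    a_met_kidney: np.ndarray
    a_met_linear: np.ndarray
    a_lost: np.ndarray
    c_arterial: np.ndarray
    c_venous: np.ndarray
    config: ClosedChamberConfig

    def to_frame(self) -> pd.DataFrame:
        """Tidy table, one row per output time."""
        return pd.DataFrame(
            {
                "time_hr": self.t,
                "chamber_ppm": self.chamber_ppm,
                "chamber_mgl": self.chamber_mgl,
                "c_adipose": self.c_tissue["adipose"],
                "c_rapid": self.c_tissue["rapidly_perfused"],
                "c_slow": self.c_tissue["slowly_perfused"],
                "c_liver": self.c_tissue["liver"],
                "c_kidney": self.c_tissue["kidney"],
                "a_met_liver": self.a_met_liver,
                "a_met_kidney": self.a_met_kidney,
                "a_met_linear": self.a_met_linear,
                "a_lost": self.a_lost,
            }
        )


def simulate(
    cfg: ClosedChamberConfig,
    t_end: float = DEFAULT_T_END,
    t_grid: np.ndarray | None = None,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the closed-chamber system from the bolus at t = 0.

    The initial state is the whole dose in chamber air
    (``A_chamber(0) = c0 [mg/L] * V_chamber``) with naive rats.  ``t_grid``
    (strictly increasing, non-negative) overrides the default 0..t_end grid at
    ``DEFAULT_T_STEP`` resolution.  Integration always starts at t = 0 even if
    the first requested output time is later.
    """
    if t_grid is None:
        if t_end <= 0:
            raise ValueError(f"t_end must be positive, got {t_end}")
        n_steps = int(round(t_end / DEFAULT_T_STEP))
        t_grid = np.linspace(0.0, n_steps * DEFAULT_T_STEP, n_steps + 1)
    else:
        t_grid = np.asarray(t_grid, dtype=float)
        if t_grid.size == 0:
            raise ValueError("t_grid is empty")
        if t_grid[0] < 0 or np.any(np.diff(t_grid) <= 0):
            raise ValueError("t_grid must be non-negative and strictly increasing")

    c0_mgl = ppm_to_mg_per_liter(cfg.c0_ppm, cfg.chemical.mw)
    y0 = np.zeros(10)
    y0[0] = c0_mgl * cfg.v_chamber
    f = make_rhs(cfg)
    sol = solve_ivp(
        f,
        (0.0, float(t_grid[-1]) if t_grid[-1] > 0 else DEFAULT_T_STEP),
        y0,
        method=method,
        t_eval=t_grid if t_grid[-1] > 0 else None,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(
            f"ODE integration failed (method={method}, c0={cfg.c0_ppm} ppm, "
            f"hypothesis={cfg.hypothesis}): {sol.message}"
        )
    if t_grid[-1] > 0:
        t, y = sol.t, sol.y
    else:  # degenerate single-point grid at t = 0
        t, y = t_grid, np.repeat(y0[:, None], t_grid.size, axis=1)

    d = cfg.derived
    flows = np.array([d.flows[tt] for tt in TISSUES])
    parts = np.array([cfg.chemical.tissue_blood_partitions[tt] for tt in TISSUES])
    chamber_mgl = y[0] / cfg.v_chamber
    c_ven = (flows / parts) @ y[1:6] / d.qc
    c_art = (d.qc * c_ven + d.qp * chamber_mgl) / (d.qc + d.qp / cfg.chemical.p_blood_air)
    return SimulationResult(
        t=t,
        chamber_mgl=chamber_mgl,
        chamber_ppm=mg_per_liter_to_ppm(chamber_mgl, cfg.chemical.mw),
        c_tissue={tt: y[1 + i] for i, tt in enumerate(TISSUES)},
        a_met_liver=y[6],
        a_met_kidney=y[7],
        a_met_linear=y[8],
        a_lost=y[9],
        c_arterial=c_art,
        c_venous=c_ven,
        config=cfg,
    )


def mass_balance_residual(result: SimulationResult) -> np.ndarray:
    """Relative mass-balance error at each output time.

    Chamber amount + n_rats * (tissue burden + cumulative metabolised) +
    cumulative chamber leak, compared with the initial dose.  Zero-dose runs
    return zeros.
    """
    cfg = result.config
    vols = cfg.derived.volumes
    body = sum(vols[t] * result.c_tissue[t] for t in TISSUES)
    total = (
        result.chamber_mgl * cfg.v_chamber
        + cfg.n_rats * (body + result.a_met_liver + result.a_met_kidney)
        + result.a_lost
    )
    a0 = ppm_to_mg_per_liter(cfg.c0_ppm, cfg.chemical.mw) * cfg.v_chamber
    if a0 == 0:
        return np.abs(total)
    return (total - a0) / a0
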