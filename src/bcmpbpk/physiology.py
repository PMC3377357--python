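"""Rat physiology and chemical constants for the closed-chamber PBPK model.

The model describes an adult Fischer 344 rat as five perfused tissue
compartments (adipose, rapidly perfused, slowly perfused, liver, kidney)
plus algebraic lung/blood.  Cardiac output scales allometrically with body
weight, ``QC = QCC * BW**0.75``, and alveolar ventilation is tied to it by
the ventilation:perfusion ratio ``QP = QV * QC``.  Four tissues carry
literature flow and volume fractions; the rapidly perfused compartment
closes both budgets: its flow fraction is ``1 - sum(named flow fractions)``
and its volume is what remains of the 91% of body weight that is modelled
as tissue once blood (9% of BW) and the four named tissues are removed.

Default values are for a 0.25 kg adult F344 rat breathing bromochloromethane
(BCM, CH2BrCl).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "TISSUES",
    "NAMED_TISSUES",
    "MOLAR_VOLUME_L",
    "BCM_MW",
    "PhysiologicalParams",
    "ChemicalParams",
    "DerivedPhysiology",
    "derive_physiology",
    "ppm_to_mg_per_liter",
    "mg_per_liter_to_ppm",
]

#: Perfused tissue compartments, in the state-vector order used by the ODE core.
TISSUES = ("adipose", "rapidly_perfused", "slowly_perfused", "liver", "kidney")

#: Tissues with explicit literature fractions; rapidly perfused closes the budget.
NAMED_TISSUES = ("adipose", "slowly_perfused", "kidney", "liver")

#: Gas molar volume, L/mol, at 25 degC and 1 atm (ppm v/v conversions).
MOLAR_VOLUME_L = 24.45

#: Molecular weight of bromochloromethane CH2BrCl, g/mol.
BCM_MW = 129.38

#: Tissue fraction of body weight that the model carries as ODE compartments.
#: Blood is the remaining 9% of BW and is treated algebraically (steady state).
_MODELED_FRACTION = 0.91
_BLOOD_FRACTION = 0.09


def _default_flow_fractions() -> dict[str, float]:
    return {
        "adipose": 0.082,
        "slowly_perfused": 0.257,
        "kidney": 0.138,
        "liver": 0.242,
    }


def _default_volume_fractions() -> dict[str, float]:
    return {
        "slowly_perfused": 0.674,
        "liver": 0.044,
        "kidney": 0.0075,
        "adipose": 0.112,
    }


def _default_partitions() -> dict[str, float]:
    return {
        "liver": 0.7,
        "rapidly_perfused": 0.7,
        "kidney": 0.7,
        "slowly_perfused": 0.267,
        "adipose": 7.8,
    }


@dataclass(frozen=True)
class PhysiologicalParams:
    """Primitive physiological constants for one rat.

    Parameters
    ----------
    bw_kg : body weight, kg.
    qcc : allometric cardiac output coefficient, L/hr/kg^0.75.
    qv_ratio : alveolar ventilation : cardiac output ratio, dimensionless.
    flow_fractions : fraction of cardiac output to each named tissue.
    volume_fractions : fraction of body weight for each named tissue.
    blood_fraction : blood as a fraction of body weight (algebraic compartment).
    body_fraction_modeled : tissue + blood fraction of body weight carried by
        the model (0.91 tissue convention, blood being the complementary 0.09).
    """

    bw_kg: float = 0.25
    qcc: float = 15.0
    qv_ratio: float = 1.7
    flow_fractions: Mapping[str, float] = field(default_factory=_default_flow_fractions)
    volume_fractions: Mapping[str, float] = field(default_factory=_default_volume_fractions)
    blood_fraction: float = _BLOOD_FRACTION
    body_fraction_modeled: float = _MODELED_FRACTION

    def __post_init__(self) -> None:
        if self.bw_kg <= 0:
            raise ValueError(f"bw_kg must be positive, got {self.bw_kg}")
        if self.qcc <= 0:
            raise ValueError(f"qcc must be positive, got {self.qcc}")
        if self.qv_ratio <= 0:
            raise ValueError(f"qv_ratio must be positive, got {self.qv_ratio}")
        for name in NAMED_TISSUES:
            if name not in self.flow_fractions:
                raise ValueError(f"flow_fractions missing tissue {name!r}")
            if name not in self.volume_fractions:
                raise ValueError(f"volume_fractions missing tissue {name!r}")
        for label, fractions in (
            ("flow_fractions", self.flow_fractions),
            ("volume_fractions", self.volume_fractions),
        ):
            for name, f in fractions.items():
                if not 0.0 < f < 1.0:
                    raise ValueError(f"{label}[{name!r}] = {f} outside (0, 1)")
        if not 0.0 < self.blood_fraction < 1.0:
            raise ValueError(f"blood_fraction = {self.blood_fraction} outside (0, 1)")
        flow_sum = sum(self.flow_fractions[t] for t in NAMED_TISSUES)
        if flow_sum >= 1.0:
            raise ValueError(
                f"named flow fractions sum to {flow_sum} >= 1; no flow left for "
                "the rapidly perfused compartment"
            )
        vol_sum = sum(self.volume_fractions[t] for t in NAMED_TISSUES)
        if vol_sum >= self.body_fraction_modeled:
            raise ValueError(
                f"named volume fractions sum to {vol_sum} >= "
                f"{self.body_fraction_modeled}; no volume left for the rapidly "
                "perfused compartment"
            )


@dataclass(frozen=True)
class ChemicalParams:
    """Chemical-specific constants: molecular weight and partition coefficients.

    ``p_blood_air`` is the blood:air partition coefficient; the
    ``tissue_blood_partitions`` map gives tissue:blood coefficients for every
    perfused compartment.  Defaults are for bromochloromethane.
    """

    mw: float = BCM_MW
    p_blood_air: float = 41.5
    tissue_blood_partitions: Mapping[str, float] = field(default_factory=_default_partitions)

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"mw must be positive, got {self.mw}")
        if self.p_blood_air <= 0:
            raise ValueError(f"p_blood_air must be positive, got {self.p_blood_air}")
        for name in TISSUES:
            p = self.tissue_blood_partitions.get(name)
            if p is None:
                raise ValueError(f"tissue_blood_partitions missing tissue {name!r}")
            if p <= 0:
                raise ValueError(f"tissue_blood_partitions[{name!r}] = {p} must be > 0")


@dataclass(frozen=True)
class DerivedPhysiology:
    """Absolute flows and volumes consumed by the ODE system.

    Invariants (by construction): the five flows sum to the cardiac output
    ``qc``; the five tissue volumes sum to ``body_fraction_modeled * BW``
    (0.91 BW by default), with blood a further ``blood_fraction * BW`` carried
    algebraically rather than as an ODE compartment.
    """

    qc: float
    qp: float
    flows: Mapping[str, float]
    volumes: Mapping[str, float]


def derive_physiology(p: PhysiologicalParams) -> DerivedPhysiology:
    """Apply the allometric and closure rules to primitive physiology.

    ``QC = QCC * BW**0.75`` and ``QP = QV * QC``.  The four named tissues get
    ``fraction * QC`` (flow) and ``fraction * BW`` (volume); the rapidly
    perfused compartment takes the remainder of each budget so that total
    perfusion equals cardiac output and total tissue volume equals
    ``body_fraction_modeled * BW``.
    """
    qc = p.qcc * p.bw_kg**0.75
    qp = p.qv_ratio * qc
    flows = {t: p.flow_fractions[t] * qc for t in NAMED_TISSUES}
    flows["rapidly_perfused"] = qc - sum(flows.values())
    volumes = {t: p.volume_fractions[t] * p.bw_kg for t in NAMED_TISSUES}
    volumes["rapidly_perfused"] = (
        p.body_fraction_modeled - sum(p.volume_fractions[t] for t in NAMED_TISSUES)
    ) * p.bw_kg
    flows = {t: flows[t] for t in TISSUES}
    volumes = {t: volumes[t] for t in TISSUES}
    return DerivedPhysiology(qc=qc, qp=qp, flows=flows, volumes=volumes)


def ppm_to_mg_per_liter(c_ppm: float, mw: float = BCM_MW) -> float:
    """Convert a gas-phase concentration from ppm (v/v) to mg/L.

    Uses the 25 degC molar volume (24.45 L/mol), i.e. ``c = ppm * MW / 24450``.
    """
    if mw <= 0:
        raise ValueError(f"mw must be positive, got {mw}")
    return c_ppm * mw / (MOLAR_VOLUME_L * 1000.0)


def mg_per_liter_to_ppm(c_mgl: float, mw: float = BCM_MW) -> float:
    """Inverse of :func:`ppm_to_mg_per_liter` (exact round trip)."""
    if mw <= 0:
        raise ValueError(f"mw must be positive, got {mw}")
    return c_mgl * (MOLAR_VOLUME_L * 1000.0) / mw
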