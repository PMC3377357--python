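"""Metabolic rate laws for the two competing hypotheses.

Both hypotheses place metabolism in liver and kidney, splitting a single
body-level capacity by fixed organ shares (94.8% liver, 5.2% kidney):

* two-pathway — saturable CYP2E1 oxidation (Michaelis-Menten, ``Vmax``,
  ``Km``) plus a first-order glutathione-transferase (GST) conjugation term
  ``kGST * C * V_organ``;
* two-binding-site — a single CYP2E1 enzyme with an active and an effector
  site, rate ``(Vmax1*C + CL2*C**2) / (Km1 + C)``, which is asymptotically
  linear with slope ``CL2`` at high substrate.

Rates are mg/hr; concentrations mg/L; organ volumes L.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "HYPOTHESES",
    "MetabolicParamsTwoPathway",
    "MetabolicParamsTwoSite",
    "met_rates_two_pathway",
    "met_rates_two_site",
]

HYPOTHESES = ("two_pathway", "two_site")

_LIVER_SHARE = 0.948
_KIDNEY_SHARE = 0.052


@dataclass(frozen=True)
class MetabolicParamsTwoPathway:
    """CYP2E1 Michaelis-Menten + first-order GST pathway.

    vmax : maximum oxidation velocity, mg/hr (body-level, split by shares).
    km : affinity constant, mg/L.
    kgst : GST first-order proportionality constant, 1/hr.
    """

    vmax: float = 3.8
    km: float = 0.35
    kgst: float = 4.7
    liver_share: float = _LIVER_SHARE
    kidney_share: float = _KIDNEY_SHARE

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("vmax and km must be positive")
        if self.kgst < 0:
            raise ValueError("kgst must be non-negative")
        if abs(self.liver_share + self.kidney_share - 1.0) > 1e-12:
            raise ValueError("liver_share + kidney_share must equal 1")

    @property
    def vector(self) -> tuple[float, float, float]:
        return (self.vmax, self.km, self.kgst)


@dataclass(frozen=True)
class MetabolicParamsTwoSite:
    """Single-enzyme two-binding-site (atypical CYP2E1) kinetics.

    vmax1 : maximum rate of the active site, mg/hr.
    km1 : affinity constant of the active site, mg/L.
    cl2 : clearance of the effector site, Vmax2/Km2, L/hr.
    """

    vmax1: float = 3.7
    km1: float = 0.3
    cl2: float = 0.047
    liver_share: float = _LIVER_SHARE
    kidney_share: float = _KIDNEY_SHARE

    def __post_init__(self) -> None:
        if self.vmax1 <= 0 or self.km1 <= 0:
            raise ValueError("vmax1 and km1 must be positive")
        if self.cl2 < 0:
            raise ValueError("cl2 must be non-negative")
        if abs(self.liver_share + self.kidney_share - 1.0) > 1e-12:
            raise ValueError("liver_share + kidney_share must equal 1")

    @property
    def vector(self) -> tuple[float, float, float]:
        return (self.vmax1, self.km1, self.cl2)


def met_rates_two_pathway(
    c_liv: float,
    c_kid: float,
    p: MetabolicParamsTwoPathway,
    v_liv: float,
    v_kid: float,
) -> tuple[float, float]:
    """Liver and kidney metabolic rates (mg/hr) under the two-pathway law.

    ``Met_l = share_l * (Vmax*C/(Km+C) + kGST*C*V_liv)`` and analogously for
    kidney with its share and volume.
    """
    if c_liv < 0 or c_kid < 0:
        raise ValueError("tissue concentrations must be non-negative")
    met_l = p.liver_share * (p.vmax * c_liv / (p.km + c_liv) + p.kgst * c_liv * v_liv)
    met_k = p.kidney_share * (p.vmax * c_kid / (p.km + c_kid) + p.kgst * c_kid * v_kid)
    return met_l, met_k


def met_rates_two_site(
    c_liv: float,
    c_kid: float,
    p: MetabolicParamsTwoSite,
    v_liv: float,
    v_kid: float,
) -> tuple[float, float]:
    """Liver and kidney metabolic rates (mg/hr) under two-binding-site kinetics.

    ``Met_l = share_l * (Vmax1*C + CL2*C**2) / (Km1 + C)``; with ``CL2 = 0``
    this is exactly single-site Michaelis-Menten.  Organ volumes are accepted
    for signature parity with the two-pathway law but do not enter the rate.
    """
    if c_liv < 0 or c_kid < 0:
        raise ValueError("tissue concentrations must be non-negative")
    del v_liv, v_kid
    met_l = p.liver_share * (p.vmax1 * c_liv + p.cl2 * c_liv**2) / (p.km1 + c_liv)
    met_k = p.kidney_share * (p.vmax1 * c_kid + p.cl2 * c_kid**2) / (p.km1 + c_kid)
    return met_l, met_k
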