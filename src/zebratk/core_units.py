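"""Compound descriptors, concentration units and bioconcentration arithmetic.

Unit conventions used throughout the package:

* water concentrations are mg/L (canonical) with lossless conversion to and
  from micromolar via the compound's molecular weight;
* internal (body/tissue) concentrations are mg/kg wet weight, with derived
  views in ng/ug (1 mg/kg = 0.001 ng/ug) and mmol/kg;
* rate constants follow first-order toxicokinetic usage: uptake ``k_in`` in
  L kg^-1 h^-1, elimination ``k_out`` in h^-1, so the kinetic
  bioconcentration factor BCF = k_in/k_out has units L/kg.

For an ionizable base the octanol-water distribution coefficient logD at a
given pH is obtained from logP with the monoprotic Henderson-Hasselbalch
correction; the medium pH is always an explicit argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Compound",
    "BcfResult",
    "MCPP",
    "micromolar_to_mg_per_l",
    "mg_per_l_to_micromolar",
    "amount_to_internal_concentration",
    "mg_per_kg_to_ng_per_ug",
    "mg_per_kg_to_mmol_per_kg",
    "log_d",
    "compute_bcf",
]


@dataclass(frozen=True)
class Compound:
    """Physico-chemical identity of a test compound.

    Parameters
    ----------
    name
        Human-readable compound name.
    molecular_weight
        Molar mass in g/mol; must be positive.
    log_p
        log10 octanol-water partition coefficient of the neutral species.
    p_ka
        Acid dissociation constant (log10), basic-centre convention: the
        compound is assumed to be a monoprotic base that is protonated
        (charged) below its pKa.
    """

    name: str
    molecular_weight: float
    log_p: float
    p_ka: float

    def __post_init__(self) -> None:
        if not (self.molecular_weight > 0):
            raise ValueError(f"molecular_weight must be > 0, got {self.molecular_weight}")
        if not math.isfinite(self.log_p):
            raise ValueError("log_p must be finite")
        if not math.isfinite(self.p_ka):
            raise ValueError("p_ka must be finite")


#: meta-chlorophenylpiperazine (mCPP), the basic piperazine psychoactive drug
#: used as the package's worked example throughout.
MCPP = Compound(name="mCPP", molecular_weight=196.68, log_p=2.06, p_ka=8.87)


@dataclass(frozen=True)
class BcfResult:
    """Kinetic bioconcentration factor with its log10 view."""

    bcf: float
    log_bcf: float


def micromolar_to_mg_per_l(conc_um: float, compound: Compound) -> float:
    """Convert a water concentration from micromolar to mg/L.

    ``mg/L = uM * MW / 1000``.  Full precision is kept; rounding to a
    printed precision is a presentation concern.
    """
    if conc_um < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_um}")
    return conc_um * compound.molecular_weight / 1000.0


def mg_per_l_to_micromolar(conc_mg_per_l: float, compound: Compound) -> float:
    """Inverse of :func:`micromolar_to_mg_per_l`."""
    if conc_mg_per_l < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_mg_per_l}")
    return conc_mg_per_l * 1000.0 / compound.molecular_weight


def amount_to_internal_concentration(amount_ng: float, wet_weight_ug: float) -> float:
    """Internal concentration (mg/kg wet weight) from a measured amount.

    ``amount_ng / wet_weight_ug`` is ng/ug, which equals g/kg; multiplying
    by 1000 gives mg/kg.
    """
    if wet_weight_ug <= 0:
        raise ValueError(f"wet_weight must be > 0, got {wet_weight_ug}")
    if amount_ng < 0:
        raise ValueError(f"amount must be >= 0, got {amount_ng}")
    return amount_ng / wet_weight_ug * 1000.0


def mg_per_kg_to_ng_per_ug(conc_mg_per_kg: float) -> float:
    """mg/kg wet weight -> ng/ug (1 mg/kg = 0.001 ng/ug)."""
    return conc_mg_per_kg * 1e-3


def mg_per_kg_to_mmol_per_kg(conc_mg_per_kg: float, compound: Compound) -> float:
    """mg/kg wet weight -> mmol/kg via the molecular weight (g/mol)."""
    return conc_mg_per_kg / compound.molecular_weight


def log_d(compound: Compound, ph: float) -> float:
    """pH-corrected distribution coefficient for a monoprotic base.

    ``logD(pH) = logP - log10(1 + 10^(pKa - pH))``: only the neutral
    fraction partitions into octanol, so logD approaches logP well above
    the pKa and falls one log unit per pH unit below it.

    Parameters
    ----------
    compound
        Compound whose ``log_p``/``p_ka`` are used.
    ph
        Medium pH, strictly inside (0, 14).  Always explicit: results such
        as a distribution coefficient depend sensitively on the assumed pH.
    """
    if not (0.0 < ph < 14.0):
        raise ValueError(f"ph must be in (0, 14), got {ph}")
    return compound.log_p - math.log10(1.0 + 10.0 ** (compound.p_ka - ph))


def compute_bcf(k_in: float, k_out: float) -> BcfResult:
    """Kinetic bioconcentration factor BCF = k_in / k_out (L/kg).

    At steady state under constant water concentration the internal level
    is BCF times the water concentration, so BCF summarizes the balance of
    first-order uptake and elimination.
    """
    if k_in <= 0:
        raise ValueError(f"k_in must be > 0, got {k_in}")
    if k_out <= 0:
        raise ValueError(f"k_out must be > 0, got {k_out}")
    bcf = k_in / k_out
    return BcfResult(bcf=bcf, log_bcf=math.log10(bcf))
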