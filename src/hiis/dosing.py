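"""Treatment protocols and clinical-unit conversions.

The model works internally in molecules/mm^3 (molecular species) and
cells/mm^3 (cell populations); clinicians measure alkaline phosphatase (AP)
activity in IU/L and cytokines in pg/mL.  Everything that crosses that
boundary goes through this module, so the conversion constants live in one
place.

Conversion constants
--------------------
One international unit (IU) of AP is the amount of enzyme converting 1 umol
of substrate per minute.  With a catalytic (specific) activity of
``AP_SPECIFIC_ACTIVITY_U_PER_MG`` and a dimer mass of ``AP_MW_G_PER_MOL``,
1 IU corresponds to a fixed number of enzyme molecules, which gives a linear
IU/L <-> molecules/mm^3 map.  Cytokine mass concentration converts through a
representative interleukin molar mass.  Both maps are linear and exactly
invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "AVOGADRO",
    "AP_MW_G_PER_MOL",
    "AP_SPECIFIC_ACTIVITY_U_PER_MG",
    "CYTOKINE_MW_G_PER_MOL",
    "BLOOD_VOLUME_L",
    "TISSUE_VOLUME_L",
    "AP_IU_PER_L_TO_MOLEC_MM3",
    "CYTOKINE_PG_ML_TO_MOLEC_MM3",
    "IU_TO_BLOOD_CONC",
    "UnitConversion",
    "TreatmentProtocol",
    "ap_to_internal",
    "ap_from_internal",
    "cytokine_to_internal",
    "cytokine_from_internal",
    "infusion_rate_at",
    "total_dose",
    "appired_ii_protocol",
    "placebo_protocol",
]

AVOGADRO = 6.02214076e23

# Dimeric tissue-nonspecific / intestinal AP, ~160 kDa, with a specific
# activity representative of purified bovine intestinal AP preparations.
AP_MW_G_PER_MOL = 1.6e5
AP_SPECIFIC_ACTIVITY_U_PER_MG = 2500.0

# IL-6 scale molar mass; IL-10 (~18 kDa monomer, dimeric in vivo) is mapped
# with the same factor so both cytokine channels share one conversion.
CYTOKINE_MW_G_PER_MOL = 2.1e4

BLOOD_VOLUME_L = 5.0
TISSUE_VOLUME_L = 15.0
_MM3_PER_L = 1.0e6

# molecules per IU = (g per IU) / (g per mol) * N_A
_MOLECULES_PER_IU = (1.0e-3 / AP_SPECIFIC_ACTIVITY_U_PER_MG) / AP_MW_G_PER_MOL * AVOGADRO

#: molecules/mm^3 per (IU/L)
AP_IU_PER_L_TO_MOLEC_MM3 = _MOLECULES_PER_IU / _MM3_PER_L

#: molecules/mm^3 per (pg/mL); 1 pg/mL = 1e-9 g/L
CYTOKINE_PG_ML_TO_MOLEC_MM3 = (1.0e-9 / CYTOKINE_MW_G_PER_MOL) * AVOGADRO / _MM3_PER_L

#: blood concentration increment (molecules/mm^3) per IU of AP given i.v.
IU_TO_BLOOD_CONC = AP_IU_PER_L_TO_MOLEC_MM3 / BLOOD_VOLUME_L


def _require_nonneg(value: float, what: str) -> None:
    if value < 0:
        raise ValueError(f"{what} must be non-negative, got {value!r}")


def ap_to_internal(value_iu_per_l: float) -> float:
    """AP activity in IU/L -> molecules/mm^3."""
    _require_nonneg(value_iu_per_l, "AP activity")
    return value_iu_per_l * AP_IU_PER_L_TO_MOLEC_MM3


def ap_from_internal(value_molec_mm3: float) -> float:
    """molecules/mm^3 -> AP activity in IU/L."""
    _require_nonneg(value_molec_mm3, "AP concentration")
    return value_molec_mm3 / AP_IU_PER_L_TO_MOLEC_MM3


def cytokine_to_internal(value_pg_ml: float) -> float:
    """Cytokine mass concentration in pg/mL -> molecules/mm^3."""
    _require_nonneg(value_pg_ml, "cytokine concentration")
    return value_pg_ml * CYTOKINE_PG_ML_TO_MOLEC_MM3


def cytokine_from_internal(value_molec_mm3: float) -> float:
    """molecules/mm^3 -> cytokine mass concentration in pg/mL."""
    _require_nonneg(value_molec_mm3, "cytokine concentration")
    return value_molec_mm3 / CYTOKINE_PG_ML_TO_MOLEC_MM3


@dataclass(frozen=True)
class UnitConversion:
    """The two linear clinical <-> internal conversion factors."""

    ap_iu_per_l_to_molec_mm3: float = AP_IU_PER_L_TO_MOLEC_MM3
    cytokine_pg_ml_to_molec_mm3: float = CYTOKINE_PG_ML_TO_MOLEC_MM3

    def __post_init__(self) -> None:
        if self.ap_iu_per_l_to_molec_mm3 <= 0 or self.cytokine_pg_ml_to_molec_mm3 <= 0:
            raise ValueError("conversion factors must be positive")


@dataclass(frozen=True)
class TreatmentProtocol:
    """Supplemented-AP dosing schedule: an i.v. bolus at t=0 plus a
    constant-rate infusion over ``infusion_duration_h``.

    ``infusion_rate_iu_per_kg_h`` and ``patient_weight_kg`` are
    informational; when a total infused dose is given it takes precedence
    (trial protocols are specified as totals).  ``scale`` multiplies every
    dose, so ``scale=0`` is an exact placebo and ``scale=2, 3`` are the
    doubled/tripled regimens of the dose-escalation experiment.
    """

    bolus_iu: float = 0.0
    infusion_total_iu: float = 0.0
    infusion_duration_h: float = 8.0
    infusion_rate_iu_per_kg_h: float | None = None
    patient_weight_kg: float | None = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        _require_nonneg(self.bolus_iu, "bolus dose")
        _require_nonneg(self.infusion_total_iu, "infusion total")
        _require_nonneg(self.scale, "protocol scale")
        if self.infusion_total_iu > 0 and self.infusion_duration_h <= 0:
            raise ValueError("infusion_duration_h must be > 0 when a dose is infused")

    @property
    def is_placebo(self) -> bool:
        return self.total_dose_iu == 0.0

    @property
    def total_dose_iu(self) -> float:
        return total_dose(self)

    def scaled(self, scale: float) -> "TreatmentProtocol":
        """Same schedule with every dose multiplied by ``scale``."""
        return replace(self, scale=scale)


def infusion_rate_at(t: float, protocol: TreatmentProtocol) -> float:
    """Instantaneous AP infusion rate (IU/h) at time ``t`` hours.

    Piecewise constant: ``infusion_total_iu / infusion_duration_h`` while the
    pump runs, zero afterwards; the bolus is not part of this rate.
    """
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t!r}")
    if protocol.infusion_total_iu <= 0 or t >= protocol.infusion_duration_h:
        return 0.0
    return protocol.scale * protocol.infusion_total_iu / protocol.infusion_duration_h


def total_dose(protocol: TreatmentProtocol) -> float:
    """Total supplemented AP (IU): bolus plus infused dose, times scale."""
    return protocol.scale * (protocol.bolus_iu + protocol.infusion_total_iu)


def appired_ii_protocol(scale: float = 1.0) -> TreatmentProtocol:
    """The high-risk-cohort trial regimen: 1,000 IU bolus followed by an
    8-h infusion totalling 9,000 IU of bovine intestinal AP."""
    return TreatmentProtocol(
        bolus_iu=1000.0,
        infusion_total_iu=8000.0,
        infusion_duration_h=8.0,
        infusion_rate_iu_per_kg_h=5.6,
        scale=scale,
    )


def placebo_protocol() -> TreatmentProtocol:
    """Carrier buffer only: all doses zero."""
    return TreatmentProtocol(bolus_iu=0.0, infusion_total_iu=0.0)
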