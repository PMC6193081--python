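"""Three-compartment ODE model of systemic inflammation with alkaline
phosphatase (AP) kinetics and supplementation-driven TNAP induction.

The body is split into blood, tissue and liver.  A massive surgical insult
loads the blood with inflammation-triggering moieties (ITMs: LPS,
extracellular nucleotides).  In blood, AP is the only effector acting on
ITMs: it binds them 1:1 into ITM-AP complexes that Kupffer cells clear.  The
drop in circulating AP is the distress signal for the liver to flush its
stored AP pool (~5,300 IU) into the bloodstream; the liver then needs about
2 h before de-novo synthesis resumes.  ITMs crossing the endothelial barrier
activate tissue-resident macrophages, which secrete pro-inflammatory
cytokines; these raise endothelial permeability and recruit neutrophils into
tissue, where the neutrophils either die by apoptosis (anti-inflammatory,
cleared by macrophages) or -- if local ITM load stays high -- by necrosis,
which releases further ITMs and sustains inflammation.  Supplemented bovine
AP (bolus + infusion) follows the same kinetics as endogenous AP and, in
addition, drives extra endogenous TNAP release through a reverse-sigmoid
induction term proportional to the supplemented pools.

State variables are concentrations (molecules/mm^3 for molecules,
cells/mm^3 for cells) except ``liver_store`` (IU-equivalents).  The delayed
onset of necrosis and cytokine secretion is realised as a linear chain of
three first-order stages, keeping the system a pure ODE with the prescribed
mean lag.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from . import dosing
from .dosing import IU_TO_BLOOD_CONC, TreatmentProtocol

__all__ = [
    "STATE_NAMES",
    "ImmuneState",
    "InductionParameters",
    "ParamSpec",
    "PARAM_TABLE",
    "ModelParameters",
    "GaussianPulse",
    "ModelError",
    "IntegrationFailure",
    "induction_rate",
    "endothelial_permeability",
    "neutrophil_fate_fluxes",
    "necrosis_itm_release",
    "itm_ap_neutralization",
    "liver_flush_gate",
    "denovo_gate",
    "rhs",
]

#: volume ratio blood : tissue used to conserve amounts across transport
VOLUME_RATIO = dosing.BLOOD_VOLUME_L / dosing.TISSUE_VOLUME_L


class ModelError(ValueError):
    """Invalid model input (negative rate, malformed state, ...)."""


class IntegrationFailure(RuntimeError):
    """The ODE right-hand side or solver met a non-finite state."""

    def __init__(self, message: str, t: float | None = None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

STATE_NAMES: tuple[str, ...] = (
    "itm_blood",
    "itm_tissue",
    "ap_endo_blood",
    "ap_endo_tissue",
    "ap_supp_blood",
    "ap_supp_tissue",
    "itm_ap_blood",
    "m_r",
    "m_a",
    "n_r",
    "n_a",
    "nd_a",
    "nd_n",
    "ch",
    "ach",
    "d",
    "liver_store",
    "delay_1",
    "delay_2",
    "delay_3",
)

N_STATES = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}


@dataclass
class ImmuneState:
    """All compartmental state variables at one instant.

    Molecular species in molecules/mm^3, cells in cells/mm^3,
    ``liver_store`` in IU-equivalents; ``delay_1..3`` are the dimensionless
    stages of the necrosis/cytokine delay chain; ``d`` is the cumulative
    tissue-damage mediator that feeds ITMs back into the tissue pool.
    """

    itm_blood: float = 0.0
    itm_tissue: float = 0.0
    ap_endo_blood: float = 0.0
    ap_endo_tissue: float = 0.0
    ap_supp_blood: float = 0.0
    ap_supp_tissue: float = 0.0
    itm_ap_blood: float = 0.0
    m_r: float = 0.0
    m_a: float = 0.0
    n_r: float = 0.0
    n_a: float = 0.0
    nd_a: float = 0.0
    nd_n: float = 0.0
    ch: float = 0.0
    ach: float = 0.0
    d: float = 0.0
    liver_store: float = 0.0
    delay_1: float = 0.0
    delay_2: float = 0.0
    delay_3: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "ImmuneState":
        y = np.asarray(y, dtype=float)
        if y.shape != (N_STATES,):
            raise ModelError(f"state vector must have length {N_STATES}, got {y.shape}")
        return cls(**{n: float(v) for n, v in zip(STATE_NAMES, y)})


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InductionParameters:
    """Reverse-sigmoid TNAP induction coefficient.

    The induction rate at time ``t`` is
    ``r_induce_peak / (1 + exp(r_induce * (t - t_ap_delay)))`` multiplied by
    the total supplemented-AP concentration; ``t_ap_delay`` (the sigmoid
    centre, calibrated at 1 h) is the lag before the recuperating liver can
    respond to the supplementation stimulus.
    """

    r_induce_peak: float
    r_induce: float
    t_ap_delay: float
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.r_induce_peak < 0:
            raise ModelError("r_induce_peak must be >= 0")
        if self.r_induce <= 0:
            raise ModelError("r_induce must be > 0")
        if self.t_ap_delay < 0:
            raise ModelError("t_ap_delay must be >= 0")


@dataclass(frozen=True)
class ParamSpec:
    default: float
    lower: float
    upper: float
    free: bool = False


def _p(default, lower, upper, free=False) -> ParamSpec:
    return ParamSpec(float(default), float(lower), float(upper), free)


#: One entry per kinetic/structural parameter: nominal (calibrated) value,
#: bounds used by the fitting routines, and whether the parameter is free by
#: default.  Rates are 1/h; second-order rate constants are mm^3/molecule/h
#: (or per cell); half-saturation constants share the units of their signal.
PARAM_TABLE: dict[str, ParamSpec] = {
    # homeostatic pools / initial conditions
    "ap_baseline_iul": _p(57.3, 20.0, 150.0),       # baseline plasma AP, IU/L
    "liver_store_iu": _p(5300.0, 1000.0, 10000.0),  # releasable hepatic AP pool
    "itm_insult": _p(4.0e9, 0.0, 2.0e10),           # ITMs loaded into blood at t=0
    "mr_pool": _p(300.0, 50.0, 1000.0),             # resting tissue macrophages
    "nr_pool": _p(5000.0, 2000.0, 8000.0),          # resting blood neutrophils
    # ITM-AP interaction
    "k_bind": _p(1.8e-9, 1.0e-10, 1.0e-6),          # blood 1:1 complexation
    "k_dephos": _p(3.0e-8, 1.0e-10, 1.0e-6),         # tissue catalytic dephosphorylation
    "k_kupffer": _p(2.0, 0.1, 20.0),                # complex clearance by Kupffer cells
    # AP turnover and transport
    "k_ap_deg": _p(0.15, 0.01, 2.0, free=True),     # endogenous AP consumption/turnover
    "k_aps_deg": _p(9.0, 0.5, 30.0, free=True),     # supplemented AP clearance (short half-life)
    "k_apt_deg": _p(0.1, 0.01, 2.0),                # tissue AP turnover
    "k_ap_perm": _p(0.05, 0.01, 2.0),                # fenestrae-level AP exchange
    # ITM transport / decay
    "k_itm_perm": _p(1.0, 0.05, 5.0),               # permeability-modulated ITM entry into tissue
    "k_itm_deg_b": _p(0.25, 0.01, 5.0),              # non-AP ITM elimination, blood
    "k_itm_deg_t": _p(0.1, 0.01, 5.0),              # non-AP ITM elimination, tissue
    "k_itm_phag": _p(1.0e-4, 0.0, 1.0e-2),          # ITM phagocytosis by activated neutrophils
    # endothelial permeability (dimensionless multiplier, Hill in CH)
    "perm_base": _p(0.05, 0.001, 0.5),
    "perm_max": _p(1.0, 0.5, 2.0),
    "perm_h_ch": _p(2.0e5, 1.0e4, 1.0e8),
    # liver flush / recovery / de-novo supply
    "k_flush": _p(40.0, 20.0, 100.0),               # stored-pool release rate under insult
    "flush_h_itm": _p(1.0e9, 1.0e7, 5.0e9),         # blood-ITM level triggering the flush
    "k_refill": _p(0.6, 0.05, 5.0),                # store re-synthesis once the insult abates
    "denovo_h": _p(0.5, 0.05, 0.95),                # store fraction gating de-novo supply
    # macrophages
    "k_mact": _p(5.0e-8, 1.0e-10, 1.0e-6),          # activation by ITMs
    "mact_blood_frac": _p(0.05, 0.0, 1.0),          # weight of blood ITMs in activation signal
    "ach_h_inhib": _p(2.9e6, 1.0e5, 1.0e8),         # anti-inflammatory inhibition half-sat
    "k_ma_death": _p(0.05, 0.005, 1.0),
    "k_mr_renew": _p(0.02, 0.001, 0.5),
    # neutrophils
    "k_nr_renew": _p(0.1, 0.01, 1.0),
    "k_diaped": _p(0.3, 0.01, 3.0),                 # recruitment per unit excess permeability
    "k_apop": _p(0.25, 0.01, 2.0),                  # apoptosis (anti-inflammatory exit)
    "k_necro_max": _p(1.0, 0.01, 5.0),              # maximal necrosis rate under ITM pressure
    "necro_h_itm": _p(4.0e7, 1.0e5, 1.0e9),
    "k_nda_phag": _p(1.0e-3, 1.0e-5, 1.0e-1),       # apoptotic-cell removal by macrophages
    "k_ndn_phag": _p(5.0e-4, 1.0e-6, 1.0e-1),       # necrotic-debris removal by macrophages
    "k_nda_deg": _p(0.05, 0.0, 1.0),
    "k_ndn_deg": _p(0.05, 0.0, 1.0),
    "k_itm_release": _p(1.0e4, 0.0, 1.0e7),         # ITMs released per necrotic cell per h
    # cytokines
    "k_ch_ma": _p(8.0e3, 1.0e2, 1.0e6),             # pro-inflammatory secretion by M_A
    "k_ch_ndn": _p(2.0e3, 0.0, 1.0e5),              # pro-inflammatory release from necrosis
    "k_ch_deg": _p(0.35, 0.05, 2.0),
    "k_ach_ma": _p(3.0e2, 0.0, 1.0e5),              # anti-inflammatory secretion by M_A
    "k_ach_phag": _p(4.0, 0.0, 1.0e3),              # anti-inflammatory effect of ND_A clearance
    "k_ach_deg": _p(0.35, 0.05, 2.0),
    # tissue damage mediator D
    "k_d_prod": _p(1.0, 0.0, 100.0),
    "k_d_deg": _p(0.1, 0.01, 2.0),
    "k_d_itm": _p(100.0, 0.0, 1.0e5),
    # delay chain (mean lag of necrosis / cytokine production)
    "tau_delay": _p(1.5, 0.25, 6.0),
    "delay_h_itm": _p(1.0e6, 1.0e5, 1.0e9),
    # TNAP induction (the mechanism under study)
    "r_induce_peak": _p(4.0, 0.0, 50.0, free=True),
    "r_induce": _p(1.5, 0.1, 50.0, free=True),
    "t_ap_delay": _p(1.0, 0.0, 6.0, free=True),
}

_DELAY_STAGES = 3
_FLUSH_HILL = 4   # steepness of the insult-sensing flush trigger
_DENOVO_HILL = 4  # steepness of the de-novo supply gate
_PERM_HILL = 2    # steepness of the permeability response


class ModelParameters:
    """All kinetic rates plus bounds/free flags, with derived homeostatic
    quantities.

    Constructed from the nominal (calibrated) table; individual values can
    be overridden by keyword.  Negative rates or values outside their bounds
    are rejected.  ``induction_enabled`` is the ablation switch: when False
    the TNAP induction term is identically zero.
    """

    def __init__(self, induction_enabled: bool = True, **overrides: float):
        unknown = set(overrides) - set(PARAM_TABLE)
        if unknown:
            raise ModelError(f"unknown parameter(s): {sorted(unknown)}")
        self._values: dict[str, float] = {}
        self._free: dict[str, bool] = {}
        for name, spec in PARAM_TABLE.items():
            value = float(overrides.get(name, spec.default))
            if value < 0:
                raise ModelError(f"parameter {name} must be >= 0, got {value}")
            if not (spec.lower <= value <= spec.upper):
                raise ModelError(
                    f"parameter {name}={value} outside bounds [{spec.lower}, {spec.upper}]"
                )
            self._values[name] = value
            self._free[name] = spec.free
        self.induction_enabled = bool(induction_enabled)

    # -- attribute-style access to values ---------------------------------
    def __getattr__(self, name: str) -> float:
        try:
            return self.__dict__["_values"][name]
        except KeyError:
            raise AttributeError(name) from None

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ModelParameters)
            and self._values == other._values
            and self.induction_enabled == other.induction_enabled
        )

    def value(self, name: str) -> float:
        return self._values[name]

    def bounds(self, name: str) -> tuple[float, float]:
        spec = PARAM_TABLE[name]
        return (spec.lower, spec.upper)

    def is_free(self, name: str) -> bool:
        return self._free[name]

    @property
    def free_names(self) -> list[str]:
        return [n for n, f in self._free.items() if f]

    def set_free(self, names: Iterable[str], free: bool = True) -> None:
        for n in names:
            if n not in self._free:
                raise ModelError(f"unknown parameter: {n}")
            self._free[n] = free

    def with_updates(
        self, induction_enabled: bool | None = None, **overrides: float
    ) -> "ModelParameters":
        values = dict(self._values)
        values.update(overrides)
        enabled = self.induction_enabled if induction_enabled is None else induction_enabled
        out = ModelParameters(induction_enabled=enabled, **values)
        out._free = dict(self._free)
        return out

    @property
    def induction(self) -> InductionParameters:
        return InductionParameters(
            r_induce_peak=self.r_induce_peak,
            r_induce=self.r_induce,
            t_ap_delay=self.t_ap_delay,
            enabled=self.induction_enabled,
        )

    # -- derived homeostatic quantities -----------------------------------
    @property
    def ap_baseline_conc(self) -> float:
        """Baseline blood AP in molecules/mm^3."""
        return dosing.ap_to_internal(self.ap_baseline_iul)

    @property
    def ap_tissue_baseline_conc(self) -> float:
        """Tissue AP balancing fenestrae exchange against tissue turnover."""
        r = VOLUME_RATIO * self.k_ap_perm
        return r * self.ap_baseline_conc / (self.k_apt_deg + r)

    @property
    def denovo_supply(self) -> float:
        """De-novo AP production (molecules/mm^3/h into blood) that makes the
        zero-insult state an exact fixed point."""
        ap_b = self.ap_baseline_conc
        ap_t = self.ap_tissue_baseline_conc
        loss = self.k_ap_deg * ap_b + self.k_ap_perm * (ap_b - ap_t)
        return loss / denovo_gate(1.0, self)

    def homeostatic_state(self) -> ImmuneState:
        """The resting fixed point: full pools, no inflammation anywhere."""
        s = ImmuneState()
        s.ap_endo_blood = self.ap_baseline_conc
        s.ap_endo_tissue = self.ap_tissue_baseline_conc
        s.m_r = self.mr_pool
        s.n_r = self.nr_pool
        s.liver_store = self.liver_store_iu
        return s

    def initial_state(self) -> ImmuneState:
        """Homeostasis plus the surgical ITM load in blood at t=0."""
        s = self.homeostatic_state()
        s.itm_blood = self.itm_insult
        return s

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "induction_enabled": self.induction_enabled,
            "parameters": {
                name: {
                    "value": self._values[name],
                    "lower": PARAM_TABLE[name].lower,
                    "upper": PARAM_TABLE[name].upper,
                    "free": self._free[name],
                }
                for name in PARAM_TABLE
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelParameters":
        params = data.get("parameters", {})
        values = {name: entry["value"] for name, entry in params.items()}
        out = cls(induction_enabled=bool(data.get("induction_enabled", True)), **values)
        for name, entry in params.items():
            out._free[name] = bool(entry.get("free", PARAM_TABLE[name].free))
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of values + ablation flag, for run manifests."""
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Forcing terms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianPulse:
    """Smooth time-localised ITM source ``A * exp(-(t-c)^2 / (2 w^2))``
    (molecules/mm^3/h into blood); integrates to ``A * w * sqrt(2*pi)``."""

    amplitude: float
    center_h: float
    width_h: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ModelError("pulse amplitude must be >= 0")
        if self.width_h <= 0:
            raise ModelError("pulse width must be > 0")

    def __call__(self, t: float) -> float:
        z = (t - self.center_h) / self.width_h
        if abs(z) > 38.0:  # exp underflow guard
            return 0.0
        return self.amplitude * math.exp(-0.5 * z * z)

    @property
    def integral(self) -> float:
        return self.amplitude * self.width_h * math.sqrt(2.0 * math.pi)


#: first-order delivery rate of the i.v. bolus (1/h); >95% delivered within
#: 0.05 h, smooth for the stiff solver
BOLUS_DELIVERY_RATE = 60.0


def bolus_source(t: float, protocol: TreatmentProtocol) -> float:
    """Supplemented-AP input to blood (molecules/mm^3/h) from the bolus."""
    dose = protocol.scale * protocol.bolus_iu
    if dose <= 0 or t * BOLUS_DELIVERY_RATE > 700.0:
        return 0.0
    return dose * BOLUS_DELIVERY_RATE * math.exp(-BOLUS_DELIVERY_RATE * t) * IU_TO_BLOOD_CONC


def infusion_source(t: float, protocol: TreatmentProtocol) -> float:
    """Supplemented-AP input to blood (molecules/mm^3/h) from the infusion."""
    return dosing.infusion_rate_at(t, protocol) * IU_TO_BLOOD_CONC


# ---------------------------------------------------------------------------
# Mechanism fluxes
# ---------------------------------------------------------------------------


def induction_rate(t: float, params: InductionParameters, ap_supp_total: float) -> float:
    """Endogenous-TNAP induction rate (molecules/mm^3/h).

    Reverse sigmoid in time, proportional to the total supplemented-AP
    concentration (blood + tissue).  Zero when disabled or when no
    supplemented AP is present.
    """
    if ap_supp_total < 0:
        raise ModelError(f"ap_supp_total must be >= 0, got {ap_supp_total!r}")
    if not params.enabled or ap_supp_total == 0.0:
        return 0.0
    x = params.r_induce * (t - params.t_ap_delay)
    if x > 700.0:
        return 0.0
    return params.r_induce_peak / (1.0 + math.exp(x)) * ap_supp_total


def endothelial_permeability(ch: float, params: ModelParameters) -> float:
    """Dimensionless endothelial transport multiplier.

    Baseline (fenestrae-level) at CH=0; rises through intermediate stages
    with pro-inflammatory cytokine load and saturates at ``perm_max``.
    """
    if ch < 0:
        raise ModelError(f"ch must be >= 0, got {ch!r}")
    h = params.perm_h_ch
    frac = ch**_PERM_HILL / (ch**_PERM_HILL + h**_PERM_HILL)
    return params.perm_base + (params.perm_max - params.perm_base) * frac


def _necrosis_pressure(itm_tissue: float, params: ModelParameters) -> float:
    h = params.necro_h_itm
    return itm_tissue**2 / (itm_tissue**2 + h**2)


def neutrophil_fate_fluxes(
    state: ImmuneState, params: ModelParameters
) -> tuple[float, float]:
    """(apoptosis flux, necrosis flux) out of the activated-neutrophil pool.

    Apoptosis is first-order; necrosis requires sustained ITM pressure in
    tissue (Hill in ``itm_tissue``) gated by the delay chain, so the
    necrotic share grows with local inflammation and its onset lags the
    insult.
    """
    apop = params.k_apop * state.n_a
    necro = (
        params.k_necro_max
        * _necrosis_pressure(state.itm_tissue, params)
        * state.delay_3
        * state.n_a
    )
    return apop, necro


def necrosis_itm_release(state: ImmuneState, params: ModelParameters) -> float:
    """ITM source in tissue from lysing necrotic neutrophils (linear in ND_N)."""
    return params.k_itm_release * state.nd_n


def itm_ap_neutralization(
    state: ImmuneState, params: ModelParameters
) -> tuple[float, float]:
    """(blood binding flux, tissue dephosphorylation flux).

    Blood: 1:1 irreversible ITM-AP complexation (consumes both reactants,
    feeds ``itm_ap_blood``).  Tissue: catalytic dephosphorylation (consumes
    ITMs only).  Endogenous and supplemented AP contribute identically.
    """
    bind = params.k_bind * state.itm_blood * (state.ap_endo_blood + state.ap_supp_blood)
    dephos = params.k_dephos * state.itm_tissue * (
        state.ap_endo_tissue + state.ap_supp_tissue
    )
    return bind, dephos


def liver_flush_gate(itm_blood: float, params: ModelParameters) -> float:
    """Insult-sensing switch in [0, 1] driving the liver AP flush."""
    h = params.flush_h_itm
    return itm_blood**_FLUSH_HILL / (itm_blood**_FLUSH_HILL + h**_FLUSH_HILL)


def denovo_gate(store_fraction: float, params: ModelParameters) -> float:
    """De-novo supply gate in (0, 1]: synthesis resumes once the liver store
    has recovered past ``denovo_h`` of capacity (smooth switch)."""
    x = max(store_fraction, 0.0)
    h = params.denovo_h
    return x**_DENOVO_HILL / (x**_DENOVO_HILL + h**_DENOVO_HILL)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------


def rhs(
    t: float,
    y: np.ndarray,
    params: ModelParameters,
    protocol: TreatmentProtocol,
    itm_source=None,
) -> np.ndarray:
    """Full derivative vector d(state)/dt at time ``t`` (hours).

    ``itm_source`` is an optional extra blood-ITM source term (e.g. a
    secondary-insult pulse), callable ``t -> molecules/mm^3/h``.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        bad = STATE_NAMES[int(np.argmin(np.isfinite(y)))]
        raise IntegrationFailure(
            f"non-finite state component {bad!r} at t={t}", t=t, state=y
        )
    s = ImmuneState.from_array(np.maximum(y, 0.0))
    p = params
    rho = VOLUME_RATIO

    perm = endothelial_permeability(s.ch, p)
    bind_b, dephos_t = itm_ap_neutralization(s, p)
    apop, necro = neutrophil_fate_fluxes(s, p)
    release = necrosis_itm_release(s, p)

    # The store tracks an insult-dependent target level L0*(1-H): under a
    # massive insult the target collapses and the excess is flushed into
    # blood at k_flush; during recovery the store is re-synthesised toward
    # the rising target at k_refill.  Release and refill are mutually
    # exclusive by construction, so re-synthesised AP is never leaked back
    # out through a half-open flush gate.
    flush_gate_val = liver_flush_gate(s.itm_blood, p)
    store_target = p.liver_store_iu * (1.0 - flush_gate_val)
    flush_flux_iu = p.k_flush * max(s.liver_store - store_target, 0.0)  # IU/h
    refill_flux_iu = p.k_refill * max(store_target - s.liver_store, 0.0)
    flush_conc = flush_flux_iu * IU_TO_BLOOD_CONC
    denovo = p.denovo_supply * denovo_gate(s.liver_store / p.liver_store_iu, p)
    induce = induction_rate(t, p.induction, s.ap_supp_blood + s.ap_supp_tissue)

    ap_exchange = p.k_ap_perm * (s.ap_endo_blood - s.ap_endo_tissue)
    aps_exchange = p.k_ap_perm * (s.ap_supp_blood - s.ap_supp_tissue)
    itm_entry = p.k_itm_perm * perm * s.itm_blood

    inhib = 1.0 / (1.0 + (s.ach / p.ach_h_inhib) ** 2)
    mact = p.k_mact * s.m_r * (s.itm_tissue + p.mact_blood_frac * s.itm_blood) * inhib
    recruit = p.k_diaped * (perm - p.perm_base) * s.n_r
    phag_nda = p.k_nda_phag * s.m_a * s.nd_a
    phag_ndn = p.k_ndn_phag * s.m_a * s.nd_n

    u = s.itm_tissue / (s.itm_tissue + p.delay_h_itm)
    kd = _DELAY_STAGES / p.tau_delay

    extra_itm = float(itm_source(t)) if itm_source is not None else 0.0
    aps_in = bolus_source(t, protocol) + infusion_source(t, protocol)

    dy = np.empty(N_STATES)
    dy[IDX["itm_blood"]] = (
        extra_itm - itm_entry - bind_b - p.k_itm_deg_b * s.itm_blood
    )
    dy[IDX["itm_tissue"]] = (
        rho * itm_entry
        - dephos_t
        - p.k_itm_phag * s.n_a * s.itm_tissue
        - p.k_itm_deg_t * s.itm_tissue
        + release
        + p.k_d_itm * s.d
    )
    dy[IDX["ap_endo_blood"]] = (
        flush_conc
        + denovo
        + induce
        - p.k_bind * s.itm_blood * s.ap_endo_blood
        - p.k_ap_deg * s.ap_endo_blood
        - ap_exchange
    )
    dy[IDX["ap_endo_tissue"]] = rho * ap_exchange - p.k_apt_deg * s.ap_endo_tissue
    dy[IDX["ap_supp_blood"]] = (
        aps_in
        - p.k_bind * s.itm_blood * s.ap_supp_blood
        - p.k_aps_deg * s.ap_supp_blood
        - aps_exchange
    )
    dy[IDX["ap_supp_tissue"]] = rho * aps_exchange - p.k_apt_deg * s.ap_supp_tissue
    dy[IDX["itm_ap_blood"]] = bind_b - p.k_kupffer * s.itm_ap_blood
    dy[IDX["m_r"]] = p.k_mr_renew * (p.mr_pool - s.m_r) - mact
    dy[IDX["m_a"]] = mact - p.k_ma_death * s.m_a
    dy[IDX["n_r"]] = p.k_nr_renew * (p.nr_pool - s.n_r) - recruit
    dy[IDX["n_a"]] = rho * recruit - apop - necro
    dy[IDX["nd_a"]] = apop - phag_nda - p.k_nda_deg * s.nd_a
    dy[IDX["nd_n"]] = necro - phag_ndn - p.k_ndn_deg * s.nd_n
    dy[IDX["ch"]] = (
        p.k_ch_ma * s.m_a * s.delay_3 * inhib
        + p.k_ch_ndn * s.nd_n
        - p.k_ch_deg * s.ch
    )
    dy[IDX["ach"]] = (
        p.k_ach_ma * s.m_a * s.delay_3
        + p.k_ach_phag * s.m_a * s.nd_a
        - p.k_ach_deg * s.ach
    )
    dy[IDX["d"]] = p.k_d_prod * s.nd_n - p.k_d_deg * s.d
    dy[IDX["liver_store"]] = -flush_flux_iu + refill_flux_iu
    dy[IDX["delay_1"]] = kd * (u - s.delay_1)
    dy[IDX["delay_2"]] = kd * (s.delay_1 - s.delay_2)
    dy[IDX["delay_3"]] = kd * (s.delay_2 - s.delay_3)
    return dy
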