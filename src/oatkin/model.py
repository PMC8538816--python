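"""Core kinetic model of OAT1-mediated indoxyl sulfate (IS) transport.

Two closed-compartment ODE systems describe IS movement across a polarized
proximal-tubule cell monolayer:

* the *fitting model* — two compartments (well medium, cell cytosol) joined
  by the basolateral membrane, used to estimate transporter parameters from
  intracellular uptake time series measured in the absence of albumin;
* the *standard model* — three compartments (blood, cell, dialysate), in
  which IS must first bind human serum albumin (HSA) and the IS-albumin
  complex is the substrate presented to the OAT1 carrier; BCRP-mediated
  efflux across the apical membrane delivers IS into the dialysate.

Unit scheme
-----------
Volumetric species are carried in µM, membrane species (free and IS-bound
OAT1) in molecules µm⁻², and time in seconds.  Membrane reaction rates are
surface flux densities in molecules µm⁻² s⁻¹; they enter a volumetric
balance only after multiplication by the membrane-to-volume conversion
factor ``u = area / (N_A · volume)`` of the receiving compartment.  Membrane
species evolve directly in molecules µm⁻² s⁻¹, which makes conservation of
total IS and of total OAT1 hold by construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "AVOGADRO",
    "AlbuminParameters",
    "CompartmentGeometry",
    "EffluxParameters",
    "FittingState",
    "InvalidGeometryError",
    "InvalidStateError",
    "StandardState",
    "TransportParameters",
    "UptakeCase",
    "UremicFactors",
    "complex_binding_rate",
    "efflux_flux",
    "fitting_model_rhs",
    "membrane_to_volume_factor",
    "standard_model_rhs",
    "uptake_flux",
]

AVOGADRO = 6.022e23
"""Avogadro's constant, molecules mol⁻¹."""

_UM3_PER_L = 1e15  # µm³ in one liter
_UL_PER_L = 1e6  # µL in one liter
_UM2_PER_CM2 = 1e8  # µm² in one cm²


class InvalidGeometryError(ValueError):
    """Raised for non-positive compartment volumes or membrane areas."""


class InvalidStateError(ValueError):
    """Raised when a state vector contains negative concentrations."""


class UptakeCase(enum.IntEnum):
    """Candidate rate laws for the OAT1 uptake boundary flux.

    MASS_ACTION          J = kf_uptake · C · OAT1
    MICHAELIS_MENTEN     J = Vmax · C / (Km + C)
    MM_TIMES_OAT1        J = Vmax · C / (Km + C) · OAT1
    MM_TIMES_C_OAT1      J = Vmax · C / (Km + C) · C · OAT1

    with C the driving concentration (free IS in the fitting model, the
    IS-albumin complex in the standard model) and OAT1 the free carrier
    surface density.
    """

    MASS_ACTION = 1
    MICHAELIS_MENTEN = 2
    MM_TIMES_OAT1 = 3
    MM_TIMES_C_OAT1 = 4


# --------------------------------------------------------------------------
# parameter and state containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CompartmentGeometry:
    """Compartment volumes and membrane areas of the 96-well monolayer setup.

    Parameters
    ----------
    well_or_blood_volume : float
        Volume of the well (fitting model) or blood (standard model)
        compartment, µL.
    cell_volume : float
        Volume of the cell monolayer, µm³.
    dialysate_volume : float
        Volume of the dialysate compartment, µL (standard model only).
    basolateral_area, apical_area : float
        Membrane areas, cm².
    """

    well_or_blood_volume: float = 100.0
    cell_volume: float = 3.2e8
    dialysate_volume: float = 100.0
    basolateral_area: float = 0.32
    apical_area: float = 0.32

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise InvalidGeometryError(
                    f"{f.name} must be strictly positive, got {getattr(self, f.name)!r}"
                )

    # volumes in liters, areas in µm² — the units the conversion factor needs
    @property
    def well_volume_l(self) -> float:
        return self.well_or_blood_volume / _UL_PER_L

    @property
    def cell_volume_l(self) -> float:
        return self.cell_volume / _UM3_PER_L

    @property
    def dialysate_volume_l(self) -> float:
        return self.dialysate_volume / _UL_PER_L

    @property
    def basolateral_area_um2(self) -> float:
        return self.basolateral_area * _UM2_PER_CM2

    @property
    def apical_area_um2(self) -> float:
        return self.apical_area * _UM2_PER_CM2


@dataclass(frozen=True)
class TransportParameters:
    """OAT1 carrier parameters.

    ``kf_uptake`` (s⁻¹ µM⁻¹) and ``kf_dissociation`` (s⁻¹) are the
    two-step mass-action binding/release constants; ``oat1_density_0`` is
    the initial free-carrier surface density (molecules µm⁻²).  For the
    Michaelis–Menten uptake variants (cases 2–4) ``vmax_case``/``km_case``
    replace ``kf_uptake`` as the free kinetic constants.
    """

    kf_uptake: float = 1.75e-5
    kf_dissociation: float = 4.18e-4
    oat1_density_0: float = 1.15e7
    uptake_case: UptakeCase = UptakeCase.MASS_ACTION
    vmax_case: float | None = None
    km_case: float | None = None

    def __post_init__(self) -> None:
        if min(self.kf_uptake, self.kf_dissociation, self.oat1_density_0) < 0:
            raise ValueError("transport rates and carrier density must be non-negative")
        case = UptakeCase(self.uptake_case)
        object.__setattr__(self, "uptake_case", case)
        if case is not UptakeCase.MASS_ACTION:
            if self.vmax_case is None or self.km_case is None:
                raise ValueError(f"uptake case {case} requires vmax_case and km_case")
            if self.km_case <= 0:
                raise ValueError("km_case must be strictly positive for cases 2-4")
            if self.vmax_case < 0:
                raise ValueError("vmax_case must be non-negative")


@dataclass(frozen=True)
class EffluxParameters:
    """BCRP apical efflux: saturable Michaelis–Menten pump.

    ``vmax_efflux`` in molecules µm⁻² s⁻¹, ``k_efflux`` in µM.
    """

    vmax_efflux: float = 24000.0
    k_efflux: float = 69.0

    def __post_init__(self) -> None:
        if self.vmax_efflux < 0 or self.k_efflux < 0:
            raise ValueError("efflux parameters must be non-negative")


@dataclass(frozen=True)
class AlbuminParameters:
    """IS-albumin complex formation.

    The pseudo-first-order binding rate saturates in albumin:
    ``KfComplex = bmax · [HSA] / (kd_hsa + [HSA])`` (s⁻¹).  ``hsa_0`` is
    the initial albumin concentration in mM.
    """

    hsa_0: float = 1.0
    bmax: float = 2.70
    kd_hsa: float = 97.92

    def __post_init__(self) -> None:
        if min(self.hsa_0, self.bmax, self.kd_hsa) < 0:
            raise ValueError("albumin parameters must be non-negative")

    @property
    def hsa_0_um(self) -> float:
        """Initial albumin concentration in µM."""
        return self.hsa_0 * 1000.0


@dataclass(frozen=True)
class UremicFactors:
    """Reduction factors mimicking uremic albumin conformational changes.

    ``f1`` multiplies the complex-formation rate, ``f2`` the OAT1 uptake
    rate; (1, 1) is the identity (healthy albumin).
    """

    f1: float = 1.0
    f2: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f1 <= 1.0 and 0.0 <= self.f2 <= 1.0):
            raise ValueError("f1 and f2 must lie in [0, 1]")


IDENTITY_FACTORS = UremicFactors(1.0, 1.0)


@dataclass
class FittingState:
    """Species of the two-compartment fitting model.

    ``is_well``/``is_cell`` in µM, ``oat1_free``/``oat1_is`` in
    molecules µm⁻².
    """

    is_well: float
    oat1_free: float
    oat1_is: float = 0.0
    is_cell: float = 0.0

    species = ("is_well", "oat1_free", "oat1_is", "is_cell")

    def to_array(self) -> np.ndarray:
        return np.array([self.is_well, self.oat1_free, self.oat1_is, self.is_cell])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "FittingState":
        return cls(*map(float, y))


@dataclass
class StandardState:
    """Species of the three-compartment standard model.

    Volumetric species (µM): free IS in blood ``is_b``, free albumin
    ``hsa``, IS-albumin ``complex``, intracellular ``is_cell``, dialysate
    ``is_d``.  Membrane species (molecules µm⁻²): ``oat1_free``,
    ``oat1_is``.
    """

    is_b: float
    hsa: float
    complex: float = 0.0
    oat1_free: float = 1.15e7
    oat1_is: float = 0.0
    is_cell: float = 0.0
    is_d: float = 0.0

    species = ("is_b", "hsa", "complex", "oat1_free", "oat1_is", "is_cell", "is_d")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.is_b, self.hsa, self.complex, self.oat1_free,
             self.oat1_is, self.is_cell, self.is_d]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StandardState":
        return cls(*map(float, y))


# --------------------------------------------------------------------------
# elementary fluxes
# --------------------------------------------------------------------------


def membrane_to_volume_factor(area_um2: float, volume_l: float) -> float:
    """Conversion from a membrane flux density to a volumetric rate.

    A surface reaction running at ``J`` molecules µm⁻² s⁻¹ over a membrane
    of ``area_um2`` µm² changes the concentration of a compartment of
    ``volume_l`` liters by ``J · u`` µM s⁻¹ with::

        u = area / (N_A · volume) · 1e6

    Raises
    ------
    InvalidGeometryError
        If the area or volume is not strictly positive.
    """
    if area_um2 <= 0 or volume_l <= 0:
        raise InvalidGeometryError("membrane area and compartment volume must be > 0")
    return area_um2 / (AVOGADRO * volume_l) * 1e6


def uptake_flux(
    case: UptakeCase | int,
    driving_conc: float,
    oat1_free: float,
    params: TransportParameters,
) -> float:
    """OAT1 uptake boundary flux density (molecules µm⁻² s⁻¹).

    ``driving_conc`` is free IS in the well for the fitting model and the
    IS-albumin complex for the standard model.  See :class:`UptakeCase`
    for the four candidate rate laws.
    """
    if driving_conc < 0 or oat1_free < 0:
        raise InvalidStateError("concentration and carrier density must be non-negative")
    case = UptakeCase(case)
    if case is UptakeCase.MASS_ACTION:
        return params.kf_uptake * driving_conc * oat1_free
    if params.km_case is None or params.vmax_case is None or params.km_case <= 0:
        raise ValueError(f"uptake case {case} requires vmax_case and km_case > 0")
    mm = params.vmax_case * driving_conc / (params.km_case + driving_conc)
    if case is UptakeCase.MICHAELIS_MENTEN:
        return mm
    if case is UptakeCase.MM_TIMES_OAT1:
        return mm * oat1_free
    return mm * driving_conc * oat1_free


def efflux_flux(is_cell: float, params: EffluxParameters) -> float:
    """BCRP efflux flux density (molecules µm⁻² s⁻¹), saturating at Vmax."""
    if is_cell < 0:
        raise InvalidStateError("intracellular concentration must be non-negative")
    return params.vmax_efflux * is_cell / (params.k_efflux + is_cell)


def complex_binding_rate(
    hsa_um: float, params: AlbuminParameters, f1: float = 1.0
) -> float:
    """Pseudo-first-order IS-albumin complex formation rate (s⁻¹).

    ``KfComplex = f1 · bmax · [HSA] / (kd_hsa + [HSA])`` with albumin in
    µM; ``f1`` is the uremic conformational-change reduction factor.
    """
    if hsa_um < 0:
        raise InvalidStateError("albumin concentration must be non-negative")
    if not 0.0 <= f1 <= 1.0:
        raise ValueError("f1 must lie in [0, 1]")
    return f1 * params.bmax * hsa_um / (params.kd_hsa + hsa_um)


# --------------------------------------------------------------------------
# right-hand sides
# --------------------------------------------------------------------------


def _check_nonnegative(y: np.ndarray, tol: float = 0.0) -> None:
    if np.min(y) < -tol:
        raise InvalidStateError(f"negative state entry: {np.asarray(y)!r}")


def fitting_model_rhs(
    y: np.ndarray | FittingState,
    transport: TransportParameters,
    efflux: EffluxParameters,
    geometry: CompartmentGeometry,
    *,
    negative_tol: float = 0.0,
) -> np.ndarray:
    """Time derivative of the two-compartment fitting model.

    Free IS in the well binds free OAT1 on the basolateral membrane
    (uptake), carrier-bound IS is released into the cytosol
    (dissociation), and BCRP pumps intracellular IS back into the well —
    the well plate is the only extracellular compartment in this
    experiment.  Membrane species evolve in molecules µm⁻² s⁻¹;
    volumetric species receive each membrane flux scaled by the
    conversion factor of their own compartment, so total IS and total
    OAT1 are conserved by construction.
    """
    if isinstance(y, FittingState):
        y = y.to_array()
    y = np.asarray(y, dtype=float)
    _check_nonnegative(y, negative_tol)
    is_well, oat1_free, oat1_is, is_cell = np.clip(y, 0.0, None)

    u_well = membrane_to_volume_factor(geometry.basolateral_area_um2, geometry.well_volume_l)
    u_cell_b = membrane_to_volume_factor(geometry.basolateral_area_um2, geometry.cell_volume_l)
    u_cell_a = membrane_to_volume_factor(geometry.apical_area_um2, geometry.cell_volume_l)
    u_well_a = membrane_to_volume_factor(geometry.apical_area_um2, geometry.well_volume_l)

    j_up = uptake_flux(transport.uptake_case, is_well, oat1_free, transport)
    j_dis = transport.kf_dissociation * oat1_is
    j_eff = efflux_flux(is_cell, efflux)

    return np.array(
        [
            -j_up * u_well + j_eff * u_well_a,
            -j_up + j_dis,
            j_up - j_dis,
            j_dis * u_cell_b - j_eff * u_cell_a,
        ]
    )


def standard_model_rhs(
    y: np.ndarray | StandardState,
    transport: TransportParameters,
    efflux: EffluxParameters,
    albumin: AlbuminParameters,
    geometry: CompartmentGeometry,
    factors: UremicFactors = IDENTITY_FACTORS,
    *,
    negative_tol: float = 0.0,
) -> np.ndarray:
    """Time derivative of the three-compartment standard model.

    Free IS in blood binds albumin at the saturable pseudo-first-order
    rate ``f1 · KfComplex``; the complex is the substrate of OAT1 uptake
    (mass action, rate ``f2 · kf_uptake``), which returns albumin to the
    blood; dissociation releases IS into the cytosol and BCRP efflux
    delivers it to the dialysate.  Conservation of total IS molecules,
    of ``hsa + complex`` and of ``oat1_free + oat1_is`` holds by
    construction.
    """
    if isinstance(y, StandardState):
        y = y.to_array()
    y = np.asarray(y, dtype=float)
    _check_nonnegative(y, negative_tol)
    is_b, hsa, cpx, oat1_free, oat1_is, is_cell, is_d = np.clip(y, 0.0, None)

    u_bb = membrane_to_volume_factor(geometry.basolateral_area_um2, geometry.well_volume_l)
    u_bc = membrane_to_volume_factor(geometry.basolateral_area_um2, geometry.cell_volume_l)
    u_ac = membrane_to_volume_factor(geometry.apical_area_um2, geometry.cell_volume_l)
    u_ad = membrane_to_volume_factor(geometry.apical_area_um2, geometry.dialysate_volume_l)

    binding = complex_binding_rate(hsa, albumin, factors.f1) * is_b  # µM s⁻¹
    scaled = replace(
        transport,
        kf_uptake=factors.f2 * transport.kf_uptake,
        vmax_case=None if transport.vmax_case is None else factors.f2 * transport.vmax_case,
    )
    j_up = uptake_flux(transport.uptake_case, cpx, oat1_free, scaled)
    j_dis = transport.kf_dissociation * oat1_is
    j_eff = efflux_flux(is_cell, efflux)

    return np.array(
        [
            -binding,
            -binding + j_up * u_bb,
            binding - j_up * u_bb,
            -j_up + j_dis,
            j_up - j_dis,
            j_dis * u_bc - j_eff * u_ac,
            j_eff * u_ad,
        ]
    )
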