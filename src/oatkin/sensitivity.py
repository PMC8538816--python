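"""Normalized local sensitivity of dialysate IS to parameter perturbations.

For a parameter k perturbed by a fraction δ (default a 20% decrease), the
sensitivity of the cleared IS concentration is::

    S = ( |IS_D(k) − IS_D(k·(1+δ))| / IS_D(k) ) / |δ| · 100   [%]

with both endpoints read at a fixed time (default 17.5 h, the removal
time of the standard scenario).  S ≈ 0% means the model is saturated in
that parameter (e.g. excess albumin in the standard scenario); S near
100% means the parameter is rate-limiting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import StandardState
from .simulate import ModelSpec, SimulationSettings, integrate, scenario

__all__ = [
    "PERTURBABLE_PARAMETERS",
    "SensitivityReport",
    "sensitivity_coefficient",
    "sensitivity_panel",
]

logger = logging.getLogger(__name__)

#: Parameters covered by the panel.  ``bmax`` is the albumin-binding rate
#: amplitude; ``dummy`` is an inert no-op retained as a negative control.
PERTURBABLE_PARAMETERS = (
    "oat1_density_0",
    "kf_uptake",
    "kf_dissociation",
    "hsa_0",
    "bmax",
)

DEFAULT_ENDPOINT_H = 17.5
DEFAULT_DELTA = -0.20


class UndefinedSensitivityError(ZeroDivisionError):
    """Baseline dialysate IS is zero at the endpoint."""


def _perturbed_spec(spec: ModelSpec, parameter: str, factor: float) -> ModelSpec:
    """Rebuild a standard-model spec with one parameter scaled by ``factor``.

    Perturbing the carrier density or the albumin concentration also
    rescales the corresponding initial-state entry.
    """
    state = spec.initial_state
    if not isinstance(state, StandardState):
        raise ValueError("sensitivity analysis is defined on the standard model")
    if parameter == "dummy":
        return spec
    if parameter == "oat1_density_0":
        transport = replace(spec.transport, oat1_density_0=spec.transport.oat1_density_0 * factor)
        return replace(
            spec, transport=transport,
            initial_state=replace(state, oat1_free=state.oat1_free * factor),
        )
    if parameter == "kf_uptake":
        return replace(spec, transport=replace(spec.transport, kf_uptake=spec.transport.kf_uptake * factor))
    if parameter == "kf_dissociation":
        return replace(spec, transport=replace(spec.transport, kf_dissociation=spec.transport.kf_dissociation * factor))
    if parameter == "hsa_0":
        albumin = replace(spec.albumin, hsa_0=spec.albumin.hsa_0 * factor)
        return replace(
            spec, albumin=albumin,
            initial_state=replace(state, hsa=state.hsa * factor),
        )
    if parameter == "bmax":
        return replace(spec, albumin=replace(spec.albumin, bmax=spec.albumin.bmax * factor))
    raise KeyError(
        f"unknown parameter {parameter!r}; perturbable: {PERTURBABLE_PARAMETERS}"
    )


def _is_d_at_endpoint(spec: ModelSpec, endpoint_h: float, rel_tol: float) -> float:
    t_end = endpoint_h * 3600.0
    settings = SimulationSettings.for_standard(t_end=t_end, rel_tol=rel_tol)
    traj = integrate(spec, settings, t_eval=np.array([0.0, t_end]))
    return float(traj["is_d"][-1])


def sensitivity_coefficient(
    spec: ModelSpec | str,
    parameter: str,
    delta_fraction: float = DEFAULT_DELTA,
    endpoint_h: float = DEFAULT_ENDPOINT_H,
    rel_tol: float = 1e-9,
) -> float:
    """Normalized sensitivity (%) of dialysate IS to one parameter.

    ``spec`` may be a scenario name (``standard``, ``physiological``,
    ``uremic``, ``uremic_conformational``) or an explicit standard-model
    spec.  A zero perturbation returns 0 (degenerate input, logged).
    """
    if isinstance(spec, str):
        spec = scenario(spec)
    if delta_fraction == 0.0:
        logger.warning("zero perturbation requested; sensitivity is 0 by convention")
        return 0.0
    baseline = _is_d_at_endpoint(spec, endpoint_h, rel_tol)
    if baseline == 0.0:
        raise UndefinedSensitivityError(
            "dialysate IS is zero at the endpoint; sensitivity undefined"
        )
    perturbed = _is_d_at_endpoint(
        _perturbed_spec(spec, parameter, 1.0 + delta_fraction), endpoint_h, rel_tol
    )
    return abs(baseline - perturbed) / baseline / abs(delta_fraction) * 100.0


@dataclass
class SensitivityReport:
    """Panel of sensitivities for one scenario."""

    scenario: str
    endpoint_h: float
    delta_fraction: float
    baseline_is_d: float
    sensitivities: dict[str, float]  # parameter → percent
    perturbed_is_d: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenario,
                "parameter": list(self.sensitivities),
                "sensitivity_percent": list(self.sensitivities.values()),
                "baseline_is_d_uM": self.baseline_is_d,
                "perturbed_is_d_uM": [self.perturbed_is_d[p] for p in self.sensitivities],
            }
        )


def sensitivity_panel(
    scenarios=("standard", "physiological", "uremic", "uremic_conformational"),
    parameters=PERTURBABLE_PARAMETERS,
    delta_fraction: float = DEFAULT_DELTA,
    endpoint_h: float = DEFAULT_ENDPOINT_H,
    rel_tol: float = 1e-9,
) -> list[SensitivityReport]:
    """One :class:`SensitivityReport` per scenario over the parameter set."""
    reports = []
    for name in scenarios:
        spec = scenario(name)  # raises KeyError on unknown scenario
        baseline = _is_d_at_endpoint(spec, endpoint_h, rel_tol)
        if baseline == 0.0:
            raise UndefinedSensitivityError(f"scenario {name!r}: no IS cleared")
        sens: dict[str, float] = {}
        perturbed: dict[str, float] = {}
        for param in parameters:
            if delta_fraction == 0.0:
                logger.warning("zero perturbation; sensitivities are 0 by convention")
                perturbed[param] = baseline
                sens[param] = 0.0
                continue
            p = _is_d_at_endpoint(
                _perturbed_spec(spec, param, 1.0 + delta_fraction), endpoint_h, rel_tol
            )
            perturbed[param] = p
            sens[param] = abs(baseline - p) / baseline / abs(delta_fraction) * 100.0
        reports.append(
            SensitivityReport(
                scenario=name,
                endpoint_h=endpoint_h,
                delta_fraction=delta_fraction,
                baseline_is_d=baseline,
                sensitivities=sens,
                perturbed_is_d=perturbed,
            )
        )
    return reports
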