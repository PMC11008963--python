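"""Biting scenarios: boundary conditions, E treatments, the 8-simulation
suite, display normalization and region-wise treatment contrasts.

Four static load cases model ant biting.  A *strike* is a bite impact: the
total load acts on the tooth tips (the apical tooth alone or every tooth of
the masticatory margin) while both head articulations (DMA, VMA) are held at
zero displacement.  A *pressure* bite is muscle-driven crushing: the load
acts on the apodeme insertion patch, with the articulations and the engaged
tooth tips all held fixed.  Each scenario runs under two Young's-modulus
treatments: *heterogeneous* (each region its own E) and *homogeneous* (the
blade value applied everywhere), giving 8 simulations in total.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fem import (
    BoundaryConditions,
    ElementField,
    MaterialMap,
    assemble_stiffness,
    compute_stresses,
    solve_static,
)
from .mesh import LabeledMesh

__all__ = [
    "Scenario",
    "DEFAULT_SCENARIOS",
    "STANDARD_LABELS",
    "build_scenario_bcs",
    "apply_E_treatment",
    "run_biting_suite",
    "normalize_stress",
    "region_median_contrast",
    "ScenarioError",
]

#: Default bite load: the 100 000 nN used in all simulations, expressed in uN.
DEFAULT_TOTAL_LOAD_UN = 100.0

NANONEWTON_TO_MICRONEWTON = 1e-3


class ScenarioError(ValueError):
    """Mesh lacks a node set the scenario requires."""


@dataclass(frozen=True)
class Scenario:
    """One biting load case.

    load_mode : "strike" (load at tooth tips) or "pressure" (load at apodeme).
    contact : "apical_tooth" or "masticatory_margin" (which teeth engage).
    total_load_un : total applied force magnitude, uN (default 100 = 1e5 nN).
    load_direction : unit vector of strike forces; default (0, 0, -1), the
        bite-closing axis normal to the synthetic blade plane.
    muscle_direction : unit vector of apodeme (muscle) pull for pressure
        bites; default (-1, 0, 0), from the apodeme insertion toward the head.
    """

    load_mode: str
    contact: str
    total_load_un: float = DEFAULT_TOTAL_LOAD_UN
    load_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    muscle_direction: tuple[float, float, float] = (-1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.load_mode not in ("strike", "pressure"):
            raise ValueError(f"unknown load_mode '{self.load_mode}'")
        if self.contact not in ("apical_tooth", "masticatory_margin"):
            raise ValueError(f"unknown contact '{self.contact}'")
        if self.total_load_un < 0:
            raise ValueError("total load must be non-negative")
        for v in (self.load_direction, self.muscle_direction):
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-8):
                raise ValueError(f"direction {v} is not unit-norm")

    @property
    def label(self) -> str:
        return f"{self.load_mode}_{self.contact}"


DEFAULT_SCENARIOS = (
    Scenario("strike", "masticatory_margin"),
    Scenario("strike", "apical_tooth"),
    Scenario("pressure", "masticatory_margin"),
    Scenario("pressure", "apical_tooth"),
)

#: The fixed simulation labels of the 8-run suite, in canonical order.
STANDARD_LABELS = tuple(
    f"{s.label}_{t}" for s in DEFAULT_SCENARIOS for t in ("heterogeneous", "homogeneous")
)

_CONTACT_SETS = {
    "apical_tooth": "apical_tooth_tip",
    "masticatory_margin": "masticatory_margin_tips",
}


def _require_set(mesh: LabeledMesh, name: str) -> np.ndarray:
    ids = mesh.node_sets.get(name)
    if ids is None or ids.size == 0:
        raise ScenarioError(f"mesh lacks required non-empty node set '{name}'")
    return ids


def build_scenario_bcs(mesh: LabeledMesh, scenario: Scenario) -> BoundaryConditions:
    """Boundary conditions of one biting scenario.

    Strike: forces split equally over the contact tip set; DMA and VMA patches
    fixed.  Pressure: forces split equally over the apodeme patch; DMA, VMA
    and the contact tip set all fixed.  Applied vectors sum to
    ``total_load_un`` times the scenario's direction.
    """
    contact_ids = _require_set(mesh, _CONTACT_SETS[scenario.contact])
    fixed = np.union1d(_require_set(mesh, "dma_patch"), _require_set(mesh, "vma_patch"))
    if scenario.load_mode == "strike":
        loaded = contact_ids
        direction = np.asarray(scenario.load_direction, dtype=float)
    else:
        loaded = _require_set(mesh, "apodeme_patch")
        fixed = np.union1d(fixed, contact_ids)
        direction = np.asarray(scenario.muscle_direction, dtype=float)
    per_node = scenario.total_load_un / loaded.size * direction
    forces = [(int(n), per_node.copy()) for n in loaded]
    return BoundaryConditions(fixed_nodes=fixed, nodal_forces=forces)


def apply_E_treatment(materials: MaterialMap, treatment: str) -> MaterialMap:
    """Heterogeneous: unchanged.  Homogeneous: blade (E, nu) everywhere."""
    if treatment == "heterogeneous":
        return materials
    if treatment != "homogeneous":
        raise ValueError(f"unknown E treatment '{treatment}'")
    if "BLADE" not in materials.properties:
        raise KeyError("homogeneous treatment requires a BLADE material entry")
    blade = materials.properties["BLADE"]
    return MaterialMap({region: blade for region in materials.properties})


def run_biting_suite(
    mesh: LabeledMesh,
    materials: MaterialMap,
    scenarios: tuple[Scenario, ...] = DEFAULT_SCENARIOS,
    treatments: tuple[str, ...] = ("heterogeneous", "homogeneous"),
) -> dict[str, ElementField]:
    """Run every (scenario, treatment) combination; return labeled fields.

    The stiffness matrix is assembled once per treatment and shared across
    the four scenarios of that treatment.
    """
    from .fem import FactorizedStiffness

    fields: dict[str, ElementField] = {}
    for treatment in treatments:
        mats = apply_E_treatment(materials, treatment)
        K = assemble_stiffness(mesh, mats)
        base_fixed = np.union1d(
            _require_set(mesh, "dma_patch"), _require_set(mesh, "vma_patch")
        )
        solver = FactorizedStiffness(K, base_fixed)
        for scenario in scenarios:
            bcs = build_scenario_bcs(mesh, scenario)
            u = solver.solve(bcs)
            label = f"{scenario.label}_{treatment}"
            fields[label] = compute_stresses(mesh, mats, u, label=label)
    return fields


def normalize_stress(field: ElementField, trim_fraction: float = 0.02) -> np.ndarray:
    """Per-element stress scaled to [0, 1] for colour-map display.

    Values are divided by the per-simulation maximum remaining after
    excluding the top ``trim_fraction`` of elements (the same trim the
    statistics pipeline applies to suppress artificially high stresses), then
    clipped to 1 so that trimmed-away peaks saturate the scale.
    """
    vm = field.sigma_vm
    if not np.any(vm > 0):
        raise ValueError("cannot normalize an all-zero stress field")
    k = int(np.ceil(trim_fraction * vm.size))
    ref = np.sort(vm)[vm.size - k - 1] if 0 < k < vm.size else vm.max()
    if ref <= 0:
        ref = vm.max()
    return np.clip(vm / ref, 0.0, 1.0)


def region_median_contrast(
    field_het: ElementField,
    field_hom: ElementField,
    region: str,
    trim_fraction: float = 0.02,
):
    """Compare a region's trimmed von Mises stresses between E treatments.

    Each field is first trimmed of its own top ``trim_fraction`` elements
    (whole-simulation trim, as in the intervals procedure), then the region's
    element stresses are compared with a Mann-Whitney test.  Returns
    ``(median_het, median_hom, W, p)`` where W is the first-sample U
    statistic of the heterogeneous sample.
    """
    from .intervals import StressSample, trim_top_stress
    from .stats import mann_whitney_W

    out = []
    for f in (field_het, field_hom):
        sample = StressSample(f.label, f.sigma_vm, f.volume, region=f.region)
        trimmed = trim_top_stress(sample, trim_fraction)
        vals = trimmed.sigma_vm[trimmed.region == region]
        if vals.size == 0:
            raise ValueError(f"region '{region}' empty after trimming")
        out.append(vals)
    het, hom = out
    result = mann_whitney_W(het, hom)
    return float(np.median(het)), float(np.median(hom)), result.statistic, result.p


def scenario_with(scenario: Scenario, **kwargs) -> Scenario:
    """Return a copy of the scenario with fields replaced (config override)."""
    return replace(scenario, **kwargs)
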