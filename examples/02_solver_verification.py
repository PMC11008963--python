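"""Closed-form verification of the TET10 elastic solver.

An axial bar loaded by a uniform end traction must stretch by FL/(EA); a
slender cantilever (L/h = 10) under a tip shear load must deflect by
FL^3/(3EI).  Deviations reflect discretization only.
"""

import numpy as np

from mandifem.fem import BoundaryConditions, MaterialMap, assemble_stiffness, solve_static, uniform_traction_forces
from mandifem.mesh import promote_tet4_to_tet10, tet_box_mesh

bar = promote_tet4_to_tet10(tet_box_mesh((10.0, 1.0, 1.0), (10, 2, 2)))
mats = MaterialMap({"BLADE": (2.0, 0.0)})  # E = 2 GPa, nu = 0
K = assemble_stiffness(bar, mats)
forces = uniform_traction_forces(bar, bar.node_sets["xmax"], [2.0, 0, 0])  # 2 MPa
u = solve_static(K, BoundaryConditions(bar.node_sets["xmin"], forces))
end = u[bar.node_sets["xmax"], 0].mean()
print(f"bar end displacement: {end:.6f} um (closed form 0.010000)")

beam = promote_tet4_to_tet10(tet_box_mesh((20.0, 2.0, 2.0), (30, 3, 3)))
mats = MaterialMap({"BLADE": (2.0, 0.3)})
K = assemble_stiffness(beam, mats)
tip = beam.node_sets["xmax"]
forces = uniform_traction_forces(beam, tip, [0, 0, 0.25])  # total 1 uN shear
u = solve_static(K, BoundaryConditions(beam.node_sets["xmin"], forces))
I = 2.0 * 2.0**3 / 12.0
print(f"cantilever tip deflection: {u[tip, 2].mean():.4f} um "
      f"(Euler-Bernoulli {20.0**3 / (3 * 2.0e3 * I):.4f})")
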