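"""Full contact geometry for a pair of elongated spherical ellipses.

Builds two aspect-ratio-3.3 ellipses at separation pi/3, computes the
contact function, the tangency point and the outward normals of the grown
ellipses, then the soft-potential forces and torques for an overlapping
configuration.
"""

import math

import numpy as np

from sphellipse import contact_function, make_ellipse, pair_force_torque

xi1, xi2 = 0.5, 0.15  # geodesic semiaxes (radians)
theta = math.pi / 3

eA = make_ellipse([0, 0, 1], [1, 0, 0.2], xi1, xi2)
eB = make_ellipse(
    [math.sin(theta), 0, math.cos(theta)], [0.3, 1, 0], xi1, xi2
)
res = contact_function(eA, eB)
print(f"F = {res.F:.6f}  branch = {res.branch.value}  overlap = {res.overlap}")
print(f"t* = {res.t_star:.6f}  (interpolation parameter of the tangency)")
print(f"contact point v = {np.array2string(res.v, precision=5)}")
print(f"normal of grown A at v: {np.array2string(res.n_a, precision=5)}")
print(f"normal of grown B at v: {np.array2string(res.n_b, precision=5)}")
print("normals antiparallel:", np.linalg.norm(np.cross(res.n_a, res.n_b)) < 1e-5)

# push the pair together until it overlaps, then look at the contact forces
theta2 = 0.55
eC = make_ellipse([math.sin(theta2), 0, math.cos(theta2)], [0.3, 1, 0], xi1, xi2)
res2 = contact_function(eA, eC)
ft = pair_force_torque(eA, eC, "ONE_MINUS")
print(f"\nat separation {theta2}: F = {res2.F:.6f} (overlap)")
print(f"force on B = {np.array2string(ft.force_on_B, precision=5)}")
print(f"torque on A = {np.array2string(ft.torque_on_A, precision=5)}")
print("forces are equal and opposite; torques about the origin cancel exactly.")
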