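"""Branch structure and optimizer cost over the orientation domain.

For a fixed center separation, both in-plane orientation angles of an
elongated pair are swept on a grid; each cell reports which branch supplies
the contact function and how many smallest-eigenvalue evaluations the Brent
maximizer needed (tolerance 1e-7 in t).
"""

import math

import numpy as np

from sphellipse import contact_function, make_ellipse

xi1, xi2 = 0.5, 0.15
theta = 1.8  # past pi/2: antipodal first contacts appear
n = 20

angles = np.linspace(0.0, math.pi, n, endpoint=False)
cB = np.array([math.sin(theta), 0, math.cos(theta)])
tB = np.array([math.cos(theta), 0, -math.sin(theta)])
counts, branch_codes = [], []
code = {"LAMBDA1": "1", "LAMBDA2": "2", "OMEGA": "."}
for pa in angles:
    row = ""
    for pb in angles:
        eA = make_ellipse([0, 0, 1], [math.cos(pa), math.sin(pa), 0], xi1, xi2)
        eB = make_ellipse(cB, math.cos(pb) * tB + math.sin(pb) * np.array([0, 1, 0.0]), xi1, xi2)
        res = contact_function(eA, eB)
        row += code[res.branch.value]
        counts.append(res.n_evals_lambda1)
    branch_codes.append(row)

print(f"branch map over orientations (separation {theta} rad):")
print("  1 = first contact valid, 2 = antipodal first contact, . = clipped\n")
print("\n".join(branch_codes))
print(f"\nlambda1 evaluations: median {np.median(counts):.0f}, max {max(counts)}")
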