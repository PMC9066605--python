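"""Contact function of two circles vs. the closed form.

Two circles on the unit sphere with inverse-squared sine radii alpha and
beta admit a closed-form contact function; this script runs the general
eigenvalue-branch algorithm across the full range of center separations and
compares.  F < 1 means overlap, F = 1 tangency; beyond the clip angle no
valid contact exists and F sticks at Omega = min(alpha, beta).
"""

import math

import numpy as np

from sphellipse import contact_function, make_ellipse
from sphellipse.oracle import circle_contact_reference

alpha, beta = 4.0, 2.0  # sine radii 1/2 and 1/sqrt(2)
ra, rb = math.asin(1 / math.sqrt(alpha)), math.asin(1 / math.sqrt(beta))
eA = make_ellipse([0, 0, 1], [1, 0, 0], ra, ra)

print(f"circles: alpha={alpha} (radius {ra:.4f} rad), beta={beta} (radius {rb:.4f} rad)")
print(f"{'theta':>8} {'F':>10} {'branch':>8} {'closed form':>12}")
for theta in np.linspace(0.3, math.pi - 0.15, 10):
    eB = make_ellipse([math.sin(theta), 0, math.cos(theta)], [1, 0, 0], rb, rb)
    res = contact_function(eA, eB)
    ref = circle_contact_reference(alpha, beta, theta)
    print(f"{theta:8.4f} {res.F:10.6f} {res.branch.value:>8} {ref:12.6f}")
print("\nF rises from overlap (F<1) through tangency (F=1), switches to the")
print("second-contact branch past pi/2, and clips at Omega =", min(alpha, beta))
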