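"""Why the expected count beats the all-desirable probability at scale.

The predicted cross value (PCV) is the probability that a transmitted
gamete is desirable at *every* locus; once any locus lacks the
desirable allele in both parents, the PCV is exactly zero and stops
discriminating between crosses.  The ECV (an expectation, not a joint
probability) keeps ranking them.
"""

import numpy as np

from ecvmate import InheritanceParams, ecv_mendel, pcv

rng = np.random.default_rng(11)

for n_loci in (4, 12, 24):
    params = InheritanceParams(r=np.full(n_loci - 1, 0.2), alpha0=0.5)
    good = rng.random((n_loci, 2)) < 0.8
    ok = rng.random((n_loci, 2)) < 0.5
    print(f"N = {n_loci:3d}:  PCV(good, ok) = {pcv(good, ok, params):.3e}   "
          f"ECV(good, ok) = {float(ecv_mendel(good, ok)):.2f}")

# a single jointly-undesirable locus kills the PCV outright
n_loci = 6
params = InheritanceParams(r=np.full(n_loci - 1, 0.2), alpha0=0.5)
a = np.ones((n_loci, 2), dtype=int)
b = np.ones((n_loci, 2), dtype=int)
a[3] = 0
b[3] = 0
print(f"\nOne locus with no desirable copy in either parent:"
      f"  PCV = {pcv(a, b, params):.1f},  ECV = {float(ecv_mendel(a, b)):.2f}")
print("PCV collapses to 0 while ECV still credits the other five loci.")
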