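"""Ring-puckering itinerary along the glycosidic-bond reaction coordinate.

Generates a synthetic six-ring trajectory whose conformation follows the
skew-boat -> boat -> chair itinerary of an inverting cellulase as a function
of RC2 (the C1-O4 cleavage distance), computes Cremer–Pople coordinates for
every frame, and prints the per-region conformer populations.  A fraction of
~1.0 for 1S3 in the reactant region means nearly every reactant-well frame
classifies as the distorted skew-boat; the product region relaxes to the
undistorted 4C1 chair.
"""

import numpy as np

from glycopmf import DEFAULT_PUCKER_PATH, cremer_pople, generate_ring_trajectory, itinerary

rc2 = np.linspace(1.4, 3.3, 2000)
frames = generate_ring_trajectory(DEFAULT_PUCKER_PATH, rc2, seed=1)

ring = ("O5", "C1", "C2", "C3", "C4", "C5")
puckers = [cremer_pople(fr.positions(ring)) for fr in frames]

result = itinerary(puckers, rc2)
print("conformer fractions per RC2 region:")
print(result.populations.round(3).fillna("").to_string())
print("\nStoddart projection statistics (A):")
print(result.stats.round(3).to_string())
print("\nmajority conformers:", result.majority)
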