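"""Geometric monitors on a labelled coordinate frame.

Builds a toy active-site frame (an idealized sugar ring plus a leaving-group
oxygen, a catalytic-water oxygen and an acid-catalyst proton), defines the
reaction coordinates used to follow an inverting glycosidase mechanism, and
prints their values.  RC2-style coordinates are plain distances (here the
anomeric carbon C1 to the glycosidic oxygen O4: the bond being cleaved);
difference coordinates track proton transfers (positive once the proton is
closer to its destination than to its origin).
"""

import numpy as np

from glycopmf import (
    Frame,
    RCSpec,
    evaluate_rc,
    hbond_present,
    inverse_cremer_pople,
    ring_plane_angle,
)

# idealized skew-boat ring (O5, C1..C5) plus surrounding reaction partners
ring = inverse_cremer_pople(Q=0.57, theta=90.0, phi=210.0, ring_radius=1.45)
extra = {
    "O4": ring[1] + np.array([0.15, 0.1, 1.42]),   # leaving group, pseudo-axial on C1
    "OW1": ring[1] + np.array([-1.2, -1.0, -2.2]),  # nucleophilic water oxygen
    "HE1": ring[1] + np.array([1.1, 0.6, 2.1]),     # acid-catalyst proton
    "OE1": ring[1] + np.array([1.9, 0.9, 2.6]),     # acid-catalyst carboxylate oxygen
}
labels = ("O5", "C1", "C2", "C3", "C4", "C5") + tuple(extra)
coords = np.vstack([ring, *extra.values()])
frame = Frame(labels=labels, elements=("O", "C", "C", "C", "C", "C", "O", "O", "H", "O"),
              coords=coords)

specs = [
    RCSpec(name="rc2_glycosidic_C1_O4", terms=(("C1", "O4", 1.0),)),
    RCSpec(name="rc3_nucleophile_OW1_C1", terms=(("OW1", "C1", 1.0),)),
    RCSpec(name="rc1_proton_transfer", terms=(("HE1", "OE1", 1.0), ("HE1", "O4", -1.0))),
]
for spec in specs:
    print(f"{spec.name:28s} = {evaluate_rc(frame, spec):8.3f} A")

axial = ring_plane_angle(frame, ["O5", "C1", "C2", "C3", "C4", "C5"], ("C1", "O4"))
print(f"{'C1-O4 vs ring mean plane':28s} = {axial:8.1f} deg  (near 90 = pseudo-axial)")

hb = hbond_present(frame, donor="OE1", hydrogen="HE1", acceptor="O4")
print(f"{'OE1-HE1...O4 hydrogen bond':28s} : present={hb.present} "
      f"d(H...A)={hb.h_acceptor_distance:.2f} A angle={hb.dha_angle:.0f} deg")
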