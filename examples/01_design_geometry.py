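"""Closed-form assay design: droplet geometry and Poisson bead loading.

Builds the reference geometry (50 μm droplets from 50 μl of reaction mix)
and shows what Poisson statistics say about bead occupancy at two loadings.
"""

import ddelisa as dd
from ddelisa.units import round_sig, sci_notation

volume_pl = dd.droplet_volume_from_diameter(50.0)
n_droplets = dd.droplet_count(50.0, volume_pl)
print(f"50 um droplet volume: {volume_pl:.2f} pl (~{round_sig(volume_pl, 2):g} pl)")
print(f"droplets from 50 ul:  {n_droplets} (~{sci_notation(n_droplets)})")

for n_beads in (400_000, 600_000):
    lam = dd.bead_loading_lambda(n_beads, n_droplets)
    occ = dd.occupancy_summary(lam)
    print(
        f"beads={n_beads}: lambda={lam:.3f}, occupied droplets={occ.p_occupied:.1%}, "
        f"beads alone in their droplet={occ.singlet_bead_fraction:.1%}"
    )

# invert: how many beads keep ~59% of beads in singlet droplets?
print("beads for singlet fraction >= 0.59:",
      dd.beads_for_singlet_fraction(0.59, n_droplets))

# The occupancy fractions quantify the trade-off the design makes: more
# beads interrogate more sample but put more beads into shared droplets.
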