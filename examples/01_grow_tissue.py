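"""Grow a small isotropic monolayer and report what formed.

Seeds a 0.4 x 0.4 mm patch (reduced from the 0.8 mm preset for a quick
demonstration) with 30% fibroblasts and runs 500 Monte-Carlo steps of the
cellular-Potts dynamics.
"""

import numpy as np

from cardiolattice import builder

state, log = builder.grow("monolayer_iso", seed=1, dims=(160, 160),
                          fb_fraction=0.3, n_mcs=500)

n_cm = int((state.ctype[1:] == 1).sum())
n_fb = int((state.ctype[1:] == 2).sum())
medium = float((state.sigma == 0).mean())
vols = state.vol[1:][state.vol[1:] > 0]

print(f"cells grown: {state.n_cells} ({n_cm} CM, {n_fb} FB)")
print(f"uncovered substrate fraction: {medium:.2f}")
print(f"cell area (subcells): mean {vols.mean():.0f}, "
      f"min {vols.min()}, max {vols.max()}")
print(f"adhesion sites per cell: mean {state.adh_n[1:].mean():.1f}")

# The uncovered fraction drops toward confluence as cells spread to their
# target areas; each cell carries at most N_protr focal-adhesion sites,
# which anchor its protrusions.
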