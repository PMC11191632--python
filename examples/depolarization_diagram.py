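"""A small single-scattering depolarization diagram and its iso-X lines.

Builds the deterministic <S3>(a, lambda) lattice and extracts the straight
depolarization lines a = X * lambda that cross it.  On this window the X ~ 9
and X ~ 12 lines appear; their endpoints on the 600-1500 nm wavelength range
are printed in (a um, lambda nm) form.
"""

import numpy as np

from cplscat import build_diagram, extract_lines

a_grid = np.arange(5.0, 14.01, 0.25)
lambda_grid = np.arange(700.0, 1300.0, 25.0)
grid = build_diagram(a_grid, lambda_grid, "single")

for line in extract_lines(grid):
    (a0, l0), (a1, l1) = line.endpoints
    print(f"X = {line.X_value:5.2f} line: ({a0:5.2f} um, {l0:4.0f} nm) -> "
          f"({a1:5.2f} um, {l1:4.0f} nm), mean S3 deficit {line.strength:.3f}")
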