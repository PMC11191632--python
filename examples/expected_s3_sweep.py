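"""Expected circular polarization after one scattering versus particle size.

Sweeps the generalized size parameter X = a/lambda and locates the
depolarization troughs — the X values at which a single scattering already
destroys circular polarization most effectively.  The second and third
troughs (X ~ 9 and 12) are the working lines of the cancer-detection
application.
"""

import numpy as np

from cplscat import find_depolarization_minima, sweep_expected_s3

grid = np.round(np.arange(1.0, 30.0 + 1e-9, 0.05), 10)
curve = sweep_expected_s3(1.59 / 1.33, grid)
minima = find_depolarization_minima(curve)

print("depolarization troughs of <S3>(X) at m = 1.195:")
print("(trough centers are found on the fringe-smoothed curve; the depth")
print(" column is the deepest raw fringe bottom within +-0.25 of the center)")
for x, prom in minima:
    near = np.abs(curve.x_grid - x) <= 0.25
    depth = curve.expected_s3[near].min()
    print(f"  X = {x:5.2f}   deepest <S3> nearby = {depth:.4f}   prominence {prom:.4f}")
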