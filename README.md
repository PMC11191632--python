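# cplscat

Polarized light scattering for biological particle monitoring: exact Mie
polarimetry plus meridian-plane polarized Monte Carlo transport of
circularly polarized light (CPL) through turbid slabs.

## The problem

When CPL scatters off particles comparable to its wavelength, how much of
its circular polarization (the Stokes component S3) survives depends
sharply on the ratio of particle diameter to wavelength — the generalized
size parameter `X = a/lambda`. At particular X values a single scattering
event already destroys circular polarization efficiently, and multiple
scattering amplifies these *depolarization troughs* dramatically. Plotting
the surviving mean S3 over a (diameter, wavelength) plane produces a
depolarization diagram crossed by straight *iso-X lines* `a = X·lambda`
(X = 9, 12, 22 for relative index m ≈ 1.195). Reading those lines backwards
turns particle sizing into wavelength choice: to monitor one particle
population inside a mixture, pick wavelengths that put it — and only it —
on a depolarization line. The package is aimed at people designing such
measurements: discriminating normal (~6 um) from cancerous (~11 um) cell
nuclei, or red (6–8 um) from white (12–15 um) blood cells.

## The model

Single sphere (relative index `m = n_particle/n_medium`, size parameter
`x = pi a n_medium / lambda`, `a` the diameter):

    S' = M(theta) S,   M = [[M11, M12, 0, 0], [M12, M11, 0, 0],
                            [0, 0, M33, M34], [0, 0, -M34, M33]]

with `M11 = (|S2|^2+|S1|^2)/2`, `M12 = (|S2|^2-|S1|^2)/2`,
`M33 = Re(S2 S1*)`, `M34 = Im(S2 S1*)` from the Mie amplitudes S1, S2.
The expected circular polarization after one scattering,

    <S3>(m, X) = ∫ M33 sin(theta) dtheta / ∫ M11 sin(theta) dtheta,

is the deterministic backbone; a polarized Monte Carlo walks photon packets
through a 12 x 6 mm slab (mu_a = 0.10, mu_s = 6.86 mm^-1), tracking the
Stokes vector in meridian frames, and scores the mean detected S3 on
reflection-side and transmission-side detector strips. See
`docs/methods.md` for the full account.

## Worked example

```sh
python examples/expected_s3_sweep.py
```

```
depolarization troughs of <S3>(X) at m = 1.195:
  X =  4.90   deepest <S3> nearby = 0.9683   prominence 0.0075
  X =  8.70   deepest <S3> nearby = 0.9319   prominence 0.0289
  X = 12.30   deepest <S3> nearby = 0.9413   prominence 0.0121
  ...
```

One scattering leaves >93% of the circular polarization everywhere, but the
troughs at X ≈ 9 and 12 lose three to five times more than their
surroundings — and a random walk through the slab compounds that:

```sh
python examples/monte_carlo_slab.py
```

```
reflection  : <S3> = +0.1104 +- 0.0179   (951 packets, 35 scatterings on average)
transmission: <S3> = +0.0164 +- 0.0373   (247 packets, 75 scatterings on average)
weight ledger closes to 20000.000000 / 20000
```

At the X = 9 condition (9 um particles, 1000 nm) the detected circular
polarization collapses to ~0.1, while off-trough conditions (try 10 or
13 um) retain 0.4–0.5. Wavelength selection then follows the iso-X lines:

```sh
python examples/wavelength_selection.py
```

```
cancer detection (A = 6 um normal, B = 11 um cancerous), reflection:
  670.0 nm  selective for A (X=9 line, contrast 0.016)
  920.0 nm  selective for B (X=12 line, contrast 0.020)
  1220.0 nm  selective for B (X=9 line, contrast 0.039)  [water absorption]
blood monitoring (A = RBC 6-8 um, B = WBC 12-15 um), transmission:
  670-890 nm band  selective for A (X=9 line, contrast 0.030)
  1000-1250 nm band  selective for B (X=12 line, contrast 0.028)  [water absorption]
```

670 nm depolarizes only the 6 um population, 920 nm only the 11 um one; a
comparison of the two readings isolates the cancerous fraction. The other
examples show single-event angular profiles and diagram/line extraction. A
thin CLI (`cplscat mie|single|xsweep|mc|diagram|optimize|fixtures`) wraps
the same calls for shell use.

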