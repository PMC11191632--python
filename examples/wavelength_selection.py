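"""Choosing wavelengths that tell particle populations apart.

Two worked cases: normal (6 um) versus cancerous (11 um) cell nuclei in
reflection geometry, and red (6-8 um) versus white (12-15 um) blood cells in
transmission geometry.  A wavelength qualifies when it puts one population
on an iso-X depolarization line while the other stays in a quiet region;
wavelengths beyond ~1150 nm carry a water-absorption warning.
"""

from cplscat import DiscriminationQuery, recommend

print("cancer detection (A = 6 um normal, B = 11 um cancerous), reflection:")
for r in recommend(DiscriminationQuery(6.0, 11.0, (600.0, 1300.0), "reflection")):
    flag = "  [water absorption]" if r.water_absorption_warning else ""
    print(f"  {r.lambda_nm} nm  selective for {r.selective_for} "
          f"(X={r.rationale_line:g} line, contrast {r.contrast:.3f}){flag}")

print("blood monitoring (A = RBC 6-8 um, B = WBC 12-15 um), transmission:")
for r in recommend(DiscriminationQuery((6.0, 8.0), (12.0, 15.0),
                                       (600.0, 1500.0), "transmission")):
    lo, hi = r.lambda_nm
    flag = "  [water absorption]" if r.water_absorption_warning else ""
    print(f"  {lo:.0f}-{hi:.0f} nm band  selective for {r.selective_for} "
          f"(X={r.rationale_line:g} line, contrast {r.contrast:.3f}){flag}")
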