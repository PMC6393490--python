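"""Interhelical spacing of an ideal coiled coil vs one with a stutter.

Builds two synthetic parallel dimers — one with a regular heptad repeat,
one carrying a four-residue (abcd) stutter insert — and prints their
per-heptad (da + da')/2 spacing side by side, then flags the locally
underwound region.
"""

from coilkit import (CrickParams, StutterSpec, build_crick_dimer,
                     detect_discontinuities, enumerate_heptads,
                     flag_underwound, regular_region_mean, spacing_profile,
                     underwound_regions)

ideal, ideal_assign = build_crick_dimer(CrickParams())
stuttered, stutter_assign = build_crick_dimer(
    CrickParams(), StutterSpec(insert_after=56, local_unwind=20.0))

[disc] = detect_discontinuities(stutter_assign)
print(f"register discontinuity: {disc.kind} at {disc.start}-{disc.end}\n")

ideal_profile = spacing_profile(ideal, ("A", "B"),
                                enumerate_heptads(ideal_assign))
stutter_profile = spacing_profile(stuttered, ("A", "B"),
                                  enumerate_heptads(stutter_assign))

print("   a   a'    d   ideal  stuttered")
for i, rec in enumerate(stutter_profile.records):
    h = rec.heptad
    ideal_mean = (f"{ideal_profile.records[i].mean:6.2f}"
                  if i < len(ideal_profile.records) else "   -  ")
    mark = "  <- stutter row" if not h.regular else ""
    print(f"{h.a:4d} {h.a_prime:4d} {h.d:4d}  {ideal_mean}  "
          f"{rec.mean:6.2f}{mark}")

baseline = regular_region_mean(stutter_profile,
                               exclude=(disc.start - 8, disc.end + 8))
flagged = flag_underwound(stutter_profile, baseline=baseline)
print(f"\nregular-region mean spacing: {baseline:.2f} A")
print(f"underwound regions (first_a, last_a'): {underwound_regions(flagged)}")
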