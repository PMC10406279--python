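"""The consensus QC arithmetic on its own, without any registration.

Shows how the SD gate and the overlap-similarity gate decide, for given
pipeline outputs, whether a measurement is accepted, retried or excluded.
"""

import numpy as np

import fetalicv as f

print("SD gate (fractional rule, 10% of the mean ICV):")
for a, b in [(85.0, 85.0), (80.0, 90.0), (80.0, 100.0)]:
    d = f.sd_gate(a, b, "fraction_of_mean", 0.10)
    print(f"  ICVs {a:6.1f} / {b:6.1f} cm^3 -> SD {d.sd_value:6.3f} vs "
          f"threshold {d.sd_threshold:5.2f} -> {d.verdict}")
print("  (SD is the two-value sample convention |a-b|/sqrt(2))")

print("SD gate (absolute rule, 20 cm^3, the ~30-week reference threshold):")
d = f.sd_gate(240.0, 275.0, "absolute", 20.0)
print(f"  ICVs 240 / 275 cm^3 -> SD {d.sd_value:.3f} -> {d.verdict}")

print("overlap similarity: sum(a*b)/sqrt(sum(a^2)*sum(b^2)) in [0, 1]")
rng = np.random.default_rng(0)
v = f.Volume(rng.uniform(0, 100, (8, 8, 8)), (1, 1, 1), (0, 0, 0))
print(f"  any volume vs itself: {f.overlap_similarity(v, v):.3f}")
lo = np.zeros((8, 8, 8)); lo[:4] = 1.0
hi = np.zeros((8, 8, 8)); hi[4:] = 1.0
print(f"  disjoint supports:    "
      f"{f.overlap_similarity(f.Volume(lo, (1,1,1), (0,0,0)), f.Volume(hi, (1,1,1), (0,0,0))):.3f}")
for s in (0.71, 0.70, 0.42):
    print(f"  similarity {s:.2f} -> {'pass' if f.similarity_gate(s) else 'fail'}"
          " (floor 0.7, inclusive)")
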