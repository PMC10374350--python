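"""Draw a synthetic validation study and summarize its structure.

A study is a set of FIT-positive patients; each colonoscopy yields a
negative-binomial number of diminutive polyps (mean 0.74, SD 1.23), each
polyp a histology from the 73/10/17 adenoma/SSL/hyperplastic mix and three
capture recipes with independently drawn degradations.
"""

from collections import Counter

from polypcadx import StudySpec, generate_study

spec = StudySpec(n_patients=500, seed=11)
study = generate_study(spec)

counts = study.polyps_per_patient
mix = Counter(p.histology for p in study.polyps)
segments = Counter(p.segment for p in study.polyps)
n = len(study)

print(f"patients: {spec.n_patients}, polyps: {n}")
print(f"polyps per colonoscopy: mean {sum(counts) / len(counts):.3f} "
      f"(design 0.74)")
print("histology mix: " + ", ".join(
    f"{c} {mix[c]} ({mix[c] / n:.1%})" for c in ("adenoma", "ssl", "hyperplastic")))
print(f"location: {segments['rectosigmoid']} rectosigmoid / "
      f"{segments['proximal']} proximal")
print("Each polyp carries 3 capture recipes; render one with "
      "study.polyps[0].render(0).")
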