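"""Run the three-image decision protocol on a small held-out study.

Each capture is answered green (high-confidence diagnosis, stop), orange
(low confidence, take another image) or red (localization or quality
failure, take another image); after three images the best low-confidence
diagnosis wins, or the polyp counts as a system failure.
"""

import numpy as np

from polypcadx import (BovwParams, PolypSession, StudySpec, SyntheticSpec,
                       fit_bovw, generate_polyp_image, generate_study,
                       process_capture, success_rate)

rng = np.random.default_rng(3)
classes = ("adenoma", "ssl", "hyperplastic")
train = []
for i in range(36):
    cls = classes[i % 3]
    img, truth = generate_polyp_image(SyntheticSpec(
        polyp_class=cls, polyp_radius=float(rng.uniform(55, 95)), seed=4000 + i))
    train.append((img, truth.box, cls))
model = fit_bovw(train, params=BovwParams(vocabulary_size=48), seed=1)

study = generate_study(StudySpec(n_patients=40, seed=5))
sessions = []
for polyp in study.polyps[:20]:
    session = PolypSession(polyp.polyp_id)
    for k in range(3):
        outcome = process_capture(session, polyp.render(k)[0], model)
        print(f"{polyp.polyp_id} capture {k + 1}: {outcome.signal:6s} ({outcome.reason})")
        if session.is_final:
            break
    final = ("FAILURE" if session.failed
             else f"{session.final.diagnosis} [{session.final.tier}]")
    print(f"{polyp.polyp_id} histology={polyp.histology:12s} final={final}")
    sessions.append(session)

sr = success_rate(sessions)
print(f"\nsuccess rate {sr.n_success}/{sr.n} = {100 * sr.proportion:.1f}% "
      f"(95% CI {100 * sr.ci[0]:.1f}-{100 * sr.ci[1]:.1f}), "
      f"images needed: {dict(sorted(sr.images_needed.items()))}")
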