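"""Calibrate the quality-gate sharpness threshold on synthetic fixtures.

Generates undegraded and blurred (sigma >= 3) captures across classes and
radii at a fixed seed, prints the in-box Laplacian-variance distributions and
the geometric-midpoint threshold, and reports the pass/fail rates that
threshold achieves. The resulting default lives in
``polypcadx.quality.DEFAULT_MIN_SHARPNESS``.

Run from the repository root:  python scripts/calibrate_quality.py
"""

import numpy as np

from polypcadx.quality import sharpness
from polypcadx.synth import Degradation, SyntheticSpec, generate_polyp_image

N = 60
BLUR_SIGMAS = (3.0, 3.5, 4.0, 4.5)


def main(seed: int = 20240101) -> None:
    rng = np.random.default_rng(seed)
    clean, blurred = [], []
    for i in range(N):
        cls = ("adenoma", "ssl", "hyperplastic")[i % 3]
        radius = float(rng.uniform(55, 95))
        s = int(rng.integers(0, 2**31 - 1))
        img, truth = generate_polyp_image(
            SyntheticSpec(polyp_class=cls, polyp_radius=radius, seed=s))
        clean.append(sharpness(img, truth.box))
        img_b, truth_b = generate_polyp_image(
            SyntheticSpec(polyp_class=cls, polyp_radius=radius, seed=s,
                          degradation=Degradation(blur_sigma=BLUR_SIGMAS[i % 4])))
        blurred.append(sharpness(img_b, truth_b.box))
    clean, blurred = np.array(clean), np.array(blurred)
    thr = float(np.sqrt(np.quantile(clean, 0.05) * np.quantile(blurred, 0.95)))
    print(f"undegraded sharpness: min {clean.min():.2f}  p5 {np.quantile(clean, 0.05):.2f} "
          f" median {np.median(clean):.2f}")
    print(f"blurred    sharpness: median {np.median(blurred):.2f} "
          f" p95 {np.quantile(blurred, 0.95):.2f}  max {blurred.max():.2f}")
    print(f"geometric-midpoint threshold: {thr:.2f}")
    for t in (thr, 12.0):
        print(f"threshold {t:6.2f}: undegraded pass {np.mean(clean >= t):.3f}, "
              f"blurred fail {np.mean(blurred < t):.3f}")


if __name__ == "__main__":
    main()
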