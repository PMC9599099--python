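"""The three metrics on hand-checkable inputs.

Computes mean SSIM for an identical pair and a perturbed pair, IoU for a
half-overlapping mask pair, and accuracy from toy confusion counts.
"""

import numpy as np

from mbada import (
    ConfusionCounts,
    FixtureSpec,
    accuracy,
    generate,
    iou,
    mean_ssim_percent,
)

img = generate(FixtureSpec(kind="random_smooth", height=48, width=48, seed=3))
noisy = np.clip(
    img.pixels + 0.05 * np.random.default_rng(0).standard_normal(img.pixels.shape),
    0, 1,
)
print(f"SSIM(image, itself)     = {mean_ssim_percent(img, img):.2f}%   (always 100)")
print(f"SSIM(image, noisy copy) = {mean_ssim_percent(img, noisy):.2f}%")

full = np.ones((8, 8), dtype=int)
half = np.zeros((8, 8), dtype=int)
half[:4] = 1
print(f"IoU(top half, full grid) = {iou(half, full):.2f}   (32 of 64 cells)")

counts = ConfusionCounts(true_positive=3, true_negative=2,
                         false_positive=3, false_negative=2)
print(f"accuracy(TP=3,TN=2,FP=3,FN=2) = {accuracy(counts):.2f}   (5 of 10)")
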