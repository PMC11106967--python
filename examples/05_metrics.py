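"""Evaluation metric arithmetic on explicit counts and printed tables.

Shows the voxel-wise confusion workflow and the harmonic-mean identity
Dice = 2PR/(P+R) = 2TP/(2TP+FP+FN), plus PSNR and the relative
improvement statistic used to compare training with and without the
conventional prefilter.
"""

import numpy as np

from rootct import (
    confusion,
    precision,
    recall,
    dice_from_pr,
    dice_from_counts,
    psnr,
    improvement,
)
from rootct.metrics import round_metric

rng = np.random.default_rng(0)
truth = rng.random((32, 32, 32)) > 0.9
pred = truth.copy()
flip = rng.random(truth.shape) < 0.05
pred ^= flip  # 5% voxel errors

c = confusion(pred, truth)
p, r = precision(c), recall(c)
print(f"counts: TP={c.true_positive} FP={c.false_positive} "
      f"FN={c.false_negative} TN={c.true_negative}")
print(f"precision={p:.3f} recall={r:.3f} "
      f"Dice={dice_from_pr(p, r):.3f} (= {dice_from_counts(c):.3f} from counts)")

# validation-table rows: Dice recomputed from printed precision/recall
rows = [("S0033", 0.377, 0.592), ("S0066", 0.419, 0.634),
        ("S0150", 0.516, 0.685), ("S0300", 0.468, 0.688)]
for name, pp, rr in rows:
    print(f"{name}: P={pp} R={rr} -> Dice={round_metric(dice_from_pr(pp, rr), 3)}")

a = np.zeros((8, 8, 8))
b = np.full((8, 8, 8), 16.0)
print(f"uniform error 16 on the 8-bit scale: PSNR={psnr(a, b, 255.0):.2f} dB")
print(f"loss 0.2 -> 0.1 is a {improvement(0.2, 0.1):.0f}% improvement")
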