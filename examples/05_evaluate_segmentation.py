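"""Object-level evaluation: what mP/mR/mF1/mAP and AJI measure.

Builds a ground truth and a deliberately flawed prediction (one merged pair,
one missed nucleus, one spurious blob) and walks through the metrics.
"""

import numpy as np

from nucsplit3d import LabelVolume, evaluate

gt = np.zeros((48, 16, 16), dtype=np.int32)
pred = np.zeros_like(gt)
for k in range(5):
    gt[9 * k + 1 : 9 * k + 8, 4:12, 4:12] = k + 1
# prediction: merge nuclei 1+2, copy 3 and 4, miss 5, add a spurious blob
pred[1:17, 4:12, 4:12] = 1
pred[19:26, 4:12, 4:12] = 2
pred[28:35, 4:12, 4:12] = 3
pred[40:43, 1:3, 1:3] = 4

report = evaluate(LabelVolume(gt), LabelVolume(pred))
print("per-threshold counts (gt=5 nuclei, pred=4 objects):")
for t, row in report.per_threshold.items():
    print(f"  IoU>={t:.2f}: TP={row['n_tp']} FP={row['n_fp']} FN={row['n_fn']}"
          f"  P={row['precision']:.0f} R={row['recall']:.0f} F1={row['f1']:.0f}")
print(f"mP {report.mean_precision:.1f}  mR {report.mean_recall:.1f}  "
      f"mF1 {report.mean_f1:.1f}  mAP {report.mean_ap:.1f}  (0-100)")
print(f"AJI {report.aji:.3f} — voxel-weighted agreement in [0, 1]; the "
      f"merged pair and the missed nucleus both pull it down")
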