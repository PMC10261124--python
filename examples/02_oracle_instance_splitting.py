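"""Split touching nuclei from a perfect mask and vector field (oracle mode).

With ground-truth inputs the splitter isolates the vector-field machinery:
the gradient map carves inter-nucleus boundaries, conditional erosion makes
seeds, and the watershed assigns every foreground voxel.  Connected-component
labeling of the same mask undercounts whenever nuclei touch — the printed
comparison shows exactly the gap the vector field closes.
"""

import numpy as np
from scipy import ndimage

from nucsplit3d import (
    InstanceSegParams,
    evaluate,
    make_fixture,
    segment_instances,
)

_, labels, field = make_fixture("touching", (64, 64, 64), seed=1)
mask = labels.binary_mask()

n_cc = ndimage.label(mask, structure=np.ones((3, 3, 3)))[1]
seg = segment_instances(mask, field, InstanceSegParams())
report = evaluate(labels, seg)

print(f"ground truth instances:        {labels.labels().size}")
print(f"connected components of mask:  {n_cc}  (touching nuclei merged)")
print(f"vector-field splitter found:   {seg.labels().size}")
print(f"mAP over IoU 0.25..0.45:       {report.mean_ap:.1f} / 100")
print(f"Aggregated Jaccard Index:      {report.aji:.3f}  (1.0 = perfect)")
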