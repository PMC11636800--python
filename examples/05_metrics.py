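"""The evaluation metrics on a worked toy example.

Shows the classification metrics (accuracy, macro F1, invasive-carcinoma
precision/recall/F1) on a small confusion matrix, and the segmentation
IoU/Dice identities on a pair of 4x4 masks.
"""

import numpy as np

from resmtunet.metrics import classification_metrics, confusion_matrix, segmentation_metrics

# two-class toy: 8/2 and 1/9 correct; class 1 plays invasive carcinoma
cm = np.array([[8, 2], [1, 9]])
m = classification_metrics(cm, ic_index=1)
print("confusion matrix:\n", cm)
print({k: round(v, 4) for k, v in m.items()})
# P_ic = 9/11 (column), R_ic = 9/10 (row), F1_ic their harmonic mean.

truth = np.zeros((4, 4), dtype=int)
truth[1:3, 1:3] = 4                       # 4 invasive pixels
pred = np.zeros((4, 4), dtype=int)
pred[1, 1:3] = 4                          # hits 2 of them ...
pred[3, 0:2] = 4                          # ... plus 2 false positives
s = segmentation_metrics([pred], [truth], n_labels=5)
print(f"IoU_ic  = {s.iou_ic:.4f}   (2 shared / 6 in union)")
print(f"Dice_ic = {s.dice_ic:.4f}  (2*2 shared / 8 total)")
print(f"identity Dice = 2 IoU/(1+IoU): {2 * s.iou_ic / (1 + s.iou_ic):.4f}")
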