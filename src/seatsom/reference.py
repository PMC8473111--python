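"""Published benchmark confusion matrices for the improved-map classifier.

These are the reported six-class confusion counts of the ISOM seat-posture
classifier on its two original human-subject evaluation datasets (the raw
pressure recordings themselves were never deposited). They serve as worked
examples for the evaluation layer: feeding them through
:func:`seatsom.metrics.precision_recall_accuracy` reproduces the published
precision/recall/accuracy figures exactly.

Rows = actual class, columns = predicted, order LC, RC, LL, LR, WB, SS;
600 test samples per class in both datasets. Dataset 1 was held out from the
sitters used for training; dataset 2 comes from sitters the model never saw.
"""

from __future__ import annotations

import numpy as np

from .metrics import ConfusionMatrix

__all__ = ["DATASET1_CONFUSION", "DATASET2_CONFUSION"]

#: Held-out split, same 40 sitters as training (overall accuracy 95.67%).
DATASET1_CONFUSION = ConfusionMatrix(np.array([
    [600,   0,   0,   0,   0,   0],
    [  0, 600,   0,   0,   0,   0],
    [ 15,   0, 574,   0,   7,   4],
    [  0,  11,   0, 584,   4,   1],
    [  1,   2,  12,  14, 545,  26],
    [  0,   0,   9,  11,  39, 541],
]))

#: 15 previously unseen sitters (overall accuracy 93.75%).
DATASET2_CONFUSION = ConfusionMatrix(np.array([
    [581,   0,  16,   0,   3,   0],
    [  0, 578,   0,  18,   4,   0],
    [ 18,   0, 571,   0,  10,   1],
    [  0,  18,   0, 577,   5,   0],
    [  3,   6,  11,  10, 533,  37],
    [  4,   0,  16,  10,  35, 535],
]))
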