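"""Bundled reference benchmark from the original driver-stress study.

Validation metrics of twelve stress classifiers — a 1D CNN and a hybrid
1D CNN-LSTM, each trained on six device subsets (SRAD physiological
signals; AffectiveROAD chest strap BH, wrist devices E4-L / E4-R, and
their fusions) — together with the criteria weights used when the
classifiers are ranked with EDAS, and the published validation confusion
counts.  These values are *inputs* to the ranking and metric machinery:
worked examples, the CLI demo, and the regression suite all consume them.

Metric order everywhere is (ACC, RCL, PRC, F1, SPC).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MODEL_NAMES",
    "CRITERIA_WEIGHTS",
    "TWO_CLASS_METRICS",
    "FUSED_THREE_CLASS_LOW",
    "CONFUSION_COUNTS",
    "two_class_matrix",
]

#: Device-subset alternatives, in canonical order.
MODEL_NAMES = ("SRAD", "BH", "E4-L", "E4-R", "E4-(L+R)", "BH+E4-(L+R)")

#: Published criteria weights for (ACC, RCL, PRC, F1, SPC); they sum to
#: 0.99993 and are used exactly as printed (renormalization is opt-in).
CRITERIA_WEIGHTS = (0.4176, 0.2850, 0.1453, 0.0844, 0.0676)

#: Two-level per-class validation metrics, keyed by (architecture, state):
#: architecture in {"cnn", "cnn_lstm"}, state in {"relaxed", "stressed"}.
#: Rows follow MODEL_NAMES; columns are (ACC, RCL, PRC, F1, SPC).
TWO_CLASS_METRICS = {
    ("cnn", "relaxed"): np.array(
        [
            [0.9271, 0.8774, 0.9118, 0.8942, 0.9541],
            [0.8909, 0.9278, 0.8267, 0.8743, 0.8654],
            [0.8653, 0.8072, 0.9394, 0.8683, 0.9363],
            [0.8825, 0.8636, 0.8693, 0.8664, 0.8974],
            [0.9235, 0.9776, 0.8617, 0.9160, 0.8833],
            [0.9564, 0.9772, 0.9224, 0.9490, 0.9417],
        ]
    ),
    ("cnn", "stressed"): np.array(
        [
            [0.9271, 0.9541, 0.9350, 0.9444, 0.8774],
            [0.8909, 0.8654, 0.9454, 0.9036, 0.9278],
            [0.8653, 0.9363, 0.7989, 0.8622, 0.8073],
            [0.8825, 0.8974, 0.8929, 0.8951, 0.8636],
            [0.9235, 0.8833, 0.9815, 0.9298, 0.9776],
            [0.9564, 0.9417, 0.9831, 0.9620, 0.9772],
        ]
    ),
    ("cnn_lstm", "relaxed"): np.array(
        [
            [0.9180, 0.9041, 0.8742, 0.8889, 0.9261],
            [0.9545, 0.9857, 0.9079, 0.9452, 0.9340],
            [0.8882, 0.9007, 0.8500, 0.8746, 0.8788],
            [0.9065, 0.9099, 0.8649, 0.8868, 0.9041],
            [0.9465, 0.9555, 0.9328, 0.9440, 0.9384],
            [0.9659, 0.9395, 0.9873, 0.9628, 0.9893],
        ]
    ),
    ("cnn_lstm", "stressed"): np.array(
        [
            [0.9181, 0.9261, 0.9444, 0.9352, 0.9041],
            [0.9545, 0.9340, 0.9900, 0.9612, 0.9857],
            [0.8882, 0.8788, 0.9206, 0.8992, 0.9007],
            [0.9065, 0.9041, 0.9371, 0.9203, 0.9099],
            [0.9465, 0.9384, 0.9593, 0.9487, 0.9555],
            [0.9659, 0.9893, 0.9486, 0.9685, 0.9395],
        ]
    ),
}

#: Three-level metrics of the fused BH+E4-(L+R) CNN for the low-stress class;
#: exactly reproducible from the one-vs-rest counts TP=190, FN=9, FP=15, TN=309.
FUSED_THREE_CLASS_LOW = {
    "ACC": 0.9541, "RCL": 0.9548, "PRC": 0.9268, "F1": 0.9406, "SPC": 0.9537,
}

#: Published validation confusion counts of the fused BH+E4-(L+R) models.
#: Two-level rows are (relaxed, stressed); three-level rows are
#: (low, medium, high).  Off-diagonal counts of three-level rows other than
#: "low" were not printed per cell; row totals and diagonals were, and the
#: splits below respect them (the derived quantities only use diagonals and
#: row/column totals that were printed).
CONFUSION_COUNTS = {
    ("cnn", "two"): np.array([[214, 5], [18, 291]]),
    ("cnn_lstm", "two"): np.array([[233, 15], [3, 277]]),
    ("cnn", "three"): np.array([[190, 3, 6], [6, 34, 10], [9, 41, 224]]),
    ("cnn_lstm", "three"): np.array([[214, 3, 8], [6, 47, 8], [12, 26, 199]]),
}


def two_class_matrix(architecture: str, state: str):
    """(names, values) for one architecture/state pair of the benchmark."""
    return MODEL_NAMES, TWO_CLASS_METRICS[(architecture, state)].copy()
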